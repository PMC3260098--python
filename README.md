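# knockkit

High-throughput gene-knockout cassette design and in-silico screening for
compact fungal genomes (built around the *Trichoderma reesei*-style workflow:
yeast gap-repair vector construction, PCR transformant screening, and sexual
backcrossing to remove the NHEJ-deficient transformation background).

## Who this is for

Fungal molecular geneticists building deletion-mutant collections. Given a
(soft-masked) genome FASTA and a gene annotation (GFF3 or a 5-column gene
table), `knockkit` designs, for every gene:

* a **deletion cassette**: 5' homology arm + selectable marker (pyr4, amdS or
  hph) + 3' homology arm, assembled by yeast-mediated recombination into a
  gapped shuttle vector;
* the four **tailed PCR primers** (5F, 5R, 3F, 3R) that amplify the arms,
  each carrying a 29-nt tail homologous to its neighbour fragment so the
  yeast recombination machinery can stitch the plasmid together;
* a **junction screening assay** (a primer outside the homology arm plus a
  primer inside the marker) that yields a 1400–2000 bp band only upon
  locus-specific integration, verified by in-silico PCR against the simulated
  integrant; and
* optionally a **locus-restoration assay** (both primers inside the deleted
  span) used after a restorative cross.

A crossing module plans the removal of the Δtku70 (NHEJ-deficient) background
by sexual backcrossing instead of retransformation.

## The core models

**Primer thermodynamics.** Melting temperatures use the unified
nearest-neighbor parameter set with the monovalent-salt entropy correction
ΔS′ = ΔS + 0.368 (N−1) ln[Na⁺] and

&nbsp;&nbsp;&nbsp;&nbsp;Tm = 1000·ΔH / (ΔS′ + R ln(C_T/x)) − 273.15,

at 50 mM Na⁺ and 200 nM oligo (x = 4 for non-self-complementary duplexes).
Candidates are enumerated exhaustively in each 1500 bp flank window under
hard constraints — length 19–23 nt (optimum 20), Tm 50–60 °C (optimum 56),
GC 50–65 %, at most 2 consecutive 3'-terminal G/C, no soft-masked base, low
ungapped self-complementarity — and a pair minimising the Primer3-style
penalty w_Tm·|Tm−56| + w_len·|len−20| is chosen subject to a 1000–1300 bp
product. Genes are classified **full** (both arms designed), **partial**
(one arm, e.g. truncated by a contig end) or **failed**.

**Giant ORFs.** Genes above 50 kb (e.g. NRPS genes) use an internal 3' flank
starting 2200 bp into the ORF, so the design deletes exactly the first
2200 bp — enough to destroy the product without a >50 kb deletion.

**Assembly and integration.** Gap repair is simulated as exact terminal
overlaps (≥ 29 nt) between ordered fragments circularising into the vector;
the final cassette PCR (5F/3R) and the double-crossover replacement of the
deleted span by the marker are simulated base-accurately, and every screening
assay is validated on the simulated mutant and wild-type genomes.

**Backcrossing.** The expected recurrent-parent genome fraction after one
outcross and n backcrosses is 1 − (1/2)^(n+1) at unlinked neutral loci
(96.875 % for n = 4), with a seeded Monte-Carlo twin; progeny screening needs
follow per-locus 1:1 Mendelian segregation of a haploid × haploid cross.

## Worked example

A bundled deterministic fixture generator stands in for a real genome, so the
whole pipeline runs offline:

```bash
knockkit fixtures --seed 11 --n-contigs 3 --n-genes 8 --out-dir demo/fixture
knockkit design-genome --genome demo/fixture/genome.fa \
    --annotation demo/fixture/genes.gff3 --marker pyr4 --out-dir demo/design
```

prints the batch classification

```
{"n_failed": 0, "n_full": 8, "n_genes": 8, "n_partial": 0}
```

and writes `primer_table.tsv` (one row per gene: status, the four tailed
primers, per-primer core Tm/GC, both product sizes), `screen_table.tsv` and
`summary.json`. The first table row looks like

```
gene_id    contig    strand  status  mode      truncated  deleted_span_bp  marker  product_5_bp  ...  5F
gene_0001  contig_1  +       full    standard  none       2498             pyr4    1085          ...  TACTACATAACGATGAGCGTTGCCACAGGTCTCGCTGGAGCGTAAGTTC
```

— the 5F primer is 49 nt: a 29-nt vector-homology tail followed by the 20-nt
genomic core whose Tm is 56.0 °C. Screening and assembly for single genes:

```bash
knockkit screen --genome demo/fixture/genome.fa --annotation demo/fixture/genes.gff3 \
    --gene gene_0003 --restoration --out-dir demo/screen
# gene_0003: 5' junction screen, expected mutant band 1689 bp, wild type: none
# gene_0003: restoration band 483 bp on intact locus, none on deletion mutant

knockkit assemble --genome demo/fixture/genome.fa --annotation demo/fixture/genes.gff3 \
    --gene gene_0002 --out-dir demo/asm
# gene_0002: plasmid 4435 bp, cassette 4093 bp, 4 exact junctions
```

The 1689 bp junction band appears only when the cassette sits at the target
locus; the 4 exact junctions are the 29-nt homology overlaps the tails were
designed to create. Cross planning:

```bash
knockkit cross-plan --backcrosses 4 --locus "geneKO:1:0:1" --locus "tku70KO:1:0:0" --seed 1
```

reports `recurrent_fraction_expected: 0.96875` (the 96–97 % figure for four
backcrosses after the outcross), a simulated mean of 0.9687 ± 0.0056 over
10,000 genomes × 1000 unlinked loci, a desired-genotype frequency of 0.25
(keep the deletion, lose Δtku70) and 11 progeny to screen for 95 %
confidence of at least one hit.

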