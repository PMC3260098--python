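# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `knockkit`, in the spirit of a methods appendix.

## Coordinates and orientation

Internally every interval is 0-based half-open; GFF3 and the 5-column gene
table (1-based inclusive) are converted on load and reports convert back.
All flank windows, primers and amplicons are handled in *gene orientation*
(5'→3' of the gene), so minus-strand genes are reverse-complemented once at
extraction; a strand-symmetry property test (reverse-complement the genome,
flip the annotation, compare oriented flank sequences) guards the
convention. Soft-masking (lowercase) is preserved by every slice and makes a
base ineligible for priming, on the rationale that masked repeats are unsafe
priming sites; amplicon interiors may contain masked bases.

## Deletion design

The annotated gene interval is the deletion boundary — the annotation's gene
span is deleted in standard mode, without attempting UTR inference. The 5'
window is the `flank_window` (default 1500 bp) immediately upstream of the
annotated start, the 3' window immediately downstream of the annotated end.
Windows truncated by a contig end are kept and flagged; a window shorter
than the minimum product becomes a one-armed ("partial") design rather than
an error.

Giant ORFs (> `giant_orf_threshold`, default 50 kb — multi-module NRPS
genes) switch to an internal 3' flank starting `giant_orf_deletion_span`
(default 2200 bp) into the ORF, so exactly the first 2200 bp are deleted;
this truncates the reading frame while keeping the construct small. Both
parameters are configurable.

The inner primer of each arm floats within its window rather than abutting
the gene boundary; the genomic span replaced at integration is always the
*designed* deletion interval (annotation-anchored), which the homology arms
bracket. This keeps the deleted span exact (important for the giant-ORF
rule) at the cost of a ≤ (flank_window − product) bp stretch of genomic
sequence between each arm amplicon and the deletion boundary that is
retained in the mutant.

## Primer thermodynamics

Unified nearest-neighbor parameters (the 1998 compilation: ten unique
stacks, terminal A·T/G·C initiation, duplex-symmetry entropy −1.4 cal/K/mol)
with the salt correction ΔS′ = ΔS + 0.368(N−1)ln[Na⁺] and
Tm = 1000ΔH/(ΔS′ + R ln(C_T/x)) − 273.15, x = 4 (1 for self-complementary
oligos). Conditions default to 50 mM monovalent cation and 200 nM annealing
oligo. The test suite pins the implementation to an established independent
NN calculator at identical conventions within 0.5 °C (observed agreement:
numerically identical to ~1e-9, since the same published table is used).

The enumeration is exhaustive over all window positions × lengths and
vectorised with prefix sums over dinucleotide ΔH/ΔS; forward and reverse
candidates share all filters except the 3'-clamp rule because Tm, GC and
self-complementarity are reverse-complement invariant. The rare even-length
self-complementary candidate is re-scored scalar with the symmetry term.

Hard constraints (the "database" preset): length 19–23 nt (optimum 20,
maximum 23 chosen as small headroom above the stated optimum), Tm 50–60 °C
(optimum 56), GC 50–65 %, 3'-terminal G/C run ≤ 2, no masked base,
ungapped self-complementarity ≤ 12 complementary pairs. The "pilot" preset
(length exactly 20, GC 40–60 %) is used for screening primers. Two
interpretation choices are deliberate:

* "maximal GC clamp = 2" is read as *at most* two consecutive 3'-terminal
  G/C bases (a stability guard against mispriming), although GC_CLAMP-style
  parameters elsewhere are minima; the threshold is configurable.
* The 1500 bp figure is the search window and 1000–1300 bp the product
  constraint; the "around 1000–1500 bp flank" phrasing describes the window,
  not the amplicon.

Scoring is a weighted deviation penalty, w_Tm·|Tm−56| + w_len·|len−20| with
both weights 1.0 (any positive weights respect the stated optima; both are
config-exposed). Pair selection minimises the penalty sum subject to the
product window, with a fully deterministic tie-break: longer product, then
leftmost/shortest forward, then leftmost/shortest reverse. Because product
size depends only on the forward start and reverse end, the search keeps the
best candidate per forward start and per reverse end; this is exact whenever
the minimum product exceeds two primer lengths (always, for the shipped
presets), and an exhaustive fallback covers degenerate configurations. A
brute-force double-loop oracle in the tests confirms optimality on full-size
windows.

## Markers, vector, tails

The built-in pyr4/amdS/hph marker systems and the 5 kb mock linearised
shuttle vector carry deterministic synthetic sequences (i.i.d. 50 % GC from
fixed per-name seeds, lengths of realistic magnitude). Tails are *derived*
from the neighbour fragment termini — 5F: last 29 nt of the vector end
abutting the 5' arm; 5R: reverse complement of the marker's first 29 nt;
3F: the marker's last 29 nt; 3R: reverse complement of the first 29 nt of
the other vector end — which is exactly the homology that makes gap repair
work and keeps the toolkit marker/vector agnostic: supplying real sequences
changes nothing structurally. Each marker also carries two internal
screening primers (one per junction side, each verified unique within the
marker), because a junction screen needs a primer oriented outward on
whichever side is screened.

## Gap repair, PCR and integration models

*Gap repair* requires an exact terminal overlap ≥ `min_overlap` (default 29
nt) between ordered adjacent fragments, circularising through the vector;
assembly failure names the offending junction. Plasmid length equals the
fragment-length sum minus the overlap sum (asserted in tests).

*In-silico PCR*: a primer binds where its 3'-terminal 15 nt match exactly
and the rest of the aligned footprint has ≤ 2 mismatches; the 5'-most
`max_dangle_5prime` bases (0 by default; 29 when amplifying with tailed
primers off a template lacking the tail homology) are exempt from mismatch
counting and dangle into the product, as in real tailed-primer PCR. This
binding model is pragmatic plumbing, not thermodynamics, and all three
knobs are exposed. Circular templates are handled by scanning an extended
copy and deduplicating sites modulo the template length.

*Integration* replaces the designed deletion interval with the marker in
gene orientation after checking that both flank windows map uniquely in the
genome (ambiguous targeting is refused). Length conservation and
substring-level presence/absence are property-tested, and the full
design → tails → assembly → cassette PCR → integration → screen round trip
runs for every full design of a fixture genome.

## Screening assays

The junction screen pairs an outside primer (searched position by position
up to 500 bp beyond the flank window, under the pilot preset) with the
marker-internal primer; a candidate is accepted only when the predicted
product — distance from primer to the deletion boundary plus the internal
site's offset in the marker — lies in 1400–2000 bp *and* in-silico PCR on
the simulated integrant yields exactly that single product while the
wild-type genome yields none. The default screens the 5' junction, falling
back to the 3' side (e.g. for one-armed designs); both-side screening is
available. The restoration screen picks a pair inside the deleted span
(default 300–800 bp product), positive on the intact or restored locus and
structurally incapable of amplifying from the deletion mutant.

The transformant rule table compares observed bands at ± 50 bp (a gel-
resolution proxy, configurable): junction band at the expected size with a
silent intact-locus assay ⇒ homologous; no bands ⇒ ectopic/none; only the
intact-locus band ⇒ wild-type contaminant; junction *and* intact-locus
bands ⇒ indeterminate (heterokaryon suspicion), as is any band at an
unexpected size.

## Crossing model

Unlinked neutral loci only: each backcross to the recurrent parent halves
the expected donor fraction, giving 1 − (1/2)^(n+1) after n backcrosses
(96.875 % for n = 4, the "96–97 %" figure; a five-generation pedigree is
one outcross plus four backcrosses). No recombination map is modelled —
linkage drag around the female-fertility locus is a real phenomenon the
model deliberately ignores for lack of map information. The Monte-Carlo
twin draws per-locus inheritance independently (default 10,000 genomes ×
1000 loci, seeded) and must agree with the closed form within three
standard errors. Desired-genotype frequencies multiply per-locus Mendelian
factors (1/2 per segregating locus in a haploid × haploid cross), checked
against exhaustive gamete enumeration; the progeny count for confidence c
is the smallest n with 1 − (1−p)^n ≥ c.

## Synthetic fixture genomes

The generator emulates what matters for this toolkit and nothing more:
multi-contig genomes at ~52 % GC (i.i.d. bases — the simplest composition
that exercises GC/Tm/clamp constraints), 1–4 kb genes, optional > 50 kb
giant ORFs, genes placed 100–900 bp from a contig end to force truncated
windows, intergenic spacing ≥ 3500 bp so interior flanks are gene-free, and
lowercase repeat blocks confined ≥ 2100 bp from any gene so they never
intersect a flank window or the outside-primer band. It does *not* model
codon structure, introns, repeat families, local GC heterogeneity or
paralogy — so passing tests demonstrate the pipeline's bookkeeping and
search logic, not primer performance on real repeat-rich genomes, where
masked-base rejection and the flank-uniqueness check do the corresponding
work. Packing that cannot satisfy the requested counts raises an explicit
error rather than degrading silently.

The acceptance run uses a 200-interior-gene / 8-contig (~1.9 Mb) fixture
including two giant ORFs, plus a 205-gene variant adding five edge genes —
sized so a full genome-wide design with verified screens completes in about
a minute on one CPU while still exercising every design path at scale.

## Known limitations

* No secondary-structure folding energetics, divalent-cation corrections or
  primer-dimer cross-checks between different primers.
* The PCR binding model is seed-plus-mismatch-count, not ΔG-based.
* Marker/vector sequences are synthetic stand-ins; real cassette sequences
  should be substituted for wet-lab use.
* Crossing assumes free recombination everywhere; mating-type biology and
  fertility genetics are out of scope.
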