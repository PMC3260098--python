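"""Deterministic synthetic-genome generator.

Emulates the gene-size landscape of a compact fungal genome so the whole
toolkit is testable without downloads: multi-contig, ~1-4 kb genes, an
optional handful of giant (> 50 kb) ORFs of the nonribosomal-peptide-
synthetase kind, optional genes truncated by a contig edge, and soft-masked
repeat blocks (lowercase) confined to deep intergenic space.

Base composition is i.i.d. per nucleotide at ``gc_mean`` — the simplest
model that still exercises the GC-content, Tm and clamp constraints.
Intergenic spacing is kept >= 3500 bp by default so both 1500 bp flank
windows of interior genes are gene-free, and masked blocks keep >= 2100 bp
clearance from every gene so they never intersect a flank window or the
outside-primer search band.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneModel, Genome


class FixturePackingError(ValueError):
    """The requested genes cannot be packed into the requested contigs."""


@dataclass(frozen=True)
class FixtureSpec:
    n_contigs: int = 4
    contig_length_range: tuple[int, int] = (150_000, 250_000)
    n_genes: int = 30
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    n_giant_genes: int = 0
    giant_gene_length_range: tuple[int, int] = (55_000, 70_000)
    gc_mean: float = 0.52
    masked_fraction: float = 0.02
    edge_gene_count: int = 0
    seed: int = 0
    intergenic_range: tuple[int, int] = (3_500, 6_500)
    edge_offset_range: tuple[int, int] = (100, 900)
    interior_margin: int = 2_100  # flank window + outside-primer search band
    mask_block_range: tuple[int, int] = (150, 600)

    def __post_init__(self) -> None:
        counts = (self.n_contigs, self.n_genes, self.n_giant_genes,
                  self.edge_gene_count)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        for frac in (self.gc_mean, self.masked_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.giant_gene_length_range[0] <= 50_000:
            raise ValueError("giant genes must be > 50000 bp")
        if self.n_giant_genes + self.edge_gene_count > self.n_genes:
            raise ValueError("n_giant_genes + edge_gene_count exceeds n_genes")
        for lo, hi in (self.contig_length_range, self.gene_length_range,
                       self.giant_gene_length_range, self.intergenic_range,
                       self.edge_offset_range, self.mask_block_range):
            if not 0 <= lo <= hi:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")


def generate_fixture(spec: FixtureSpec) -> tuple[Genome, list[GeneModel]]:
    """Generate a (genome, annotation) pair; byte-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    contig_lengths = [
        int(rng.integers(spec.contig_length_range[0], spec.contig_length_range[1] + 1))
        for _ in range(spec.n_contigs)
    ]
    if spec.edge_gene_count > spec.n_contigs:
        raise FixturePackingError("more edge genes than contigs")

    n_interior = spec.n_genes - spec.n_giant_genes - spec.edge_gene_count
    gene_lengths = (
        [int(rng.integers(*_incl(spec.giant_gene_length_range)))
         for _ in range(spec.n_giant_genes)]
        + [int(rng.integers(*_incl(spec.gene_length_range)))
           for _ in range(n_interior)]
    )
    edge_lengths = [
        int(rng.integers(*_incl(spec.gene_length_range)))
        for _ in range(spec.edge_gene_count)
    ]

    # Placement: edge genes hug the start of the first contigs; giant genes
    # are packed first (hardest to fit), then ordinary genes, sequentially
    # with randomised intergenic spacing and interior margins at contig ends.
    placements: list[tuple[int, int, int]] = []  # (contig index, start, end)
    cursors = []
    for ci in range(spec.n_contigs):
        if ci < spec.edge_gene_count:
            offset = int(rng.integers(*_incl(spec.edge_offset_range)))
            glen = edge_lengths[ci]
            if offset + glen + spec.interior_margin > contig_lengths[ci]:
                raise FixturePackingError(f"edge gene does not fit contig {ci}")
            placements.append((ci, offset, offset + glen))
            cursors.append(offset + glen + int(rng.integers(*_incl(spec.intergenic_range))))
        else:
            cursors.append(spec.interior_margin)

    queue = list(gene_lengths)
    ci = 0
    while queue and ci < spec.n_contigs:
        glen = queue[0]
        start = cursors[ci]
        if start + glen + spec.interior_margin <= contig_lengths[ci]:
            placements.append((ci, start, start + glen))
            cursors[ci] = start + glen + int(
                rng.integers(*_incl(spec.intergenic_range))
            )
            queue.pop(0)
        else:
            ci += 1
    if queue:
        raise FixturePackingError(
            f"{len(queue)} genes do not fit the requested contigs"
        )

    contigs: dict[str, str] = {}
    seqs = []
    for ci, clen in enumerate(contig_lengths):
        p = [(1 - spec.gc_mean) / 2, spec.gc_mean / 2,
             spec.gc_mean / 2, (1 - spec.gc_mean) / 2]
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=clen, p=p)
        seqs.append(arr)

    genes: list[GeneModel] = []
    order = sorted(range(len(placements)), key=lambda i: (placements[i][0],
                                                          placements[i][1]))
    for serial, idx in enumerate(order, start=1):
        ci, start, end = placements[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene_{serial:04d}",
                contig=f"contig_{ci + 1}",
                start=start,
                end=end,
                strand=strand,
            )
        )

    _apply_masking(spec, rng, seqs, contig_lengths, genes)

    for ci, arr in enumerate(seqs):
        contigs[f"contig_{ci + 1}"] = arr.tobytes().decode("ascii")
    return Genome(contigs), genes


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _apply_masking(spec, rng, seqs, contig_lengths, genes) -> None:
    """Lowercase random blocks in intergenic space, away from all flanks."""
    target = int(spec.masked_fraction * sum(contig_lengths))
    if target <= 0:
        return
    margin = spec.interior_margin
    free: list[tuple[int, int, int]] = []
    by_contig: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(seqs))}
    for g in genes:
        ci = int(g.contig.split("_")[1]) - 1
        by_contig[ci].append((g.start, g.end))
    for ci, clen in enumerate(contig_lengths):
        cursor = 0
        for start, end in sorted(by_contig[ci]) + [(clen, clen)]:
            lo, hi = cursor, start - margin
            if hi - lo >= spec.mask_block_range[0]:
                free.append((ci, lo, hi))
            cursor = end + margin
    rng.shuffle(free)
    masked = 0
    for ci, lo, hi in free:
        if masked >= target:
            break
        block = int(rng.integers(*_incl(spec.mask_block_range)))
        block = min(block, hi - lo)
        start = int(rng.integers(lo, hi - block + 1))
        seg = seqs[ci][start : start + block]
        seqs[ci][start : start + block] = seg | 0x20  # lowercase
        masked += block


GFF_SOURCE = "knockkit"


def write_gff3(genes: list[GeneModel], genome: Genome, path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t{GFF_SOURCE}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_fixture(
    spec: FixtureSpec, out_dir: str | os.PathLike
) -> tuple[str, str]:
    """Generate and write genome.fa + genes.gff3; returns the two paths."""
    genome, genes = generate_fixture(spec)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "genome.fa")
    gff = os.path.join(out_dir, "genes.gff3")
    genome.to_fasta(fasta)
    write_gff3(genes, genome, gff)
    return fasta, gff
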