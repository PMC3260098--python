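"""Genome and annotation access, and per-gene flanking-window extraction.

Internal coordinates are 0-based half-open throughout; GFF3 and gene-table
input (1-based inclusive) is converted on load, and report writers convert
back. Soft-masking (lowercase) is preserved on every slice.

Knockout designs replace the annotated gene interval with a selectable
marker. Two flank modes exist:

* ``standard`` — the 5' window is the ``flank_window`` bp immediately
  upstream of the start codon and the 3' window the ``flank_window`` bp
  immediately downstream of the stop codon, both in gene orientation; the
  whole annotated ORF is the deleted span.
* ``internal_3prime`` — for giant ORFs (> ``giant_orf_threshold`` bp, e.g.
  multi-module NRPS genes) the 3' window is taken from *within* the ORF,
  starting ``giant_orf_deletion_span`` bp downstream of the start codon, so
  that only the first ``giant_orf_deletion_span`` bp (default 2200) are
  deleted — enough to destroy the reading frame without requiring a >50 kb
  deletion.

Windows truncated by a contig end are returned short and flagged, not
rejected; downstream primer design turns them into "partial" designs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .seq import revcomp

STRANDS = ("+", "-")


class GenomeError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene's location on a contig (0-based half-open, strand +/-)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(
                f"{self.gene_id}: unknown strand symbol {self.strand!r}"
            )

    @property
    def orf_length(self) -> int:
        return self.end - self.start


class Genome:
    """In-memory random-access genome preserving soft-masking case."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise GenomeError("empty genome")
        self._contigs = dict(contigs)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        path = os.fspath(path)
        if os.path.getsize(path) == 0:
            raise GenomeError(f"empty FASTA file: {path}")
        try:
            fa = Fasta(path, duplicate_action="stop", as_raw=True, rebuild=True)
        except ValueError as exc:
            raise GenomeError(f"bad FASTA {path}: {exc}") from exc
        try:
            contigs = {name: str(fa[name][:]) for name in fa.keys()}
        finally:
            fa.close()
        return cls(contigs)

    @property
    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def contig_length(self, contig: str) -> int:
        return len(self._contig(contig))

    def _contig(self, contig: str) -> str:
        try:
            return self._contigs[contig]
        except KeyError:
            raise GenomeError(f"unknown contig {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice [start, end) of a contig; out-of-bounds is an error."""
        seq = self._contig(contig)
        if not 0 <= start <= end <= len(seq):
            raise GenomeError(
                f"interval [{start}, {end}) outside {contig} (length {len(seq)})"
            )
        return seq[start:end]

    def fetch_oriented(self, contig: str, start: int, end: int, strand: str) -> str:
        seq = self.fetch(contig, start, end)
        return seq if strand == "+" else revcomp(seq)

    def with_replacement(
        self, contig: str, start: int, end: int, insert: str
    ) -> "Genome":
        """New genome with [start, end) of *contig* replaced by *insert*."""
        seq = self._contig(contig)
        if not 0 <= start <= end <= len(seq):
            raise GenomeError(f"replacement interval outside {contig}")
        contigs = dict(self._contigs)
        contigs[contig] = seq[:start] + insert + seq[end:]
        return Genome(contigs)

    def items(self) -> Iterable[tuple[str, str]]:
        return self._contigs.items()

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_genome(path: str | os.PathLike) -> Genome:
    """Read a (possibly soft-masked) FASTA into an indexed genome."""
    return Genome.from_fasta(path)


_TABLE_COLUMNS = ["gene_id", "contig", "start", "end", "strand"]


def load_annotation(
    path: str | os.PathLike, genome: Genome | None = None
) -> list[GeneModel]:
    """Read gene models from GFF3 or a 5-column TSV gene table.

    Both dialects use 1-based inclusive coordinates; they are converted to
    the internal 0-based half-open convention. When *genome* is given, each
    gene is checked to lie within its contig.
    """
    path = os.fspath(path)
    if path.endswith((".gff", ".gff3")):
        genes = _load_gff(path)
    else:
        genes = _load_table(path)
    if genome is not None:
        for g in genes:
            if g.contig not in genome:
                raise AnnotationError(f"{g.gene_id}: unknown contig {g.contig!r}")
            if g.end > genome.contig_length(g.contig):
                raise AnnotationError(
                    f"{g.gene_id}: extends past end of contig {g.contig}"
                )
    return genes


def _load_gff(path: str) -> list[GeneModel]:
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig=feat.seqid,
                start=feat.start - 1,  # GFF 1-based inclusive -> half-open
                end=feat.end,
                strand=feat.strand,
            )
        )
    return genes


def _load_table(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(row.gene_id),
            contig=str(row.contig),
            start=int(row.start) - 1,
            end=int(row.end),
            strand=str(row.strand),
        )
        for row in df.itertuples()
    ]


@dataclass(frozen=True)
class FlankConfig:
    flank_window: int = 1500
    giant_orf_threshold: int = 50_000
    giant_orf_deletion_span: int = 2_200

    def __post_init__(self) -> None:
        if min(self.flank_window, self.giant_orf_threshold,
               self.giant_orf_deletion_span) <= 0:
            raise ValueError("flank parameters must be positive")


@dataclass(frozen=True)
class Window:
    """An oriented flank window: sequence is 5'->3' in gene orientation."""

    seq: str
    contig: str
    gstart: int  # genomic, 0-based half-open
    gend: int

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FlankPair:
    five_prime: Window
    three_prime: Window
    mode: str  # "standard" | "internal_3prime"
    truncated: str  # "none" | "5'" | "3'" | "both"
    deleted_span: int
    deletion_start: int = field(default=0)  # genomic interval replaced by marker
    deletion_end: int = field(default=0)


def extract_flanks(
    genome: Genome, gene: GeneModel, config: FlankConfig = FlankConfig()
) -> FlankPair:
    """Extract the oriented 5' and 3' flank windows for a knockout design."""
    w = config.flank_window
    clen = genome.contig_length(gene.contig)
    if gene.end > clen:
        raise AnnotationError(f"{gene.gene_id}: gene extends past contig end")
    internal = gene.orf_length > config.giant_orf_threshold
    d = config.giant_orf_deletion_span

    if gene.strand == "+":
        up = (max(0, gene.start - w), gene.start)
        if internal:
            down = (gene.start + d, min(gene.start + d + w, gene.end))
            deletion = (gene.start, gene.start + d)
        else:
            down = (gene.end, min(clen, gene.end + w))
            deletion = (gene.start, gene.end)
        trunc5 = up[1] - up[0] < w
        trunc3 = down[1] - down[0] < w
    else:
        up = (gene.end, min(clen, gene.end + w))
        if internal:
            down = (max(gene.start, gene.end - d - w), gene.end - d)
            deletion = (gene.end - d, gene.end)
        else:
            down = (max(0, gene.start - w), gene.start)
            deletion = (gene.start, gene.end)
        trunc5 = up[1] - up[0] < w
        trunc3 = down[1] - down[0] < w

    five = Window(
        genome.fetch_oriented(gene.contig, up[0], up[1], gene.strand),
        gene.contig, up[0], up[1],
    )
    three = Window(
        genome.fetch_oriented(gene.contig, down[0], down[1], gene.strand),
        gene.contig, down[0], down[1],
    )
    truncated = {(False, False): "none", (True, False): "5'",
                 (False, True): "3'", (True, True): "both"}[(trunc5, trunc3)]
    return FlankPair(
        five_prime=five,
        three_prime=three,
        mode="internal_3prime" if internal else "standard",
        truncated=truncated,
        deleted_span=deletion[1] - deletion[0],
        deletion_start=deletion[0],
        deletion_end=deletion[1],
    )
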