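"""Homology-tail attachment, yeast gap-repair assembly, in-silico PCR and
genomic integration.

The deletion cassette is assembled in vivo by the yeast homologous
recombination machinery from four fragments sharing exact terminal homology:

    linearised vector -- 5' flank amplicon -- marker -- 3' flank amplicon -- (back to vector)

Each flank-amplification primer carries a ``linker_length`` (default 29) nt
5' tail equal to the terminus of its neighbour fragment in that order, which
is exactly what makes the junctions recombinogenic:

    5F tail = last 29 nt of the vector end abutting the 5' flank
    5R tail = reverse complement of the first 29 nt of the marker
    3F tail = last 29 nt of the marker
    3R tail = reverse complement of the first 29 nt of the vector end
              abutting the 3' flank

The assembled plasmid is then the template for the cassette PCR with the
outermost tailed primers (5F and 3R), and the cassette integrates into the
genome by double crossover, replacing the designed deletion span with the
marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .genome_io import Genome, GenomeError
from .markers import MarkerSystem
from .primer_design import DeletionDesign, PrimerPair
from .seq import revcomp

DEFAULT_LINKER_LENGTH = 29

ROLES = ("5F", "5R", "3F", "3R")


@dataclass(frozen=True)
class TailedPrimer:
    tail: str
    core: str
    role: str

    @property
    def full_seq(self) -> str:
        return self.tail + self.core


def attach_linkers(
    pair_5prime: PrimerPair,
    pair_3prime: PrimerPair,
    marker: MarkerSystem,
    linker_length: int = DEFAULT_LINKER_LENGTH,
) -> dict[str, TailedPrimer]:
    """Attach assembly-homology tails to the four flank primers."""
    if linker_length < 0:
        raise ValueError("linker_length must be >= 0")
    for label, seq in (
        ("marker_seq", marker.marker_seq),
        ("vector_left_end", marker.vector_left_end),
        ("vector_right_end", marker.vector_right_end),
    ):
        if len(seq) < linker_length:
            raise ValueError(f"{label} shorter than linker_length={linker_length}")
    k = linker_length
    tails = {
        "5F": marker.vector_left_end[len(marker.vector_left_end) - k :],
        "5R": revcomp(marker.marker_seq[:k]),
        "3F": marker.marker_seq[len(marker.marker_seq) - k :],
        "3R": revcomp(marker.vector_right_end[:k]),
    }
    if k == 0:
        tails = {r: "" for r in ROLES}
    cores = {
        "5F": pair_5prime.forward.core_seq,
        "5R": pair_5prime.reverse.core_seq,
        "3F": pair_3prime.forward.core_seq,
        "3R": pair_3prime.reverse.core_seq,
    }
    return {r: TailedPrimer(tail=tails[r], core=cores[r], role=r) for r in ROLES}


def tailed_amplicon(window: str, pair: PrimerPair, tail_f: str, tail_r: str) -> str:
    """Top-strand product of a tailed-primer PCR on a flank window."""
    return (
        tail_f
        + window[pair.forward.window_offset : pair.reverse.substring_end].upper()
        + revcomp(tail_r)
    )


@dataclass(frozen=True)
class Junction:
    fragment_a: int
    fragment_b: int
    overlap: int
    exact: bool


@dataclass
class AssemblyResult:
    ok: bool
    plasmid_seq: Optional[str] = None  # circular; starts at the vector fragment
    cassette_seq: Optional[str] = None
    junction_report: list[Junction] = field(default_factory=list)
    failed_junction: Optional[tuple[int, int]] = None
    message: str = ""


def _terminal_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap with a[-k:] == b[:k] (0 if none)."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def simulate_gap_repair(
    fragments: Sequence[str],
    vector: Optional[str] = None,
    min_overlap: int = DEFAULT_LINKER_LENGTH,
) -> AssemblyResult:
    """Assemble ordered fragments (optionally into a circular gapped vector).

    Adjacent fragments must share an exact terminal overlap of at least
    ``min_overlap`` nt; with a vector, the junction from the last fragment
    back to the vector closes the circle. A missing or mutated overlap is an
    assembly failure naming the bad junction, not an exception.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    frags = [f.upper() for f in fragments]
    circular = vector is not None
    order = ([vector.upper()] + frags) if circular else frags

    junctions: list[Junction] = []
    merged = order[0]
    positions = [0]
    for i in range(1, len(order)):
        ov = _terminal_overlap(order[i - 1], order[i], min_overlap)
        if ov == 0:
            return AssemblyResult(
                ok=False,
                failed_junction=(i - 1, i),
                message=(
                    f"no exact terminal overlap >= {min_overlap} nt between "
                    f"fragments {i - 1} and {i}"
                ),
            )
        junctions.append(Junction(i - 1, i, ov, True))
        positions.append(len(merged) - ov)
        merged = merged + order[i][ov:]
    if circular:
        ov = _terminal_overlap(order[-1], order[0], min_overlap)
        if ov == 0:
            return AssemblyResult(
                ok=False,
                failed_junction=(len(order) - 1, 0),
                message=(
                    f"no exact terminal overlap >= {min_overlap} nt closing "
                    "the circle"
                ),
            )
        junctions.append(Junction(len(order) - 1, 0, ov, True))
        plasmid = merged[:-ov]
        cassette = None
        if len(order) > 1:
            # the cassette ends with homology to the vector start, so as a
            # substring of the *circular* plasmid it wraps the origin
            cassette = plasmid[positions[1] :] + plasmid[:ov]
        return AssemblyResult(
            ok=True,
            plasmid_seq=plasmid,
            cassette_seq=cassette,
            junction_report=junctions,
        )
    return AssemblyResult(
        ok=True, plasmid_seq=None, cassette_seq=merged, junction_report=junctions
    )


def assemble_cassette(
    design: DeletionDesign,
    marker: MarkerSystem,
    linker_length: int = DEFAULT_LINKER_LENGTH,
    vector: Optional[str] = None,
) -> AssemblyResult:
    """Gap-repair the full vector--5'flank--marker--3'flank plasmid for a design."""
    if design.status != "full" or design.tailed_primers is None:
        raise ValueError("cassette assembly requires a full design with tails")
    tp = design.tailed_primers
    amp5 = tailed_amplicon(
        design.flanks.five_prime.seq, design.pair_5prime, tp["5F"].tail, tp["5R"].tail
    )
    amp3 = tailed_amplicon(
        design.flanks.three_prime.seq, design.pair_3prime, tp["3F"].tail, tp["3R"].tail
    )
    if vector is None:
        # minimal linearised-vector stand-in: just the two homology ends,
        # right end first (it abuts the 3' flank when the circle closes)
        vector = marker.vector_right_end + marker.vector_left_end
    return simulate_gap_repair(
        [amp5, marker.marker_seq, amp3], vector=vector, min_overlap=linker_length
    )


@dataclass(frozen=True)
class PcrProduct:
    seq: str
    length: int
    fwd_start: int  # leftmost template coordinate spanned (5' end incl. dangle)
    rev_end: int


@dataclass(frozen=True)
class _Site:
    three_end: int  # plus: exclusive end of 3' terminus; minus: position of 3' base
    primer: str
    strand: str


MIN_PCR_PRIMER_LEN = 15


def _plus_sites(
    template: str, primer: str, seed_len: int, max_mismatch: int, dangle: int
) -> list[_Site]:
    seed = primer[-seed_len:].upper()
    sites = []
    pos = template.find(seed)
    while pos != -1:
        three_end = pos + seed_len
        aln_start = three_end - len(primer)
        mism = 0
        for i in range(max(0, aln_start + dangle), pos):
            if template[i] != primer[i - aln_start].upper():
                mism += 1
        if mism <= max_mismatch:
            sites.append(_Site(three_end=three_end, primer=primer, strand="+"))
        pos = template.find(seed, pos + 1)
    return sites


def _minus_sites(
    template: str, primer: str, seed_len: int, max_mismatch: int, dangle: int
) -> list[_Site]:
    seed_rc = revcomp(primer[-seed_len:].upper())
    rc_full = revcomp(primer.upper())
    sites = []
    pos = template.find(seed_rc)
    while pos != -1:
        # primer 3' end maps to template position pos; alignment covers
        # [pos, pos + len(primer)) with any 5' dangle off the right
        mism = 0
        end = min(len(template), pos + len(primer) - dangle)
        for i in range(pos + seed_len, end):
            if template[i] != rc_full[i - pos]:
                mism += 1
        if mism <= max_mismatch:
            sites.append(_Site(three_end=pos, primer=primer, strand="-"))
        pos = template.find(seed_rc, pos + 1)
    return sites


def in_silico_pcr(
    template: str,
    fwd: str,
    rev: str,
    max_product: int = 5_000,
    circular: bool = False,
    seed_len: int = 15,
    max_mismatch: int = 2,
    max_dangle_5prime: int = 0,
) -> list[PcrProduct]:
    """Predict PCR products on a linear or circular template.

    A primer binds where its 3'-terminal ``seed_len`` nt match the template
    exactly and the rest of the aligned region has at most ``max_mismatch``
    mismatches. The 5'-most ``max_dangle_5prime`` bases are exempt from
    mismatch counting, which is how a non-homologous assembly tail is modelled
    (it dangles, but still appears in the product, as in real tailed-primer
    PCR); a 5' overhang running off the template end always dangles. Products
    are reported for every plus-strand/minus-strand site combination in
    productive orientation with total length <= ``max_product``. An empty
    list is a valid outcome.
    """
    for p in (fwd, rev):
        if len(p) < MIN_PCR_PRIMER_LEN:
            raise ValueError(f"primer shorter than {MIN_PCR_PRIMER_LEN} nt")
    seed_len = min(seed_len, min(len(fwd), len(rev)))
    dangle = max(0, max_dangle_5prime)
    t = template.upper()
    n = len(t)
    scan = t + t[: max_product] if circular else t

    plus: list[_Site] = []
    minus: list[_Site] = []
    for primer in (fwd, rev):
        plus += _plus_sites(scan, primer.upper(), seed_len, max_mismatch, dangle)
        minus += _minus_sites(scan, primer.upper(), seed_len, max_mismatch, dangle)

    products = []
    seen = set()
    for p in plus:
        if circular and p.three_end - seed_len >= n:
            continue  # duplicate of a canonical first-copy site; partner may wrap
        for m in minus:
            if m.three_end < p.three_end:
                continue
            gap = m.three_end - p.three_end
            length = len(p.primer) + gap + len(m.primer)
            if length > max_product:
                continue
            seq = p.primer.upper() + scan[p.three_end : m.three_end] + revcomp(m.primer.upper())
            key = (p.three_end % n if circular else p.three_end,
                   m.three_end % n if circular else m.three_end,
                   p.primer, m.primer)
            if key in seen:
                continue
            seen.add(key)
            products.append(
                PcrProduct(
                    seq=seq,
                    length=length,
                    fwd_start=p.three_end - len(p.primer),
                    rev_end=m.three_end + len(m.primer),
                )
            )
    products.sort(key=lambda pr: (pr.fwd_start, pr.length))
    return products


class MultiMappingFlankError(GenomeError):
    pass


def _count_occurrences(genome: Genome, pattern: str) -> int:
    pat = pattern.upper()
    rc = revcomp(pat)
    total = 0
    for _, seq in genome.items():
        s = seq.upper()
        total += s.count(pat)
        if rc != pat:
            total += s.count(rc)
    return total


def simulate_integration(
    genome: Genome,
    design: DeletionDesign,
    marker: MarkerSystem,
    check_unique: bool = True,
) -> Genome:
    """Homologous replacement of the designed deletion span by the marker.

    The mutant contig is the original with [deletion_start, deletion_end)
    replaced by the marker sequence in gene orientation; every other contig is
    untouched. Flank windows that map to more than one genomic locus are
    refused (double-crossover targeting would be ambiguous).
    """
    fl = design.flanks
    if check_unique:
        for win in (fl.five_prime, fl.three_prime):
            if win.seq and _count_occurrences(genome, win.seq) != 1:
                raise MultiMappingFlankError(
                    f"{design.gene_id}: flank window maps to multiple loci"
                )
    insert = (
        marker.marker_seq
        if design.gene.strand == "+"
        else revcomp(marker.marker_seq)
    )
    return genome.with_replacement(
        design.gene.contig, fl.deletion_start, fl.deletion_end, insert
    )
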