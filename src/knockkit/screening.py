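"""PCR screening assays for transformant verification.

Three assay families:

* Junction screen — an "outside" primer beyond the cassette's homology arm
  paired with a primer inside the selectable marker. Only locus-specific
  (homologous) integration juxtaposes the two sites, giving a product in the
  expected 1400-2000 bp range; wild type and ectopic integrants give nothing.
* Locus-restoration screen — a primer pair wholly inside the deleted span.
  Positive on the wild-type (or crossing-restored) locus, silent on the
  deletion mutant. Used e.g. to confirm restoration of the NHEJ gene after
  backcrossing.
* A deterministic rule table that turns band observations from those assays
  into a transformant call.

Every designed assay is verified by in-silico PCR against the simulated
integrant and the wild-type genome before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from . import thermo
from .assembly import in_silico_pcr, simulate_integration
from .genome_io import GeneModel, Genome, extract_flanks
from .markers import MarkerSystem
from .primer_design import (
    PILOT_PRESET,
    DeletionDesign,
    DesignConstraints,
    pick_pair,
)
from .seq import is_unmasked_dna

SIDE_5 = "5'"
SIDE_3 = "3'"

DEFAULT_SCREEN_RANGE = (1400, 2000)
DEFAULT_SEARCH_BEYOND = 500
DEFAULT_RESTORATION_RANGE = (300, 800)
_PCR_MAX_PRODUCT = 3_000


class ScreenDesignError(RuntimeError):
    """No valid screening assay exists within the search range."""


@dataclass(frozen=True)
class ScreenAssay:
    gene_id: str
    side: str  # 5' or 3'
    outside_primer: str
    outside_primer_contig: str
    outside_primer_start: int  # genomic, 0-based
    marker_primer: str
    expected_mutant_product: int
    expected_wildtype_product: None = None


@dataclass(frozen=True)
class RestorationAssay:
    gene_id: str
    fwd: str
    rev: str
    expected_restored_product: int
    expected_deletion_product: None = None


def _primer_ok(seq: str, constraints: DesignConstraints) -> bool:
    if not is_unmasked_dna(seq):
        return False
    if not constraints.primer_len_min <= len(seq) <= constraints.primer_len_max:
        return False
    gc = thermo.gc_content(seq)
    if not constraints.gc_min <= gc <= constraints.gc_max:
        return False
    tm = thermo.melting_temperature(seq, constraints.thermo)
    if not constraints.tm_min <= tm <= constraints.tm_max:
        return False
    if thermo.gc_clamp_run(seq) > constraints.gc_clamp_max_run:
        return False
    if thermo.self_complementarity(seq) > constraints.self_comp_max:
        return False
    return True


def _genome_products(genome: Genome, fwd: str, rev: str) -> list:
    products = []
    for _, seq in genome.items():
        products += in_silico_pcr(seq, fwd, rev, max_product=_PCR_MAX_PRODUCT)
    return products


def design_screen(
    genome: Genome,
    design: DeletionDesign,
    marker: MarkerSystem,
    side: str = SIDE_5,
    constraints: DesignConstraints = PILOT_PRESET,
    search_beyond: int = DEFAULT_SEARCH_BEYOND,
    amplicon_range: tuple[int, int] = DEFAULT_SCREEN_RANGE,
    mutant: Optional[Genome] = None,
) -> ScreenAssay:
    """Design and verify a junction screening assay on one side of a design.

    The outside primer is searched position by position beyond the flank
    window (up to ``search_beyond`` bp out) under the relaxed "pilot"
    constraint preset, keeping the first candidate whose predicted amplicon on
    the simulated integrant falls within ``amplicon_range`` and which in-silico
    PCR confirms as a single mutant-specific product absent from wild type.
    """
    if side not in (SIDE_5, SIDE_3):
        raise ValueError(f"side must be {SIDE_5!r} or {SIDE_3!r}")
    pair = design.pair_5prime if side == SIDE_5 else design.pair_3prime
    if pair is None:
        raise ScreenDesignError(
            f"{design.gene_id}: no {side} flank amplicon to screen across"
        )
    gene = design.gene
    win = design.flanks.five_prime if side == SIDE_5 else design.flanks.three_prime
    span = win.gend - win.gstart
    plen = constraints.primer_len_opt
    clen = genome.contig_length(gene.contig)

    if side == SIDE_5:
        marker_primer = marker.internal_screen_primer
        into_marker = marker.screen_site_end_5prime
    else:
        marker_primer = marker.internal_screen_primer_3prime
        into_marker = marker.screen_site_start_3prime

    # Genomic geometry: the outside primer extends *toward* the window. For a
    # (+ gene, 5' side) or (- gene, 3' side) it sits at lower genomic
    # coordinates and reads the top strand; in the mirror cases it sits at
    # higher coordinates and reads the bottom strand.
    lower_side = (gene.strand == "+") == (side == SIDE_5)

    if mutant is None:
        mutant = simulate_integration(genome, design, marker)

    for gap in range(1, search_beyond - plen + 1):
        predicted = gap + plen + span + into_marker
        if predicted < amplicon_range[0]:
            continue
        if predicted > amplicon_range[1]:
            break  # predicted size grows with gap; nothing further can fit
        if lower_side:
            gstart = win.gstart - gap - plen
            if gstart < 0:
                break
            primer = genome.fetch(gene.contig, gstart, gstart + plen)
        else:
            gstart = win.gend + gap
            if gstart + plen > clen:
                break
            primer = genome.fetch_oriented(
                gene.contig, gstart, gstart + plen, "-"
            )
        if not _primer_ok(primer, constraints):
            continue
        mutant_products = _genome_products(mutant, primer, marker_primer)
        if len(mutant_products) != 1 or mutant_products[0].length != predicted:
            continue
        if _genome_products(genome, primer, marker_primer):
            continue  # must be silent on wild type
        return ScreenAssay(
            gene_id=design.gene_id,
            side=side,
            outside_primer=primer,
            outside_primer_contig=gene.contig,
            outside_primer_start=gstart,
            marker_primer=marker_primer,
            expected_mutant_product=predicted,
        )
    raise ScreenDesignError(
        f"{design.gene_id}: no valid {side} outside primer within "
        f"{search_beyond} bp of the flank window"
    )


def design_screen_auto(
    genome: Genome,
    design: DeletionDesign,
    marker: MarkerSystem,
    mutant: Optional[Genome] = None,
    **kwargs,
) -> Optional[ScreenAssay]:
    """Junction screen on the 5' side, falling back to the 3' side."""
    sides = [SIDE_5, SIDE_3] if design.pair_5prime is not None else [SIDE_3]
    if mutant is None:
        mutant = simulate_integration(genome, design, marker)
    for side in sides:
        if (design.pair_5prime if side == SIDE_5 else design.pair_3prime) is None:
            continue
        try:
            return design_screen(
                genome, design, marker, side=side, mutant=mutant, **kwargs
            )
        except ScreenDesignError:
            continue
    return None


def design_restoration_screen(
    genome: Genome,
    gene: GeneModel,
    constraints: DesignConstraints = PILOT_PRESET,
    product_range: tuple[int, int] = DEFAULT_RESTORATION_RANGE,
    mutant: Optional[Genome] = None,
) -> RestorationAssay:
    """Primer pair inside the deleted span: positive on the intact locus only.

    In the deletion background the template is absent, so no product is
    possible by construction; after a restorative cross the band returns.
    """
    flanks = extract_flanks(genome, gene, constraints.flank_config())
    span_seq = genome.fetch_oriented(
        gene.contig, flanks.deletion_start, flanks.deletion_end, gene.strand
    )
    if len(span_seq) < product_range[0]:
        raise ScreenDesignError(
            f"{gene.gene_id}: deleted span ({len(span_seq)} bp) too short for a "
            f">= {product_range[0]} bp restoration amplicon"
        )
    c = replace(
        constraints,
        product_min=product_range[0],
        product_max=min(product_range[1], len(span_seq)),
        flank_window=len(span_seq),
    )
    pair, reason = pick_pair(span_seq, c)
    if pair is None:
        raise ScreenDesignError(
            f"{gene.gene_id}: no restoration primer pair in deleted span ({reason})"
        )
    fwd = pair.forward.core_seq
    rev = pair.reverse.core_seq
    wt_products = _genome_products(genome, fwd, rev)
    if len(wt_products) != 1 or wt_products[0].length != pair.product_length:
        raise ScreenDesignError(
            f"{gene.gene_id}: restoration pair is not locus-specific on wild type"
        )
    if mutant is not None and _genome_products(mutant, fwd, rev):
        raise ScreenDesignError(
            f"{gene.gene_id}: restoration pair amplifies from the deletion mutant"
        )
    return RestorationAssay(
        gene_id=gene.gene_id,
        fwd=fwd,
        rev=rev,
        expected_restored_product=pair.product_length,
    )


@dataclass(frozen=True)
class BandObservation:
    present: bool
    size: Optional[int] = None


CALL_HOMOLOGOUS = "homologous"
CALL_ECTOPIC_OR_NONE = "ectopic/none"
CALL_WT_CONTAMINANT = "wild-type-contaminant"
CALL_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class TransformantCall:
    call: str
    reasons: tuple[str, ...] = ()


def classify_transformant(
    observations: Mapping[str, BandObservation],
    junction_assays: Sequence[ScreenAssay],
    locus_assay: Optional[RestorationAssay] = None,
    size_tolerance: int = 50,
) -> TransformantCall:
    """Deterministic rule table over junction and locus-presence bands.

    ``observations`` maps assay keys — ``"junction:5'"`` / ``"junction:3'"``
    for junction screens and ``"locus"`` for the restoration assay — to band
    observations. Sizes are compared at gel resolution (± ``size_tolerance``
    bp). Contradictory observations (a band at an unexpected size, or both
    mutant- and wild-type-specific bands, suggesting a heterokaryon) yield an
    indeterminate call with reasons.
    """
    reasons: list[str] = []
    junction_present = False
    junction_ok = bool(junction_assays)
    for assay in junction_assays:
        obs = observations.get(f"junction:{assay.side}")
        if obs is None or not obs.present:
            junction_ok = False
            continue
        junction_present = True
        if obs.size is not None and abs(obs.size - assay.expected_mutant_product) > size_tolerance:
            reasons.append(
                f"junction:{assay.side} band at {obs.size} bp, expected "
                f"{assay.expected_mutant_product} bp"
            )
            junction_ok = False

    locus_present = False
    if locus_assay is not None:
        obs = observations.get("locus")
        if obs is not None and obs.present:
            locus_present = True
            if obs.size is not None and abs(
                obs.size - locus_assay.expected_restored_product
            ) > size_tolerance:
                reasons.append(
                    f"locus band at {obs.size} bp, expected "
                    f"{locus_assay.expected_restored_product} bp"
                )
                return TransformantCall(CALL_INDETERMINATE, tuple(reasons))

    if junction_ok and not locus_present:
        return TransformantCall(CALL_HOMOLOGOUS, tuple(reasons))
    if junction_present and locus_present:
        reasons.append("both mutant-junction and intact-locus bands (heterokaryon?)")
        return TransformantCall(CALL_INDETERMINATE, tuple(reasons))
    if junction_present and not junction_ok:
        return TransformantCall(CALL_INDETERMINATE, tuple(reasons))
    if locus_present:
        return TransformantCall(CALL_WT_CONTAMINANT, tuple(reasons))
    return TransformantCall(CALL_ECTOPIC_OR_NONE, tuple(reasons))
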