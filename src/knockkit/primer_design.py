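"""Flank-primer enumeration, scoring and selection, plus genome-wide batch design.

The search is exhaustive: every substring of the flank window at every allowed
length is a candidate, kept only if it passes all *hard* constraints —

* length within [primer_len_min, primer_len_max]
* melting temperature within [tm_min, tm_max] (nearest-neighbor model,
  50 mM Na+, 200 nM oligo by default)
* GC content within [gc_min, gc_max]
* 3'-terminal G/C run at most gc_clamp_max_run bases
* no soft-masked (lowercase) or ambiguous base
* ungapped self-complementarity at most self_comp_max pairs

Surviving candidates are ranked by a Primer3-style weighted deviation from the
optima, ``penalty = w_tm * |Tm - tm_opt| + w_len * |len - len_opt|``, and a
forward/reverse pair is chosen that minimises the penalty sum subject to the
product-size window. Ties are broken deterministically by (longer product,
leftmost forward start, shorter forward, leftmost reverse start, shorter
reverse).

Two constraint presets are shipped: ``database`` (the genome-wide batch
settings: length 19-23 opt 20, Tm 50-60 opt 56 degC, GC 50-65%, product
1000-1300 bp in a 1500 bp window) and ``pilot`` (length exactly 20, Tm 50-60,
GC 40-60%), the latter used for screening primers where constraints are
deliberately looser.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import thermo
from .genome_io import FlankConfig, FlankPair, GeneModel, Genome, extract_flanks
from .thermo import ThermoConfig, DEFAULT_THERMO

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class DesignConstraints:
    """Hard constraints and scoring weights for flank primer design."""

    primer_len_min: int = 19
    primer_len_opt: int = 20
    primer_len_max: int = 23
    tm_min: float = 50.0
    tm_opt: float = 56.0
    tm_max: float = 60.0
    gc_min: float = 0.50
    gc_max: float = 0.65
    gc_clamp_max_run: int = 2
    self_comp_max: int = 12
    product_min: int = 1000
    product_max: int = 1300
    flank_window: int = 1500
    giant_orf_threshold: int = 50_000
    giant_orf_deletion_span: int = 2_200
    w_tm: float = 1.0  # penalty per degC deviation from tm_opt
    w_len: float = 1.0  # penalty per nt deviation from primer_len_opt
    thermo: ThermoConfig = DEFAULT_THERMO

    def __post_init__(self) -> None:
        if not self.primer_len_min <= self.primer_len_opt <= self.primer_len_max:
            raise ValueError("primer length bounds must satisfy min <= opt <= max")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("Tm bounds must satisfy min <= opt <= max")
        if not 0 <= self.gc_min <= self.gc_max <= 1:
            raise ValueError("GC bounds must satisfy 0 <= min <= max <= 1")
        if not 0 < self.product_min <= self.product_max <= self.flank_window:
            raise ValueError("need 0 < product_min <= product_max <= flank_window")

    def flank_config(self) -> FlankConfig:
        return FlankConfig(
            flank_window=self.flank_window,
            giant_orf_threshold=self.giant_orf_threshold,
            giant_orf_deletion_span=self.giant_orf_deletion_span,
        )


DATABASE_PRESET = DesignConstraints()
PILOT_PRESET = DesignConstraints(
    primer_len_min=20, primer_len_opt=20, primer_len_max=20,
    gc_min=0.40, gc_max=0.60,
)
PRESETS = {"database": DATABASE_PRESET, "pilot": PILOT_PRESET}


def get_preset(name: str) -> DesignConstraints:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown constraint preset {name!r}") from None


@dataclass(frozen=True)
class PrimerCandidate:
    """A primer candidate within a flank window.

    ``window_offset`` is the start of the *template substring* in window
    coordinates regardless of orientation; a reverse candidate's sequence is
    the reverse complement of ``window[offset : offset + length]`` and its 3'
    end sits at ``window_offset``.
    """

    core_seq: str
    window_offset: int
    orientation: str
    tm: float
    gc: float
    clamp_run: int
    penalty: float

    def __len__(self) -> int:
        return len(self.core_seq)

    @property
    def substring_end(self) -> int:
        return self.window_offset + len(self.core_seq)


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate

    @property
    def product_length(self) -> int:
        return self.reverse.substring_end - self.forward.window_offset

    @property
    def penalty(self) -> float:
        return self.forward.penalty + self.reverse.penalty

    def product_seq(self, window: str) -> str:
        return window[self.forward.window_offset : self.reverse.substring_end]


def score(candidate: PrimerCandidate, constraints: DesignConstraints) -> float:
    """Weighted deviation from the length and Tm optima (0 iff both optimal)."""
    return (
        constraints.w_tm * abs(candidate.tm - constraints.tm_opt)
        + constraints.w_len * abs(len(candidate) - constraints.primer_len_opt)
    )


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_DH16 = np.zeros(16)
_DS16 = np.zeros(16)
for _d, (_h, _s) in thermo.NN_TABLE.items():
    _idx = 4 * int(_BASE_CODE[ord(_d[0])]) + int(_BASE_CODE[ord(_d[1])])
    _DH16[_idx] = _h
    _DS16[_idx] = _s


def enumerate_candidates(
    window: str, orientation: str, constraints: DesignConstraints
) -> list[PrimerCandidate]:
    """Exhaustively enumerate hard-constraint-satisfying primers in a window.

    Every substring at every allowed length is considered; the thermodynamic
    filters run as vectorised prefix-sum arithmetic, which is exact (Tm, GC
    and self-complementarity are reverse-complement invariant, so forward and
    reverse candidates share all filters except the 3'-clamp rule).
    """
    if orientation not in (FORWARD, REVERSE):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    forwards, reverses = _enumerate_both(window, constraints)
    return forwards if orientation == FORWARD else reverses


def _enumerate_both(
    window: str, constraints: DesignConstraints
) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
    if not window:
        raise ValueError("empty window")
    n = len(window)
    if n < constraints.primer_len_min:
        return [], []

    arr = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    code = _BASE_CODE[arr]
    valid = code >= 0  # uppercase unambiguous bases only
    code_c = np.where(valid, code, 0)
    is_gc = valid & ((code_c == 1) | (code_c == 2))

    pref_valid = np.concatenate(([0], np.cumsum(valid)))
    pref_gc = np.concatenate(([0], np.cumsum(is_gc)))

    dinuc_ok = valid[:-1] & valid[1:]
    dinuc_idx = 4 * code_c[:-1] + code_c[1:]
    pref_dh = np.concatenate(([0.0], np.cumsum(np.where(dinuc_ok, _DH16[dinuc_idx], 0.0))))
    pref_ds = np.concatenate(([0.0], np.cumsum(np.where(dinuc_ok, _DS16[dinuc_idx], 0.0))))

    # terminal-pair initiation terms per base
    init_h = np.where(is_gc, thermo.INIT_GC[0], thermo.INIT_AT[0])
    init_s = np.where(is_gc, thermo.INIT_GC[1], thermo.INIT_AT[1])

    # G/C runs: ending at i (for forward 3' ends) and starting at i (reverse)
    run_end = np.zeros(n, dtype=np.int32)
    run_start = np.zeros(n, dtype=np.int32)
    r = 0
    for i in range(n):
        r = r + 1 if is_gc[i] else 0
        run_end[i] = r
    r = 0
    for i in range(n - 1, -1, -1):
        r = r + 1 if is_gc[i] else 0
        run_start[i] = r

    cfg = constraints.thermo
    log_conc = thermo.R_GAS * math.log(cfg.oligo_conc / 4.0)
    salt_log = math.log(cfg.monovalent_salt)

    # one-hot views for per-candidate self-complementarity convolutions
    one_hot = [((code_c == b) & valid).astype(np.int32) for b in range(4)]
    at_a, at_t = one_hot[0], one_hot[3]
    cg_c, cg_g = one_hot[1], one_hot[2]

    def _self_comp(s: int, e: int) -> int:
        tot = np.convolve(at_a[s:e], at_t[s:e]) + np.convolve(cg_c[s:e], cg_g[s:e])
        return 2 * int(tot.max())

    forwards: list[PrimerCandidate] = []
    reverses: list[PrimerCandidate] = []
    for length in range(constraints.primer_len_min, constraints.primer_len_max + 1):
        if length > n:
            break
        starts = np.arange(0, n - length + 1)
        ends = starts + length  # exclusive
        ok = (pref_valid[ends] - pref_valid[starts]) == length

        gc_count = pref_gc[ends] - pref_gc[starts]
        gc_frac = gc_count / length
        ok &= (gc_frac >= constraints.gc_min - 1e-12) & (
            gc_frac <= constraints.gc_max + 1e-12
        )

        dh = pref_dh[ends - 1] - pref_dh[starts] + init_h[starts] + init_h[ends - 1]
        ds = pref_ds[ends - 1] - pref_ds[starts] + init_s[starts] + init_s[ends - 1]
        ds_corr = ds + 0.368 * (length - 1) * salt_log
        with np.errstate(divide="ignore", invalid="ignore"):
            tm_vec = dh * 1000.0 / (ds_corr + log_conc) - 273.15
        ok &= (tm_vec >= constraints.tm_min) & (tm_vec <= constraints.tm_max)

        clamp_f = np.minimum(run_end[ends - 1], length) <= constraints.gc_clamp_max_run
        clamp_r = np.minimum(run_start[starts], length) <= constraints.gc_clamp_max_run
        ok &= clamp_f | clamp_r

        for start in np.nonzero(ok)[0]:
            start = int(start)
            sub = window[start : start + length]
            tm = float(tm_vec[start])
            if length % 2 == 0 and sub == _revcomp_upper(sub):
                # self-complementary duplex: symmetry-corrected scalar Tm
                tm = thermo.melting_temperature(sub.upper(), cfg)
                if not constraints.tm_min <= tm <= constraints.tm_max:
                    continue
            if _self_comp(start, start + length) > constraints.self_comp_max:
                continue
            common = dict(
                window_offset=start,
                tm=tm,
                gc=float(gc_frac[start]),
                penalty=(
                    constraints.w_tm * abs(tm - constraints.tm_opt)
                    + constraints.w_len * abs(length - constraints.primer_len_opt)
                ),
            )
            if clamp_f[start]:
                forwards.append(
                    PrimerCandidate(
                        core_seq=sub.upper(),
                        orientation=FORWARD,
                        clamp_run=int(min(run_end[start + length - 1], length)),
                        **common,
                    )
                )
            if clamp_r[start]:
                reverses.append(
                    PrimerCandidate(
                        core_seq=_revcomp_upper(sub.upper()),
                        orientation=REVERSE,
                        clamp_run=int(min(run_start[start], length)),
                        **common,
                    )
                )
    return forwards, reverses


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp_upper(seq: str) -> str:
    return seq.translate(_RC)[::-1]


NO_PAIR_WINDOW_TOO_SHORT = "window_shorter_than_product_min"
NO_PAIR_NO_COMBINATION = "no_valid_primer_combination"


def pick_pair(
    window: str, constraints: DesignConstraints
) -> tuple[Optional[PrimerPair], Optional[str]]:
    """Best forward/reverse pair with product in the configured size range.

    Returns ``(pair, None)`` on success, ``(None, reason)`` otherwise; the
    absence of a valid pair is an outcome, not an error. The selected pair
    minimises the penalty sum; exact ties prefer the longer product, then the
    leftmost (then shorter) forward, then the leftmost (then shorter) reverse.
    """
    if len(window) > constraints.flank_window:
        raise ValueError("window longer than configured flank_window")
    if len(window) < constraints.product_min:
        return None, NO_PAIR_WINDOW_TOO_SHORT

    forwards, reverses = _enumerate_both(window, constraints)
    if not forwards or not reverses:
        return None, NO_PAIR_NO_COMBINATION

    # The product size depends only on the forward start and the reverse
    # substring end, and the tie-break orders candidates sharing a position by
    # (penalty, length) / (penalty, start, length); primers can only overlap
    # when the product is shorter than two primer lengths, which the product
    # floor rules out. So it suffices to keep the best candidate per forward
    # start and per reverse end.
    if constraints.product_min <= 2 * constraints.primer_len_max:
        return _pick_pair_exhaustive(forwards, reverses, constraints)

    best_f: dict[int, PrimerCandidate] = {}
    for f in forwards:
        cur = best_f.get(f.window_offset)
        if cur is None or (f.penalty, len(f)) < (cur.penalty, len(cur)):
            best_f[f.window_offset] = f
    best_r: dict[int, PrimerCandidate] = {}
    for r in reverses:
        cur = best_r.get(r.substring_end)
        if cur is None or (r.penalty, r.window_offset, len(r)) < (
            cur.penalty, cur.window_offset, len(cur)
        ):
            best_r[r.substring_end] = r

    rev_by_end = sorted(best_r.items())
    rev_ends = [end for end, _ in rev_by_end]
    best: Optional[tuple] = None
    best_pair: Optional[PrimerPair] = None
    for off in sorted(best_f):
        fwd = best_f[off]
        lo = bisect.bisect_left(rev_ends, off + constraints.product_min)
        hi = bisect.bisect_right(rev_ends, off + constraints.product_max)
        for end, rev in rev_by_end[lo:hi]:
            key = (
                fwd.penalty + rev.penalty,
                -(end - off),
                off,
                len(fwd),
                rev.window_offset,
                len(rev),
            )
            if best is None or key < best:
                best = key
                best_pair = PrimerPair(forward=fwd, reverse=rev)
    if best_pair is None:
        return None, NO_PAIR_NO_COMBINATION
    return best_pair, None


def _pick_pair_exhaustive(
    forwards: list[PrimerCandidate],
    reverses: list[PrimerCandidate],
    constraints: DesignConstraints,
) -> tuple[Optional[PrimerPair], Optional[str]]:
    """Fallback for tiny product ranges where primer overlap can bind."""
    reverses = sorted(reverses, key=lambda c: c.substring_end)
    rev_ends = [c.substring_end for c in reverses]
    best: Optional[tuple] = None
    best_pair: Optional[PrimerPair] = None
    for fwd in forwards:
        lo = bisect.bisect_left(rev_ends, fwd.window_offset + constraints.product_min)
        hi = bisect.bisect_right(rev_ends, fwd.window_offset + constraints.product_max)
        for rev in reverses[lo:hi]:
            if rev.window_offset < fwd.substring_end:
                continue  # primers must not overlap
            key = (
                fwd.penalty + rev.penalty,
                -(rev.substring_end - fwd.window_offset),
                fwd.window_offset,
                len(fwd),
                rev.window_offset,
                len(rev),
            )
            if best is None or key < best:
                best = key
                best_pair = PrimerPair(forward=fwd, reverse=rev)
    if best_pair is None:
        return None, NO_PAIR_NO_COMBINATION
    return best_pair, None


STATUS_FULL = "full"
STATUS_PARTIAL = "partial"
STATUS_FAILED = "failed"


@dataclass
class DeletionDesign:
    """Everything designed for one gene knockout."""

    gene: GeneModel
    marker_name: str
    flanks: FlankPair
    pair_5prime: Optional[PrimerPair]
    pair_3prime: Optional[PrimerPair]
    reason_5prime: Optional[str]
    reason_3prime: Optional[str]
    status: str
    tailed_primers: Optional[dict] = None  # role -> TailedPrimer, full designs only
    screen: Optional[object] = None  # ScreenAssay, when screening was requested

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


def design_gene(
    genome: Genome,
    gene: GeneModel,
    constraints: DesignConstraints = DATABASE_PRESET,
    marker_system=None,
) -> DeletionDesign:
    """Design the four flank-amplification primers for one gene.

    Extracts the oriented flank windows, picks a primer pair per flank, and
    (for full designs, when a marker system is given) attaches the 29-nt
    assembly homology tails. Failures are encoded in the status and reason
    fields, never raised.
    """
    flanks = extract_flanks(genome, gene, constraints.flank_config())
    pair5, reason5 = pick_pair(flanks.five_prime.seq, constraints)
    pair3, reason3 = pick_pair(flanks.three_prime.seq, constraints)

    n_ok = (pair5 is not None) + (pair3 is not None)
    status = {2: STATUS_FULL, 1: STATUS_PARTIAL, 0: STATUS_FAILED}[n_ok]

    design = DeletionDesign(
        gene=gene,
        marker_name=getattr(marker_system, "name", ""),
        flanks=flanks,
        pair_5prime=pair5,
        pair_3prime=pair3,
        reason_5prime=reason5,
        reason_3prime=reason3,
        status=status,
    )
    if status == STATUS_FULL and marker_system is not None:
        from .assembly import attach_linkers

        design.tailed_primers = attach_linkers(pair5, pair3, marker_system)
    return design


def design_genome(
    genome: Genome,
    annotation: list[GeneModel],
    constraints: DesignConstraints = DATABASE_PRESET,
    marker_system=None,
    screen: bool = False,
) -> tuple[list[DeletionDesign], dict]:
    """Batch design over an annotation; classifies each gene full/partial/failed.

    With ``screen=True`` a junction screening assay (outside primer + marker
    internal primer, verified by in-silico PCR against the simulated
    integrant) is attached to every non-failed design when possible.
    """
    designs = []
    for gene in annotation:
        d = design_gene(genome, gene, constraints, marker_system)
        if screen and marker_system is not None and d.status != STATUS_FAILED:
            from .screening import design_screen_auto

            d.screen = design_screen_auto(genome, d, marker_system)
        designs.append(d)
    summary = {
        "n_genes": len(designs),
        "n_full": sum(d.status == STATUS_FULL for d in designs),
        "n_partial": sum(d.status == STATUS_PARTIAL for d in designs),
        "n_failed": sum(d.status == STATUS_FAILED for d in designs),
    }
    return designs, summary
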