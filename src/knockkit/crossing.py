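"""Backcross introgression and progeny-segregation planning.

After an initial outcross between a donor (e.g. a sexually competent wild
isolate) and a recurrent parent, the F1 carries half of each genome. Each
subsequent backcross to the recurrent parent halves the expected donor
fraction at unlinked neutral loci, so after ``n`` backcrosses the expected
recurrent-parent genome fraction is

    f(n) = 1 - (1/2) ** (n + 1)

One outcross plus four backcrosses gives f(4) = 1 - 2**-5 = 96.875%, i.e.
the familiar "~96-97% recurrent parent" figure for a five-generation
pedigree. A Monte-Carlo twin samples per-locus inheritance to give the
distribution around that expectation.

Progeny of a haploid x haploid fungal cross segregate 1:1 per unlinked
heterologous locus, so the chance of recovering a desired multi-locus
genotype (keep the gene deletion, lose the NHEJ-deletion background, pick a
mating type, ...) is a product of per-locus Mendelian factors, and the number
of random ascospore progeny to screen follows from a geometric argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

UNLINKED = "unlinked"


@dataclass(frozen=True)
class CrossScheme:
    """An outcross followed by ``n_backcrosses`` crosses to the recurrent parent."""

    n_backcrosses: int
    n_loci: int = 1000
    n_sim: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0:
            raise ValueError("n_backcrosses must be >= 0")
        if self.n_loci < 1 or self.n_sim < 1:
            raise ValueError("n_loci and n_sim must be >= 1")


@dataclass(frozen=True)
class Locus:
    """One unlinked locus in a haploid x haploid cross.

    ``parent_a`` / ``parent_b`` are the parental allele states (True = the
    allele of interest is present); ``desired`` is the state wanted in the
    progeny.
    """

    name: str
    parent_a: bool
    parent_b: bool
    desired: bool


@dataclass(frozen=True)
class LocusConfig:
    loci: Sequence[Locus]
    linkage: str = UNLINKED


def introgression_fraction(n_backcrosses: int) -> float:
    """Expected recurrent-parent genome fraction after the backcross series."""
    if n_backcrosses < 0:
        raise ValueError("n_backcrosses must be >= 0")
    return 1.0 - 0.5 ** (n_backcrosses + 1)


@dataclass(frozen=True)
class IntrogressionSummary:
    mean: float
    sd: float
    quantiles: dict[float, float]
    expected: float
    n_sim: int
    n_loci: int


def simulate_introgression(scheme: CrossScheme) -> IntrogressionSummary:
    """Monte-Carlo distribution of the recurrent-parent fraction.

    Each replicate genome carries ``n_loci`` unlinked loci, each inheriting
    the donor allele independently with probability 2**-(n_backcrosses + 1);
    the recurrent fraction is one minus the donor-allele proportion.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(scheme.seed)
    p_donor = 0.5 ** (scheme.n_backcrosses + 1)
    donor = rng.random((scheme.n_sim, scheme.n_loci)) < p_donor
    frac = 1.0 - donor.mean(axis=1)
    qs = (0.025, 0.25, 0.5, 0.75, 0.975)
    return IntrogressionSummary(
        mean=float(frac.mean()),
        sd=float(frac.std(ddof=1)) if scheme.n_sim > 1 else 0.0,
        quantiles={q: float(np.quantile(frac, q)) for q in qs},
        expected=introgression_fraction(scheme.n_backcrosses),
        n_sim=scheme.n_sim,
        n_loci=scheme.n_loci,
    )


def progeny_genotype_frequency(config: LocusConfig) -> float:
    """Probability a random ascospore progeny has the desired genotype.

    Per unlinked locus: 1/2 when the parents differ (the cross segregates
    1:1), 1 when both parents already carry the desired state, 0 when
    neither does. Zero loci means every progeny qualifies.
    """
    if config.linkage != UNLINKED:
        raise ValueError(f"unsupported linkage mode {config.linkage!r}")
    p = 1.0
    for locus in config.loci:
        if locus.parent_a == locus.parent_b:
            p *= 1.0 if locus.parent_a == locus.desired else 0.0
        else:
            p *= 0.5
    return p


def progeny_to_screen(p_desired: float, confidence: float) -> int:
    """Smallest n with P(at least one desired among n progeny) >= confidence."""
    if not 0 < p_desired <= 1:
        raise ValueError("p_desired must be in (0, 1]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if p_desired == 1.0:
        return 1
    n = max(1, math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p_desired)))
    while 1.0 - (1.0 - p_desired) ** n < confidence:  # guard fp edge cases
        n += 1
    while n > 1 and 1.0 - (1.0 - p_desired) ** (n - 1) >= confidence:
        n -= 1
    return n
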