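"""Primer thermodynamics.

Melting temperature from the unified nearest-neighbor parameter set
(SantaLucia 1998 compilation: stacking enthalpies/entropies plus terminal
A·T / G·C initiation terms and a duplex-symmetry correction), with the
associated monovalent-salt entropy correction

    dS' = dS + 0.368 * (N - 1) * ln[Na+]

and the two-state duplex transition

    Tm = 1000 * dH / (dS' + R * ln(C_T / x)) - 273.15

where R = 1.987 cal/(K mol), C_T is total oligo concentration and x = 4 for
non-self-complementary duplexes (x = 1 for self-complementary ones).

Also: GC content, the 3'-terminal G/C run ("GC clamp" guard) and a simple
ungapped self-complementarity score used as a hairpin/dimer filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq import require_unmasked_dna, revcomp

R_GAS = 1.987  # cal / (K mol)

#: Unified NN stacking parameters: dinucleotide (5'->3' top strand) ->
#: (dH kcal/mol, dS cal/(K mol)).  The table lists the ten unique stacks;
#: the remaining six follow by reverse-complement symmetry.
UNIFIED_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

INIT_GC = (0.1, -2.8)  # terminal G·C pair initiation
INIT_AT = (2.3, 4.1)  # terminal A·T pair initiation
SYM_CORRECTION = (0.0, -1.4)  # self-complementary duplex entropy penalty

MIN_PRIMER_LEN = 10
MAX_PRIMER_LEN = 36


def _full_nn_table() -> dict[str, tuple[float, float]]:
    table = dict(UNIFIED_NN)
    for dinuc, hs in UNIFIED_NN.items():
        rc = revcomp(dinuc)
        table.setdefault(rc, hs)
    return table


NN_TABLE = _full_nn_table()


@dataclass(frozen=True)
class ThermoConfig:
    """Solution conditions for Tm prediction.

    monovalent_salt : molar Na+ (default 0.050 M)
    oligo_conc      : total annealing-oligo concentration, molar (default 200 nM)
    """

    monovalent_salt: float = 0.050
    oligo_conc: float = 200e-9
    nn_parameter_set: str = "unified-1998"

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0 or self.oligo_conc <= 0:
            raise ValueError("concentrations must be > 0")
        if self.nn_parameter_set != "unified-1998":
            raise ValueError(f"unknown NN parameter set {self.nn_parameter_set!r}")


DEFAULT_THERMO = ThermoConfig()


def gc_content(seq: str) -> float:
    """Fraction of G+C bases. Rejects masked (lowercase) or ambiguous input."""
    require_unmasked_dna(seq, "primer")
    return (seq.count("G") + seq.count("C")) / len(seq)


def nn_sums(seq: str) -> tuple[float, float]:
    """Total (dH kcal/mol, dS cal/(K mol)) including initiation and symmetry."""
    dh, ds = 0.0, 0.0
    for a, b in ((INIT_GC if seq[0] in "GC" else INIT_AT),
                 (INIT_GC if seq[-1] in "GC" else INIT_AT)):
        dh += a
        ds += b
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i : i + 2]]
        dh += h
        ds += s
    if seq == revcomp(seq):
        dh += SYM_CORRECTION[0]
        ds += SYM_CORRECTION[1]
    return dh, ds


def melting_temperature(seq: str, cfg: ThermoConfig = DEFAULT_THERMO) -> float:
    """Nearest-neighbor duplex melting temperature in deg C."""
    require_unmasked_dna(seq, "primer")
    n = len(seq)
    if not MIN_PRIMER_LEN <= n <= MAX_PRIMER_LEN:
        raise ValueError(
            f"primer length {n} outside [{MIN_PRIMER_LEN}, {MAX_PRIMER_LEN}]"
        )
    dh, ds = nn_sums(seq)
    ds += 0.368 * (n - 1) * math.log(cfg.monovalent_salt)
    x = 1.0 if seq == revcomp(seq) else 4.0
    tm_k = dh * 1000.0 / (ds + R_GAS * math.log(cfg.oligo_conc / x))
    return tm_k - 273.15


def gc_clamp_run(seq: str) -> int:
    """Length of the maximal 3'-terminal run of G/C bases."""
    require_unmasked_dna(seq, "primer")
    run = 0
    for b in reversed(seq):
        if b in "GC":
            run += 1
        else:
            break
    return run


_COMP_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


def self_complementarity(seq: str) -> int:
    """Max count of complementary base pairs over all ungapped self-annealing
    offsets (two antiparallel copies of *seq*).

    Positions i and j pair when i + j lands on a fixed antidiagonal, so the
    per-offset counts are convolutions of base-indicator vectors.
    """
    require_unmasked_dna(seq, "primer")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ind = {b: (arr == ord(b)).astype(np.int32) for b in "ACGT"}
    total = None
    for a, b in _COMP_PAIRS:
        conv = np.convolve(ind[a], ind[b])
        total = conv if total is None else total + conv
    return int(total.max())
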