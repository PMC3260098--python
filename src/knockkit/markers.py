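"""Selectable-marker systems and the mock shuttle vector.

The real pyr4 / amdS / hph cassette sequences and the EcoRI/XhoI-linearised
pRS426 shuttle vector are not redistributable here, so the built-in marker
systems carry deterministic *synthetic* stand-in sequences (i.i.d. bases at
50% GC from a fixed per-name seed). The assembly logic never depends on the
literal sequence content — homology tails are derived from fragment termini —
so swapping in real sequences via :func:`MarkerSystem` construction or FASTA
input changes nothing structurally.

Marker lengths are of realistic magnitude for the three classic fungal
selection cassettes: pyr4 (uridine prototrophy) ~1.7 kb, amdS (acetamide
utilisation) ~2.7 kb, hph (hygromycin B resistance) ~1.4 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import revcomp

MOCK_VECTOR_LENGTH = 5_000
_SCREEN_PRIMER_LEN = 20
#: 5'-side internal screen primer anneals at marker[140:160] (reverse
#: orientation); the 3'-side one at marker[-160:-140] (forward orientation).
_SCREEN_SITE_OFFSET = 140

_MARKER_LENGTHS = {"pyr4": 1_700, "amdS": 2_700, "hph": 1_400}
_MARKER_NOTES = {
    "pyr4": "orotidine-5'-phosphate decarboxylase; selects uridine prototrophy "
            "in a pyr4- / tku70-deletion background (synthetic stand-in sequence)",
    "amdS": "acetamidase; selects growth on acetamide as sole N source; "
            "heterologous, RIP-safe (synthetic stand-in sequence)",
    "hph": "hygromycin B phosphotransferase; selects hygromycin resistance; "
           "heterologous, RIP-safe (synthetic stand-in sequence)",
}
_NAME_SEEDS = {"pyr4": 740_020, "amdS": 120_001, "hph": 120_002, "_vector": 9_414}


def _random_dna(length: int, seed: int, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@dataclass(frozen=True)
class MarkerSystem:
    """A selectable marker plus the vector-end homology context.

    ``vector_left_end`` is the terminus of the linearised vector that abuts
    the 5' flank in the assembled plasmid; ``vector_right_end`` abuts the 3'
    flank. ``internal_screen_primer`` points out of the marker toward the 5'
    junction (reverse orientation on the marker top strand);
    ``internal_screen_primer_3prime`` points toward the 3' junction.
    """

    name: str
    marker_seq: str
    vector_left_end: str
    vector_right_end: str
    internal_screen_primer: str
    internal_screen_primer_3prime: str
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.marker_seq:
            raise ValueError("marker_seq must be non-empty")
        for label, primer in (
            ("internal_screen_primer", revcomp(self.internal_screen_primer)),
            ("internal_screen_primer_3prime", self.internal_screen_primer_3prime),
        ):
            if self.marker_seq.count(primer) != 1:
                raise ValueError(
                    f"{label} must occur exactly once in marker_seq"
                )

    @property
    def screen_site_end_5prime(self) -> int:
        """Offset (from marker start) of the 3' end of the 5'-side screen site."""
        return self.marker_seq.index(revcomp(self.internal_screen_primer)) + len(
            self.internal_screen_primer
        )

    @property
    def screen_site_start_3prime(self) -> int:
        """Distance from the marker *end* to the 5' start of the 3'-side site."""
        return len(self.marker_seq) - self.marker_seq.index(
            self.internal_screen_primer_3prime
        )


def mock_vector() -> str:
    """Synthetic 5 kb linear stand-in for the EcoRI/XhoI-opened shuttle vector.

    By convention the string's *end* abuts the 5' flank and its *start* abuts
    the 3' flank when the gap is repaired into a circle.
    """
    return _random_dna(MOCK_VECTOR_LENGTH, _NAME_SEEDS["_vector"])


def builtin_marker(name: str) -> MarkerSystem:
    """One of the three shipped marker systems: pyr4, amdS or hph."""
    if name not in _MARKER_LENGTHS:
        raise ValueError(
            f"unknown marker {name!r}; choose from {sorted(_MARKER_LENGTHS)}"
        )
    seq = _random_dna(_MARKER_LENGTHS[name], _NAME_SEEDS[name])
    vec = mock_vector()
    site5 = seq[_SCREEN_SITE_OFFSET : _SCREEN_SITE_OFFSET + _SCREEN_PRIMER_LEN]
    site3 = seq[-(_SCREEN_SITE_OFFSET + _SCREEN_PRIMER_LEN) : -_SCREEN_SITE_OFFSET]
    return MarkerSystem(
        name=name,
        marker_seq=seq,
        vector_left_end=vec[-200:],
        vector_right_end=vec[:200],
        internal_screen_primer=revcomp(site5),
        internal_screen_primer_3prime=site3,
        notes=_MARKER_NOTES[name],
    )


BUILTIN_MARKERS = ("pyr4", "amdS", "hph")
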