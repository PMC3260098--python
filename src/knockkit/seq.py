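"""Small shared sequence helpers."""

from __future__ import annotations

from Bio.Seq import Seq

_UPPER_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (soft-masking survives)."""
    return str(Seq(seq).reverse_complement())


def is_unmasked_dna(seq: str) -> bool:
    """True iff *seq* is non-empty, uppercase and unambiguous (A/C/G/T only)."""
    return bool(seq) and all(b in _UPPER_BASES for b in seq)


def require_unmasked_dna(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty {what}")
    bad = {b for b in seq if b not in _UPPER_BASES}
    if bad:
        raise ValueError(
            f"{what} contains non-ACGT or soft-masked characters: {sorted(bad)!r}"
        )
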