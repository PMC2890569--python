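"""Small shared sequence helpers (plain strings over A/C/G/T/N)."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string; non-ACGT characters map to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that position ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]
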