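"""Nucleotide-string helpers shared across the pipeline.

Internal canonical form is uppercase DNA: ``U`` is accepted on input and
mapped to ``T``; comparisons are case-insensitive. Coordinates throughout
the package are 1-based inclusive; conversion to 0-based half-open happens
only at slicing boundaries inside functions.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

VALID_BASES = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Canonicalize a nucleotide string: uppercase DNA, U mapped to T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA string in the RNA alphabet (T -> U)."""
    return normalize(seq).replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet, IUPAC codes complemented)."""
    return normalize(seq).translate(_COMPLEMENT)[::-1]


def subseq(seq: str, start: int, end: int) -> str:
    """1-based inclusive slice."""
    if start < 1 or end > len(seq) or start > end:
        raise ValueError(f"span {start}-{end} outside sequence of length {len(seq)}")
    return seq[start - 1 : end]
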