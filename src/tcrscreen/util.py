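"""Small DNA helpers shared across modules."""

from __future__ import annotations

from .errors import TcrScreenError

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising if it contains non-DNA characters."""
    s = seq.upper()
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(s) - allowed
    if bad:
        raise TcrScreenError(f"invalid characters {sorted(bad)} in {what}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (A<->T, C<->G; N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def kmers(seq: str, k: int) -> set[str]:
    """Set of all k-mers of ``seq`` (empty if shorter than k)."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
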