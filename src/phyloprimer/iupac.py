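"""IUPAC nucleotide ambiguity algebra.

The 15 single-letter codes map bijectively onto the non-empty subsets of
{A, C, G, T}; a degenerate oligonucleotide is the Cartesian product of its
per-position subsets.  Everything downstream (consensus building, primer
degeneracy, in-silico PCR matching) reduces to set operations on this table.
"""

from __future__ import annotations

import itertools
from math import prod

#: code -> frozenset of concrete bases
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: frozenset of bases -> code (inverse of the above; bijection by construction)
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

#: complement is an involution: A<->T, C<->G, R<->Y, K<->M, S/W/N self
COMPLEMENT: dict[str, str] = {
    code: BASES_TO_CODE[frozenset({"A": "T", "T": "A", "C": "G", "G": "C"}[b] for b in bases)]
    for code, bases in CODE_TO_BASES.items()
}


def _check(s: str) -> None:
    for i, c in enumerate(s):
        if c not in CODE_TO_BASES:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i}")


def degeneracy(s: str) -> int:
    """Number of concrete sequences encoded: product of per-position set sizes."""
    _check(s)
    return prod(len(CODE_TO_BASES[c]) for c in s)


def expand(s: str) -> list[str]:
    """All concrete DNA strings encoded by ``s``, lexicographically sorted."""
    _check(s)
    pools = [sorted(CODE_TO_BASES[c]) for c in s]
    return ["".join(p) for p in itertools.product(*pools)]


def revcomp(s: str) -> str:
    """Reverse complement over the full ambiguity alphabet."""
    _check(s)
    return "".join(COMPLEMENT[c] for c in reversed(s))


def consensus_code(bases) -> str:
    """IUPAC code for a non-empty subset of {A,C,G,T}."""
    key = frozenset(bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    try:
        return BASES_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a subset of ACGT: {sorted(key)}") from None


def matches(code: str, base: str) -> bool:
    """True if concrete template ``base`` is compatible with primer ``code``.

    An N in the *template* never matches (conservative: unknown bases are not
    assumed to pair).
    """
    return base in CODE_TO_BASES[code]
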