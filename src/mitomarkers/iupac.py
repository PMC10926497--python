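"""IUPAC nucleotide codes: base sets, ambiguity lookup, reverse complement.

Single-letter ambiguity codes denote sets of bases (W = {A,T}, S = {G,C},
N = {A,C,G,T}, ...). They appear both in consensus sequences and in
restriction-enzyme recognition sites, so the set algebra lives here.
"""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: set of bases -> the unique ambiguity letter
SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)

DNA_LETTERS = frozenset(IUPAC_SETS) | {"-"}


def is_iupac(letter: str) -> bool:
    return letter in IUPAC_SETS


def base_set(letter: str) -> frozenset[str]:
    """Concrete bases denoted by an IUPAC letter; KeyError for non-IUPAC."""
    return IUPAC_SETS[letter]


def ambiguity_code(bases: frozenset[str] | set[str] | str) -> str:
    """The IUPAC letter for a non-empty set of concrete bases."""
    return SET_TO_CODE[frozenset(bases)]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sets_overlap(a: str, b: str) -> bool:
    """True if the two letters share at least one concrete base."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def set_subsumes(site_letter: str, seq_letter: str) -> bool:
    """True if every resolution of ``seq_letter`` matches ``site_letter``."""
    return IUPAC_SETS[seq_letter] <= IUPAC_SETS[site_letter]
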