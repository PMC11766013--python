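"""IUPAC nucleotide codes and gap handling shared across the package.

The alignment gap character ``-`` is treated as a first-class state
throughout: an indel column can be diagnostic, and a gap never matches a
base. Degenerate codes expand to their base sets before any intersection
test, which is conservative — a degenerate panel base that *could* equal a
target base is never called a difference.
"""

from __future__ import annotations

GAP = "-"

#: Single-letter code → set of concrete bases it denotes.
IUPAC_CODES: dict[str, frozenset[str]] = {
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

#: Reverse lookup: frozenset of bases → canonical code.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

VALID_CHARS = frozenset(IUPAC_CODES) | {GAP}
UNAMBIGUOUS = frozenset("ACGT")


def expand(char: str) -> frozenset[str]:
    """Expand one alignment character to its state set (gap stays ``{'-'}``)."""
    if char == GAP:
        return frozenset(GAP)
    try:
        return IUPAC_CODES[char]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {char!r}") from None


def code_for(bases: frozenset[str]) -> str:
    """Canonical IUPAC code for a nonempty set of concrete bases."""
    try:
        return CODE_FOR_SET[frozenset(bases)]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(bases)!r}") from None


def is_degenerate(seq: str) -> bool:
    """True if any character denotes more than one base."""
    return any(c not in UNAMBIGUOUS for c in seq)
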