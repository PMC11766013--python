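"""Oligo properties: length, %GC and melting temperature with IUPAC
degenerate bases.

Two closed-form Tm models are provided, matching the OligoCalc online
calculator that assay designers commonly report:

* **basic**: Wallace rule ``Tm = 2(A+T) + 4(G+C)`` for oligos shorter than
  14 nt, and ``Tm = 64.9 + 41·(GC − 16.4)/N`` otherwise;
* **salt-adjusted** (the reference value here):
  ``Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10([Na+])`` at a default
  monovalent cation concentration of 0.05 M.

Both depend on the sequence only through its length and G+C count, so a
degenerate oligo yields a closed interval obtained at the minimum and
maximum resolvable G+C counts. Nearest-neighbor thermodynamics are
deliberately not implemented: the point of these closed forms is to
reproduce the numbers a designer publishes next to their oligo table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, NamedTuple

import pandas as pd
from Bio.Seq import Seq

from diagpcr.errors import ParameterError, SequenceContentError
from diagpcr.iupac import GAP, IUPAC_CODES

__all__ = [
    "TmInterval",
    "OligoProperties",
    "gc_percent",
    "tm_basic",
    "tm_salt_adjusted",
    "reverse_complement",
    "oligo_properties",
    "properties_table",
    "round_half_up",
    "format_percent",
    "format_tm",
]

GcPolicy = Literal["max_gc", "min_gc", "expected"]

DEFAULT_NA_MOLAR = 0.05


class TmInterval(NamedTuple):
    """Closed Tm interval in °C; a point value has ``min == max``."""

    min: float
    max: float

    @property
    def is_point(self) -> bool:
        return self.min == self.max

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min + self.max)


def _validate_oligo(seq: str) -> str:
    if not seq:
        raise SequenceContentError("empty oligo sequence")
    seq = seq.upper().replace("U", "T")
    for i, char in enumerate(seq):
        if char == GAP:
            raise SequenceContentError(f"gap character at position {i} in oligo")
        if char not in IUPAC_CODES:
            raise SequenceContentError(
                f"illegal character {char!r} at position {i} in oligo"
            )
    return seq


def _gc_count_bounds(seq: str) -> tuple[int, int]:
    """(min, max) G+C count over all resolutions of degenerate codes."""
    lo = hi = 0
    gc = frozenset("GC")
    for char in seq:
        states = IUPAC_CODES[char]
        if states <= gc:
            lo += 1
        if states & gc:
            hi += 1
    return lo, hi


def gc_percent(seq: str, ambiguity: GcPolicy = "max_gc") -> float:
    """Percent G+C of a 5′→3′ IUPAC oligo, exact (unrounded).

    ``max_gc`` (default) counts a degenerate code toward GC whenever its
    base set contains G or C — the convention under which a single M in a
    30-mer with 12 certain G/C gives 13/30 = 43.3%. ``min_gc`` requires the
    code set to be a subset of {G, C}; ``expected`` averages uniformly over
    resolutions.
    """
    seq = _validate_oligo(seq)
    n = len(seq)
    if ambiguity == "expected":
        gc = frozenset("GC")
        total = sum(len(IUPAC_CODES[c] & gc) / len(IUPAC_CODES[c]) for c in seq)
        return 100.0 * total / n
    lo, hi = _gc_count_bounds(seq)
    if ambiguity == "max_gc":
        return 100.0 * hi / n
    if ambiguity == "min_gc":
        return 100.0 * lo / n
    raise ParameterError(f"unknown ambiguity policy {ambiguity!r}")


def _tm_basic_from_counts(n: int, gc: int) -> float:
    if n < 14:
        # Wallace rule: 2 °C per A/T, 4 °C per G/C.
        return 2.0 * (n - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def _tm_salt_from_counts(n: int, gc: int, na_molar: float) -> float:
    return 100.5 + 41.0 * gc / n - 820.0 / n + 16.6 * math.log10(na_molar)


def tm_basic(seq: str) -> TmInterval:
    """Basic (salt-free) Tm in °C; degenerate input yields an interval."""
    seq = _validate_oligo(seq)
    lo, hi = _gc_count_bounds(seq)
    n = len(seq)
    return TmInterval(_tm_basic_from_counts(n, lo), _tm_basic_from_counts(n, hi))


def tm_salt_adjusted(seq: str, na_molar: float = DEFAULT_NA_MOLAR) -> TmInterval:
    """Salt-adjusted Tm in °C at the given monovalent cation concentration.

    This is the reference Tm for reporting: at the default 0.05 M it
    reproduces published oligo-table values. Degenerate input yields the
    interval spanned by the min/max G+C resolutions.
    """
    if na_molar <= 0:
        raise ParameterError(f"na_molar must be positive, got {na_molar}")
    seq = _validate_oligo(seq)
    lo, hi = _gc_count_bounds(seq)
    n = len(seq)
    return TmInterval(
        _tm_salt_from_counts(n, lo, na_molar), _tm_salt_from_counts(n, hi, na_molar)
    )


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (M↔K, R↔Y, ...); an involution."""
    seq = _validate_oligo(seq)
    return str(Seq(seq).reverse_complement())


# -- reporting ---------------------------------------------------------------


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed oligo tables do."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_percent(value: float) -> str:
    """One decimal, with a trailing .0 shown as an integer (45.0 → "45")."""
    rounded = round_half_up(value, 1)
    return f"{rounded:.0f}" if rounded == int(rounded) else f"{rounded:.1f}"


def format_tm(interval: TmInterval) -> str:
    """Point Tm to 0.1 °C; a degenerate interval as an integer range "68–69"."""
    if interval.is_point:
        return format_percent(interval.min)
    lo = round_half_up(interval.min, 0)
    hi = round_half_up(interval.max, 0)
    return f"{lo:.0f}–{hi:.0f}"


@dataclass(frozen=True)
class OligoProperties:
    """Computed property bundle for one oligo."""

    name: str
    sequence: str
    length: int
    gc_percent: float
    tm_basic: TmInterval
    tm_salt: TmInterval
    na_molar: float


def oligo_properties(
    name: str, seq: str, na_molar: float = DEFAULT_NA_MOLAR
) -> OligoProperties:
    seq = _validate_oligo(seq)
    return OligoProperties(
        name=name,
        sequence=seq,
        length=len(seq),
        gc_percent=gc_percent(seq),
        tm_basic=tm_basic(seq),
        tm_salt=tm_salt_adjusted(seq, na_molar),
        na_molar=na_molar,
    )


def properties_table(
    oligos: Iterable[tuple[str, str]], na_molar: float = DEFAULT_NA_MOLAR
) -> pd.DataFrame:
    """Property report for (name, sequence) pairs, one row per oligo.

    Columns mirror a published oligo table: name, sequence, length, %GC
    (formatted at table precision), and both Tm models, with the raw
    salt-adjusted interval endpoints alongside for machine use.
    """
    rows = []
    for name, seq in oligos:
        props = oligo_properties(name, seq, na_molar)
        rows.append(
            {
                "name": props.name,
                "sequence": props.sequence,
                "length": props.length,
                "gc_percent": format_percent(props.gc_percent),
                "tm_basic": format_tm(props.tm_basic),
                "tm_salt": format_tm(props.tm_salt),
                "tm_salt_min": round_half_up(props.tm_salt.min, 1),
                "tm_salt_max": round_half_up(props.tm_salt.max, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "sequence",
            "length",
            "gc_percent",
            "tm_basic",
            "tm_salt",
            "tm_salt_min",
            "tm_salt_max",
        ],
    )
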