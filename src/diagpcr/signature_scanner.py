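"""Scan a species-labelled alignment for diagnostic signature windows.

A column is *diagnostic* against a non-target species when the set of
states observed in the target records shares no character with that
species' states, after expanding degenerate codes and treating the gap as
a state of its own. Indel columns can therefore be diagnostic — probes are
routinely designed across insertion/deletion differences.

Two window roles are searched:

* **probe sites** must contain, for *every* non-target species, a run of at
  least ``min_consecutive`` consecutive diagnostic columns (default 5);
* **primer sites** need at least ``min_diffs`` diagnostic columns against a
  species, not necessarily consecutive (default 3). Windows meeting the
  bar against only a subset of species are still reported, flagged
  ``partial`` — a designer needs only one primer of the pair to clear the
  bar against every species.

Within a window the target must be effectively invariant: each column is
either conserved across target records (a single observed state, which may
be the gap) or, when a ``max_variable_columns`` budget is granted, a
column of intraspecific variation representable as one IUPAC code.
Columns where the target mixes gap and base never qualify. Length
constraints apply to the *degapped* window length — the number of columns
the resulting oligo actually contains.
"""

from __future__ import annotations

from dataclasses import dataclass

from diagpcr.alignment_io import SpeciesAlignment
from diagpcr.errors import ParameterError
from diagpcr.iupac import GAP, code_for, expand

__all__ = [
    "ColumnProfile",
    "SignatureWindow",
    "profile_columns",
    "find_probe_sites",
    "find_primer_sites",
    "windows_table",
]


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column summary of target conservation and diagnosticity."""

    column: int
    target_states: frozenset[str]  # observed characters among target records
    per_species_states: dict[str, frozenset[str]]
    is_target_conserved: bool
    diagnostic_vs: frozenset[str]  # species with empty state intersection

    @property
    def is_target_gap(self) -> bool:
        return self.target_states == frozenset(GAP)

    @property
    def target_has_gap(self) -> bool:
        return GAP in self.target_states


@dataclass(frozen=True)
class SignatureWindow:
    """A candidate oligo footprint in alignment coordinates [start, end)."""

    start: int
    end: int
    role: str  # "probe-site" | "primer-site"
    degapped_length: int
    consecutive_diag_run: int  # min over species of best run in window
    diag_positions: int  # min over species of diagnostic-column count
    species_covered: frozenset[str]
    partial: bool = False
    variable_columns: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def profile_columns(aln: SpeciesAlignment, target: str) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per alignment column.

    Diagnosticity is computed on expanded state sets: degenerate codes in
    either the target or a panel species widen the intersection, so fewer
    columns are called diagnostic (conservative direction).
    """
    target_records = aln.records_for(target)
    non_target_species = [sp for sp in aln.species if sp != target]
    profiles: list[ColumnProfile] = []
    for col in range(aln.n_columns):
        target_states = frozenset(rec.sequence[col] for rec in target_records)
        target_expanded = frozenset().union(*(expand(c) for c in target_states))
        per_species: dict[str, frozenset[str]] = {}
        diagnostic: set[str] = set()
        for sp in non_target_species:
            states = frozenset(rec.sequence[col] for rec in aln.records_for(sp))
            per_species[sp] = states
            expanded = frozenset().union(*(expand(c) for c in states))
            if not (target_expanded & expanded):
                diagnostic.add(sp)
        profiles.append(
            ColumnProfile(
                column=col,
                target_states=target_states,
                per_species_states=per_species,
                is_target_conserved=len(target_states) == 1,
                diagnostic_vs=frozenset(diagnostic),
            )
        )
    return profiles


def _check_length_range(length_range: tuple[int, int]) -> None:
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ParameterError(f"invalid length range {length_range}")


def _column_usable(p: ColumnProfile) -> tuple[bool, bool]:
    """(usable, counts_against_variable_budget) for one column.

    A conserved column (single observed state, gap included) is free; a
    column of pure intraspecific base variation (no gap in target) is
    usable only against the degeneracy budget; a gap/base mix is never
    usable inside an oligo footprint.
    """
    if p.is_target_conserved:
        return True, False
    if p.target_has_gap:
        return False, False
    return True, True


def _max_run(flags: list[bool]) -> int:
    best = run = 0
    for flag in flags:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def _scan_windows(
    profiles: list[ColumnProfile],
    length_range: tuple[int, int],
    max_variable_columns: int,
) -> list[tuple[int, int, int, int]]:
    """Enumerate (start, end, degapped_length, variable_count) for windows
    whose target is usable throughout and whose degapped length is in range."""
    lo, hi = length_range
    n = len(profiles)
    out = []
    for start in range(n):
        degapped = 0
        variable = 0
        for end in range(start + 1, n + 1):
            p = profiles[end - 1]
            usable, is_variable = _column_usable(p)
            if not usable:
                break
            if is_variable:
                variable += 1
            if not p.is_target_gap:
                degapped += 1
            if variable > max_variable_columns or degapped > hi:
                break
            if degapped >= lo:
                out.append((start, end, degapped, variable))
    return out


def find_probe_sites(
    aln: SpeciesAlignment,
    target: str,
    min_consecutive: int = 5,
    length_range: tuple[int, int] = (18, 32),
    max_variable_columns: int = 0,
    profiles: list[ColumnProfile] | None = None,
) -> list[SignatureWindow]:
    """Windows usable as hydrolysis-probe footprints.

    Every returned window contains, for each non-target species, at least
    ``min_consecutive`` consecutive columns diagnostic against that
    species (runs may sit at different positions for different species).
    Results are sorted by (start, end).
    """
    _check_length_range(length_range)
    if min_consecutive < 1:
        raise ParameterError("min_consecutive must be ≥ 1")
    if profiles is None:
        profiles = profile_columns(aln, target)
    non_target = [sp for sp in aln.species if sp != target]
    windows: list[SignatureWindow] = []
    for start, end, degapped, variable in _scan_windows(
        profiles, length_range, max_variable_columns
    ):
        runs = []
        counts = []
        qualifies = True
        for sp in non_target:
            flags = [sp in profiles[c].diagnostic_vs for c in range(start, end)]
            run = _max_run(flags)
            if run < min_consecutive:
                qualifies = False
                break
            runs.append(run)
            counts.append(sum(flags))
        if not qualifies or not non_target:
            continue
        windows.append(
            SignatureWindow(
                start=start,
                end=end,
                role="probe-site",
                degapped_length=degapped,
                consecutive_diag_run=min(runs),
                diag_positions=min(counts),
                species_covered=frozenset(non_target),
                variable_columns=variable,
            )
        )
    return sorted(windows, key=lambda w: (w.start, w.end))


def find_primer_sites(
    aln: SpeciesAlignment,
    target: str,
    min_diffs: int = 3,
    length_range: tuple[int, int] = (17, 25),
    max_variable_columns: int = 0,
    include_partial: bool = True,
    profiles: list[ColumnProfile] | None = None,
) -> list[SignatureWindow]:
    """Windows usable as primer footprints.

    A window *covers* a species when it holds ≥ ``min_diffs`` diagnostic
    columns against it (any positions). Windows covering every non-target
    species are returned with ``partial=False``; windows covering a
    nonempty proper subset are flagged ``partial=True`` (dropped entirely
    when ``include_partial`` is false). Sorted by (start, end).
    """
    _check_length_range(length_range)
    if min_diffs < 1:
        raise ParameterError("min_diffs must be ≥ 1")
    if profiles is None:
        profiles = profile_columns(aln, target)
    non_target = [sp for sp in aln.species if sp != target]
    windows: list[SignatureWindow] = []
    for start, end, degapped, variable in _scan_windows(
        profiles, length_range, max_variable_columns
    ):
        covered = set()
        runs = []
        counts = []
        for sp in non_target:
            flags = [sp in profiles[c].diagnostic_vs for c in range(start, end)]
            count = sum(flags)
            if count >= min_diffs:
                covered.add(sp)
            runs.append(_max_run(flags))
            counts.append(count)
        if not covered:
            continue
        partial = len(covered) < len(non_target)
        if partial and not include_partial:
            continue
        windows.append(
            SignatureWindow(
                start=start,
                end=end,
                role="primer-site",
                degapped_length=degapped,
                consecutive_diag_run=min(runs),
                diag_positions=min(counts),
                species_covered=frozenset(covered),
                partial=partial,
                variable_columns=variable,
            )
        )
    return sorted(windows, key=lambda w: (w.start, w.end))


def consensus_chars(aln: SpeciesAlignment, target: str) -> list[str | None]:
    """Per-column target consensus character.

    ``None`` marks an all-gap target column (skipped in oligos);
    intraspecific variation collapses to the IUPAC code of the observed
    base union; a gap/base mix has no consensus and raises when an oligo
    is requested across it (see :func:`window_oligo_sequence`).
    """
    target_records = aln.records_for(target)
    out: list[str | None] = []
    for col in range(aln.n_columns):
        states = frozenset(rec.sequence[col] for rec in target_records)
        if states == frozenset(GAP):
            out.append(None)
        elif GAP in states:
            out.append("!")  # sentinel: mixed gap/base, unusable
        else:
            bases = frozenset().union(*(expand(c) for c in states))
            out.append(code_for(bases))
    return out


def window_oligo_sequence(
    aln: SpeciesAlignment,
    target: str,
    start: int,
    end: int,
    consensus: list[str | None] | None = None,
) -> str:
    """Degapped target consensus over [start, end); intraspecific variation
    becomes an IUPAC code, target-gap columns are skipped."""
    if consensus is None:
        consensus = consensus_chars(aln, target)
    chars: list[str] = []
    for col in range(start, end):
        char = consensus[col]
        if char is None:
            continue
        if char == "!":
            raise ParameterError(
                f"column {col}: target mixes gap and base; no consensus oligo"
            )
        chars.append(char)
    return "".join(chars)


def windows_table(windows: list[SignatureWindow]):
    """TSV-ready report of windows (0-based half-open alignment coordinates)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start": w.start,
                "end": w.end,
                "role": w.role,
                "degapped_length": w.degapped_length,
                "min_consecutive_run": w.consecutive_diag_run,
                "min_diag_positions": w.diag_positions,
                "species_covered": ",".join(sorted(w.species_covered)),
                "partial": w.partial,
            }
            for w in windows
        ],
        columns=[
            "start",
            "end",
            "role",
            "degapped_length",
            "min_consecutive_run",
            "min_diag_positions",
            "species_covered",
            "partial",
        ],
    )
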