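"""Assemble and rank candidate assays (forward primer, reverse primer,
hydrolysis probe) from signature windows.

An assay candidate is a non-overlapping triple of windows in alignment
order forward < probe < reverse, where:

* the probe window carries a run of ≥ ``min_consecutive_probe_diffs``
  consecutive diagnostic columns against *every* non-target species;
* at least one of the two primers carries ≥ ``min_primer_diffs``
  diagnostic columns against every non-target species (the other primer
  may match non-targets — specificity rides on the pair plus probe);
* the degapped target amplicon length, oligo lengths, %GC and
  salt-adjusted Tm all sit inside the configured intervals, with the probe
  Tm at least ``probe_tm_offset`` °C above the hotter primer, the usual
  hydrolysis-probe design rule.

Ranking is deterministic and lexicographic: widest worst-case probe run
first, then total worst-case primer mismatch count, then amplicon length
closest to ``preferred_amplicon`` (short amplicons tolerate the degraded
DNA typical of intercepted specimens), then 5′-most coordinates. The
qualifying triple space on a realistic alignment is dominated by ±1-column
shift variants of the same underlying signature, so scoring runs
vectorised over the full space and only the ``max_candidates`` best
triples are materialised; ranking is still computed over every qualifying
triple, making the output deterministic and, for small inputs (or
``max_candidates=None``), exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from diagpcr.alignment_io import SpeciesAlignment
from diagpcr.errors import ParameterError, SpeciesLookupError
from diagpcr.iupac import GAP, expand
from diagpcr.oligo_thermo import (
    DEFAULT_NA_MOLAR,
    TmInterval,
    format_percent,
    format_tm,
    gc_percent,
    reverse_complement,
    tm_salt_adjusted,
)
from diagpcr.signature_scanner import (
    ColumnProfile,
    SignatureWindow,
    _max_run,
    _scan_windows,
    consensus_chars,
    find_probe_sites,
    profile_columns,
    window_oligo_sequence,
)

__all__ = [
    "DesignConstraints",
    "OligoCandidate",
    "AssayCandidate",
    "design_assays",
    "render_assay_report",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable design thresholds; defaults follow standard hydrolysis-probe
    practice for short diagnostic amplicons."""

    min_consecutive_probe_diffs: int = 5
    min_primer_diffs: int = 3
    amplicon_length: tuple[int, int] = (60, 150)
    primer_length: tuple[int, int] = (17, 25)
    probe_length: tuple[int, int] = (18, 32)
    primer_tm: tuple[float, float] = (50.0, 65.0)
    probe_tm_offset: float = 5.0
    gc: tuple[float, float] = (30.0, 70.0)
    na_molar: float = DEFAULT_NA_MOLAR
    degenerate_budget: int = 1  # IUPAC positions allowed per oligo
    preferred_amplicon: int = 80

    def __post_init__(self) -> None:
        for name in ("amplicon_length", "primer_length", "probe_length", "primer_tm", "gc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} interval is empty: {lo} > {hi}")
        if self.probe_tm_offset < 0 or self.degenerate_budget < 0:
            raise ParameterError("offsets and budgets must be ≥ 0")


@dataclass(frozen=True)
class OligoCandidate:
    """A designed oligo: role, alignment footprint, 5′→3′ sequence, properties."""

    role: str  # "forward" | "reverse" | "probe"
    start: int
    end: int
    sequence: str  # degapped; reverse primer is bottom-strand 5′→3′
    gc_percent: float
    tm_salt: TmInterval

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssayCandidate:
    forward: OligoCandidate
    reverse: OligoCandidate
    probe: OligoCandidate
    amplicon_span: tuple[int, int]  # alignment columns [fwd.start, rev.end)
    amplicon_length: int  # degapped target bases
    probe_min_run: int  # worst-case consecutive diagnostic run
    primer_total_diffs: int  # summed worst-case per-primer mismatch minima
    mismatch_summary: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def oligos(self) -> tuple[OligoCandidate, OligoCandidate, OligoCandidate]:
        return (self.forward, self.reverse, self.probe)


class _MismatchTable:
    """Per-record cumulative mismatch counts against the target consensus,
    so any span's worst-case (fewest-mismatch) count per species is two
    array lookups instead of a column scan."""

    def __init__(self, aln: SpeciesAlignment, target: str) -> None:
        target_records = aln.records_for(target)
        n_cols = aln.n_columns
        union_states = [
            frozenset().union(*(expand(rec.sequence[c]) for rec in target_records))
            for c in range(n_cols)
        ]
        self.species_rows: dict[str, list[int]] = {}
        prefix_rows = []
        for rec in aln.records:
            if rec.species == target:
                continue
            flags = [
                0 if (union_states[c] & expand(rec.sequence[c])) else 1
                for c in range(n_cols)
            ]
            self.species_rows.setdefault(rec.species, []).append(len(prefix_rows))
            prefix_rows.append(np.concatenate(([0], np.cumsum(flags))))
        self.prefix = np.asarray(prefix_rows)

    def min_by_species(self, start: int, end: int) -> dict[str, int]:
        counts = self.prefix[:, end] - self.prefix[:, start]
        return {sp: int(counts[rows].min()) for sp, rows in self.species_rows.items()}

    def worst_case(self, start: int, end: int) -> int:
        """Fewest mismatches any non-target record shows over the span."""
        return min(self.min_by_species(start, end).values())


def _primer_windows(
    profiles: list[ColumnProfile],
    non_target: list[str],
    constraints: DesignConstraints,
) -> list[SignatureWindow]:
    """All target-conserved primer-length windows with per-species coverage.

    Unlike the scanner's primer search, windows diagnostic against *no*
    species are kept: only one primer of a pair must clear the difference
    bar, and the companion primer merely needs to sit on conserved target
    sequence.
    """
    out = []
    for start, end, degapped, variable in _scan_windows(
        profiles, constraints.primer_length, constraints.degenerate_budget
    ):
        covered = set()
        runs, counts = [], []
        for sp in non_target:
            flags = [sp in profiles[c].diagnostic_vs for c in range(start, end)]
            count = sum(flags)
            if count >= constraints.min_primer_diffs:
                covered.add(sp)
            runs.append(_max_run(flags))
            counts.append(count)
        out.append(
            SignatureWindow(
                start=start,
                end=end,
                role="primer-site",
                degapped_length=degapped,
                consecutive_diag_run=min(runs) if runs else 0,
                diag_positions=min(counts) if counts else 0,
                species_covered=frozenset(covered),
                partial=len(covered) < len(non_target),
                variable_columns=variable,
            )
        )
    out.sort(key=lambda w: (w.start, w.end))
    return out


def _make_oligo(
    aln: SpeciesAlignment,
    target: str,
    window: SignatureWindow,
    role: str,
    constraints: DesignConstraints,
    consensus: list[str | None] | None = None,
) -> OligoCandidate | None:
    """Realise a window as an oligo; None when thermo constraints fail."""
    top = window_oligo_sequence(aln, target, window.start, window.end, consensus)
    seq = reverse_complement(top) if role == "reverse" else top
    gc = gc_percent(seq)
    if not (constraints.gc[0] <= gc <= constraints.gc[1]):
        return None
    tm = tm_salt_adjusted(seq, constraints.na_molar)
    if role in ("forward", "reverse"):
        if not (constraints.primer_tm[0] <= tm.midpoint <= constraints.primer_tm[1]):
            return None
    return OligoCandidate(
        role=role, start=window.start, end=window.end, sequence=seq,
        gc_percent=gc, tm_salt=tm,
    )


def _target_gap_flags(aln: SpeciesAlignment, target: str) -> list[bool]:
    """Per-column flag: all target records gapped (column absent from amplicon)."""
    target_records = aln.records_for(target)
    return [
        all(rec.sequence[c] == GAP for rec in target_records)
        for c in range(aln.n_columns)
    ]


def _realise_all(
    aln: SpeciesAlignment,
    target: str,
    windows: list[SignatureWindow],
    role: str,
    constraints: DesignConstraints,
    consensus: list[str | None],
) -> tuple[list[SignatureWindow], list[OligoCandidate]]:
    kept_w, kept_o = [], []
    for window in windows:
        oligo = _make_oligo(aln, target, window, role, constraints, consensus)
        if oligo is not None:
            kept_w.append(window)
            kept_o.append(oligo)
    return kept_w, kept_o


def design_assays(
    aln: SpeciesAlignment,
    target: str,
    constraints: DesignConstraints = DesignConstraints(),
    max_candidates: int | None = 200,
) -> list[AssayCandidate]:
    """Enumerate, rank, and return assay candidates satisfying the constraints.

    Scoring covers every qualifying (forward, probe, reverse) triple; at
    most ``max_candidates`` best-ranked triples are returned as realised
    :class:`AssayCandidate` objects (``None`` materialises all — exhaustive
    mode for small alignments). Deterministic: the same alignment and
    constraints always yield the same ordered list. Returns an empty list
    when no window combination works; refuses outright
    (``SpeciesLookupError``) when the alignment has no non-target species,
    since specificity would be undefined.
    """
    aln.records_for(target)
    non_target = [sp for sp in aln.species if sp != target]
    if not non_target:
        raise SpeciesLookupError(
            "alignment has no non-target species; cannot design a "
            "species-diagnostic assay"
        )
    profiles = profile_columns(aln, target)
    consensus = consensus_chars(aln, target)
    probe_w = find_probe_sites(
        aln,
        target,
        min_consecutive=constraints.min_consecutive_probe_diffs,
        length_range=constraints.probe_length,
        max_variable_columns=constraints.degenerate_budget,
        profiles=profiles,
    )
    primer_w = _primer_windows(profiles, non_target, constraints)
    probe_w, probe_o = _realise_all(aln, target, probe_w, "probe", constraints, consensus)
    fwd_w, fwd_o = _realise_all(aln, target, primer_w, "forward", constraints, consensus)
    rev_w, rev_o = _realise_all(aln, target, primer_w, "reverse", constraints, consensus)
    if not probe_w or not fwd_w or not rev_w:
        return []
    if max(len(fwd_w), len(rev_w), len(probe_w)) >= (1 << 14):
        raise ParameterError(
            "window space too large to rank; restrict the design to a "
            "sub-alignment or tighten the length constraints"
        )

    mismatch = _MismatchTable(aln, target)
    gap_flags = _target_gap_flags(aln, target)
    prefix = np.concatenate(([0], np.cumsum([0 if f else 1 for f in gap_flags])))

    def arrays(ws, os_):
        return {
            "start": np.array([w.start for w in ws]),
            "end": np.array([w.end for w in ws]),
            "full": np.array([not w.partial for w in ws]),
            "tm": np.array([o.tm_salt.midpoint for o in os_]),
            "wc": np.array([mismatch.worst_case(w.start, w.end) for w in ws]),
        }

    fa, ra = arrays(fwd_w, fwd_o), arrays(rev_w, rev_o)
    pa = arrays(probe_w, probe_o)
    p_run = np.array([w.consecutive_diag_run for w in probe_w])

    amp_lo, amp_hi = constraints.amplicon_length
    offset = constraints.probe_tm_offset

    # One packed uint64 rank key per triple, ascending-lexicographic:
    #   [run (inverted, 6b) | primer diffs (inverted, 6b) | amplicon
    #    distance (10b) | fwd idx (14b) | probe idx (14b) | rev idx (14b)]
    # Window lists are (start, end)-sorted, so index order IS coordinate
    # order and the low bits give deterministic 5'-most tie-breaking.
    run_inv = (63 - np.minimum(p_run, 63)).astype(np.uint64)
    keys_per_fwd: list[np.ndarray] = []
    for fi in range(len(fwd_w)):
        f_start, f_end = int(fa["start"][fi]), int(fa["end"][fi])
        rev_ok = ra["start"] >= f_end
        if not fa["full"][fi]:
            rev_ok &= ra["full"]
        amp = prefix[ra["end"]] - prefix[f_start]
        rev_ok &= (amp >= amp_lo) & (amp <= amp_hi)
        ris = np.nonzero(rev_ok)[0]
        if ris.size == 0:
            continue
        probe_ok = (pa["start"] >= f_end) & (pa["tm"] >= fa["tm"][fi] + offset)
        pis = np.nonzero(probe_ok)[0]
        if pis.size == 0:
            continue
        fit = (pa["end"][pis][None, :] <= ra["start"][ris][:, None]) & (
            pa["tm"][pis][None, :] >= ra["tm"][ris][:, None] + offset
        )
        r_idx, p_idx = np.nonzero(fit)
        if r_idx.size == 0:
            continue
        ris_sel = ris[r_idx].astype(np.uint64)
        pis_sel = pis[p_idx].astype(np.uint64)
        diffs = fa["wc"][fi] + ra["wc"][ris[r_idx]]
        diffs_inv = (63 - np.minimum(diffs, 63)).astype(np.uint64)
        amp_dist = np.minimum(
            np.abs(amp[ris[r_idx]] - constraints.preferred_amplicon), 1023
        ).astype(np.uint64)
        keys = (
            (run_inv[pis[p_idx]] << np.uint64(58))
            | (diffs_inv << np.uint64(52))
            | (amp_dist << np.uint64(42))
            | (np.uint64(fi) << np.uint64(28))
            | (pis_sel << np.uint64(14))
            | ris_sel
        )
        keys_per_fwd.append(keys)
    if not keys_per_fwd:
        return []
    all_keys = np.concatenate(keys_per_fwd)
    if max_candidates is not None and all_keys.size > max_candidates:
        part = np.argpartition(all_keys, max_candidates - 1)[:max_candidates]
        chosen = np.sort(all_keys[part])
    else:
        chosen = np.sort(all_keys)

    mask14 = np.uint64((1 << 14) - 1)
    candidates: list[AssayCandidate] = []
    for key in chosen:
        ri = int(key & mask14)
        pi = int((key >> np.uint64(14)) & mask14)
        fi = int((key >> np.uint64(28)) & mask14)
        fwd, rev, probe = fwd_o[fi], rev_o[ri], probe_o[pi]
        per_oligo = [
            mismatch.min_by_species(o.start, o.end) for o in (fwd, rev, probe)
        ]
        summary = {
            sp: (per_oligo[0][sp], per_oligo[1][sp], per_oligo[2][sp])
            for sp in per_oligo[0]
        }
        candidates.append(
            AssayCandidate(
                forward=fwd,
                reverse=rev,
                probe=probe,
                amplicon_span=(fwd.start, rev.end),
                amplicon_length=int(prefix[rev.end] - prefix[fwd.start]),
                probe_min_run=probe_w[pi].consecutive_diag_run,
                primer_total_diffs=int(fa["wc"][fi] + ra["wc"][ri]),
                mismatch_summary=summary,
            )
        )
    return candidates


def render_assay_report(candidates: list[AssayCandidate]) -> pd.DataFrame:
    """Oligo table in the layout of a published primer/probe table.

    One row per oligo; the amplicon length is printed on the forward-primer
    row only; degenerate Tm renders as an integer range.
    """
    rows = []
    for i, cand in enumerate(candidates, start=1):
        for oligo, suffix in ((cand.forward, "F"), (cand.reverse, "R"), (cand.probe, "P")):
            rows.append(
                {
                    "oligo_name": f"assay{i}{suffix}",
                    "sequence": oligo.sequence,
                    "amplicon_length": cand.amplicon_length if suffix == "F" else "",
                    "oligo_length": oligo.length,
                    "gc_percent": format_percent(oligo.gc_percent),
                    "tm_c": format_tm(oligo.tm_salt),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "oligo_name",
            "sequence",
            "amplicon_length",
            "oligo_length",
            "gc_percent",
            "tm_c",
        ],
    )
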