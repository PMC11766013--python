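"""Permissive in-silico amplification screen and panel metrics.

Permissive PCR conditions can tolerate a few mismatches between an oligo
and its template — as many as three across a primer or probe — so the
screen predicts amplification for a panel record whenever *every* oligo of
the assay has at most ``permissive_threshold`` mismatches against it
(default 3; a ``stringent`` preset of 1 is available for sensitivity
analysis). The probe participates in the predicate: an unbound hydrolysis
probe yields no signal even when both primers extend.

Mismatches are counted column-wise on the shared alignment: a column
mismatches when the record's expanded state set does not intersect the
oligo's, with gaps counting as states (a 2-base deletion inside a primer
footprint is 2 mismatches). Degenerate codes intersect by base set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from diagpcr.alignment_io import AlignmentRecord, SpeciesAlignment
from diagpcr.assay_designer import AssayCandidate
from diagpcr.errors import CoordinateError, ParameterError, SpeciesLabelError
from diagpcr.iupac import expand

__all__ = [
    "ScreenResult",
    "PanelMetrics",
    "PERMISSIVE_THRESHOLD",
    "STRINGENT_THRESHOLD",
    "count_oligo_mismatches",
    "predict_amplification",
    "screen_panel",
    "panel_metrics",
    "screen_table",
]

PERMISSIVE_THRESHOLD = 3
STRINGENT_THRESHOLD = 1


@dataclass(frozen=True)
class ScreenResult:
    record_id: str
    species: str
    mismatches: tuple[int, int, int]  # (forward, reverse, probe)
    predicted: str  # "amplifies" | "blocked"
    blocking_oligo: tuple[str, ...]  # oligo roles over threshold


@dataclass(frozen=True)
class PanelMetrics:
    """Inclusivity/exclusivity bookkeeping for a tested panel.

    ``inclusivity`` = 100·TP/(TP+FN); ``specificity`` = 100·TN/(TN+FP).
    A percentage whose denominator class is empty is ``None`` (undefined),
    never coerced to 0.
    """

    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    @property
    def panel_size(self) -> int:
        return (
            self.true_positives
            + self.false_negatives
            + self.true_negatives
            + self.false_positives
        )

    @property
    def inclusivity(self) -> float | None:
        denom = self.true_positives + self.false_negatives
        return 100.0 * self.true_positives / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.true_negatives + self.false_positives
        return 100.0 * self.true_negatives / denom if denom else None


def count_oligo_mismatches(
    aln: SpeciesAlignment,
    target: str,
    start: int,
    end: int,
    record: AlignmentRecord,
) -> int:
    """Mismatches of ``record`` against the target consensus over [start, end).

    The oligo's per-column state set is the union of target states; at
    columns where the target is entirely gapped the oligo "expects" a gap,
    so a base there (an insertion relative to the oligo) is a mismatch.
    """
    if start < 0 or end > aln.n_columns or start >= end:
        raise CoordinateError(f"span [{start}, {end}) outside alignment")
    target_records = aln.records_for(target)
    mismatches = 0
    for col in range(start, end):
        oligo_states = frozenset().union(
            *(expand(rec.sequence[col]) for rec in target_records)
        )
        record_states = expand(record.sequence[col])
        if not (oligo_states & record_states):
            mismatches += 1
    return mismatches


def predict_amplification(
    aln: SpeciesAlignment,
    target: str,
    assay: AssayCandidate,
    record: AlignmentRecord,
    permissive_threshold: int = PERMISSIVE_THRESHOLD,
) -> ScreenResult:
    """Predict whether one panel record amplifies under the assay."""
    if permissive_threshold < 0:
        raise ParameterError("permissive_threshold must be ≥ 0")
    counts = tuple(
        count_oligo_mismatches(aln, target, oligo.start, oligo.end, record)
        for oligo in (assay.forward, assay.reverse, assay.probe)
    )
    blocking = tuple(
        role
        for role, count in zip(("forward", "reverse", "probe"), counts)
        if count > permissive_threshold
    )
    return ScreenResult(
        record_id=record.record_id,
        species=record.species,
        mismatches=counts,
        predicted="blocked" if blocking else "amplifies",
        blocking_oligo=blocking,
    )


def screen_panel(
    aln: SpeciesAlignment,
    target: str,
    assay: AssayCandidate,
    permissive_threshold: int = PERMISSIVE_THRESHOLD,
) -> list[ScreenResult]:
    """Screen every record of the alignment against the assay."""
    return [
        predict_amplification(aln, target, assay, rec, permissive_threshold)
        for rec in aln.records
    ]


def panel_metrics(
    calls: Iterable[tuple[str, bool]],
    target: str,
) -> PanelMetrics:
    """Confusion counts from (species, called_positive) pairs.

    Works identically for in-silico screen predictions and observed qPCR
    outcomes; the caller maps its result type to a positive/negative call.
    """
    tp = fn = tn = fp = 0
    for species, positive in calls:
        if not species:
            raise SpeciesLabelError("panel member without a species label")
        if species == target:
            tp, fn = (tp + 1, fn) if positive else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if positive else (fp, tn + 1)
    return PanelMetrics(tp, fn, tn, fp)


def metrics_from_screen(results: Iterable[ScreenResult], target: str) -> PanelMetrics:
    return panel_metrics(
        ((r.species, r.predicted == "amplifies") for r in results), target
    )


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    """TSV-ready screen report."""
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "species": r.species,
                "fwd_mismatches": r.mismatches[0],
                "rev_mismatches": r.mismatches[1],
                "probe_mismatches": r.mismatches[2],
                "predicted": r.predicted,
                "blocking_oligo": ",".join(r.blocking_oligo),
            }
            for r in results
        ],
        columns=[
            "record_id",
            "species",
            "fwd_mismatches",
            "rev_mismatches",
            "probe_mismatches",
            "predicted",
            "blocking_oligo",
        ],
    )
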