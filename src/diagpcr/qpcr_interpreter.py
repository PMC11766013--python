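"""Interpret duplex qPCR runs: a diagnostic probe (FAM channel) multiplexed
with a universal 18S internal-control probe (Quasar 670 channel).

The internal control distinguishes a true negative (control amplifies,
diagnostic does not) from a failed extraction (neither amplifies). The
decision tree is total over the Cq domain, ``ND`` included:

=====================  =====================  ==========================
diagnostic detected    control detected       call
=====================  =====================  ==========================
yes                    yes, |ΔCq| ≤ fail      TARGET_POSITIVE
yes                    yes, |ΔCq| > fail      ANOMALOUS (DCQ_FAIL)
no                     yes                    NOT_TARGET
yes                    no                     ANOMALOUS (retest: control
                                              failed while diagnostic fired)
no                     no                     INVALID_DNA (re-extract)
=====================  =====================  ==========================

ΔCq = control − diagnostic. |ΔCq| above the warn threshold (default 4
cycles) flags ``DCQ_WARN`` without changing the call; above the fail
threshold (default 6) the result is anomalous. "Detected" means a Cq is
present and at most ``cq_cutoff`` (default 39, the cycle count of the run
protocol). A no-template control showing any signal in either channel
invalidates the whole run.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal

import pandas as pd

from diagpcr.errors import ParameterError, PlateFormatError
from diagpcr.insilico_specificity import PanelMetrics, panel_metrics

__all__ = [
    "Call",
    "SpecimenResult",
    "InterpretationParams",
    "Outcome",
    "RunVerdict",
    "classify_specimen",
    "validate_run",
    "batch_interpret",
    "read_plate",
    "outcomes_table",
]

DIAG_CHANNEL_ALIASES = {"FAM", "DIAG", "DIAGNOSTIC", "ITS", "ITS2"}
CONTROL_CHANNEL_ALIASES = {"QUASAR670", "QUASAR", "CONTROL", "18S"}
ND_TOKENS = {"", "ND", "N/A", "NA", "NONE", "NAN"}


class Call(enum.Enum):
    TARGET_POSITIVE = "TARGET_POSITIVE"
    NOT_TARGET = "NOT_TARGET"
    INVALID_DNA = "INVALID_DNA"
    ANOMALOUS = "ANOMALOUS"


@dataclass(frozen=True)
class SpecimenResult:
    """Per-specimen Cq pair; ``None`` encodes no amplification (never 0 or 40)."""

    specimen_id: str
    cq_diag: float | None
    cq_control: float | None
    well: str | None = None
    is_ntc: bool = False


@dataclass(frozen=True)
class InterpretationParams:
    max_cycles: int = 39
    cq_cutoff: float = 39.0
    dcq_warn: float = 4.0
    dcq_fail: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.dcq_warn <= self.dcq_fail):
            raise ParameterError("require 0 < dcq_warn ≤ dcq_fail")
        if self.cq_cutoff > self.max_cycles:
            raise ParameterError("cq_cutoff cannot exceed max_cycles")


@dataclass(frozen=True)
class Outcome:
    specimen_id: str
    call: Call
    delta_cq: float | None  # control − diagnostic, when both present
    flags: frozenset[str] = frozenset()
    advice: str = ""


@dataclass(frozen=True)
class RunVerdict:
    valid: bool
    warnings: tuple[str, ...] = ()
    failing_ntcs: tuple[str, ...] = ()


def _validate_cq(value: float | None, params: InterpretationParams, label: str) -> None:
    if value is None:
        return
    if math.isnan(value) or value <= 0 or value > params.max_cycles:
        raise ParameterError(
            f"{label}: Cq {value} outside (0, {params.max_cycles}]"
        )


def classify_specimen(
    result: SpecimenResult,
    params: InterpretationParams = InterpretationParams(),
) -> Outcome:
    """Apply the decision tree to one (non-NTC) specimen."""
    if result.is_ntc:
        raise ParameterError("NTC wells are judged by validate_run, not classified")
    _validate_cq(result.cq_diag, params, f"{result.specimen_id} diagnostic")
    _validate_cq(result.cq_control, params, f"{result.specimen_id} control")

    diag_pos = result.cq_diag is not None and result.cq_diag <= params.cq_cutoff
    ctrl_pos = result.cq_control is not None and result.cq_control <= params.cq_cutoff
    delta = (
        result.cq_control - result.cq_diag
        if (result.cq_diag is not None and result.cq_control is not None)
        else None
    )

    flags: set[str] = set()
    if diag_pos and ctrl_pos:
        assert delta is not None
        if abs(delta) > params.dcq_fail:
            return Outcome(
                result.specimen_id,
                Call.ANOMALOUS,
                delta,
                frozenset({"DCQ_FAIL"}),
                advice="duplex channels disagree beyond QC bounds; retest",
            )
        if abs(delta) > params.dcq_warn:
            flags.add("DCQ_WARN")
        return Outcome(result.specimen_id, Call.TARGET_POSITIVE, delta, frozenset(flags))
    if ctrl_pos:
        return Outcome(result.specimen_id, Call.NOT_TARGET, delta)
    if diag_pos:
        return Outcome(
            result.specimen_id,
            Call.ANOMALOUS,
            delta,
            frozenset({"CONTROL_FAILURE"}),
            advice="diagnostic signal without internal control; retest",
        )
    return Outcome(
        result.specimen_id,
        Call.INVALID_DNA,
        delta,
        advice="no amplification in either channel; re-extract DNA",
    )


def validate_run(results: Iterable[SpecimenResult]) -> RunVerdict:
    """Run-level QC: any signal in a no-template control invalidates the run."""
    ntcs = [r for r in results if r.is_ntc]
    if not ntcs:
        return RunVerdict(valid=True, warnings=("MISSING_NTC",))
    failing = tuple(
        r.specimen_id
        for r in ntcs
        if r.cq_diag is not None or r.cq_control is not None
    )
    if failing:
        return RunVerdict(valid=False, failing_ntcs=failing)
    return RunVerdict(valid=True)


def batch_interpret(
    results: list[SpecimenResult],
    params: InterpretationParams = InterpretationParams(),
    truth: dict[str, str] | None = None,
    target: str | None = None,
) -> tuple[RunVerdict, list[Outcome], PanelMetrics | None]:
    """Interpret a whole plate.

    Outcomes are withheld (empty list) when the run is invalid. When a
    ``truth`` map (specimen → species) and ``target`` species are given,
    panel metrics are computed with TARGET_POSITIVE as the positive call
    and every other outcome (including anomalous/invalid) as negative.
    """
    seen: set[str] = set()
    for r in results:
        if not r.is_ntc:
            if r.specimen_id in seen:
                raise ParameterError(f"duplicate specimen id {r.specimen_id!r}")
            seen.add(r.specimen_id)
    verdict = validate_run(results)
    if not verdict.valid:
        return verdict, [], None
    outcomes = [classify_specimen(r, params) for r in results if not r.is_ntc]
    metrics = None
    if truth is not None:
        if target is None:
            raise ParameterError("truth labels given without a target species")
        calls = []
        for outcome in outcomes:
            if outcome.specimen_id not in truth:
                raise ParameterError(
                    f"specimen {outcome.specimen_id!r} missing from truth labels"
                )
            calls.append(
                (truth[outcome.specimen_id], outcome.call is Call.TARGET_POSITIVE)
            )
        metrics = panel_metrics(calls, target)
    return verdict, outcomes, metrics


# -- plate I/O ---------------------------------------------------------------


def _parse_cq(raw) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip().upper()
    if text in ND_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise PlateFormatError(f"unparseable Cq value {raw!r}") from None


def _classify_channel(raw: str) -> Literal["diag", "control"]:
    token = str(raw).strip().upper().replace(" ", "")
    if token in DIAG_CHANNEL_ALIASES:
        return "diag"
    if token in CONTROL_CHANNEL_ALIASES:
        return "control"
    raise PlateFormatError(f"unknown probe channel {raw!r}")


def read_plate(
    path: str | Path,
    aggregate: Literal["median", "mean"] = "median",
) -> list[SpecimenResult]:
    """Read a plate-style delimited export into per-specimen results.

    Expected columns (case-insensitive): ``well``, ``specimen``,
    ``channel`` (FAM/Quasar670 or aliases), ``cq`` ("ND" or empty for no
    amplification) and optionally ``ntc`` (truthy marks a no-template
    control). Replicate wells for the same specimen/channel are aggregated
    by median (default) or mean of the *detected* replicates; a channel
    with no detected replicate stays not-detected.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"specimen", "channel", "cq"}
    if not required <= set(frame.columns):
        raise PlateFormatError(
            f"plate file must have columns {sorted(required)}; "
            f"found {list(frame.columns)}"
        )
    agg_fn: Callable[[list[float]], float] = (
        (lambda v: float(pd.Series(v).median()))
        if aggregate == "median"
        else (lambda v: float(pd.Series(v).mean()))
    )

    order: list[str] = []
    wells: dict[str, str | None] = {}
    is_ntc: dict[str, bool] = {}
    cqs: dict[str, dict[str, list[float]]] = {}
    for _, row in frame.iterrows():
        specimen = str(row["specimen"]).strip()
        if specimen not in cqs:
            order.append(specimen)
            cqs[specimen] = {"diag": [], "control": []}
            wells[specimen] = str(row["well"]).strip() if "well" in frame.columns else None
            ntc_raw = str(row.get("ntc", "")).strip().lower()
            is_ntc[specimen] = ntc_raw in {"1", "true", "yes", "ntc"}
        channel = _classify_channel(row["channel"])
        cq = _parse_cq(row["cq"])
        if cq is not None:
            cqs[specimen][channel].append(cq)

    results = []
    for specimen in order:
        diag = agg_fn(cqs[specimen]["diag"]) if cqs[specimen]["diag"] else None
        ctrl = agg_fn(cqs[specimen]["control"]) if cqs[specimen]["control"] else None
        results.append(
            SpecimenResult(
                specimen_id=specimen,
                cq_diag=diag,
                cq_control=ctrl,
                well=wells[specimen],
                is_ntc=is_ntc[specimen],
            )
        )
    return results


def outcomes_table(outcomes: list[Outcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "specimen": o.specimen_id,
                "call": o.call.value,
                "delta_cq": "" if o.delta_cq is None else round(o.delta_cq, 2),
                "flags": ",".join(sorted(o.flags)),
                "advice": o.advice,
            }
            for o in outcomes
        ],
        columns=["specimen", "call", "delta_cq", "flags", "advice"],
    )
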