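"""Standard curves for serial-dilution qPCR data.

A ten-fold dilution series yields, per probe, aggregated Cq values that
fall linearly in log10(template concentration). Ordinary least squares of
Cq on log10(c) gives slope and intercept; amplification efficiency follows
as E = 10^(−1/slope) − 1 (a perfect doubling per cycle has slope
−1/log10(2) ≈ −3.3219 and E = 1). The limit of detection is the lowest
concentration whose replicates are detected under the chosen rule.

Not-detected replicates are excluded from the fit — mixing censored
observations into OLS would bias the slope — but they drive the LOD.
Concentration units are carried through as-is and never converted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from diagpcr.errors import FitError, ParameterError

__all__ = [
    "DilutionSeries",
    "CurveFit",
    "fit_standard_curve",
    "limit_of_detection",
    "read_series",
    "delta_cq_by_concentration",
]

DOUBLING_SLOPE = -1.0 / math.log10(2.0)  # ≈ −3.3219 cycles per decade


@dataclass(frozen=True)
class DilutionSeries:
    """Replicate Cq readings across a dilution ladder for one probe.

    ``points`` maps each concentration (strictly positive, in the units of
    the input, e.g. ng/µL) to its replicate Cqs, with ``None`` for a
    replicate that never crossed threshold.
    """

    points: tuple[tuple[float, tuple[float | None, ...]], ...]
    probe: str = ""
    specimen: str = ""
    units: str = "ng/µL"

    def __post_init__(self) -> None:
        if any(conc <= 0 for conc, _ in self.points):
            raise ParameterError("concentrations must be strictly positive")
        concs = [conc for conc, _ in self.points]
        if len(set(concs)) != len(concs):
            raise ParameterError("duplicate concentration in series")


@dataclass(frozen=True)
class CurveFit:
    slope: float  # cycles per log10(concentration)
    intercept: float  # cycles at 1 unit of concentration
    r_squared: float
    efficiency: float | None  # 10^(−1/slope) − 1; None for slope ≥ 0
    lod: float | None
    n_points: int
    warnings: tuple[str, ...] = ()


def _aggregate(values: list[float], how: Literal["mean", "median"]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.median(arr) if how == "median" else np.mean(arr))


def fit_standard_curve(
    series: DilutionSeries,
    aggregate: Literal["mean", "median"] = "mean",
    lod_rule: Literal["all_replicates", "any_replicate"] = "all_replicates",
) -> CurveFit:
    """OLS fit of aggregated Cq on log10(concentration).

    Replicates are aggregated per concentration (mean by default, matching
    the convention of averaging Cq at each dilution step before plotting);
    concentrations with no detected replicate are dropped. Raises
    :class:`FitError` with fewer than two usable concentrations. A
    non-decreasing aggregated Cq with rising concentration triggers a
    ``NON_MONOTONE`` warning; a non-negative slope leaves the efficiency
    undefined with a ``NON_NEGATIVE_SLOPE`` warning.
    """
    xs, ys = [], []
    for conc, replicates in sorted(series.points):
        detected = [cq for cq in replicates if cq is not None]
        if detected:
            xs.append(math.log10(conc))
            ys.append(_aggregate(detected, aggregate))
    if len(xs) < 2:
        raise FitError(
            f"need ≥2 concentrations with a detected replicate, have {len(xs)}"
        )
    fit = stats.linregress(xs, ys)
    warn: list[str] = []
    if any(b >= a for a, b in zip(ys, ys[1:])):
        warn.append("NON_MONOTONE")
        warnings.warn("aggregated Cq is not strictly decreasing in concentration",
                      stacklevel=2)
    if fit.slope >= 0:
        warn.append("NON_NEGATIVE_SLOPE")
        efficiency = None
    else:
        efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return CurveFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency,
        lod=limit_of_detection(series, lod_rule),
        n_points=len(xs),
        warnings=tuple(warn),
    )


def limit_of_detection(
    series: DilutionSeries,
    rule: Literal["all_replicates", "any_replicate"] = "all_replicates",
) -> float | None:
    """Lowest concentration whose replicate detections satisfy the rule."""
    qualifying = []
    for conc, replicates in series.points:
        detected = [cq is not None for cq in replicates]
        if not detected:
            continue
        ok = all(detected) if rule == "all_replicates" else any(detected)
        if ok:
            qualifying.append(conc)
    return min(qualifying) if qualifying else None


def read_series(path) -> list[DilutionSeries]:
    """Read a CSV with columns specimen, probe, concentration, replicate, cq
    ("ND"/empty = not detected) into one series per (specimen, probe)."""
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"specimen", "probe", "concentration", "cq"}
    if not required <= set(frame.columns):
        raise ParameterError(
            f"series file must have columns {sorted(required)}; "
            f"found {list(frame.columns)}"
        )
    grouped: dict[tuple[str, str], dict[float, list[float | None]]] = {}
    for _, row in frame.iterrows():
        key = (str(row["specimen"]).strip(), str(row["probe"]).strip())
        conc = float(row["concentration"])
        raw = str(row["cq"]).strip().upper() if not pd.isna(row["cq"]) else ""
        cq = None if raw in {"", "ND", "NA", "NAN", "NONE"} else float(raw)
        grouped.setdefault(key, {}).setdefault(conc, []).append(cq)
    out = []
    for (specimen, probe), concs in grouped.items():
        points = tuple(
            (conc, tuple(replicates)) for conc, replicates in sorted(concs.items())
        )
        out.append(DilutionSeries(points=points, probe=probe, specimen=specimen))
    return out


def delta_cq_by_concentration(
    diag: DilutionSeries,
    control: DilutionSeries,
    aggregate: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Per-concentration ΔCq (control − diagnostic) for paired series from
    one specimen — a duplex-consistency summary across the ladder."""
    diag_map = {c: [v for v in reps if v is not None] for c, reps in diag.points}
    ctrl_map = {c: [v for v in reps if v is not None] for c, reps in control.points}
    rows = []
    for conc in sorted(set(diag_map) & set(ctrl_map)):
        if diag_map[conc] and ctrl_map[conc]:
            rows.append(
                {
                    "concentration": conc,
                    "cq_diag": _aggregate(diag_map[conc], aggregate),
                    "cq_control": _aggregate(ctrl_map[conc], aggregate),
                }
            )
    frame = pd.DataFrame(rows, columns=["concentration", "cq_diag", "cq_control"])
    if not frame.empty:
        frame["delta_cq"] = frame["cq_control"] - frame["cq_diag"]
    else:
        frame["delta_cq"] = []
    return frame
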