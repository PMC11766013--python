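"""Seeded synthetic alignments and qPCR panels with planted ground truth.

The alignment simulator emulates the structure a marker like ITS2 shows in
a well-chosen diagnostic locus: high conservation within the target
species, clear interspecific differences, and indel blocks that a probe
can be designed across. Ground truth is made exactly recoverable by a
*sister species* construction: one designated non-target species is
identical to the target everywhere except at the planted probe block and
planted primer-difference positions. Any window diagnostic against *all*
non-targets must then be diagnostic against the sister, which pins every
qualifying probe window to the planted block (and primer coverage to the
planted sites) with no probabilistic slack, while the remaining species
carry free random divergence and indels for realism.

The panel simulator draws Cq values from the normal distributions a real
validation panel exhibits — targets detected early in both channels,
non-targets in the control channel only — truncated to the cycle range,
with optional per-channel dropout emulating degraded DNA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from diagpcr.alignment_io import AlignmentRecord, SpeciesAlignment
from diagpcr.errors import ParameterError

__all__ = [
    "AlignmentSimParams",
    "PlantedTruth",
    "simulate_alignment",
    "PanelSimParams",
    "simulate_panel",
    "panel_to_csv",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AlignmentSimParams:
    """Knobs for the alignment simulator.

    Defaults emulate a conserved-flank spacer panel: a ~200-column
    alignment, six target individuals essentially identical to each other
    (intraspecific substitution probability 0.002 per site outside planted
    windows), three non-target species at 5% background divergence plus
    one indel block, and a planted 6-column probe signature flanked by two
    primer sites with three diagnostic positions each.
    """

    n_target_seqs: int = 6
    nontarget_counts: dict[str, int] = field(
        default_factory=lambda: {
            "Cydia_splendana": 4,
            "Cydia_fagiglandana": 3,
            "Grapholita_molesta": 3,
        }
    )
    sister_species: str = "Cydia_splendana"
    n_columns: int = 200
    target_species: str = "Cydia_pomonella"
    intraspecific_sub_prob: float = 0.002
    interspecific_divergence: float = 0.05
    probe_block: tuple[int, int] = (90, 96)  # half-open columns, length ≥ 5
    fwd_primer_site: tuple[int, int] = (40, 60)
    fwd_primer_diffs: tuple[int, ...] = (45, 50, 55)
    rev_primer_site: tuple[int, int] = (120, 140)
    rev_primer_diffs: tuple[int, ...] = (125, 130, 135)
    indel_block: tuple[int, int] | None = (150, 156)  # gapped in non-sister species
    plant_features: bool = True  # False: no diagnostic columns at all
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.probe_block, self.fwd_primer_site, self.rev_primer_site):
            if not (0 <= lo < hi <= self.n_columns):
                raise ParameterError("planted span outside alignment bounds")
        if self.probe_block[1] - self.probe_block[0] < 5:
            raise ParameterError("planted probe block must span ≥ 5 columns")
        if self.sister_species not in self.nontarget_counts:
            raise ParameterError("sister_species must be one of the non-target species")
        if not (0 <= self.intraspecific_sub_prob <= 1):
            raise ParameterError("probabilities must lie in [0, 1]")
        for pos_set, (lo, hi) in (
            (self.fwd_primer_diffs, self.fwd_primer_site),
            (self.rev_primer_diffs, self.rev_primer_site),
        ):
            if len(pos_set) < 3 or any(not (lo <= p < hi) for p in pos_set):
                raise ParameterError("need ≥3 planted primer diffs inside their site")


@dataclass(frozen=True)
class PlantedTruth:
    """Manifest of planted coordinates for recovery tests."""

    probe_block: tuple[int, int]
    fwd_primer_site: tuple[int, int]
    fwd_primer_diffs: tuple[int, ...]
    rev_primer_site: tuple[int, int]
    rev_primer_diffs: tuple[int, ...]
    sister_species: str
    target_species: str


def _protected_columns(p: AlignmentSimParams) -> set[int]:
    cols: set[int] = set()
    for lo, hi in (p.probe_block, p.fwd_primer_site, p.rev_primer_site):
        cols.update(range(lo, hi))
    return cols


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def simulate_alignment(
    p: AlignmentSimParams = AlignmentSimParams(),
) -> tuple[SpeciesAlignment, PlantedTruth]:
    """Generate a species-labelled alignment with planted diagnostic truth.

    Deterministic for a fixed seed. Every planted diagnostic column is a
    clean four-way difference: the target base differs from every
    non-target species' base there, and planted windows are excluded from
    random substitution so recovery is exact, not merely probable.
    """
    rng = np.random.default_rng(p.seed)
    protected = _protected_columns(p)
    planted_diag: set[int] = set()
    if p.plant_features:
        planted_diag = set(p.fwd_primer_diffs) | set(p.rev_primer_diffs) | set(
            range(*p.probe_block)
        )

    target_consensus = rng.choice(BASES, size=p.n_columns)
    species_consensus: dict[str, list[str]] = {}
    for species in p.nontarget_counts:
        consensus = target_consensus.copy()
        if species != p.sister_species:
            for col in range(p.n_columns):
                if col not in protected and rng.random() < p.interspecific_divergence:
                    consensus[col] = _other_base(rng, consensus[col])
            if p.indel_block is not None:
                lo, hi = p.indel_block
                consensus[lo:hi] = "-"
        species_consensus[species] = list(consensus)

    # Plant the diagnostic columns: one shared non-target base ≠ target base,
    # so the column is diagnostic against every non-target species.
    for col in sorted(planted_diag):
        nontarget_base = _other_base(rng, target_consensus[col])
        for species, consensus in species_consensus.items():
            consensus[col] = nontarget_base

    records: list[AlignmentRecord] = []
    for i in range(p.n_target_seqs):
        seq = list(target_consensus)
        for col in range(p.n_columns):
            if col not in protected and rng.random() < p.intraspecific_sub_prob:
                seq[col] = _other_base(rng, seq[col])
        records.append(
            AlignmentRecord(f"t{i + 1}", p.target_species, "".join(seq))
        )
    for species, count in p.nontarget_counts.items():
        consensus = species_consensus[species]
        for i in range(count):
            seq = list(consensus)
            for col in range(p.n_columns):
                if (
                    col not in planted_diag
                    and seq[col] != "-"
                    and rng.random() < p.intraspecific_sub_prob
                ):
                    seq[col] = _other_base(rng, seq[col])
            prefix = "".join(w[0] for w in species.split("_")).lower()
            records.append(AlignmentRecord(f"{prefix}{i + 1}", species, "".join(seq)))

    aln = SpeciesAlignment(records, target_species=p.target_species)
    truth = PlantedTruth(
        probe_block=p.probe_block,
        fwd_primer_site=p.fwd_primer_site,
        fwd_primer_diffs=p.fwd_primer_diffs,
        rev_primer_site=p.rev_primer_site,
        rev_primer_diffs=p.rev_primer_diffs,
        sister_species=p.sister_species,
        target_species=p.target_species,
    )
    return aln, truth


@dataclass(frozen=True)
class PanelSimParams:
    """Cq panel simulator.

    Default distributions follow a validated duplex assay: target
    specimens average 18.7 ± 3.3 cycles in the diagnostic channel and
    21.6 ± 2.7 in the control channel; non-targets amplify only in the
    control channel at 19.8 ± 3.7. Within a target specimen the two
    channels are strongly correlated (both track template quantity), so
    the control Cq is drawn as the diagnostic Cq plus a duplex offset
    N(control_mean − diag_mean, dcq_jitter_sd²) bounded by ``dcq_max`` —
    matching the observed behaviour that ΔCq stays within the QC window
    even though per-specimen Cq varies by several cycles. Both printed
    channel means are preserved exactly; the control channel's marginal
    SD then tracks the diagnostic SD rather than its own printed value.
    """

    n_target: int = 110
    n_nontarget: int = 90
    diag_mean: float = 18.7
    diag_sd: float = 3.3
    control_mean_target: float = 21.6
    control_sd_target: float = 2.7
    control_mean_nontarget: float = 19.8
    control_sd_nontarget: float = 3.7
    dcq_jitter_sd: float = 0.8
    dcq_max: float = 6.0
    dropout_prob: float = 0.0
    max_cycles: int = 39
    target_species: str = "Cydia_pomonella"
    nontarget_species: str = "non_target"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.diag_sd, self.control_sd_target, self.control_sd_nontarget,
               self.dcq_jitter_sd) < 0:
            raise ParameterError("standard deviations must be ≥ 0")
        if not (0 <= self.dropout_prob <= 1):
            raise ParameterError("dropout_prob must lie in [0, 1]")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, max_cycles: int
) -> float:
    """Rejection-sample N(mean, sd²) into (0, max_cycles]; the printed panel
    means sit >5 SD from both bounds, so truncation is vanishingly rare."""
    for _ in range(1000):
        value = float(rng.normal(mean, sd))
        if 0 < value <= max_cycles:
            return value
    raise ParameterError(f"cannot sample Cq in (0, {max_cycles}] from N({mean}, {sd}²)")


def simulate_panel(p: PanelSimParams = PanelSimParams()) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a plate export (long format) plus a specimen→species truth map.

    Targets receive Cqs in both channels, non-targets in the control
    channel only; each drawn Cq independently drops out (ND) with
    probability ``dropout_prob``. One clean no-template control row pair is
    appended. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(p.seed)
    rows = []
    truth: dict[str, str] = {}

    def emit(specimen: str, channel: str, cq: float | None, ntc: bool = False) -> None:
        rows.append(
            {
                "well": f"W{len(rows) + 1:03d}",
                "specimen": specimen,
                "channel": channel,
                "cq": "ND" if cq is None else f"{cq:.2f}",
                "ntc": "1" if ntc else "0",
            }
        )

    def maybe_drop(value: float) -> float | None:
        return None if rng.random() < p.dropout_prob else value

    dcq_mean = p.control_mean_target - p.diag_mean
    for i in range(p.n_target):
        specimen = f"target_{i + 1:03d}"
        truth[specimen] = p.target_species
        for _ in range(1000):
            diag = _truncated_normal(rng, p.diag_mean, p.diag_sd, p.max_cycles)
            dcq = float(rng.normal(dcq_mean, p.dcq_jitter_sd))
            control = diag + dcq
            if abs(dcq) <= p.dcq_max and 0 < control <= p.max_cycles:
                break
        else:  # pragma: no cover - parameters would have to be pathological
            raise ParameterError("cannot sample a within-QC duplex Cq pair")
        emit(specimen, "FAM", maybe_drop(diag))
        emit(specimen, "Quasar670", maybe_drop(control))
    for i in range(p.n_nontarget):
        specimen = f"nontarget_{i + 1:03d}"
        truth[specimen] = p.nontarget_species
        emit(specimen, "FAM", None)
        emit(specimen, "Quasar670",
             maybe_drop(_truncated_normal(rng, p.control_mean_nontarget,
                                          p.control_sd_nontarget, p.max_cycles)))
    emit("NTC", "FAM", None, ntc=True)
    emit("NTC", "Quasar670", None, ntc=True)
    return pd.DataFrame(rows), truth


def panel_to_csv(frame: pd.DataFrame) -> str:
    buffer = io.StringIO()
    frame.to_csv(buffer, index=False)
    return buffer.getvalue()
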