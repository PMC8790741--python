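"""Study configuration: YAML schema, validation, bundled example studies.

A study config couples a synthetic cohort description (animals with their
infusion schedules, subsets with their exchange kinetics, tissues, cell
counts, seed) with the analysis options (CC lookback windows, entry-rate
window, gate quantile, labeling efficiency, subset comparisons).

YAML layout::

    name: fig2_like
    seed: 1
    burn_in_hours: 0.0
    schedule:
      dose_ug_per_kg: 30.0
      pulses:
        - {time: 48.0, channel: AF647}
        - {time: 0.0833, channel: BV421}
    animals:
      - {name: RM1}
      - {name: RM2, invalid_channels: [AF647]}   # masked (e.g. extravasated)
    tissues:
      - {name: LN, sinusoidal: false}
    subsets:
      - {name: CD16, exit_rate_blood: 0.02, return_rate_tissue: 0.3}
    cell_counts:
      CD16: {LN: 4000}
    analysis:
      lookbacks: [6.0, 48.0]
      entry_rate_window: 6.0
      gate_quantile: 0.999
      label_efficiency: 1.0
      control_n: 5000
      comparisons:
        - {metric: cc_6h, tissue: blood}
      holm: false
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from sivskit.labeling import InfusionSchedule, IntensityModel, Pulse
from sivskit.trafficking import (
    AnimalSpec,
    CohortConfig,
    ConfigurationError,
    SubsetKinetics,
    TissueSpec,
)


@dataclass(frozen=True)
class ComparisonSpec:
    """One family of pairwise subset comparisons: a summary metric evaluated
    on rows from one harvest site, over all subset pairs."""

    metric: str
    tissue: str


@dataclass(frozen=True)
class StudyConfig:
    name: str
    cohort: CohortConfig
    lookbacks: tuple[float, ...] = (6.0,)
    entry_rate_window: float | None = 6.0
    gate_quantile: float = 0.999
    label_efficiency: float = 1.0
    control_n: int = 5000
    comparisons: tuple[ComparisonSpec, ...] = ()
    holm: bool = False
    raw: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("study name must be non-empty")
        if any(lb <= 0 for lb in self.lookbacks):
            raise ConfigurationError("lookbacks must be > 0")
        if not 0.0 < self.gate_quantile <= 1.0:
            raise ConfigurationError("gate_quantile must be in (0, 1]")
        if not 0.0 <= self.label_efficiency <= 1.0:
            raise ConfigurationError("label_efficiency must be in [0, 1]")

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def with_seed(self, seed: int) -> "StudyConfig":
        cohort = CohortConfig(
            animals=self.cohort.animals,
            subsets=self.cohort.subsets,
            tissues=self.cohort.tissues,
            cell_counts=self.cohort.cell_counts,
            burn_in_hours=self.cohort.burn_in_hours,
            seed=seed,
        )
        raw = dict(self.raw)
        raw["seed"] = seed
        return StudyConfig(
            name=self.name,
            cohort=cohort,
            lookbacks=self.lookbacks,
            entry_rate_window=self.entry_rate_window,
            gate_quantile=self.gate_quantile,
            label_efficiency=self.label_efficiency,
            control_n=self.control_n,
            comparisons=self.comparisons,
            holm=self.holm,
            raw=raw,
        )

    def intensity_model(self) -> IntensityModel:
        return IntensityModel.default(
            self.cohort.channels, control_n=self.control_n
        )


def _build_schedule(spec: dict, invalid_channels: set[str]) -> InfusionSchedule:
    pulses = tuple(
        Pulse(
            time_before_harvest=float(p["time"]),
            channel=str(p["channel"]),
            valid=str(p["channel"]) not in invalid_channels,
        )
        for p in spec["pulses"]
    )
    dose = spec.get("dose_ug_per_kg")
    return InfusionSchedule(pulses=pulses, dose_ug_per_kg=None if dose is None else float(dose))


def study_config_from_dict(data: dict) -> StudyConfig:
    try:
        schedule_spec = data["schedule"]
        animals = tuple(
            AnimalSpec(
                name=str(a["name"]),
                schedule=_build_schedule(
                    schedule_spec, set(a.get("invalid_channels", []))
                ),
            )
            for a in data["animals"]
        )
        tissues = tuple(
            TissueSpec(name=str(t["name"]), sinusoidal=bool(t.get("sinusoidal", False)))
            for t in data["tissues"]
        )
        subsets = tuple(
            SubsetKinetics(
                subset_name=str(s["name"]),
                exit_rate_blood=float(s["exit_rate_blood"]),
                return_rate_tissue=float(s["return_rate_tissue"]),
                peri_entry_rate=float(s.get("peri_entry_rate", 0.0)),
                peri_exit_rate=float(s.get("peri_exit_rate", 0.0)),
                marker_acquisition_rate=float(s.get("marker_acquisition_rate", 1.0)),
                marker_loss_rate=float(s.get("marker_loss_rate", 0.5)),
                marker_initial_prob=float(s.get("marker_initial_prob", 0.0)),
            )
            for s in data["subsets"]
        )
        cohort = CohortConfig(
            animals=animals,
            subsets=subsets,
            tissues=tissues,
            cell_counts={
                str(k): {str(t): int(n) for t, n in v.items()}
                for k, v in data["cell_counts"].items()
            },
            burn_in_hours=float(data.get("burn_in_hours", 0.0)),
            seed=int(data.get("seed", 0)),
        )
        analysis = data.get("analysis", {})
        comparisons = tuple(
            ComparisonSpec(metric=str(c["metric"]), tissue=str(c["tissue"]))
            for c in analysis.get("comparisons", [])
        )
        return StudyConfig(
            name=str(data["name"]),
            cohort=cohort,
            lookbacks=tuple(float(lb) for lb in analysis.get("lookbacks", [6.0])),
            entry_rate_window=(
                None
                if analysis.get("entry_rate_window") is None
                else float(analysis["entry_rate_window"])
            ),
            gate_quantile=float(analysis.get("gate_quantile", 0.999)),
            label_efficiency=float(analysis.get("label_efficiency", 1.0)),
            control_n=int(analysis.get("control_n", 5000)),
            comparisons=comparisons,
            holm=bool(analysis.get("holm", False)),
            raw=data,
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing config key: {exc}") from exc


def load_study_config(path: str | Path) -> StudyConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return study_config_from_dict(data)


def bundled_config(name: str) -> StudyConfig:
    """Load one of the packaged example studies by name
    (``fig2_like``, ``depletion_like``, ``single_pulse``, ``ln_steady_state``)."""
    ref = resources.files("sivskit.data").joinpath(f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise KeyError(f"no bundled config named {name!r}") from None
    return study_config_from_dict(yaml.safe_load(text))
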