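"""Pulse-label model: infusion schedules, label vectors, intensities, gating.

An intravascular antibody infusion tags every cell that is inside an exposed
compartment at the instant of infusion.  The antibody's in-vivo half-life
(minutes) is far below the smallest inter-pulse gap (hours), so each infusion
is modeled as a zero-duration pulse; once acquired, a label never decays.
Fluorescence readout is modeled per channel as a mixture of a negative
(background) and a positive (labeled) lognormal population, and calls are
recovered by thresholding at a high quantile of a pre-infusion negative
control — mirroring how flow-cytometry gates are drawn against unstained
controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Compartment names shared with the trafficking simulator.
BLOOD = "blood"
PERIVASCULAR = "perivascular"
TISSUE_LOCALIZED = "tissue_localized"

#: A final pulse given within this many hours of harvest is the IVas pulse.
IVAS_CUTOFF_HOURS = 0.25

#: Default label policy: only cells in flowing blood are exposed to the
#: infusion.  Perivascular exposure is added per tissue when its vasculature
#: is sinusoidal (discontinuous endothelium lets antibody reach the
#: perivascular space).
DEFAULT_LABEL_POLICY = frozenset({BLOOD})


class CoverageError(ValueError):
    """A pulse time falls outside the span of the trajectory."""


@dataclass(frozen=True)
class Pulse:
    """One timed infusion: hours before harvest, dye channel, validity."""

    time_before_harvest: float
    channel: str
    valid: bool = True

    def __post_init__(self) -> None:
        if not (self.time_before_harvest > 0 and math.isfinite(self.time_before_harvest)):
            raise ValueError(
                f"pulse time must be a positive, finite number of hours before "
                f"harvest, got {self.time_before_harvest!r}"
            )
        if not self.channel:
            raise ValueError("pulse channel must be non-empty")


@dataclass(frozen=True)
class InfusionSchedule:
    """Ordered infusion pulses, oldest first (strictly decreasing times).

    The final pulse is designated the IVas pulse when it is given within
    ``IVAS_CUTOFF_HOURS`` of harvest; it separates intravascular from
    extravascular cells at the moment of sampling.  ``dose_ug_per_kg`` is
    carried as metadata only and never affects labeling.
    """

    pulses: tuple[Pulse, ...]
    dose_ug_per_kg: float | None = None

    def __post_init__(self) -> None:
        if len(self.pulses) == 0:
            raise ValueError("schedule must contain at least one pulse")
        times = [p.time_before_harvest for p in self.pulses]
        if any(t1 <= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                "pulse times must be strictly decreasing toward harvest "
                f"(oldest first); got {times}"
            )
        channels = [p.channel for p in self.pulses]
        if len(set(channels)) != len(channels):
            raise ValueError(f"pulse channels must be unique; got {channels}")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(p.time_before_harvest for p in self.pulses)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(p.channel for p in self.pulses)

    @property
    def ivas_index(self) -> int | None:
        """Index of the IVas pulse, or None when the schedule lacks one."""
        if self.pulses[-1].time_before_harvest <= IVAS_CUTOFF_HOURS:
            return len(self.pulses) - 1
        return None

    def valid_mask(self) -> np.ndarray:
        return np.array([p.valid for p in self.pulses], dtype=bool)

    def with_validity(self, valid: Sequence[bool]) -> "InfusionSchedule":
        """Copy of this schedule with a per-pulse validity mask applied."""
        if len(valid) != len(self.pulses):
            raise ValueError("validity mask length must equal number of pulses")
        return InfusionSchedule(
            pulses=tuple(
                Pulse(p.time_before_harvest, p.channel, bool(v))
                for p, v in zip(self.pulses, valid)
            ),
            dose_ug_per_kg=self.dose_ug_per_kg,
        )


@dataclass(frozen=True)
class LabelVector:
    """Per-cell pulse calls and interpretability mask, oldest pulse first.

    ``mask[k]`` False marks a pulse that is not interpretable for this cell
    (e.g. an extravasated infusion); classifiers never consult the call at a
    masked position.
    """

    calls: tuple[bool, ...]
    mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.mask):
            raise ValueError("calls and mask must have equal length")

    def __len__(self) -> int:
        return len(self.calls)


def apply_pulse_labels(
    trajectory,
    schedule: InfusionSchedule,
    label_policy: frozenset[str] = DEFAULT_LABEL_POLICY,
    efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
) -> LabelVector:
    """Pulse-sample a trajectory: the call at pulse *k* is true iff the cell
    sits in a policy compartment at that instant (and the pulse tags it,
    with probability ``efficiency``).  Labels are permanent by construction:
    each call records exposure at its own pulse and no later operation may
    clear it.

    ``trajectory`` is anything with ``start_hours_before_harvest`` and a
    ``compartment_at(hours_before_harvest)`` method.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"labeling efficiency must be in [0, 1], got {efficiency}")
    calls = []
    for pulse in schedule.pulses:
        t = pulse.time_before_harvest
        if t > trajectory.start_hours_before_harvest:
            raise CoverageError(
                f"pulse at {t} h before harvest precedes trajectory start "
                f"({trajectory.start_hours_before_harvest} h)"
            )
        exposed = trajectory.compartment_at(t) in label_policy
        if exposed and efficiency < 1.0:
            if rng is None:
                raise ValueError("rng required when labeling efficiency < 1")
            exposed = bool(rng.random() < efficiency)
        calls.append(exposed)
    return LabelVector(calls=tuple(calls), mask=tuple(schedule.valid_mask().tolist()))


def calls_from_truth(
    truth_compartments: np.ndarray,
    label_policy: frozenset[str] = DEFAULT_LABEL_POLICY,
    efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized pulse labeling from an (n_cells, n_pulses) array of
    ground-truth compartment names at the pulse instants."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"labeling efficiency must be in [0, 1], got {efficiency}")
    exposed = np.isin(truth_compartments, sorted(label_policy))
    if efficiency < 1.0:
        if rng is None:
            raise ValueError("rng required when labeling efficiency < 1")
        exposed &= rng.random(exposed.shape) < efficiency
    return exposed


@dataclass(frozen=True)
class ChannelIntensity:
    """Lognormal negative/positive fluorescence populations for one channel.

    Medians are on the linear fluorescence scale; sigmas are standard
    deviations of log-intensity.  Zero sigma degenerates to a point mass at
    the median.
    """

    negative_median: float = 100.0
    negative_sigma: float = 0.6
    positive_median: float = 5000.0
    positive_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.negative_median <= 0 or self.positive_median <= 0:
            raise ValueError("population medians must be positive")
        if self.negative_sigma < 0 or self.positive_sigma < 0:
            raise ValueError("population sigmas must be non-negative")
        if self.positive_median <= self.negative_median:
            raise ValueError(
                "positive population median must exceed negative median "
                f"({self.positive_median} <= {self.negative_median})"
            )


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel intensity populations plus negative-control sample size."""

    channels: Mapping[str, ChannelIntensity]
    control_n: int = 5000

    def __post_init__(self) -> None:
        if self.control_n < 1:
            raise ValueError("control sample size must be >= 1")

    @classmethod
    def default(cls, channels: Iterable[str], control_n: int = 5000) -> "IntensityModel":
        return cls(channels={ch: ChannelIntensity() for ch in channels}, control_n=control_n)

    def _params(self, channel: str) -> ChannelIntensity:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(f"intensity model has no channel {channel!r}") from None

    def sample_negative(self, channel: str, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self._params(channel)
        return p.negative_median * np.exp(p.negative_sigma * rng.standard_normal(n))

    def sample_positive(self, channel: str, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self._params(channel)
        return p.positive_median * np.exp(p.positive_sigma * rng.standard_normal(n))


def render_intensities(
    labels: LabelVector,
    channels: Sequence[str],
    model: IntensityModel,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw one fluorescence intensity per channel: positive population when
    the call is true, negative otherwise."""
    if len(channels) != len(labels):
        raise ValueError("channel list must align with label vector")
    out = {}
    for call, ch in zip(labels.calls, channels):
        if call:
            out[ch] = float(model.sample_positive(ch, 1, rng)[0])
        else:
            out[ch] = float(model.sample_negative(ch, 1, rng)[0])
    return out


def render_intensity_matrix(
    calls: np.ndarray,
    channels: Sequence[str],
    model: IntensityModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized ``render_intensities`` over an (n_cells, n_pulses) call
    matrix; returns a float matrix of the same shape."""
    calls = np.asarray(calls, dtype=bool)
    n, k = calls.shape
    if k != len(channels):
        raise ValueError("channel list must align with call matrix columns")
    out = np.empty((n, k), dtype=float)
    for j, ch in enumerate(channels):
        p = model._params(ch)
        z = rng.standard_normal(n)
        pos = calls[:, j]
        out[:, j] = np.where(
            pos,
            p.positive_median * np.exp(p.positive_sigma * z),
            p.negative_median * np.exp(p.negative_sigma * z),
        )
    return out


def gate_channel(
    sample_intensities: np.ndarray,
    control_intensities: np.ndarray,
    control_quantile: float = 0.999,
) -> tuple[float, np.ndarray]:
    """Threshold one channel against a negative control.

    The threshold is the ``control_quantile`` empirical quantile of the
    control intensities, computed with the inclusive linear-interpolation
    method (numpy ``method="linear"``, the Excel/pandas "inclusive"
    convention), which is deterministic and bit-stable.  A sample event is
    called positive iff its intensity strictly exceeds the threshold.
    """
    control = np.asarray(control_intensities, dtype=float)
    if control.size == 0:
        raise ValueError("negative control must be non-empty")
    if not 0.0 < control_quantile <= 1.0:
        raise ValueError(f"control quantile must be in (0, 1], got {control_quantile}")
    threshold = float(np.quantile(control, control_quantile, method="linear"))
    sample = np.asarray(sample_intensities, dtype=float)
    if sample.size == 0:
        logger.warning("gate_channel called with empty sample; returning empty calls")
        return threshold, np.zeros(0, dtype=bool)
    return threshold, sample > threshold
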