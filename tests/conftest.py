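import numpy as np
import pytest

from sivskit.labeling import InfusionSchedule, LabelVector, Pulse
from sivskit.trafficking import SubsetKinetics, Trajectory


def lv(calls: str, mask: str | None = None) -> LabelVector:
    """Shorthand label vector: '+-+-' calls, optional '1101' mask."""
    c = tuple(ch == "+" for ch in calls)
    m = tuple(ch == "1" for ch in mask) if mask else tuple(True for _ in calls)
    return LabelVector(calls=c, mask=m)


def make_schedule(times, invalid=(), dose=None) -> InfusionSchedule:
    return InfusionSchedule(
        pulses=tuple(
            Pulse(t, f"ch{i}", valid=i not in invalid) for i, t in enumerate(times)
        ),
        dose_ug_per_kg=dose,
    )


def constant_trajectory(compartment: str, start: float = 100.0) -> Trajectory:
    return Trajectory(
        start_hours_before_harvest=start,
        segments=[(start, compartment)],
        marker_track=[(start, False)],
    )


@pytest.fixture
def schedule4() -> InfusionSchedule:
    """The long time course: 48 h, 24 h, 6 h and 5 min before harvest."""
    return make_schedule([48.0, 24.0, 6.0, 0.0833])


@pytest.fixture
def schedule2() -> InfusionSchedule:
    return make_schedule([6.0, 0.0833])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211208)


def two_state(exit_rate: float, return_rate: float, **kw) -> SubsetKinetics:
    kw.setdefault("marker_acquisition_rate", 0.0)
    kw.setdefault("marker_loss_rate", 0.0)
    return SubsetKinetics(
        subset_name=kw.pop("name", "test"),
        exit_rate_blood=exit_rate,
        return_rate_tissue=return_rate,
        **kw,
    )
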