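"""Kinetic summaries: tissue localization, entry rates, blood residence.

These operations turn per-cell positional-history calls into the summary
quantities of a pulse-labeling study: the tissue-localized fraction of
IVas-negative cells, the tissue entry rate (fraction of IVas-negative
cells positive for the pulse given ``window`` hours before harvest,
divided by the window), retention-marker-stratified TL fractions, and the
inversion of a continuously-circulating fraction into a blood exit rate
under a memoryless-exit model.

The residence estimator is deliberately conservative: being labeled at all
pulses is a weaker condition than never having left blood, so the measured
CC fraction is at least exp(-true_rate * lookback) and the inverted rate is
a lower bound on the true exit rate (equivalently, an upper bound on mean
blood residence).  This inequality is a tested property of the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from sivskit.history import HistoryClass, _TIME_EPS, _require_ivas, _stack, classify_many
from sivskit.labeling import InfusionSchedule, LabelVector

logger = logging.getLogger(__name__)


def tissue_localized_fraction(
    tissue_cells: Sequence[LabelVector], schedule: InfusionSchedule
) -> float:
    """TL count / IVas- count among tissue-harvested cells.

    IVas- cells are those classified recent immigrant or tissue localized;
    indeterminate cells are excluded.  Raises when no IVas- cell exists.
    """
    classes = classify_many(tissue_cells, schedule)
    n_tl = sum(1 for c in classes if c is HistoryClass.TISSUE_LOCALIZED)
    n_ri = sum(1 for c in classes if c is HistoryClass.RECENT_IMMIGRANT)
    if n_tl + n_ri == 0:
        raise ValueError("no classifiable IVas- cells; TL fraction undefined")
    return n_tl / (n_tl + n_ri)


def entry_rate(
    tissue_cells: Sequence[LabelVector],
    schedule: InfusionSchedule,
    window_hours: float = 6.0,
) -> float:
    """Tissue entry rate in percent of IVas- cells per hour.

    100 x (IVas- cells positive at the pulse given ``window_hours`` before
    harvest / IVas- cells) / ``window_hours``.  The schedule must contain a
    pulse at exactly the window boundary; positions are pulse samples and
    are never interpolated.  Cells are counted only when valid at both the
    IVas pulse and the window pulse.
    """
    times = np.array(schedule.times)
    matches = np.nonzero(np.abs(times - window_hours) <= _TIME_EPS)[0]
    if matches.size == 0:
        raise ValueError(
            f"no pulse at {window_hours} h before harvest; entry rate "
            "requires a pulse at the window boundary (no interpolation)"
        )
    w = int(matches[0])
    ivas = _require_ivas(schedule)
    calls, mask = _stack(tissue_cells)
    if calls.shape[0] == 0:
        raise ValueError("no tissue cells supplied")
    usable = mask[:, ivas] & mask[:, w]
    ivas_neg = usable & ~calls[:, ivas]
    n_ivas_neg = int(ivas_neg.sum())
    if n_ivas_neg == 0:
        raise ValueError("no IVas- cells valid at the window pulse; entry rate undefined")
    n_pos = int((ivas_neg & calls[:, w]).sum())
    return 100.0 * (n_pos / n_ivas_neg) / window_hours


@dataclass(frozen=True)
class ResidenceEstimate:
    """Blood exit rate and mean residence from a CC fraction.

    Lower-bound-biased for the exit rate (upper bound on residence): the
    labeled-at-all-pulses event contains the never-left-blood event.
    """

    exit_rate_per_hour: float
    mean_residence_hours: float
    lookback_hours: float
    cc_fraction: float

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.mean_residence_hours)


def estimate_blood_residence(
    cc_fraction: float, lookback_hours: float
) -> ResidenceEstimate:
    """Invert a continuously-circulating fraction to a blood exit rate under
    memoryless exit: rate = -ln(cc) / lookback, mean residence = 1 / rate.

    cc = 1 gives rate 0 and infinite residence (flagged via the estimate's
    ``is_infinite`` property); cc <= 0 is rejected.
    """
    if not 0.0 < cc_fraction <= 1.0:
        raise ValueError(f"cc_fraction must be in (0, 1], got {cc_fraction}")
    if lookback_hours <= 0:
        raise ValueError("lookback_hours must be > 0")
    rate = -math.log(cc_fraction) / lookback_hours
    residence = math.inf if rate == 0 else 1.0 / rate
    if rate == 0:
        logger.info(
            "cc_fraction = 1 over %g h: exit rate 0, residence unbounded",
            lookback_hours,
        )
    return ResidenceEstimate(
        exit_rate_per_hour=rate,
        mean_residence_hours=residence,
        lookback_hours=lookback_hours,
        cc_fraction=cc_fraction,
    )


def fit_exit_rate_multiwindow(cc_by_lookback: Mapping[float, float]) -> float:
    """Least-squares log-linear fit of ln(cc) = -rate * lookback through the
    origin, over several lookback windows.  Provided for simulator
    validation; the single-window inversion is the default estimator."""
    if not cc_by_lookback:
        raise ValueError("at least one (lookback, cc) pair required")
    lb = np.array(list(cc_by_lookback.keys()), dtype=float)
    cc = np.array(list(cc_by_lookback.values()), dtype=float)
    if (lb <= 0).any() or (cc <= 0).any() or (cc > 1).any():
        raise ValueError("lookbacks must be > 0 and cc fractions in (0, 1]")
    return float(-(lb @ np.log(cc)) / (lb @ lb))


@dataclass(frozen=True)
class MarkerStratifiedTL:
    """TL fraction within retention-marker positive and negative strata.

    A stratum with no classifiable IVas- cell is reported as None
    (undefined), never as zero.
    """

    tl_fraction_marker_pos: float | None
    tl_fraction_marker_neg: float | None
    n_ivas_neg_marker_pos: int
    n_ivas_neg_marker_neg: int


def tl_fraction_by_marker(
    tissue_cells: Sequence[LabelVector],
    marker_states: Sequence[bool],
    schedule: InfusionSchedule,
) -> MarkerStratifiedTL:
    """TL fraction computed separately within marker+ and marker- cells."""
    if len(tissue_cells) != len(marker_states):
        raise ValueError("marker_states must align with tissue_cells")
    marker = np.asarray(marker_states, dtype=bool)
    classes = np.array(classify_many(tissue_cells, schedule), dtype=object)

    def _stratum(sel: np.ndarray) -> tuple[float | None, int]:
        cls = classes[sel]
        n_tl = int((cls == HistoryClass.TISSUE_LOCALIZED).sum())
        n_ri = int((cls == HistoryClass.RECENT_IMMIGRANT).sum())
        if n_tl + n_ri == 0:
            return None, 0
        return n_tl / (n_tl + n_ri), n_tl + n_ri

    pos_frac, n_pos = _stratum(marker)
    neg_frac, n_neg = _stratum(~marker)
    return MarkerStratifiedTL(
        tl_fraction_marker_pos=pos_frac,
        tl_fraction_marker_neg=neg_frac,
        n_ivas_neg_marker_pos=n_pos,
        n_ivas_neg_marker_neg=n_neg,
    )
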