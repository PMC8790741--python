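"""Positional-history classification and transition (Sankey) flows.

A label vector is a pulse-sampled record of a cell's position.  For cells
harvested from a tissue, the final (IVas) pulse separates intravascular
from extravascular cells, and the earlier pulses split the IVas-negative
cells into recent immigrants (positive for at least one earlier pulse:
they were in blood during the experiment) and tissue-localized cells
(negative for every interpretable pulse: in the tissue for at least the
experiment's span).  For cells harvested from blood, the continuously
circulating fraction counts cells positive at every pulse inside a chosen
lookback window.  Masked (uninterpretable) pulses never contribute: cells
are dropped from any summary whose window touches a masked pulse
(complete-case analysis); no imputation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from sivskit.labeling import InfusionSchedule, LabelVector

logger = logging.getLogger(__name__)

_TIME_EPS = 1e-9


class HistoryClass(Enum):
    IVAS_POS = "IVas+"
    RECENT_IMMIGRANT = "RI"
    TISSUE_LOCALIZED = "TL"
    INDETERMINATE = "indeterminate"


def _stack(cells: Sequence[LabelVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack label vectors into (calls, mask) boolean matrices."""
    if len(cells) == 0:
        return np.zeros((0, 0), dtype=bool), np.zeros((0, 0), dtype=bool)
    calls = np.array([v.calls for v in cells], dtype=bool)
    mask = np.array([v.mask for v in cells], dtype=bool)
    return calls, mask


def _require_ivas(schedule: InfusionSchedule) -> int:
    idx = schedule.ivas_index
    if idx is None:
        raise ValueError(
            "schedule has no IVas pulse (final pulse must be within "
            "0.25 h of harvest)"
        )
    return idx


def is_ivas_positive(v: LabelVector, schedule: InfusionSchedule) -> bool | None:
    """Call at the IVas pulse (the infusion given minutes before harvest).

    Returns None when the IVas pulse is masked for this cell; such cells
    are excluded from IVas-based summaries.
    """
    idx = _require_ivas(schedule)
    if len(v) != len(schedule.pulses):
        raise ValueError("label vector length does not match schedule")
    if not v.mask[idx]:
        logger.debug("IVas pulse masked; cell indeterminate")
        return None
    return bool(v.calls[idx])


def classify_position_history(
    v: LabelVector, schedule: InfusionSchedule
) -> HistoryClass:
    """Classify a tissue-harvested cell as IVas+, recent immigrant, or
    tissue-localized.

    IVas+ if positive at the IVas pulse; otherwise recent immigrant if
    positive at >= 1 valid earlier pulse; otherwise tissue-localized when
    every valid earlier pulse is negative.  When the IVas call cannot be
    read, or the cell is IVas- but no earlier pulse is interpretable,
    the result is INDETERMINATE — tissue localization is never assumed by
    default.
    """
    idx = _require_ivas(schedule)
    ivas = is_ivas_positive(v, schedule)
    if ivas is None:
        return HistoryClass.INDETERMINATE
    if ivas:
        return HistoryClass.IVAS_POS
    earlier_mask = np.asarray(v.mask[:idx], dtype=bool)
    earlier_calls = np.asarray(v.calls[:idx], dtype=bool)
    if not earlier_mask.any():
        logger.debug("IVas- cell with no interpretable earlier pulse; indeterminate")
        return HistoryClass.INDETERMINATE
    if (earlier_calls & earlier_mask).any():
        return HistoryClass.RECENT_IMMIGRANT
    return HistoryClass.TISSUE_LOCALIZED


def classify_many(
    cells: Sequence[LabelVector], schedule: InfusionSchedule
) -> list[HistoryClass]:
    """Vectorized ``classify_position_history`` over a list of cells."""
    idx = _require_ivas(schedule)
    calls, mask = _stack(cells)
    if calls.shape[0] == 0:
        return []
    if calls.shape[1] != len(schedule.pulses):
        raise ValueError("label vector length does not match schedule")
    out = np.full(calls.shape[0], HistoryClass.INDETERMINATE, dtype=object)
    readable = mask[:, idx]
    ivas_pos = readable & calls[:, idx]
    out[ivas_pos] = HistoryClass.IVAS_POS
    earlier_any_valid = mask[:, :idx].any(axis=1)
    earlier_pos = (calls[:, :idx] & mask[:, :idx]).any(axis=1)
    ivas_neg = readable & ~calls[:, idx]
    out[ivas_neg & earlier_any_valid & earlier_pos] = HistoryClass.RECENT_IMMIGRANT
    out[ivas_neg & earlier_any_valid & ~earlier_pos] = HistoryClass.TISSUE_LOCALIZED
    n_ind = int((out == HistoryClass.INDETERMINATE).sum())
    if n_ind:
        logger.info("classify_many: %d of %d cells indeterminate", n_ind, len(cells))
    return list(out)


def continuously_circulating_fraction(
    blood_cells: Sequence[LabelVector],
    schedule: InfusionSchedule,
    lookback_start: float,
) -> float:
    """Fraction of blood-harvested cells positive at every valid pulse from
    ``lookback_start`` hours before harvest through the IVas pulse.

    Cells with any masked pulse inside the window are excluded from both
    numerator and denominator.  Raises when no cell is eligible.
    """
    if lookback_start <= 0:
        raise ValueError("lookback_start must be > 0")
    calls, mask = _stack(blood_cells)
    if calls.shape[0] == 0:
        raise ValueError("no blood cells supplied")
    times = np.array(schedule.times)
    window = times <= lookback_start + _TIME_EPS
    if not window.any():
        raise ValueError(
            f"no pulse lies within the {lookback_start} h lookback window"
        )
    eligible = mask[:, window].all(axis=1)
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError(
            "no cell has a fully interpretable pulse window; CC undefined"
        )
    if n_eligible < calls.shape[0]:
        logger.info(
            "CC(%g h): excluded %d/%d cells with masked pulses in window",
            lookback_start,
            calls.shape[0] - n_eligible,
            calls.shape[0],
        )
    all_pos = calls[eligible][:, window].all(axis=1)
    return float(all_pos.mean())


@dataclass(frozen=True)
class FlowPair:
    """2x2 contingency of calls between two consecutive interpretable
    pulses, over cells valid at both."""

    from_index: int
    to_index: int
    from_channel: str
    to_channel: str
    pos_pos: int
    pos_neg: int
    neg_pos: int
    neg_neg: int

    @property
    def denominator(self) -> int:
        return self.pos_pos + self.pos_neg + self.neg_pos + self.neg_neg


@dataclass(frozen=True)
class TransitionFlow:
    """Sankey-style transition flows across consecutive pulses."""

    pairs: tuple[FlowPair, ...]

    def to_sankey(self) -> dict:
        """Node/link export for standard Sankey renderers.

        Nodes are pulse x {pos, neg}; link values are raw counts with
        fractions computed as exact count ratios against the pair
        denominator.
        """
        nodes: list[dict] = []
        node_id: dict[tuple[int, str], int] = {}

        def _node(pulse_index: int, channel: str, state: str) -> int:
            key = (pulse_index, state)
            if key not in node_id:
                node_id[key] = len(nodes)
                nodes.append(
                    {"id": len(nodes), "pulse_index": pulse_index,
                     "channel": channel, "state": state}
                )
            return node_id[key]

        links = []
        for pair in self.pairs:
            denom = pair.denominator
            for s_from, s_to, count in (
                ("pos", "pos", pair.pos_pos),
                ("pos", "neg", pair.pos_neg),
                ("neg", "pos", pair.neg_pos),
                ("neg", "neg", pair.neg_neg),
            ):
                links.append(
                    {
                        "source": _node(pair.from_index, pair.from_channel, s_from),
                        "target": _node(pair.to_index, pair.to_channel, s_to),
                        "count": count,
                        "fraction": (count / denom) if denom else None,
                    }
                )
        return {"nodes": nodes, "links": links}


def transition_flows(
    cells: Sequence[LabelVector], schedule: InfusionSchedule
) -> TransitionFlow:
    """2x2 call contingencies between consecutive interpretable pulses.

    Pulses masked for every cell are bridged (their neighbours become
    consecutive); a cell contributes to a pair only when valid at both of
    its pulses.  A single-pulse schedule yields an empty flow set.
    """
    calls, mask = _stack(cells)
    if calls.shape[0] and calls.shape[1] != len(schedule.pulses):
        raise ValueError("label vector length does not match schedule")
    if calls.shape[0] == 0:
        return TransitionFlow(pairs=())
    usable = [j for j in range(len(schedule.pulses)) if mask[:, j].any()]
    pairs = []
    for i, j in zip(usable, usable[1:]):
        both = mask[:, i] & mask[:, j]
        ci, cj = calls[both, i], calls[both, j]
        pairs.append(
            FlowPair(
                from_index=i,
                to_index=j,
                from_channel=schedule.pulses[i].channel,
                to_channel=schedule.pulses[j].channel,
                pos_pos=int((ci & cj).sum()),
                pos_neg=int((ci & ~cj).sum()),
                neg_pos=int((~ci & cj).sum()),
                neg_neg=int((~ci & ~cj).sum()),
            )
        )
    return TransitionFlow(pairs=tuple(pairs))
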