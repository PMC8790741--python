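"""End-to-end study driver: simulate -> label -> gate -> classify ->
summarize -> compare, with auditable per-stage outputs.

Every stage writes a delimited-text table (or JSON export) under the study
output directory, and a manifest records the seed, a config digest and
per-file checksums so a run can be reproduced bit-identically.  No stage
after simulation consumes the ground-truth trajectory fields; they are
carried only for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import sivskit
from sivskit.config import StudyConfig
from sivskit.history import (
    HistoryClass,
    classify_many,
    continuously_circulating_fraction,
    transition_flows,
)
from sivskit.io import write_json, write_manifest, write_table
from sivskit.kinetics import (
    entry_rate,
    estimate_blood_residence,
    tissue_localized_fraction,
    tl_fraction_by_marker,
)
from sivskit.labeling import (
    BLOOD,
    PERIVASCULAR,
    DEFAULT_LABEL_POLICY,
    InfusionSchedule,
    IntensityModel,
    LabelVector,
    calls_from_truth,
    gate_channel,
    render_intensity_matrix,
)
from sivskit.stats import compare_subsets, holm_adjust
from sivskit.trafficking import Cohort, simulate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(name, str(exc)) from exc

        return wrapper

    return deco


def label_vectors_from_table(
    table: pd.DataFrame, channels: tuple[str, ...], call_prefix: str = "call_"
) -> list[LabelVector]:
    """Build per-cell label vectors from ``call_<channel>`` and
    ``valid_<channel>`` columns."""
    calls = table[[f"{call_prefix}{ch}" for ch in channels]].to_numpy(dtype=bool)
    mask = table[[f"valid_{ch}" for ch in channels]].to_numpy(dtype=bool)
    return [
        LabelVector(calls=tuple(c), mask=tuple(m)) for c, m in zip(calls, mask)
    ]


@_stage("label")
def apply_labels_stage(
    cohort: Cohort, efficiency: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Ground-truth pulse exposure per cell: in blood at the pulse instant,
    or perivascular in a sinusoidal tissue (infused antibody reaches the
    perivascular space there).  Adds ``truecall_<channel>`` columns."""
    table = cohort.table.copy()
    channels = cohort.channels
    truth = table[[f"truth_{ch}" for ch in channels]].to_numpy(dtype=object)
    out = np.zeros(truth.shape, dtype=bool)
    for tissue in cohort.config.tissues:
        sel = (table["home_tissue"] == tissue.name).to_numpy()
        if not sel.any():
            continue
        policy = (
            frozenset({BLOOD, PERIVASCULAR}) if tissue.sinusoidal else DEFAULT_LABEL_POLICY
        )
        out[sel] = calls_from_truth(
            truth[sel], label_policy=policy, efficiency=efficiency, rng=rng
        )
    for j, ch in enumerate(channels):
        table[f"truecall_{ch}"] = out[:, j]
    return table


@_stage("intensity")
def render_stage(
    table: pd.DataFrame,
    channels: tuple[str, ...],
    model: IntensityModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    table = table.copy()
    calls = table[[f"truecall_{ch}" for ch in channels]].to_numpy(dtype=bool)
    intensities = render_intensity_matrix(calls, channels, model, rng)
    for j, ch in enumerate(channels):
        table[f"intensity_{ch}"] = intensities[:, j]
    return table


@_stage("gate")
def gate_stage(
    table: pd.DataFrame,
    channels: tuple[str, ...],
    model: IntensityModel,
    quantile: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Threshold each channel against a synthetic pre-infusion negative
    control drawn from the model's background population; adds
    ``call_<channel>`` columns."""
    table = table.copy()
    thresholds: dict[str, float] = {}
    for ch in channels:
        control = model.sample_negative(ch, model.control_n, rng)
        thr, calls = gate_channel(table[f"intensity_{ch}"].to_numpy(), control, quantile)
        thresholds[ch] = thr
        table[f"call_{ch}"] = calls
    return table, thresholds


@_stage("classify")
def classify_stage(table: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Positional-history class per tissue-harvested cell; blood-draw rows
    are left unclassified (CC is a blood-side quantity)."""
    table = table.copy()
    channels = config.cohort.channels
    classes = np.full(len(table), "", dtype=object)
    for animal in config.cohort.animals:
        sel = (table["animal"] == animal.name) & (table["tissue"] != BLOOD)
        idx = np.nonzero(sel.to_numpy())[0]
        if idx.size == 0:
            continue
        vectors = label_vectors_from_table(table.iloc[idx], channels)
        for i, cls in zip(idx, classify_many(vectors, animal.schedule)):
            classes[i] = cls.value
    table["history_class"] = classes
    return table


def _counts_log(table: pd.DataFrame) -> dict:
    """Structured per-class counts so every denominator is auditable."""
    tissue_rows = table[table["tissue"] != BLOOD]
    return {
        "n_cells": int(len(table)),
        "n_blood_draw": int((table["tissue"] == BLOOD).sum()),
        "n_tissue_harvest": int(len(tissue_rows)),
        "history_class_counts": {
            str(k): int(v)
            for k, v in tissue_rows["history_class"].value_counts().items()
        },
    }


@_stage("kinetics")
def summarize_stage(table: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """One summary row per animal x harvest site x subset: IVas+/TL/RI
    fractions, marker-stratified TL, entry rate, and CC by lookback."""
    channels = config.cohort.channels
    cc_cols = [f"cc_{lb:g}h" for lb in config.lookbacks]
    rows = []
    for animal in config.cohort.animals:
        schedule = animal.schedule
        sub_table = table[table["animal"] == animal.name]
        for subset in config.cohort.subsets:
            s_table = sub_table[sub_table["subset"] == subset.subset_name]
            for site, group in s_table.groupby("tissue"):
                vectors = label_vectors_from_table(group, channels)
                row: dict = {
                    "animal": animal.name,
                    "tissue": site,
                    "subset": subset.subset_name,
                    "n_cells": len(group),
                }
                if site == BLOOD:
                    for lb, col in zip(config.lookbacks, cc_cols):
                        try:
                            row[col] = continuously_circulating_fraction(
                                vectors, schedule, lb
                            )
                        except ValueError as exc:
                            logger.info(
                                "CC undefined for %s/%s at %g h: %s",
                                animal.name, subset.subset_name, lb, exc,
                            )
                            row[col] = np.nan
                else:
                    classes = np.array(
                        [c.value for c in classify_many(vectors, schedule)], dtype=object
                    )
                    classifiable = classes != HistoryClass.INDETERMINATE.value
                    n_cls = int(classifiable.sum())
                    row["n_classified"] = n_cls
                    row["ivas_pos_fraction"] = (
                        float((classes == HistoryClass.IVAS_POS.value).sum() / n_cls)
                        if n_cls
                        else np.nan
                    )
                    try:
                        row["tl_fraction"] = tissue_localized_fraction(vectors, schedule)
                        row["ri_fraction"] = 1.0 - row["tl_fraction"]
                    except ValueError:
                        row["tl_fraction"] = np.nan
                        row["ri_fraction"] = np.nan
                    n_ivas_neg = int(
                        np.isin(
                            classes,
                            [
                                HistoryClass.RECENT_IMMIGRANT.value,
                                HistoryClass.TISSUE_LOCALIZED.value,
                            ],
                        ).sum()
                    )
                    row["n_ivas_neg"] = n_ivas_neg
                    if config.entry_rate_window is not None:
                        try:
                            row["entry_rate_pct_per_hour"] = entry_rate(
                                vectors, schedule, config.entry_rate_window
                            )
                        except ValueError as exc:
                            logger.info(
                                "entry rate undefined for %s/%s/%s: %s",
                                animal.name, site, subset.subset_name, exc,
                            )
                            row["entry_rate_pct_per_hour"] = np.nan
                    marker = group["marker_state"].to_numpy(dtype=bool)
                    strata = tl_fraction_by_marker(vectors, marker, schedule)
                    row["tl_fraction_marker_pos"] = (
                        np.nan
                        if strata.tl_fraction_marker_pos is None
                        else strata.tl_fraction_marker_pos
                    )
                    row["tl_fraction_marker_neg"] = (
                        np.nan
                        if strata.tl_fraction_marker_neg is None
                        else strata.tl_fraction_marker_neg
                    )
                rows.append(row)
    summary = pd.DataFrame(rows)
    ordered = [
        "animal", "tissue", "subset", "n_cells", "n_classified", "n_ivas_neg",
        "ivas_pos_fraction", "tl_fraction", "ri_fraction",
        "tl_fraction_marker_pos", "tl_fraction_marker_neg",
        "entry_rate_pct_per_hour", *cc_cols,
    ]
    return summary[[c for c in ordered if c in summary.columns]]


@_stage("residence")
def residence_stage(summary: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Blood residence-time estimates per animal x subset x lookback from
    the blood-draw CC fractions."""
    rows = []
    blood = summary[summary["tissue"] == BLOOD]
    for _, r in blood.iterrows():
        for lb in config.lookbacks:
            cc = r.get(f"cc_{lb:g}h", np.nan)
            if pd.isna(cc) or cc <= 0:
                continue
            est = estimate_blood_residence(float(cc), lb)
            rows.append(
                {
                    "animal": r["animal"],
                    "subset": r["subset"],
                    "lookback_hours": lb,
                    "cc_fraction": est.cc_fraction,
                    "exit_rate_per_hour": est.exit_rate_per_hour,
                    "mean_residence_hours": est.mean_residence_hours,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "animal", "subset", "lookback_hours", "cc_fraction",
            "exit_rate_per_hour", "mean_residence_hours",
        ],
    )


@_stage("flows")
def flows_stage(
    table: pd.DataFrame, config: StudyConfig
) -> dict[tuple[str, str], dict]:
    """Sankey node/link export per animal x subset over blood-draw cells."""
    channels = config.cohort.channels
    exports = {}
    for animal in config.cohort.animals:
        for subset in config.cohort.subsets:
            sel = (
                (table["animal"] == animal.name)
                & (table["subset"] == subset.subset_name)
                & (table["tissue"] == BLOOD)
            )
            group = table[sel]
            if len(group) == 0:
                continue
            vectors = label_vectors_from_table(group, channels)
            flow = transition_flows(vectors, animal.schedule)
            exports[(animal.name, subset.subset_name)] = flow.to_sankey()
    return exports


@_stage("compare")
def compare_stage(summary: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for spec in config.comparisons:
        site_rows = summary[summary["tissue"] == spec.tissue]
        subsets = [
            s.subset_name
            for s in config.cohort.subsets
            if s.subset_name in set(site_rows["subset"])
        ]
        specs_rows = []
        for i, sx in enumerate(subsets):
            for sy in subsets[i + 1 :]:
                try:
                    cmp_res = compare_subsets(site_rows, spec.metric, (sx, sy))
                except ValueError as exc:
                    logger.info(
                        "comparison skipped (%s, %s vs %s): %s",
                        spec.metric, sx, sy, exc,
                    )
                    continue
                specs_rows.append(
                    {
                        "metric": spec.metric,
                        "tissue": spec.tissue,
                        "subset_x": sx,
                        "subset_y": sy,
                        "n_x": len(cmp_res.x),
                        "n_y": len(cmp_res.y),
                        "rank_sum_x": cmp_res.rank_sum_x,
                        "p_value": cmp_res.p_value,
                        "method": cmp_res.method,
                    }
                )
        if config.holm and specs_rows:
            adj = holm_adjust([r["p_value"] for r in specs_rows])
            for r, p in zip(specs_rows, adj):
                r["p_holm"] = p
        rows.extend(specs_rows)
    cols = [
        "metric", "tissue", "subset_x", "subset_y", "n_x", "n_y",
        "rank_sum_x", "p_value", "method",
    ]
    if config.holm:
        cols.append("p_holm")
    return pd.DataFrame(rows, columns=cols)


@dataclass
class StudyResult:
    config: StudyConfig
    cohort: Cohort
    called_table: pd.DataFrame
    thresholds: dict[str, float]
    summary: pd.DataFrame
    residence: pd.DataFrame
    comparisons: pd.DataFrame
    sankey: dict[tuple[str, str], dict]
    counts: dict
    out_dir: Path | None = None
    outputs: list[Path] = field(default_factory=list)


def run_study(
    config: StudyConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    collect_trajectories: bool = False,
) -> StudyResult:
    """Run the full synthetic study and (optionally) write all outputs.

    Deterministic given the seed: the cohort, labels, intensities, gates and
    every downstream table depend only on the config and the seed.
    """
    if seed is not None:
        config = config.with_seed(seed)
    s = config.seed
    rng_label = np.random.default_rng([s, 101])
    rng_intensity = np.random.default_rng([s, 102])
    rng_control = np.random.default_rng([s, 103])

    try:
        cohort = simulate_cohort(config.cohort, collect_trajectories=collect_trajectories)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    model = config.intensity_model()
    channels = config.cohort.channels
    labeled = apply_labels_stage(cohort, config.label_efficiency, rng_label)
    rendered = render_stage(labeled, channels, model, rng_intensity)
    called, thresholds = gate_stage(
        rendered, channels, model, config.gate_quantile, rng_control
    )
    classified = classify_stage(called, config)
    counts = _counts_log(classified)
    logger.info("study %s cell accounting: %s", config.name, counts)
    summary = summarize_stage(classified, config)
    residence = residence_stage(summary, config)
    sankey = flows_stage(classified, config)
    comparisons = compare_stage(summary, config)

    result = StudyResult(
        config=config,
        cohort=cohort,
        called_table=classified,
        thresholds=thresholds,
        summary=summary,
        residence=residence,
        comparisons=comparisons,
        sankey=sankey,
        counts=counts,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = [
            write_table(cohort.table, out_dir / "cohort.csv"),
            write_table(classified, out_dir / "called.csv"),
            write_table(summary, out_dir / "summary.csv"),
            write_table(residence, out_dir / "residence.csv"),
            write_table(comparisons, out_dir / "comparisons.csv"),
            write_json(thresholds, out_dir / "thresholds.json"),
            write_json(counts, out_dir / "cell_counts.json"),
        ]
        for (animal, subset), export in sankey.items():
            outputs.append(
                write_json(export, out_dir / f"sankey_{animal}_{subset}.json")
            )
        write_manifest(
            out_dir,
            config.name,
            config.seed,
            config.raw,
            outputs,
            sivskit.__version__,
        )
        result.out_dir = out_dir
        result.outputs = outputs
    return result
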