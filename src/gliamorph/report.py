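"""Pipeline orchestration, group summaries, and evaluation against truth.

`run_pipeline` chains projection, preprocessing, segmentation, morphometry
and marker quantification into per-cell and per-group tables (cells.csv /
groups.csv) plus a machine-readable run log.  `evaluate` scores a pipeline
run against the synthetic generator's ground truth by greedy one-to-one
Jaccard matching.  `sample_size` is the standard two-group normal-
approximation group-size formula n = 2 sigma^2 f(alpha, beta) / Delta^2.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .morphometry import CLASS_LABELS, population_fractions
from .pipeline import (
    LabelMask,
    PipelineConfig,
    max_project,
    preprocess_iba1,
    preprocess_marker,
    segment_cells,
)
from .quant import RoiSpec, quantify_roi
from .stack import CalibratedStack, read_stack

__all__ = [
    "EvaluationReport",
    "run_pipeline",
    "evaluate",
    "summarize",
    "sample_size",
    "CELLS_CSV_COLUMNS",
]

CELLS_CSV_COLUMNS = [
    "cell_id", "roi", "area_um2", "perimeter_um", "circularity", "class",
    "infiltrated_flag", "mean_tmem_total", "mean_tmem_soma",
    "mean_tmem_ramification", "ramification_literal",
]

FLOAT_FORMAT = "%.6g"


def run_pipeline(
    stack: CalibratedStack | str | Path,
    config: PipelineConfig,
    rois: list[RoiSpec] | None = None,
    out_dir: str | Path | None = None,
    group_keys: tuple[str, ...] = ("roi", "class"),
) -> tuple[pd.DataFrame, pd.DataFrame, LabelMask]:
    """Full deterministic run from a calibrated stack to per-cell tables.

    Returns ``(cells, groups, label_mask)``.  When ``out_dir`` is given,
    cells.csv, groups.csv and run_log.json are written there with floats
    at 6 significant digits.
    """
    if not isinstance(stack, CalibratedStack):
        stack = read_stack(stack)
    px = stack.pixel_size_um
    projections = max_project(stack)
    iba1_img = preprocess_iba1(projections["iba1"], config)
    marker_img = preprocess_marker(projections["tmem119"], config)
    labels = segment_cells(iba1_img, config, px)
    if rois is None:
        rois = [RoiSpec.whole_image(stack.shape_yx, px)]
    tables = [
        quantify_roi(labels, marker_img, roi,
                     perimeter_estimator=config.perimeter_estimator)
        for roi in rois
    ]
    cells = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    groups = summarize(cells, list(group_keys)) if len(cells) else pd.DataFrame(
        columns=list(group_keys) + ["n", "mean", "sd", "median", "q1", "q3"]
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cells.reindex(columns=[c for c in cells.columns]).to_csv(
            out_dir / "cells.csv", index=False, float_format=FLOAT_FORMAT
        )
        groups.to_csv(out_dir / "groups.csv", index=False, float_format=FLOAT_FORMAT)
        log = {
            "gliamorph_version": __version__,
            "numpy_version": np.__version__,
            "config": asdict(config),
            "pixel_size_um": px,
            "rois": [
                {"name": r.name, "anchor_um": list(r.anchor_um),
                 "direction": list(r.direction), "offset_um": r.offset_um,
                 "window_um": list(r.window_um)}
                for r in rois
            ],
            "n_cells": int(len(cells)),
            "n_segmented": labels.n_cells,
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return cells, groups, labels


def summarize(
    records: pd.DataFrame,
    keys: list[str],
    value: str = "mean_tmem_total",
) -> pd.DataFrame:
    """Group-wise n / mean / SD / median / quartiles of one value column."""
    if records.empty:
        raise ValueError("no records to summarize")

    def _agg(s: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": int(s.count()),
                "mean": s.mean(),
                "sd": s.std(ddof=1) if s.count() > 1 else 0.0,
                "median": s.median(),
                "q1": s.quantile(0.25),
                "q3": s.quantile(0.75),
            }
        )

    out = records.groupby(keys, sort=True)[value].apply(_agg).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return out


@dataclass
class EvaluationReport:
    """Segmentation / classification / intensity scores versus ground truth."""

    confusion: pd.DataFrame          # rows truth class, cols assigned + 'missed'
    fraction_error_pp: dict[str, float]
    n_matched: int
    n_missed: int
    n_spurious: int
    mean_jaccard: float
    intensity_relative_errors: list[float] = field(default_factory=list)

    @property
    def mean_intensity_relative_error(self) -> float:
        if not self.intensity_relative_errors:
            return float("nan")
        return float(np.mean(self.intensity_relative_errors))

    def to_dict(self) -> dict:
        return {
            "confusion": {r: self.confusion.loc[r].to_dict() for r in self.confusion.index},
            "fraction_error_pp": self.fraction_error_pp,
            "n_matched": self.n_matched,
            "n_missed": self.n_missed,
            "n_spurious": self.n_spurious,
            "mean_jaccard": self.mean_jaccard,
            "mean_intensity_relative_error": self.mean_intensity_relative_error,
        }


def _pair_overlaps(truth_labels: np.ndarray, seg_labels: np.ndarray):
    """Joint pixel counts for all overlapping (truth, segmented) label pairs."""
    t = truth_labels.ravel()
    s = seg_labels.ravel()
    both = (t > 0) & (s > 0)
    if not both.any():
        return {}
    keys, counts = np.unique(np.stack([t[both], s[both]]), axis=1, return_counts=True)
    return {(int(keys[0, i]), int(keys[1, i])): int(counts[i]) for i in range(keys.shape[1])}


def evaluate(
    cells: pd.DataFrame,
    label_mask: LabelMask,
    truth_labels: np.ndarray,
    truth_table: pd.DataFrame,
    jaccard_floor: float = 0.3,
) -> EvaluationReport:
    """Score a pipeline run against synthetic ground truth.

    Segmented cells are matched one-to-one to truth cells greedily by
    decreasing Jaccard overlap (pairs below ``jaccard_floor`` never match).
    The confusion matrix rows are truth classes (row sums equal truth
    counts; unmatched truth cells land in the 'missed' column); intensity
    recovery is the per-matched-cell relative error of the total marker
    mean versus the painted truth mean.
    """
    seg = label_mask.data
    overlaps = _pair_overlaps(truth_labels, seg)
    t_sizes = {int(k): int(v) for k, v in zip(*np.unique(truth_labels[truth_labels > 0],
                                                         return_counts=True))}
    s_sizes = {int(k): int(v) for k, v in zip(*np.unique(seg[seg > 0], return_counts=True))}
    scored = []
    for (ti, si), inter in overlaps.items():
        union = t_sizes[ti] + s_sizes[si] - inter
        j = inter / union
        if j >= jaccard_floor:
            scored.append((j, ti, si))
    scored.sort(reverse=True)
    matched_t: dict[int, int] = {}
    matched_s: set[int] = set()
    jaccards = []
    for j, ti, si in scored:
        if ti in matched_t or si in matched_s:
            continue
        matched_t[ti] = si
        matched_s.add(si)
        jaccards.append(j)

    truth_by_id = truth_table.set_index("cell_id")
    cells_by_id = cells.set_index("cell_id") if len(cells) else cells
    cols = list(CLASS_LABELS) + ["missed"]
    confusion = pd.DataFrame(0, index=list(CLASS_LABELS), columns=cols)
    intensity_errors = []
    for ti in truth_by_id.index:
        t_class = truth_by_id.loc[ti, "class"]
        si = matched_t.get(int(ti))
        if si is None or si not in getattr(cells_by_id, "index", []):
            confusion.loc[t_class, "missed"] += 1
            continue
        a_class = cells_by_id.loc[si, "class"]
        confusion.loc[t_class, a_class] += 1
        t_mean = truth_by_id.loc[ti, "mean_tmem_total"]
        if t_mean > 0:
            rel = abs(cells_by_id.loc[si, "mean_tmem_total"] - t_mean) / t_mean
            intensity_errors.append(float(rel))

    truth_fracs = population_fractions(list(truth_by_id["class"]))
    if len(cells):
        seg_fracs = population_fractions(list(cells["class"]))
    else:
        seg_fracs = {k: 0.0 for k in CLASS_LABELS}
    frac_err = {k: seg_fracs[k] - truth_fracs[k] for k in CLASS_LABELS}

    return EvaluationReport(
        confusion=confusion,
        fraction_error_pp=frac_err,
        n_matched=len(matched_t),
        n_missed=len(truth_by_id) - len(matched_t),
        n_spurious=label_mask.n_cells - len(matched_s),
        mean_jaccard=float(np.mean(jaccards)) if jaccards else float("nan"),
        intensity_relative_errors=intensity_errors,
    )


def sample_size(
    sigma: float,
    delta: float,
    alpha: float = 0.05,
    beta: float = 0.2,
    f: float | None = None,
) -> tuple[float, int]:
    """Two-group size for detecting a mean difference Delta at spread sigma.

    ``n = 2 sigma^2 f(alpha, beta) / Delta^2`` with
    ``f = (z_{1-alpha/2} + z_{1-beta})^2`` unless an explicit ``f`` is
    supplied (published tables sometimes use slightly different factors).
    Returns ``(n_unrounded, n_rounded_up)``.
    """
    if sigma <= 0 or delta <= 0:
        raise ValueError("sigma and delta must be positive")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must lie in (0, 1)")
    if f is None:
        f = float((stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(1 - beta)) ** 2)
    n = 2 * sigma**2 * f / delta**2
    return n, math.ceil(n)
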