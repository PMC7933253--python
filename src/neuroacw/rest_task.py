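"""Rest-task similarity and difference analyses.

Similarity has three layers, from coarse to fine:

* **spatial correlation** — one Pearson r between the subject-averaged
  rest map and a subject-averaged task map, across regions;
* **regression** — OLS of the task map on the rest map (how much task
  topography is explained by rest topography, R-squared);
* **regional correlation** — per region, Pearson r between rest and task
  values across subjects, FDR-corrected over regions.

The rest-task difference is the percent change
``(rest - task) / rest * 100`` per region per subject: positive when the
timescale shortens during the task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "SimilarityReport",
    "spatial_correlation",
    "rest_task_regression",
    "regional_correlation",
    "percent_change",
]


@dataclass(frozen=True)
class SimilarityReport:
    """Similarity of one task map to the rest map."""

    task: str
    spatial_r: float
    spatial_p: float
    slope: float
    intercept: float
    r_squared: float

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "spatial_r": self.spatial_r,
            "spatial_p": self.spatial_p,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


def _check_maps(map_a: np.ndarray, map_b: np.ndarray) -> None:
    if map_a.shape != map_b.shape or map_a.ndim != 1:
        raise ValueError("maps must be 1-D with matching regions")
    if map_a.size < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(map_a) == 0 or np.ptp(map_b) == 0:
        raise ValueError("correlation undefined for a constant map")


def spatial_correlation(map_a, map_b) -> tuple[float, float]:
    """Pearson r (and p) between two subject-averaged regional maps."""
    map_a, map_b = np.asarray(map_a, float), np.asarray(map_b, float)
    _check_maps(map_a, map_b)
    res = sps.pearsonr(map_a, map_b)
    return float(res.statistic), float(res.pvalue)


def rest_task_regression(rest_map, task_map) -> tuple[float, float, float]:
    """OLS of task on rest across regions: (slope, intercept, R-squared)."""
    rest_map, task_map = np.asarray(rest_map, float), np.asarray(task_map, float)
    _check_maps(rest_map, task_map)
    res = sps.linregress(rest_map, task_map)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def regional_correlation(
    rest: pd.DataFrame, task: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-region Pearson r across subjects, with a BH-FDR mask.

    ``rest`` and ``task`` are subject x region frames (index subject_id,
    columns region_id) from the same subjects. Returns one row per
    region: ``region_id, r, p, p_adj, significant``; regions that do not
    survive FDR at ``alpha`` are reported but flagged insignificant.
    """
    if not rest.index.equals(task.index):
        raise ValueError("rest and task frames must share the same subjects (index)")
    if not rest.columns.equals(task.columns):
        raise ValueError("rest and task frames must share the same regions (columns)")
    if len(rest) < 3:
        raise ValueError("need at least 3 subjects")
    r = np.empty(rest.shape[1])
    p = np.empty(rest.shape[1])
    for i, region in enumerate(rest.columns):
        a, b = rest[region].to_numpy(), task[region].to_numpy()
        if (
            not (np.all(np.isfinite(a)) and np.all(np.isfinite(b)))
            or np.ptp(a) == 0
            or np.ptp(b) == 0
        ):
            # correlation undefined (missing crossings, or lag-quantized
            # values identical across subjects): r = nan, never significant
            r[i], p[i] = np.nan, 1.0
            continue
        res = sps.pearsonr(a, b)
        r[i], p[i] = res.statistic, res.pvalue
    reject, p_adj = bh_fdr(p, alpha=alpha)
    return pd.DataFrame(
        {
            "region_id": rest.columns,
            "r": r,
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )


def percent_change(rest, task, labels=None) -> np.ndarray:
    """Percent change from rest to task: ``(rest - task) / rest * 100``.

    Elementwise over matching arrays (any shape); positive when the task
    value is smaller than rest. ``labels`` (same shape) is only used to
    name offending entries when a rest value is zero.
    """
    rest, task = np.asarray(rest, float), np.asarray(task, float)
    if rest.shape != task.shape:
        raise ValueError("rest and task must have matching shapes")
    zero = rest == 0
    if zero.any():
        where = (
            np.asarray(labels)[zero].tolist()
            if labels is not None
            else np.argwhere(zero).tolist()
        )
        raise ValueError(f"zero rest value(s) at {where[:5]}")
    return (rest - task) / rest * 100.0
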