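"""Density estimation of the pooled, min-max-scaled timescale values.

The pooled distribution of ACW values (all subjects, regions and
conditions together) is summarized by a Gaussian kernel density estimate
on the unit interval after min-max scaling. Pooling options mirror the
three views of the data: no pooling (the full subject x region
interaction), averaging over regions (one value per subject), and
averaging over subjects (one value per region).

Bimodality is assessed two ways: local maxima of the KDE curve, and a
two-component versus one-component Gaussian-mixture fit compared by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.nonparametric.kde import KDEUnivariate

__all__ = [
    "DensityEstimate",
    "minmax_scale",
    "estimate_density",
    "bimodality_report",
]

POOLINGS = ("none", "avg_regions", "avg_subjects")


@dataclass(frozen=True)
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    kernel: str = "gaussian"

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def n_modes(self, prominence: float = 0.1) -> int:
        """Local maxima of the density, relative-prominence filtered."""
        threshold = prominence * self.density.max()
        peaks, _ = find_peaks(self.density, prominence=threshold)
        # A substantial maximum at a support boundary also counts as a
        # mode (boundary reflection flattens the slope there, so
        # find_peaks cannot see it).
        modes = list(peaks)
        if self.density[0] > self.density[1] and self.density[0] >= threshold:
            modes.append(0)
        if self.density[-1] > self.density[-2] and self.density[-1] >= threshold:
            modes.append(self.density.size - 1)
        return len(modes)


def minmax_scale(values) -> np.ndarray:
    """Scale values to [0, 1] as ``(x - min) / (max - min)``."""
    values = np.asarray(values, float)
    span = np.ptp(values)
    if span == 0:
        raise ValueError("min-max scaling undefined for constant input")
    return (values - values.min()) / span


def _pool(table: pd.DataFrame, value_col: str, pooling: str) -> np.ndarray:
    if pooling == "none":
        return table[value_col].to_numpy()
    if pooling == "avg_regions":
        return table.groupby("subject_id")[value_col].mean().to_numpy()
    if pooling == "avg_subjects":
        return table.groupby("region_id")[value_col].mean().to_numpy()
    raise ValueError(f"pooling must be one of {POOLINGS}")


def estimate_density(
    values,
    *,
    grid_size: int = 512,
    bandwidth: str | float = "silverman",
) -> DensityEstimate:
    """Gaussian KDE of min-max-scaled values on a [0, 1] grid.

    ``values`` are scaled internally; Silverman's rule sets the default
    bandwidth. Kernel mass leaking past the support edges (the scaled
    minimum and maximum sit exactly on them) is folded back by boundary
    reflection, so the trapezoidal integral of the returned curve is ~1.
    """
    values = np.asarray(values, float)
    if values.size < 10:
        raise ValueError("need at least 10 values for a density estimate")
    scaled = minmax_scale(values)
    kde = KDEUnivariate(scaled)
    kde.fit(kernel="gau", bw=bandwidth, fft=False)
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde.evaluate(grid) + kde.evaluate(-grid) + kde.evaluate(2.0 - grid)
    density = np.clip(density, 0.0, None)
    return DensityEstimate(grid=grid, density=density, bandwidth=float(kde.bw))


def pooled_density(
    acw_table: pd.DataFrame, value_col: str, pooling: str = "none", **kwargs
) -> DensityEstimate:
    """Density of one ACW scale after the requested pooling.

    ``acw_table`` needs ``subject_id``, ``region_id`` and the value
    column; pooling (averaging) is applied before scaling.
    """
    return estimate_density(_pool(acw_table, value_col, pooling), **kwargs)


def bimodality_report(values) -> dict:
    """Is the (scaled) sample bimodal?

    Returns the KDE mode count and whether a 2-component Gaussian
    mixture is preferred over 1 component by BIC. ``bimodal`` requires
    both indicators to agree.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, float)
    scaled = minmax_scale(values).reshape(-1, 1)
    estimate = estimate_density(values)
    bics = []
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=0).fit(scaled)
        bics.append(gm.bic(scaled))
    # Guard against BIC preferring 2 nearly-coincident components.
    gm2 = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(scaled)
    means = np.sort(gm2.means_.ravel())
    sds = np.sqrt(gm2.covariances_.ravel())
    separated = (means[1] - means[0]) > 1.5 * sds.mean()
    n_modes = estimate.n_modes()
    return {
        "n_modes": n_modes,
        "bic_1": float(bics[0]),
        "bic_2": float(bics[1]),
        "mixture_preferred": bool(bics[1] < bics[0] and separated),
        "bimodal": bool(n_modes >= 2 and bics[1] < bics[0] and separated),
    }
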