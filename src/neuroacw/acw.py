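"""Autocorrelation-window estimation.

The intrinsic neural timescale of a signal is summarized by two lag
statistics of its sample autocorrelation function (ACF):

* **ACW-50** — the first lag (in ms) where the normalized ACF drops below
  half of its lag-0 maximum.
* **ACW-0** — the first lag (in ms) where the ACF reaches zero, i.e. the
  first non-positive coefficient.

The ACF is the biased (denominator ``n``) estimator computed with FFTs on
the zero-padded, demeaned signal, normalized to 1 at lag 0. The biased
estimator keeps every coefficient in ``[-1, 1]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft

__all__ = [
    "CONDITIONS",
    "DegenerateSignalError",
    "TimeSeries",
    "ParcellatedRecording",
    "ACFCurve",
    "ACWResult",
    "compute_acf",
    "acf_matrix",
    "acw50",
    "acw0",
    "acw_from_acf",
    "acw_map",
]

#: Closed set of recording conditions: resting state plus the three tasks
#: (story listening / language, motor, working memory).
CONDITIONS = ("Rest", "StoryM", "Motort", "Wrkmem")


class DegenerateSignalError(ValueError):
    """Raised when a signal has zero variance after demeaning."""


@dataclass(frozen=True)
class TimeSeries:
    """A single real-valued signal with its sampling rate in Hz."""

    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("time series must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if not (np.isfinite(self.fs_hz) and self.fs_hz > 0):
            raise ValueError(f"sampling rate must be finite and positive, got {self.fs_hz}")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ParcellatedRecording:
    """Region x time matrix for one subject in one condition.

    ``matrix`` rows follow ``region_ids`` order. Serialized as a
    tab-delimited matrix plus a JSON sidecar carrying subject, condition,
    sampling rate and the region-id list.
    """

    matrix: np.ndarray
    region_ids: list[str]
    subject_id: str
    condition: str
    fs_hz: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (regions x samples)")
        if self.matrix.shape[0] != len(self.region_ids):
            raise ValueError(
                f"row count {self.matrix.shape[0]} != number of region ids {len(self.region_ids)}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition {self.condition!r} not one of {CONDITIONS}")
        if not (np.isfinite(self.fs_hz) and self.fs_hz > 0):
            raise ValueError("fs_hz must be finite and positive")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def save(self, path: str | Path) -> None:
        """Write the matrix as TSV and a ``<path>.json`` sidecar."""
        path = Path(path)
        np.savetxt(path, self.matrix, delimiter="\t")
        sidecar = {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "fs_hz": self.fs_hz,
            "region_ids": self.region_ids,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ParcellatedRecording":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        matrix = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(
            matrix=matrix,
            region_ids=sidecar["region_ids"],
            subject_id=sidecar["subject_id"],
            condition=sidecar["condition"],
            fs_hz=float(sidecar["fs_hz"]),
        )


@dataclass(frozen=True)
class ACFCurve:
    """Normalized sample autocorrelation by lag, ``coefficients[0] == 1``."""

    coefficients: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        coefficients = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coefficients)
        if coefficients.ndim != 1 or coefficients.size < 2:
            raise ValueError("ACF needs coefficients for lag 0 and at least lag 1")
        if abs(coefficients[0] - 1.0) > 1e-12:
            raise ValueError("ACF must be normalized to 1 at lag 0")

    @property
    def max_lag(self) -> int:
        return self.coefficients.size - 1

    @property
    def lag_ms(self) -> np.ndarray:
        return np.arange(self.coefficients.size) * 1000.0 / self.fs_hz


@dataclass(frozen=True)
class ACWResult:
    """The two window statistics in milliseconds, with found flags.

    Values are ``nan`` when the corresponding crossing was not found
    within the computed lags; callers must check the flags rather than
    rely on sentinels.
    """

    acw50_ms: float
    acw0_ms: float
    acw50_found: bool
    acw0_found: bool


def _default_max_lag(n: int, fs_hz: float) -> int:
    # 10 s of lags comfortably exceeds cortical ACW values (hundreds of ms)
    return min(n - 1, int(round(10.0 * fs_hz)))


def acf_matrix(matrix: np.ndarray, fs_hz: float, max_lag: int | None = None) -> np.ndarray:
    """Biased FFT autocorrelation of each row; rows of shape (n_lags+1,).

    Rows with zero variance yield all-``nan`` coefficient rows; callers
    decide how to treat them (see :func:`acw_map`).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[1]
    if max_lag is None:
        max_lag = _default_max_lag(n, fs_hz)
    if not 1 <= max_lag < n:
        raise ValueError(f"max_lag must satisfy 1 <= max_lag < {n}, got {max_lag}")
    means = matrix.mean(axis=1, keepdims=True)
    demeaned = matrix - means
    variance = np.einsum("ij,ij->i", demeaned, demeaned)
    # relative threshold: a constant signal leaves only rounding residue
    tiny = n * (np.finfo(float).eps * (1.0 + np.abs(means[:, 0]))) ** 2 * 100.0
    variance = np.where(variance <= tiny, 0.0, variance)
    # Zero-pad to >= 2n so the circular convolution equals the linear one.
    nfft = next_fast_len(2 * n)
    spectrum = rfft(demeaned, n=nfft, axis=1)
    raw = irfft(np.abs(spectrum) ** 2, n=nfft, axis=1)[:, : max_lag + 1]
    coeffs = np.full_like(raw, np.nan)
    ok = variance > 0
    coeffs[ok] = raw[ok] / variance[ok, None]
    coeffs[ok, 0] = 1.0  # exact, avoids 1 +/- eps round-off
    return coeffs


def compute_acf(ts: TimeSeries, max_lag: int | None = None) -> ACFCurve:
    """Sample ACF of ``ts`` up to ``max_lag`` (default min(n-1, 10 s))."""
    coeffs = acf_matrix(ts.values[None, :], ts.fs_hz, max_lag)[0]
    if np.isnan(coeffs).any():
        raise DegenerateSignalError("signal has zero variance after demeaning")
    return ACFCurve(coefficients=coeffs, fs_hz=ts.fs_hz)


def _first_crossing(coeffs: np.ndarray, predicate: np.ndarray) -> int | None:
    hits = np.flatnonzero(predicate[1:])
    return None if hits.size == 0 else int(hits[0]) + 1


def acw50(acf: ACFCurve, interpolate: bool = False) -> tuple[float, bool]:
    """First lag (ms) where the ACF decays below half its lag-0 maximum.

    Returns ``(value_ms, found)``. With ``interpolate=True`` the crossing
    is linearly interpolated between the bracketing lags instead of
    reported at the first whole lag below 0.5.
    """
    coeffs = acf.coefficients
    k = _first_crossing(coeffs, coeffs < 0.5)
    if k is None:
        return float("nan"), False
    lag = float(k)
    if interpolate and k >= 1 and coeffs[k - 1] > coeffs[k]:
        lag = (k - 1) + (coeffs[k - 1] - 0.5) / (coeffs[k - 1] - coeffs[k])
    return lag * 1000.0 / acf.fs_hz, True


def acw0(acf: ACFCurve, interpolate: bool = False) -> tuple[float, bool]:
    """First lag (ms) where the ACF reaches zero (first non-positive value)."""
    coeffs = acf.coefficients
    k = _first_crossing(coeffs, coeffs <= 0.0)
    if k is None:
        return float("nan"), False
    lag = float(k)
    if interpolate and k >= 1 and coeffs[k - 1] > coeffs[k]:
        lag = (k - 1) + coeffs[k - 1] / (coeffs[k - 1] - coeffs[k])
    return lag * 1000.0 / acf.fs_hz, True


def acw_from_acf(acf: ACFCurve, interpolate: bool = False) -> ACWResult:
    w50, f50 = acw50(acf, interpolate=interpolate)
    w0, f0 = acw0(acf, interpolate=interpolate)
    return ACWResult(acw50_ms=w50, acw0_ms=w0, acw50_found=f50, acw0_found=f0)


def _crossings_from_rows(coeffs: np.ndarray, fs_hz: float) -> pd.DataFrame:
    """Vectorized ACW-50 / ACW-0 extraction from a stack of ACF rows."""
    period_ms = 1000.0 / fs_hz
    below_half = coeffs[:, 1:] < 0.5
    non_pos = coeffs[:, 1:] <= 0.0
    k50 = np.where(below_half.any(axis=1), below_half.argmax(axis=1) + 1, -1)
    k0 = np.where(non_pos.any(axis=1), non_pos.argmax(axis=1) + 1, -1)
    degenerate = np.isnan(coeffs[:, 0])
    out = pd.DataFrame(
        {
            "acw50_ms": np.where(k50 > 0, k50 * period_ms, np.nan),
            "acw0_ms": np.where(k0 > 0, k0 * period_ms, np.nan),
            "acw50_found": (k50 > 0) & ~degenerate,
            "acw0_found": (k0 > 0) & ~degenerate,
            "degenerate": degenerate,
        }
    )
    out.loc[degenerate, ["acw50_ms", "acw0_ms"]] = np.nan
    return out


def acw_map(rec: ParcellatedRecording, max_lag: int | None = None) -> pd.DataFrame:
    """Per-region ACW table for a parcellated recording.

    Columns: ``region_id, acw50_ms, acw0_ms, acw50_found, acw0_found,
    degenerate``. Degenerate (zero-variance) rows are flagged and carry
    ``nan`` values; all other regions are still computed.
    """
    coeffs = acf_matrix(rec.matrix, rec.fs_hz, max_lag)
    table = _crossings_from_rows(coeffs, rec.fs_hz)
    table.insert(0, "region_id", rec.region_ids)
    table.insert(1, "subject_id", rec.subject_id)
    table.insert(2, "condition", rec.condition)
    return table
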