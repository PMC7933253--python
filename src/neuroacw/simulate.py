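"""Synthetic signals and cohorts with known timescale structure.

Two generators live here:

1. A four-category catalogue of pseudo-aleatory signals — pink noise,
   sine waves, and their linear combinations with and without white
   noise — used to study how the two autocorrelation-window scales relate
   to each other under controlled spectral content.
2. A cohort generator that emits parcellated rest/task recordings whose
   regional timescales are controlled by a known slow-fluctuation weight
   ``a``: each region's signal is ``a * s_slow + (1 - a) * s_fast`` plus
   a weak oscillation and white measurement noise, where ``s_slow`` is
   pink noise low-passed at a corner frequency (with spectral content
   extending below the analysis band, as real infra-slow fluctuations
   do) and ``s_fast`` is pink noise over the full analysis band. Larger
   ``a`` means more slow power and hence a longer autocorrelation
   window. The white-noise term scales the whole autocorrelation
   function toward zero, which shortens the half-maximum crossing but
   does not move the zero crossing, so the slow-weight contrast is
   expressed mostly in ACW-0 — the regime in which the long window is
   the more informative scale. The weight is composed of a
   network-level hierarchy ramp (periphery low, core high), a shared
   regional jitter (the spatial topography), a subject-level random
   effect drawn from a two-component Gaussian mixture (emulating two
   subject subpopulations), and multiplicative task modulation. Every
   realized weight is recorded as ground truth for recovery tests.

Pink noise is synthesized in the frequency domain: Gaussian spectral
coefficients are shaped so the expected power spectral density is 1/f
inside the pass band and zero outside, then inverse-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfftfreq

from .acw import ParcellatedRecording, TimeSeries, acf_matrix, _crossings_from_rows
from .parcellation import TEMPLATE_NETWORKS, validate_region_table

__all__ = [
    "DEFAULT_FS_HZ",
    "DEFAULT_FREQ_RANGE",
    "SIGNAL_CATEGORIES",
    "NETWORK_HIERARCHY",
    "SignalCategorySpec",
    "CohortSpec",
    "Cohort",
    "make_region_table",
    "simulate_signal",
    "simulate_signal_matrix",
    "simulate_catalogue",
    "generate_cohort",
    "mixture_cohort_spec",
]

#: Sampling rate of the emulated recordings (Hz).
DEFAULT_FS_HZ = 508.62
#: Analysis band of the emulated recordings (Hz).
DEFAULT_FREQ_RANGE = (1.3, 50.0)

SIGNAL_CATEGORIES = ("pink", "sine", "pink+sine", "pink+sine+white")

#: Networks ordered from periphery (sensory/motor) to core (transmodal);
#: the cohort generator places slow-weight means along this ramp.
NETWORK_HIERARCHY: dict[str, tuple[str, ...]] = {
    "schaefer": (
        "Visual",
        "Somatomotor",
        "Dorsal Attention",
        "Salience",
        "Limbic",
        "FPC",
        "DMN",
    ),
    "ji": (
        "Visual1",
        "Visual2",
        "Auditory",
        "Somatomotor",
        "Dorsal Attention",
        "Posterior Multimodal",
        "Ventral Multimodal",
        "Orbito Affective",
        "Language",
        "Cingulo Opercular",
        "FPC",
        "DMN",
    ),
}

# Region counts per network, in hierarchy order (sums: 200 and 360).
_NETWORK_SIZES: dict[str, tuple[int, ...]] = {
    "schaefer": (31, 37, 26, 23, 13, 26, 44),
    "ji": (12, 54, 15, 48, 23, 14, 6, 6, 23, 56, 50, 53),
}

# Posterior-to-anterior mean y (mm) per network, in hierarchy order.
_NETWORK_Y_MM: dict[str, tuple[float, ...]] = {
    "schaefer": (-75.0, -20.0, -40.0, 5.0, 10.0, 25.0, 0.0),
    "ji": (-80.0, -70.0, -25.0, -20.0, -40.0, -55.0, -30.0, 30.0, -10.0, 5.0, 25.0, 0.0),
}


def make_region_table(template: str, rng: np.random.Generator | int | None = 0) -> pd.DataFrame:
    """Synthetic region-metadata table for a template.

    Region counts per network follow realistic proportions (200 regions /
    7 networks for ``schaefer``, 360 / 12 for ``ji``); anterior-posterior
    coordinates are drawn per network around plausible means.
    """
    if template not in TEMPLATE_NETWORKS:
        raise ValueError(f"unknown template {template!r}")
    rng = np.random.default_rng(rng)
    rows = []
    for network, size, y_mean in zip(
        NETWORK_HIERARCHY[template], _NETWORK_SIZES[template], _NETWORK_Y_MM[template]
    ):
        y = rng.normal(y_mean, 12.0, size=size)
        for i in range(size):
            idx = len(rows) + 1
            rows.append(
                {
                    "region_id": f"{template[0].upper()}{idx:03d}",
                    "name": f"{network.replace(' ', '')}_{i + 1}",
                    "template": template,
                    "network": network,
                    "y_mm": round(float(y[i]), 2),
                }
            )
    return validate_region_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Elementary signal generators (vectorized over rows)
# ---------------------------------------------------------------------------


def _standardize(rows: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    return rows / np.where(sd > 0, sd, 1.0)


def _pink_rows(
    rng: np.random.Generator,
    n_rows: int,
    n: int,
    fs_hz: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Band-limited 1/f noise, one unit-variance realization per row."""
    freqs = rfftfreq(n, 1.0 / fs_hz)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"band {band} Hz contains no DFT frequency at n={n}, fs={fs_hz}")
    amplitude = np.zeros_like(freqs)
    amplitude[in_band] = 1.0 / np.sqrt(freqs[in_band])
    coeffs = rng.normal(size=(n_rows, freqs.size)) + 1j * rng.normal(size=(n_rows, freqs.size))
    rows = irfft(coeffs * amplitude, n=n, axis=1)
    return _standardize(rows)


def _sine_rows(
    rng: np.random.Generator,
    n_rows: int,
    n: int,
    fs_hz: float,
    freq_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance sines with frequency ~ U(freq_range), random phase."""
    freq = rng.uniform(freq_range[0], freq_range[1], size=n_rows)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_rows)
    t = np.arange(n) / fs_hz
    rows = np.sin(2.0 * np.pi * freq[:, None] * t[None, :] + phase[:, None])
    return _standardize(rows), freq


@dataclass(frozen=True)
class SignalCategorySpec:
    """Specification of one pseudo-aleatory signal draw."""

    category: str
    duration_s: float = 10.0
    fs_hz: float = DEFAULT_FS_HZ
    freq_range_hz: tuple[float, float] = DEFAULT_FREQ_RANGE
    rng_seed: int | None = 0

    def __post_init__(self) -> None:
        if self.category not in SIGNAL_CATEGORIES:
            raise ValueError(f"category must be one of {SIGNAL_CATEGORIES}")
        low, high = self.freq_range_hz
        if not 0 < low < high:
            raise ValueError(f"invalid frequency range {self.freq_range_hz}")
        # Require at least 3 cycles of the slowest component for a usable ACF.
        if self.duration_s * low < 3.0:
            raise ValueError(
                f"duration {self.duration_s} s too short for {low} Hz (< 3 cycles)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


def simulate_signal_matrix(
    category: str,
    n_signals: int,
    rng: np.random.Generator,
    *,
    duration_s: float = 10.0,
    fs_hz: float = DEFAULT_FS_HZ,
    freq_range_hz: tuple[float, float] = DEFAULT_FREQ_RANGE,
) -> np.ndarray:
    """``n_signals`` standardized signals of one category, one per row.

    Mixture categories draw independent U(0, 1) weights per component and
    per signal before linearly combining the unit-variance components.
    """
    spec = SignalCategorySpec(category, duration_s, fs_hz, freq_range_hz)
    n = spec.n_samples
    if category == "pink":
        rows = _pink_rows(rng, n_signals, n, fs_hz, freq_range_hz)
    elif category == "sine":
        rows, _ = _sine_rows(rng, n_signals, n, fs_hz, freq_range_hz)
    else:
        pink = _pink_rows(rng, n_signals, n, fs_hz, freq_range_hz)
        sine, _ = _sine_rows(rng, n_signals, n, fs_hz, freq_range_hz)
        w = rng.uniform(size=(n_signals, 2))
        rows = w[:, :1] * pink + w[:, 1:2] * sine
        if category == "pink+sine+white":
            white = _standardize(rng.normal(size=(n_signals, n)))
            rows = rows + rng.uniform(size=(n_signals, 1)) * white
    return _standardize(rows)


def simulate_signal(spec: SignalCategorySpec) -> TimeSeries:
    """One signal drawn according to ``spec`` (seeded from ``spec.rng_seed``)."""
    rng = np.random.default_rng(spec.rng_seed)
    row = simulate_signal_matrix(
        spec.category,
        1,
        rng,
        duration_s=spec.duration_s,
        fs_hz=spec.fs_hz,
        freq_range_hz=spec.freq_range_hz,
    )
    return TimeSeries(values=row[0], fs_hz=spec.fs_hz)


def simulate_catalogue(
    counts: Mapping[str, int] | None = None,
    *,
    duration_s: float = 10.0,
    fs_hz: float = DEFAULT_FS_HZ,
    freq_range_hz: tuple[float, float] = DEFAULT_FREQ_RANGE,
    rng_seed: int | None = 0,
    batch_size: int = 500,
) -> pd.DataFrame:
    """Simulate the signal catalogue and tabulate both ACW scales.

    By default 5000 signals per category (20,000 in total) are drawn.
    Returns one row per signal: ``category, acw50_ms, acw0_ms,
    acw50_found, acw0_found``. Signals are generated and analysed in
    batches to bound memory use.
    """
    if counts is None:
        counts = {category: 5000 for category in SIGNAL_CATEGORIES}
    unknown = set(counts) - set(SIGNAL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    if any(c < 1 for c in counts.values()):
        raise ValueError("category counts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    frames = []
    for category in SIGNAL_CATEGORIES:
        remaining = counts.get(category, 0)
        while remaining > 0:
            size = min(batch_size, remaining)
            rows = simulate_signal_matrix(
                category,
                size,
                rng,
                duration_s=duration_s,
                fs_hz=fs_hz,
                freq_range_hz=freq_range_hz,
            )
            coeffs = acf_matrix(rows, fs_hz)
            table = _crossings_from_rows(coeffs, fs_hz)
            table.insert(0, "category", category)
            frames.append(table.drop(columns="degenerate"))
            remaining -= size
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _default_task_factors() -> dict[tuple[str, str], float]:
    """Mild multiplicative task modulation of the slow weight.

    Keys are ``(condition, network)``; ``"*"`` matches any network.
    Values near 1 keep the rest topography dominant, so rest and task
    maps stay strongly correlated while each task leaves a distinct
    signature in specific networks.
    """
    return {
        ("StoryM", "*"): 0.94,
        ("StoryM", "Auditory"): 1.06,
        ("StoryM", "Language"): 1.08,
        ("StoryM", "DMN"): 1.02,
        ("Motort", "*"): 1.05,
        ("Motort", "Somatomotor"): 0.92,
        ("Wrkmem", "*"): 0.96,
        ("Wrkmem", "FPC"): 1.05,
        ("Wrkmem", "DMN"): 0.90,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for a synthetic rest/task cohort.

    The slow-fluctuation weight of a region in a given condition is

    ``a = clip(base + cp_effect * (ramp(network) - mean_ramp) + jitter(region)
    + subject_effect, 0.02, 0.98) * task_factor(condition, network)``

    where ``ramp`` spaces the template's networks evenly from 0
    (periphery end) to 1 (core end), ``jitter`` is a per-region normal
    draw shared by all subjects (the spatial topography), and the subject
    effect is drawn from a two-component Gaussian mixture: a fraction
    ``mixture_fraction`` of subjects is shifted upward by
    ``mixture_shift`` relative to the rest, each component having
    standard deviation ``subject_sd``. After task modulation the weight
    is clipped to [0.02, 0.98] again.
    """

    template: str = "schaefer"
    n_subjects: int = 12
    duration_s: float = 60.0
    conditions: tuple[str, ...] = ("Rest", "StoryM", "Motort", "Wrkmem")
    fs_hz: float = DEFAULT_FS_HZ
    freq_range_hz: tuple[float, float] = DEFAULT_FREQ_RANGE
    slow_floor_hz: float = 0.3
    slow_corner_hz: float = 8.0
    base_weight: float = 0.35
    cp_effect: float = 0.3
    region_jitter_sd: float = 0.05
    subject_sd: float = 0.03
    mixture_fraction: float = 0.5
    mixture_shift: float = 0.18
    slow_weight_by_network: Mapping[str, float] | None = None
    task_factors: Mapping[tuple[str, str], float] = field(
        default_factory=_default_task_factors
    )
    sine_amp_range: tuple[float, float] = (0.05, 0.15)
    sine_freq_range: tuple[float, float] = (8.0, 13.0)
    white_weight_range: tuple[float, float] = (0.25, 0.55)
    rng_seed: int | None = 0

    def __post_init__(self) -> None:
        if self.template not in TEMPLATE_NETWORKS:
            raise ValueError(f"unknown template {self.template!r}")
        if "Rest" not in self.conditions:
            raise ValueError("conditions must include Rest")
        unknown = set(self.conditions) - {"Rest", "StoryM", "Motort", "Wrkmem"}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if self.slow_weight_by_network is not None:
            bad = set(self.slow_weight_by_network) - set(TEMPLATE_NETWORKS[self.template])
            if bad:
                raise ValueError(
                    f"slow_weight_by_network names unknown networks: {sorted(bad)}"
                )
        all_networks = {n for nets in TEMPLATE_NETWORKS.values() for n in nets}
        for (_, network) in self.task_factors:
            # factors may span both templates; entries for networks absent
            # from this template are inert
            if network != "*" and network not in all_networks:
                raise ValueError(f"task_factors names unknown network {network!r}")

    def network_means(self) -> dict[str, float]:
        """Slow-weight mean per network (explicit map or hierarchy ramp)."""
        networks = NETWORK_HIERARCHY[self.template]
        if self.slow_weight_by_network is not None:
            return {n: float(self.slow_weight_by_network[n]) for n in networks}
        ramp = np.linspace(0.0, 1.0, len(networks))
        ramp -= ramp.mean()
        return {n: self.base_weight + self.cp_effect * r for n, r in zip(networks, ramp)}

    def task_factor(self, condition: str, network: str) -> float:
        if condition == "Rest":
            return 1.0
        specific = self.task_factors.get((condition, network))
        if specific is not None:
            return float(specific)
        return float(self.task_factors.get((condition, "*"), 1.0))


@dataclass
class Cohort:
    """Generated recordings plus the ground truth that produced them."""

    spec: CohortSpec
    region_table: pd.DataFrame
    subject_table: pd.DataFrame  # subject_id, subpopulation, subject_effect
    ground_truth: pd.DataFrame  # subject_id, region_id, condition, slow_weight
    recordings: list[ParcellatedRecording]

    def recording(self, subject_id: str, condition: str) -> ParcellatedRecording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.condition == condition:
                return rec
        raise KeyError(f"no recording for {subject_id}/{condition}")


def _clip_weight(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.02, 0.98)


def region_signals(
    weights: np.ndarray,
    rng: np.random.Generator,
    *,
    n_samples: int,
    fs_hz: float = DEFAULT_FS_HZ,
    freq_range_hz: tuple[float, float] = DEFAULT_FREQ_RANGE,
    slow_floor_hz: float = 0.3,
    slow_corner_hz: float = 8.0,
    sine_amp: float | np.ndarray = 0.1,
    sine_freq: np.ndarray | None = None,
    white_weight: float | np.ndarray = 0.4,
) -> np.ndarray:
    """Standardized signals for a vector of slow weights (one row each).

    ``a * s_slow + (1 - a) * s_fast + sine_amp * sine +
    white_weight * white`` with unit-variance components. ``sine_amp``
    and ``white_weight`` may vary per row (alpha-amplitude and
    noise-level topographies); ``sine_freq`` (Hz, per row) defaults to
    uniform draws from the 8-13 Hz resting alpha band. The white-noise
    term rescales the autocorrelation uniformly over positive lags, so
    it shortens the half-maximum crossing without moving the zero
    crossing.
    """
    weights = np.asarray(weights, dtype=float)[:, None]
    n_rows = weights.shape[0]
    slow = _pink_rows(rng, n_rows, n_samples, fs_hz, (slow_floor_hz, slow_corner_hz))
    fast = _pink_rows(rng, n_rows, n_samples, fs_hz, freq_range_hz)
    rows = weights * slow + (1.0 - weights) * fast
    amp = np.broadcast_to(np.asarray(sine_amp, dtype=float), (n_rows,))[:, None]
    if np.any(amp > 0):
        if sine_freq is None:
            sine_freq = rng.uniform(8.0, 13.0, size=n_rows)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_rows)
        t = np.arange(n_samples) / fs_hz
        sine = _standardize(
            np.sin(2.0 * np.pi * np.asarray(sine_freq)[:, None] * t[None, :] + phase[:, None])
        )
        rows = rows + amp * sine
    white = np.broadcast_to(np.asarray(white_weight, dtype=float), (n_rows,))[:, None]
    if np.any(white > 0):
        rows = rows + white * _standardize(rng.normal(size=(n_rows, n_samples)))
    return _standardize(rows)


def generate_cohort(
    spec: CohortSpec, region_table: pd.DataFrame | None = None
) -> Cohort:
    """Generate recordings for every (subject, condition) plus ground truth.

    All draws come from a single RNG stream seeded with
    ``spec.rng_seed``, in a fixed order, so equal specs give bit-identical
    cohorts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if region_table is None:
        region_table = make_region_table(spec.template, rng)
    else:
        validate_region_table(region_table)
        if set(region_table["template"]) != {spec.template}:
            raise ValueError("region table template does not match spec.template")
    n_regions = len(region_table)
    networks = region_table["network"].to_numpy()
    means = spec.network_means()
    base = np.array([means[n] for n in networks])
    jitter = rng.normal(0.0, spec.region_jitter_sd, size=n_regions)

    # Region-stable topographies drawn once per region and shared by all
    # subjects and conditions: a weak alpha oscillation, and a noise
    # level emulating the spatially varying SNR of source-reconstructed
    # recordings. The noise level gives the short timescale a
    # reproducible spatial map that is orthogonal to the core-periphery
    # gradient; it cannot move the zero crossing of the autocorrelation.
    sine_amp = rng.uniform(*spec.sine_amp_range, size=n_regions)
    sine_freq = rng.uniform(*spec.sine_freq_range, size=n_regions)
    white_weight = rng.uniform(*spec.white_weight_range, size=n_regions)

    subject_ids = [f"sub{j + 1:03d}" for j in range(spec.n_subjects)]
    subpop = rng.random(spec.n_subjects) < spec.mixture_fraction
    centre = np.where(subpop, spec.mixture_shift / 2.0, -spec.mixture_shift / 2.0)
    subject_effect = rng.normal(centre, spec.subject_sd)
    subject_table = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "subpopulation": np.where(subpop, "high", "low"),
            "subject_effect": subject_effect,
        }
    )

    n_samples = int(round(spec.duration_s * spec.fs_hz))
    recordings = []
    truth_rows = []
    region_ids = region_table["region_id"].tolist()
    for j, subject_id in enumerate(subject_ids):
        rest_weight = _clip_weight(base + jitter + subject_effect[j])
        for condition in spec.conditions:
            factor = np.array([spec.task_factor(condition, n) for n in networks])
            a = _clip_weight(rest_weight * factor)
            matrix = region_signals(
                a,
                rng,
                n_samples=n_samples,
                fs_hz=spec.fs_hz,
                freq_range_hz=spec.freq_range_hz,
                slow_floor_hz=spec.slow_floor_hz,
                slow_corner_hz=spec.slow_corner_hz,
                sine_amp=sine_amp,
                sine_freq=sine_freq,
                white_weight=white_weight,
            )
            recordings.append(
                ParcellatedRecording(
                    matrix=matrix,
                    region_ids=region_ids,
                    subject_id=subject_id,
                    condition=condition,
                    fs_hz=spec.fs_hz,
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "region_id": region_ids,
                        "condition": condition,
                        "slow_weight": a,
                    }
                )
            )
    ground_truth = pd.concat(truth_rows, ignore_index=True)
    cohort = Cohort(
        spec=spec,
        region_table=region_table,
        subject_table=subject_table,
        ground_truth=ground_truth,
        recordings=recordings,
    )
    return cohort


def mixture_cohort_spec(**overrides) -> CohortSpec:
    """Cohort preset in which the subject mixture dominates.

    A strong two-subpopulation subject effect (``mixture_shift`` 0.35)
    against a mild regional gradient, so the pooled per-(subject,
    region) ACW-0 distribution splits into two modes while the
    subject-averaged regional distribution stays unimodal. Used to study
    how inter-individual variability shapes the pooled density of the
    long timescale.
    """
    params = dict(
        template="ji",
        cp_effect=0.08,
        region_jitter_sd=0.05,
        subject_sd=0.04,
        mixture_fraction=0.5,
        mixture_shift=0.35,
    )
    params.update(overrides)
    return CohortSpec(**params)
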