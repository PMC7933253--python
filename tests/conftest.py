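"""Shared fixtures: synthetic cohorts and derived ACW tables.

The cohorts are the expensive fixtures; they are session-scoped and
generated once at the default effect structure. Sizes (subjects,
duration) are chosen to keep the suite fast while leaving the generator's
statistical regimes intact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neuroacw.pipeline import acw_long_table
from neuroacw.simulate import (
    CohortSpec,
    generate_cohort,
    mixture_cohort_spec,
    simulate_catalogue,
)


@pytest.fixture(scope="session")
def schaefer_cohort():
    """Default-structure rest+task cohort on the 200-region template."""
    spec = CohortSpec(template="schaefer", n_subjects=12, duration_s=60.0, rng_seed=42)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def schaefer_acw(schaefer_cohort):
    return acw_long_table(schaefer_cohort.recordings)


@pytest.fixture(scope="session")
def ji_rest_cohort():
    """Rest-only cohort on the 360-region template (JCP/RCP analyses)."""
    spec = CohortSpec(
        template="ji", n_subjects=6, duration_s=60.0, conditions=("Rest",), rng_seed=7
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def ji_rest_acw(ji_rest_cohort):
    return acw_long_table(ji_rest_cohort.recordings)


@pytest.fixture(scope="session")
def mixture_acw():
    """ACW table from the subject-mixture-dominated preset cohort."""
    spec = mixture_cohort_spec(
        n_subjects=8, duration_s=30.0, conditions=("Rest",), rng_seed=3
    )
    return acw_long_table(generate_cohort(spec).recordings)


@pytest.fixture(scope="session")
def default_catalogue():
    """The full four-category signal catalogue at default counts."""
    return simulate_catalogue(rng_seed=1)


def direct_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Brute-force biased sample ACF: independent oracle for the FFT path."""
    x = np.asarray(x, float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = float(xc[: x.size - k] @ xc[k:]) / denom
    return out
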