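import numpy as np
import pytest

from omipipe import (
    CohortConfig,
    EcgMorphParams,
    annotate_cohort,
    generate_cohort,
    synthesize_ecg,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort (shared, read-only)."""
    config = CohortConfig(n_patients=400, sampling_rate_hz=100.0, seed=20)
    return config, generate_cohort(config)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    _, cases = small_cohort
    return annotate_cohort(cases)


@pytest.fixture
def make_ecg():
    """Factory for single synthetic ECGs, noiseless by default."""

    def _make(
        st=None,
        heart_rate=60.0,
        sampling_rate_hz=500.0,
        noise_sd_mv=0.0,
        seed=0,
        morphology="normal",
        duration_s=10.0,
    ):
        params = EcgMorphParams(
            heart_rate=heart_rate,
            st_offset_mv=st or {},
            noise_sd_mv=noise_sd_mv,
            baseline_wander_amp_mv=0.0,
            morphology=morphology,
        )
        return synthesize_ecg(
            params,
            seed=seed,
            sampling_rate_hz=sampling_rate_hz,
            duration_s=duration_s,
        )

    return _make
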