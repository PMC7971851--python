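"""Shared fixtures: small seeded traces and a reduced synthetic cohort.

Everything is generated programmatically at collection/run time; sizes
are scaled so the full suite runs on one CPU in a few minutes.
"""

import numpy as np
import pytest

from mrcrit import (
    ActivityTrace,
    EstimationConfig,
    ScenarioSpec,
    simulate_stationary,
)

#: Reduced estimation settings used throughout the unit tests: shorter lag
#: range suited to m <= 0.95 at 4 ms bins, bootstrap off.
FAST_EST = EstimationConfig(k_max_bins=150, n_boot=0)


@pytest.fixture(scope="session")
def stationary_trace_m09() -> ActivityTrace:
    """120 s stationary branching run, m=0.9, h=1 (mean activity 10)."""
    return simulate_stationary(0.9, 1.0, 30000, seed=11)


@pytest.fixture(scope="session")
def stationary_trace_m095() -> ActivityTrace:
    """240 s stationary branching run, m=0.95, h=1 (mean activity 20)."""
    return simulate_stationary(0.95, 1.0, 60000, seed=12)


@pytest.fixture(scope="session")
def noise_trace() -> ActivityTrace:
    """iid Poisson counts: no temporal structure at all."""
    rng = np.random.default_rng(13)
    return ActivityTrace(rng.poisson(0.5, size=20000))


def reduced_cohort_spec(**overrides) -> ScenarioSpec:
    """A small cohort whose rate calibration stays inside the clinical
    band: alpha and drive traded off so alpha*h/(1-m) ~ 0.1 per bin."""
    params = dict(
        scenario="null",
        n_patients=3,
        recordings_per_patient=2,
        m_contra=0.9,
        alpha=0.05,
        drive_rate=0.2,
        duration=120.0,
        n_units=5,
        seed=20,
    )
    params.update(overrides)
    return ScenarioSpec(**params)


@pytest.fixture(scope="session")
def small_cohort():
    """Generated records + manifest for a 3-patient null cohort."""
    from mrcrit import generate_cohort

    spec = reduced_cohort_spec()
    records, manifest = generate_cohort(spec)
    return spec, records, manifest
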