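import numpy as np
import pandas as pd
import pytest

from gaitbrain.cohort import BrainSimSpec, CohortSpec, simulate_brain_maps


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A quick cohort: few subjects, short trials, noise-free steps."""
    return CohortSpec(
        n_young=3, n_old=2, n_steps_split=120, n_steps_baseline=60, step_noise_sd=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noisy_spec() -> CohortSpec:
    return CohortSpec(n_young=4, n_old=2, n_steps_split=150, n_steps_baseline=60, seed=5)


def random_covariates(n: int, rng: np.random.Generator, n_old: int | None = None) -> pd.DataFrame:
    n_old = n // 2 if n_old is None else n_old
    return pd.DataFrame(
        {
            "subject": [f"S{i:02d}" for i in range(n)],
            "group": ["young"] * (n - n_old) + ["old"] * n_old,
            "sex": rng.choice(["F", "M"], n),
            "tiv": rng.normal(1450.0, 100.0, n),
        }
    )


@pytest.fixture(scope="session")
def planted_stack():
    """Small cohort stack with a strong planted score effect."""
    rng = np.random.default_rng(42)
    cov = random_covariates(30, rng)
    scores = rng.normal(20.0, 15.0, 30)
    spec = BrainSimSpec(shape=(10, 10, 10), slope=0.3, noise_sd=1.0, noise_fwhm=2.0, seed=8)
    stack, truth = simulate_brain_maps(spec, scores, cov)
    table = cov.copy()
    table["sym_StepCoM"] = scores
    return stack, table, truth
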