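import numpy as np
import pytest

from bdscreen import ModelParams, synthetic_profile

# operating points printed for the screening tests (2-decimal text values)
DELTA_ACC = (0.87, 0.81)   # misdiagnosis-optimal cutoff 0.46
DELTA_COST = (0.76, 0.87)  # cost-optimal cutoff 0.56
MDQ_11 = (0.56, 0.92)      # MDQ at cutoff >= 11


@pytest.fixture
def base_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def delta_profile():
    """Synthetic stand-in for the screening algorithm's operating-point table."""
    return synthetic_profile(auc_target=0.92, prevalence=0.16, n=10_000, seed=7)


def random_valid_params(rng: np.random.Generator) -> ModelParams:
    """One random parameter draw inside the validated ranges."""
    c_rbp = rng.uniform(5_000, 30_000)
    return ModelParams.model_validate({
        "epi": {
            "plan_size": rng.uniform(1e5, 2e6),
            "mde_incidence": rng.uniform(0.01, 0.1),
            "help_seeking": rng.uniform(0.2, 1.0),
            "ubp_prevalence": rng.uniform(0.01, 0.5),
            "annual_correction": rng.uniform(0.0, 0.5),
            "attrition": rng.uniform(0.0, 0.4),
            "referral_prob": rng.uniform(0.0, 1.0),
            "psych_accuracy": rng.uniform(0.5, 1.0),
            "horizon": int(rng.integers(1, 11)),
        },
        "costs": {
            "c_mdd": rng.uniform(1_000, c_rbp),
            "c_rbp": c_rbp,
            "c_ubp": rng.uniform(c_rbp, 60_000),
            "c_screen": rng.uniform(0, 100),
            "c_eval": rng.uniform(0, 1_000),
            "discount": rng.uniform(0.0, 0.1),
        },
    })
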