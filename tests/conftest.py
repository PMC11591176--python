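import numpy as np
import pytest

from beatwise.synthetic import CohortConfig, EffectSpec, LEAD_NAMES

#: small, fast training settings shared by the recovery tests
FAST_MODEL = {"n_blocks": 3, "filters": (8, 16, 16), "kernels": (7, 5, 3),
              "pools": (4, 2, 2), "epochs": 6, "batch_size": 32}


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, jitter-free cohort config used by analytic checks."""
    return CohortConfig(noise_sd=0.0, baseline_wander_amp=0.0,
                        rr_jitter_sd_ms=0.0, heart_rate_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_record(clean_config):
    from beatwise.synthetic import simulate_record
    return simulate_record(clean_config, lvef=62.0, af=False,
                           rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def t_effect():
    """Strong reduced-class T-wave attenuation on all leads."""
    return EffectSpec("ST-T", LEAD_NAMES, amplitude_multiplier=0.4)


@pytest.fixture(scope="session")
def small_cohort(t_effect):
    from beatwise.synthetic import make_cohort
    cfg = CohortConfig(n_cases={"pEF": 30, "mrEF": 10, "rEF": 10},
                       effects=[t_effect], seed=11)
    return cfg, make_cohort(cfg)
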