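import numpy as np
import pytest

from esmnet.simulate import SimConfig, generate_cohort

K = 6


def null_sim_config(seed=0, n_pairs=15, n_days=2, beeps_per_day=10, **over):
    """Cohort with no dynamics (A = 0): every lagged coefficient is truly zero."""
    base = dict(
        n_pairs=n_pairs,
        n_sisters=0,
        n_days=n_days,
        beeps_per_day=beeps_per_day,
        transition_matrices={"base": np.zeros((K, K))},
        trauma_effect={"low": "base", "medium": "base", "high": "base"},
        item_intercepts=(4.0,) * K,
        residual_sd=(1.0,) * K,
        pair_intercept_sd=(0.4,) * K,
        time_slope_sd=0.0,
        p_invalid=0.0,
        seed=seed,
    )
    base.update(over)
    return SimConfig(**base)


def ar_sim_config(seed=0, n_pairs=100, diag=0.3, cross=(("relaxed", "cheerful", 0.2),), **over):
    """Continuous-output cohort with known autoregressive dynamics."""
    from esmnet.simulate import DEFAULT_ITEMS

    idx = {n: i for i, n in enumerate(DEFAULT_ITEMS)}
    a = np.eye(K) * diag
    for p, o, v in cross:
        a[idx[p], idx[o]] = v
    base = dict(
        n_pairs=n_pairs,
        n_sisters=0,
        likert_clip=False,
        p_invalid=0.0,
        transition_matrices={"base": a},
        trauma_effect={"low": "base", "medium": "base", "high": "base"},
        time_slope_sd=0.002,
        seed=seed,
    )
    base.update(over)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Discretized panel with defaults at small size (shared, read-only)."""
    cfg = SimConfig(n_pairs=20, n_sisters=4, seed=11)
    panel, meta = generate_cohort(cfg)
    return cfg, panel, meta


@pytest.fixture(scope="session")
def continuous_cohort():
    """Continuous-output AR cohort for model checks (shared, read-only)."""
    cfg = ar_sim_config(seed=21, n_pairs=40)
    panel, meta = generate_cohort(cfg)
    return cfg, panel, meta
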