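import numpy as np
import pandas as pd
import pytest

from hapticdyad.config import SimConfig
from hapticdyad.pipeline import population_outcomes
from hapticdyad.strategies import HapticNoiseModel, calibrate_haptic_noise

KAPPA_LEVELS = [np.log10(0.3), np.log10(1.7), np.log10(17.2)]


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def haptic_table(cfg):
    return calibrate_haptic_noise(cfg, seed=5)


@pytest.fixture(scope="session")
def haptic_model(haptic_table):
    return HapticNoiseModel(partner_visual_var=0.0,
                            stiffness_noise=haptic_table)


@pytest.fixture(scope="session")
def populations(cfg, haptic_model):
    """14-dyad synthetic populations per strategy, shared across tests."""
    return {strat: population_outcomes(strat, 14, 1, cfg=cfg,
                                       haptic_noise=haptic_model)
            for strat in ("neuromechanical", "goal_integration",
                          "follow_leader")}


def make_lme_dataset(beta, n_dyads=14, pairs_per_dyad=20, sigma_re=0.05,
                     sigma_eps=0.1, seed=0, effort_model=False):
    """Draw a dataset from the (known-coefficient) mixed model itself —
    the generative oracle for coefficient-recovery and calibration tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_dyads):
        u = rng.normal(0.0, sigma_re)
        for _ in range(pairs_per_dyad):
            dp = rng.uniform(-0.6, 0.6)
            k = rng.choice(KAPPA_LEVELS)
            if effort_model:
                y = beta[0] + beta[1] * dp + beta[2] * k + beta[3] * dp * k
            else:
                y = (beta[0] + beta[1] * dp + beta[2] * k + beta[3] * dp ** 2
                     + beta[4] * dp * k + beta[5] * dp ** 2 * k)
            y += u + rng.normal(0.0, sigma_eps)
            rows.append({"dyad": d, "delta_p": dp, "kappa": k,
                         "delta_c": y, "E": y})
    return pd.DataFrame(rows)
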