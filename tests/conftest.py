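import numpy as np
import pytest

import knockboost as kb


@pytest.fixture(scope="session")
def block_design():
    """n=5000 draw from the 10x10 AR(1) block covariance, p=50."""
    scen = kb.SimulationScenario(kind="lin_reg", n=5000, p=50)
    return kb.draw_design(scen, seed=42)


@pytest.fixture(scope="session")
def tiny_booster():
    """A small deterministic regression booster on a 6-column augmented design."""
    rng = np.random.default_rng(7)
    p = 3
    x = kb.DesignMatrix(rng.normal(size=(120, p)))
    knock = rng.normal(size=(120, p))
    cov = kb.estimate_covariance(x)
    kmod = kb.KnockoffModel(knock, kb.SVector(np.ones(p), "equi"), cov, seed=0)
    aug = kb.augment(x, kmod)
    y = 2 * x.values[:, 0] + x.values[:, 1] ** 2 + 0.1 * rng.normal(size=120)
    cfg = kb.default_config("regression")
    cfg.hyperparameters.update(
        {"num_leaves": 4, "max_depth": 2, "n_estimators": 6, "feature_fraction": 1.0, "min_data_in_leaf": 5}
    )
    model = kb.fit_booster(aug, y, cfg)
    return model, aug, y
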