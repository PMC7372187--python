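import numpy as np
import pytest

from refusion.fusion import FusionConfig
from refusion.synthetic import SimulationConfig, generate_multimodal


def bh_bruteforce(p, alpha):
    """Literal step-up enumeration: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            kmax = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:kmax]] = True
    return reject


def pearson_oracle(x, y):
    """Textbook Pearson formula, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with a clearly planted joint component."""
    cfg = SimulationConfig(
        n_patients=50,
        n_controls=50,
        features_per_modality=(120, 100, 80),
        rho_ref=0.5,
        group_effect_d=1.0,
        seed=42,
    )
    return generate_multimodal(cfg)


@pytest.fixture()
def small_fusion_config():
    return FusionConfig(n_components=5, lam=0.5, seed=42)
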