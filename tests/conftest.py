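import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import idcard as ic

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TOL = ic.ToleranceSpec()  # 0.05 min / 0.05 Da defaults


@pytest.fixture
def tol():
    return TOL


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def small_generator_config(**overrides) -> ic.GeneratorConfig:
    """Down-scaled corpus: same structure as the full study, ~1/10 the ions."""
    params = dict(
        n_origins=3,
        batches_per_origin=3,
        heldout_per_origin=2,
        common_panel_size=300,
        unique_panel_size=60,
        noise_ions_per_batch=120,
        blank_panel_size=400,
        blank_ions_per_sample=50,
        dropout_rate=0.05,
        detection_floor=5000.0,
        seed=20240517,
    )
    params.update(overrides)
    return ic.GeneratorConfig(**params)


@pytest.fixture(scope="session")
def small_corpus():
    return ic.generate_corpus(small_generator_config())


@pytest.fixture(scope="session")
def two_class_corpus():
    """Authentic-vs-adulterant corpus for adulteration-mode tests."""
    cfg = small_generator_config(
        n_origins=2,
        batches_per_origin=(4, 5),
        origin_labels=("authentic", "adulterant"),
        seed=99,
    )
    return ic.generate_corpus(cfg)


def brute_force_pairs(card_rt, card_mz, s_rt, s_mz, tol: ic.ToleranceSpec):
    """Independent oracle: literal double loop over card x sample ions.

    Uses the documented predicate |Δ| <= tol + 1e-9 (the guard is part of
    the matching definition, not of the join algorithm under test).
    """
    pairs = []
    for i in range(len(card_rt)):
        for j in range(len(s_rt)):
            if (
                abs(card_rt[i] - s_rt[j]) <= tol.delta_rt + 1e-9
                and abs(card_mz[i] - s_mz[j]) <= tol.delta_mz + 1e-9
            ):
                pairs.append((i, j))
    return pairs


def separated_ions(rng, n, lo_mz=100.0, hi_mz=1500.0, lo_rt=1.0, hi_rt=26.0, spacing=0.2):
    """Random ions pairwise separated by > spacing in m/z (never self-matching)."""
    mz = np.sort(rng.choice(np.arange(lo_mz, hi_mz, spacing), size=n, replace=False))
    mz = mz + rng.uniform(0, 0.02, n)
    rt = rng.uniform(lo_rt, hi_rt, n)
    intensity = np.exp(rng.normal(10, 1.5, n))
    return rt, mz, intensity
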