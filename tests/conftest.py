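import numpy as np
import pytest

import tripletlstm as tl

RULE = {"R01": "train", "R02": "train", "R03": "val", "R04": "test"}


@pytest.fixture(scope="session")
def small_dataset():
    """2000-sample easy-condition synthetic dataset (session-cached)."""
    cfg = tl.easy_config(n_samples=2000, seed=11)
    return cfg, tl.generate(cfg)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    cfg, samples = small_dataset
    return tl.split_by_region(samples, RULE, class_count=cfg.n_classes)


@pytest.fixture(scope="session")
def small_arrays(small_split):
    X, y, r = tl.stack_series(small_split.train)
    Xv, yv, _ = tl.stack_series(small_split.validation)
    return X, y, r, Xv, yv


@pytest.fixture(scope="session")
def degeneracy_dataset():
    """2000 standardized samples as flat arrays for trainer-equivalence runs."""
    cfg = tl.easy_config(n_samples=2000, seed=42)
    std = [tl.standardize(s) for s in tl.generate(cfg)]
    X, y, _ = tl.stack_series(std)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tiny_samples(n_per_cell=3, n_classes=3, n_regions=2, T=12, B=4, seed=0):
    """Fully balanced miniature dataset for constraint/partition tests."""
    rng = np.random.default_rng(seed)
    out = []
    uid = 0
    for r in range(n_regions):
        for c in range(n_classes):
            for _ in range(n_per_cell):
                series = np.abs(rng.normal(0.2, 0.05, size=(T, B)))
                out.append(
                    tl.TimeSeriesSample(
                        parcel_id=f"t{uid:04d}",
                        region=f"R{r + 1:02d}",
                        label=c,
                        series=series,
                    )
                )
                uid += 1
    return out
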