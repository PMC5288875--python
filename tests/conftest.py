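import numpy as np
import pytest

from masterreg import ExpressionDataset


def make_dataset(values, n_tf, r1, r2, case_label="case"):
    """Build a labeled dataset from a raw matrix: first n_tf rows are TFs,
    first r1 columns are cases."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    assert n_samp == r1 + r2
    return ExpressionDataset(
        values=values,
        feature_ids=np.array(
            [f"TF{i + 1:02d}" for i in range(n_tf)]
            + [f"G{i + 1:03d}" for i in range(n_feat - n_tf)],
            dtype=object,
        ),
        sample_ids=np.array([f"s{i + 1:03d}" for i in range(n_samp)], dtype=object),
        group=np.array(["case"] * r1 + ["control"] * r2, dtype=object),
        is_tf=np.array([True] * n_tf + [False] * (n_feat - n_tf)),
        case_label=case_label,
    )


@pytest.fixture
def small_random_dataset():
    """3 TFs, 5 genes, 10 + 10 samples; fixed seed."""
    rng = np.random.default_rng(12345)
    return make_dataset(rng.normal(size=(8, 20)), n_tf=3, r1=10, r2=10)


@pytest.fixture
def medium_random_dataset():
    """4 TFs, 8 genes, 15 + 12 samples with correlated structure."""
    rng = np.random.default_rng(777)
    base = rng.normal(size=27)
    vals = 0.5 * base + rng.normal(size=(12, 27))
    return make_dataset(vals, n_tf=4, r1=15, r2=12)
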