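"""Unit tests for the connectivity and concordance statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from masterreg import (
    ConnectivityProfile,
    ValidationError,
    ZeroVarianceWarning,
    connectivity_profile,
    differential_connectivity,
    kendall_concordance,
    master_statistic,
    tf_correlation_matrix,
)
from .conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_differential_connectivity(data):
    """Per-pair scipy.stats.pearsonr double loop."""
    case, ctl = data.case_indices, data.control_indices
    tfs = data.values[data.is_tf]
    genes = data.values[~data.is_tf]
    out = []
    for i in range(tfs.shape[0]):
        acc = 0.0
        for g in range(genes.shape[0]):
            r_case = stats.pearsonr(tfs[i, case], genes[g, case]).statistic
            r_ctl = stats.pearsonr(tfs[i, ctl], genes[g, ctl]).statistic
            acc += abs(r_case - r_ctl)
        out.append(acc / genes.shape[0])
    return np.array(out)


def naive_kendall(x, y_j):
    """Explicit O(M^2) pair enumeration with the ties-count-zero rule."""
    m = len(x)
    n_c = n_d = 0
    for i in range(m):
        for k in range(i + 1, m):
            prod = (x[i] - x[k]) * (y_j[i] - y_j[k])
            if prod > 0:
                n_c += 1
            elif prod < 0:
                n_d += 1
    return (n_c - n_d) / (m * (m - 1) / 2)


# ---------------------------------------------------------------------------
# Differential connectivity x
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_connectivity_exactly():
    """Duplicating the same columns into both groups makes every within-group
    correlation identical, so x must be the machine-exact zero vector."""
    rng = np.random.default_rng(0)
    half = rng.normal(size=(6, 8))
    data = make_dataset(np.hstack([half, half]), n_tf=2, r1=8, r2=8)
    x = differential_connectivity(data)
    assert np.all(x == 0.0)


def test_perfect_correlation_flip_gives_unit_connectivity():
    """One gene tracks the TF exactly in both groups (|1-1| = 0); a second
    is anti-correlated in cases and correlated in controls (|-1-1| = 2);
    the mean is exactly 1.  Two identical TF rows keep M >= 2."""
    t = np.array([1.0, 2, 3, 1, 2, 3])
    vals = np.vstack([t, t, t, np.concatenate([-t[:3], t[3:]])])
    data = make_dataset(vals, n_tf=2, r1=3, r2=3)
    x = differential_connectivity(data)
    assert x == pytest.approx([1.0, 1.0], abs=1e-12)


def test_differential_connectivity_matches_pearsonr_oracle(small_random_dataset):
    x = differential_connectivity(small_random_dataset)
    expected = naive_differential_connectivity(small_random_dataset)
    assert x == pytest.approx(expected, abs=1e-12)
    assert np.all((x >= 0) & (x <= 2))


def test_gene_order_permutation_leaves_x_unchanged(small_random_dataset):
    data = small_random_dataset
    rng = np.random.default_rng(1)
    perm = rng.permutation(data.n_gene)
    vals = data.values.copy()
    gene_rows = np.flatnonzero(~data.is_tf)
    vals[gene_rows] = vals[gene_rows[perm]]
    permuted = make_dataset(vals, n_tf=data.n_tf, r1=data.r1, r2=data.r2)
    assert differential_connectivity(permuted) == pytest.approx(
        differential_connectivity(data), abs=1e-12
    )


def test_tf_order_permutation_is_equivariant(medium_random_dataset):
    data = medium_random_dataset
    perm = np.array([2, 0, 3, 1])
    vals = data.values.copy()
    vals[: data.n_tf] = vals[perm]
    permuted = make_dataset(vals, n_tf=data.n_tf, r1=data.r1, r2=data.r2)
    x, y = differential_connectivity(data), tf_correlation_matrix(data)
    xp, yp = differential_connectivity(permuted), tf_correlation_matrix(permuted)
    assert xp == pytest.approx(x[perm], abs=1e-12)
    assert yp == pytest.approx(y[np.ix_(perm, perm)], abs=1e-12)
    kp = master_statistic(connectivity_profile(permuted)).k_per_tf
    k = master_statistic(connectivity_profile(data)).k_per_tf
    assert kp == pytest.approx(k[perm], abs=1e-12)


def test_small_groups_rejected():
    rng = np.random.default_rng(3)
    data = make_dataset(rng.normal(size=(4, 5)), n_tf=2, r1=2, r2=3)
    with pytest.raises(ValidationError, match="3 samples"):
        differential_connectivity(data)


def test_constant_feature_warns_and_scores_zero():
    rng = np.random.default_rng(4)
    vals = rng.normal(size=(5, 12))
    vals[4] = 7.0  # constant gene in both groups
    data = make_dataset(vals, n_tf=2, r1=6, r2=6)
    with pytest.warns(ZeroVarianceWarning, match="G003"):
        x = differential_connectivity(data)
    assert np.all(np.isfinite(x))


def test_pluggable_score_function(small_random_dataset):
    """A custom connectivity score replaces Pearson without API change."""
    def spearman_cross(a, b):
        ra = np.apply_along_axis(stats.rankdata, 1, a)
        rb = np.apply_along_axis(stats.rankdata, 1, b)
        return np.corrcoef(np.vstack([ra, rb]))[: a.shape[0], a.shape[0]:]

    x = differential_connectivity(small_random_dataset, score=spearman_cross)
    assert x.shape == (3,)
    assert np.all((x >= 0) & (x <= 2))


# ---------------------------------------------------------------------------
# Pooled TF correlation matrix y
# ---------------------------------------------------------------------------

def test_affine_and_negated_tfs_have_unit_correlation():
    rng = np.random.default_rng(5)
    base = rng.normal(size=14)
    vals = np.vstack([base, 2 * base + 5, -base, rng.normal(size=14)])
    data = make_dataset(vals, n_tf=3, r1=7, r2=7)
    y = tf_correlation_matrix(data)
    assert y[0, 1] == pytest.approx(1.0, abs=1e-12)   # affine increasing
    assert y[0, 2] == pytest.approx(1.0, abs=1e-12)   # sign flip, abs taken
    assert np.allclose(y, y.T) and np.all(np.diag(y) == 1.0)
    assert np.all((y >= 0) & (y <= 1))


def test_tf_matrix_matches_pearsonr_oracle_and_pools_groups(medium_random_dataset):
    data = medium_random_dataset
    y = tf_correlation_matrix(data)
    tfs = data.values[data.is_tf]
    for j in range(4):
        for k in range(4):
            expected = abs(stats.pearsonr(tfs[j], tfs[k]).statistic) if j != k else 1.0
            assert y[j, k] == pytest.approx(expected, abs=1e-12)
    # pooling matters: computing within one group must differ for this data
    case_only = make_dataset(
        data.values[:, data.case_indices][:, : data.r1],
        n_tf=4, r1=8, r2=7,
    )
    assert not np.allclose(tf_correlation_matrix(case_only), y)


# ---------------------------------------------------------------------------
# Kendall tau-a concordance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y_j, expected",
    [
        ((3, 2, 1), (1, 0.9, 0.5), 1.0),     # all 3 pairs concordant
        ((1, 2, 3), (1, 0.9, 0.5), -1.0),    # all 3 pairs discordant
        ((1, 2, 2, 4), (0.1, 0.5, 0.5, 0.2), None),  # ties -> oracle
    ],
)
def test_kendall_concordance_examples(x, y_j, expected):
    k = kendall_concordance(x, y_j)
    if expected is None:
        expected = naive_kendall(x, y_j)
    assert k == expected
    assert k == naive_kendall(x, y_j)


def test_kendall_matches_pair_enumeration_with_ties():
    """Exact agreement with the O(M^2) oracle on random tie-rich instances."""
    rng = np.random.default_rng(20)
    for _ in range(25):
        m = int(rng.integers(2, 12))
        x = rng.integers(0, 4, size=m).astype(float)   # heavy ties
        y = np.round(rng.uniform(0, 1, size=m), 1)
        assert kendall_concordance(x, y) == naive_kendall(x, y)


def test_kendall_agrees_with_scipy_when_tie_free():
    """Without ties tau-a equals scipy's tau-b: an independent cross-check."""
    rng = np.random.default_rng(21)
    for _ in range(10):
        x = rng.permutation(8).astype(float)
        y = rng.permutation(8).astype(float)
        assert kendall_concordance(x, y) == pytest.approx(
            stats.kendalltau(x, y).statistic, abs=1e-12
        )


def test_kendall_input_validation():
    with pytest.raises(ValidationError):
        kendall_concordance([1.0, 2.0], [1.0])
    with pytest.raises(ValidationError):
        kendall_concordance([1.0], [1.0])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(-50, 50), min_size=3, max_size=10, unique=True),
       st.sampled_from([lambda v: 3 * v + 1, np.exp, np.arctan]))
def test_kendall_invariant_under_increasing_transforms(xs, f):
    """A rank statistic: strictly increasing maps of x (or of y) leave it fixed."""
    x = np.array(xs, dtype=float)
    rng = np.random.default_rng(99)
    y = rng.uniform(0, 1, size=len(x))
    base = kendall_concordance(x, y)
    assert kendall_concordance(f(x), y) == base
    assert kendall_concordance(x, f(y)) == base


# ---------------------------------------------------------------------------
# Max statistic and master set
# ---------------------------------------------------------------------------

def test_two_tf_case_exhaustively():
    """M = 2: each K_j is a single pair including the unit self-correlation."""
    profile = ConnectivityProfile(
        x=np.array([2.0, 1.0]),
        y=np.array([[1.0, 0.5], [0.5, 1.0]]),
        tf_ids=np.array(["TF01", "TF02"], dtype=object),
    )
    res = master_statistic(profile)
    assert res.k_per_tf == pytest.approx([1.0, -1.0])
    assert res.k_max == 1.0
    assert res.master_set == ["TF01"]


def test_duplicated_tf_rows_tie_in_master_set():
    rng = np.random.default_rng(8)
    vals = rng.normal(size=(6, 16))
    vals[1] = vals[0]  # two identical TFs
    data = make_dataset(vals, n_tf=3, r1=8, r2=8)
    res = master_statistic(connectivity_profile(data))
    assert res.k_per_tf[0] == res.k_per_tf[1]
    if res.k_per_tf[0] == res.k_max:
        assert {"TF01", "TF02"} <= set(res.master_set)


def test_k_max_is_exact_max_and_master_set_tight(medium_random_dataset):
    res = master_statistic(connectivity_profile(medium_random_dataset))
    assert res.k_max == res.k_per_tf.max()
    in_set = np.isin(res.tf_ids, res.master_set)
    assert np.all(np.abs(res.k_per_tf[in_set] - res.k_max) <= 1e-10)
    assert np.all(np.abs(res.k_per_tf[~in_set] - res.k_max) > 1e-10)
    assert np.all((res.k_per_tf >= -1) & (res.k_per_tf <= 1))


def test_master_statistic_equals_per_row_kendall(medium_random_dataset):
    prof = connectivity_profile(medium_random_dataset)
    res = master_statistic(prof)
    for j in range(len(prof.x)):
        assert res.k_per_tf[j] == naive_kendall(prof.x, prof.y[j])
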