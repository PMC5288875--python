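"""Core statistics of the master-regulator test.

Two rankings of the M candidate transcription factors are compared:

* differential connectivity ``x_i`` — the mean absolute difference, over the
  N non-TF genes, between TF_i's Pearson correlation with each gene in the
  case group and in the control group;
* hierarchy position ``y_ji`` — the absolute Pearson correlation between
  TF_i and candidate master TF_j, computed on case and control samples
  pooled.

For each candidate j a Kendall tau-a concordance ``K_j`` between ``x`` and
row j of ``y`` is computed over all M(M-1)/2 unordered index pairs; the test
statistic is ``K = max_j K_j`` and the identified master set is
``argmax_j K_j`` (ties reported together).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .dataset import ExpressionDataset, ValidationError, ZeroVarianceWarning

#: callable mapping two row-matrices (features x samples within one group) to
#: a cross-association matrix; the built-in default is Pearson correlation
ScoreFunction = Callable[[np.ndarray, np.ndarray], np.ndarray]

TIE_TOLERANCE = 1e-10
MIN_GROUP_SAMPLES = 3  # Pearson needs >= 2; with exactly 2 every r is +/-1


@dataclass
class ConnectivityProfile:
    """Differential connectivity vector and pooled TF-TF correlation matrix.

    ``x[i]`` is the mean absolute case-vs-control difference of TF_i's
    correlations with the genes (each entry in [0, 2]); ``y`` is the M x M
    matrix of absolute pooled Pearson correlations among TFs, with unit
    diagonal.
    """

    x: np.ndarray
    y: np.ndarray
    tf_ids: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        m = self.x.shape[0]
        if self.y.shape != (m, m):
            raise ValidationError("y must be square and aligned with x")
        if len(self.tf_ids) != m:
            raise ValidationError("tf_ids must be aligned with x")


@dataclass
class MasterRegulatorResult:
    """Per-TF concordance statistics and the max-statistic identification.

    ``p_value`` stays ``None`` until bootstrap inference is run.
    """

    k_per_tf: np.ndarray
    k_max: float
    master_set: list
    tf_ids: np.ndarray
    p_value: float | None = None
    n_bootstrap: int | None = None
    bootstrap_stats: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "k_per_tf": {str(t): float(k) for t, k in zip(self.tf_ids, self.k_per_tf)},
            "k_max": float(self.k_max),
            "master_set": [str(t) for t in self.master_set],
            "p_value": None if self.p_value is None else float(self.p_value),
            "n_bootstrap": self.n_bootstrap,
        }


# ---------------------------------------------------------------------------
# Low-level kernels (shared with the bootstrap hot path)
# ---------------------------------------------------------------------------

def _standardize_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit Euclidean norm.

    Constant rows (zero variance) are mapped to zero rows, so any dot
    product with them — i.e. their Pearson correlation — is 0.
    Returns the standardized matrix and the boolean mask of constant rows.
    """
    centered = a - a.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    zero = norms == 0.0
    if zero.any():
        norms = norms.copy()
        norms[zero] = 1.0
    return centered / norms[:, None], zero


def _warn_zero_variance(ids: np.ndarray, zero: np.ndarray, context: str) -> None:
    if zero.any():
        names = ", ".join(str(i) for i in ids[zero][:10])
        warnings.warn(
            f"constant feature(s) in {context}: {names}; correlations set to 0",
            ZeroVarianceWarning,
            stacklevel=3,
        )


def _pearson_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of ``b``."""
    za, _ = _standardize_rows(a)
    zb, _ = _standardize_rows(b)
    return np.clip(za @ zb.T, -1.0, 1.0)


def _kendall_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Tau-a concordance of ``x`` with every row of ``y`` at once.

    Returns the length-M vector K_j = (n_c,j - n_d,j) / (M(M-1)/2), where a
    pair (i, k) is concordant for row j when (x_i - x_k)(y_ji - y_jk) > 0,
    discordant when < 0, and ties count toward neither.
    """
    m = x.shape[0]
    iu, ik = np.triu_indices(m, k=1)
    sx = np.sign(x[iu] - x[ik])                  # (n0,)
    sy = np.sign(y[:, iu] - y[:, ik])            # (M, n0)
    return (sy * sx).sum(axis=1) / (m * (m - 1) / 2.0)


def _max_concordance(
    values: np.ndarray,
    is_tf: np.ndarray,
    case_idx: np.ndarray,
    ctl_idx: np.ndarray,
) -> np.ndarray:
    """k_per_tf for an arbitrary column split; the bootstrap hot path.

    Recomputes both x (within-group TF-gene correlations) and y (pooled
    TF-TF correlations) from the given columns.
    """
    tf_vals = values[is_tf]
    gene_vals = values[~is_tf]
    c_case = _pearson_cross(tf_vals[:, case_idx], gene_vals[:, case_idx])
    c_ctl = _pearson_cross(tf_vals[:, ctl_idx], gene_vals[:, ctl_idx])
    x = np.abs(c_case - c_ctl).mean(axis=1)
    pooled = tf_vals[:, np.concatenate([case_idx, ctl_idx])]
    z, _ = _standardize_rows(pooled)
    y = np.abs(np.clip(z @ z.T, -1.0, 1.0))
    np.fill_diagonal(y, 1.0)
    return _kendall_rows(x, y)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def differential_connectivity(
    data: ExpressionDataset,
    score: ScoreFunction | None = None,
) -> np.ndarray:
    """Mean absolute case-vs-control difference of TF-gene connectivity.

    For each TF_i, ``x_i = (1/N) * sum_g |r(TF_i, g | case) - r(TF_i, g |
    control)|`` over the N non-TF genes, with r the within-group Pearson
    correlation (or a user-supplied connectivity ``score`` with the same
    signature).  Each x_i lies in [0, 2].

    Raises if either group has fewer than 3 samples: with 2 samples every
    Pearson correlation is degenerately +/-1.
    """
    data.require_complete()
    if data.r1 < MIN_GROUP_SAMPLES or data.r2 < MIN_GROUP_SAMPLES:
        raise ValidationError(
            f"each group needs >= {MIN_GROUP_SAMPLES} samples for meaningful "
            f"correlations (got r1={data.r1}, r2={data.r2})"
        )
    tf_vals = data.values[data.is_tf]
    gene_vals = data.values[~data.is_tf]
    case, ctl = data.case_indices, data.control_indices

    if data.has_missing and score is None:
        c_case = _pairwise_complete_cross(tf_vals[:, case], gene_vals[:, case])
        c_ctl = _pairwise_complete_cross(tf_vals[:, ctl], gene_vals[:, ctl])
        return np.abs(c_case - c_ctl).mean(axis=1)

    if score is None:
        for idx, label in ((case, "case group"), (ctl, "control group")):
            _, zero_tf = _standardize_rows(tf_vals[:, idx])
            _, zero_g = _standardize_rows(gene_vals[:, idx])
            _warn_zero_variance(data.tf_ids, zero_tf, label)
            _warn_zero_variance(data.gene_ids, zero_g, label)
        score = _pearson_cross
    c_case = np.asarray(score(tf_vals[:, case], gene_vals[:, case]), dtype=float)
    c_ctl = np.asarray(score(tf_vals[:, ctl], gene_vals[:, ctl]), dtype=float)
    return np.abs(c_case - c_ctl).mean(axis=1)


def tf_correlation_matrix(data: ExpressionDataset) -> np.ndarray:
    """Absolute Pearson correlations among TFs over all samples pooled.

    Case and control columns are pooled deliberately: the resulting matrix
    encodes the overall regulatory hierarchy among the TFs, not a
    group-specific one.  Diagonal is exactly 1.
    """
    data.require_complete()
    if data.n_samples < 3:
        raise ValidationError("need at least 3 pooled samples")
    tf_vals = data.values[data.is_tf]
    if data.has_missing:
        y = np.abs(_pairwise_complete_cross(tf_vals, tf_vals))
    else:
        z, zero = _standardize_rows(tf_vals)
        _warn_zero_variance(data.tf_ids, zero, "pooled samples")
        y = np.abs(np.clip(z @ z.T, -1.0, 1.0))
    np.fill_diagonal(y, 1.0)
    return y


def connectivity_profile(
    data: ExpressionDataset,
    score: ScoreFunction | None = None,
) -> ConnectivityProfile:
    """Convenience wrapper computing both x and y for a dataset."""
    return ConnectivityProfile(
        x=differential_connectivity(data, score=score),
        y=tf_correlation_matrix(data),
        tf_ids=data.tf_ids,
    )


def kendall_concordance(x: Sequence[float], y_j: Sequence[float]) -> float:
    """Kendall tau-a between ``x`` and one candidate's correlation row.

    The denominator is fixed at n0 = M(M-1)/2 and ties contribute to neither
    the concordant nor the discordant count, so ties shrink |K_j| rather than
    rescaling it.  The pair involving the candidate's own unit self-
    correlation is included like any other element.
    """
    x = np.asarray(x, dtype=float)
    y_j = np.asarray(y_j, dtype=float)
    if x.ndim != 1 or y_j.ndim != 1 or x.shape != y_j.shape:
        raise ValidationError("x and y_j must be 1-D vectors of equal length")
    m = x.shape[0]
    if m < 2:
        raise ValidationError("need at least 2 transcription factors")
    iu, ik = np.triu_indices(m, k=1)
    prod = np.sign(x[iu] - x[ik]) * np.sign(y_j[iu] - y_j[ik])
    n_c = int((prod > 0).sum())
    n_d = int((prod < 0).sum())
    return (n_c - n_d) / (m * (m - 1) / 2.0)


def master_statistic(
    profile: ConnectivityProfile,
    tie_tolerance: float = TIE_TOLERANCE,
) -> MasterRegulatorResult:
    """Max concordance K = max_j K_j and the attaining TF set.

    Every K_j is a rational with denominator M(M-1)/2, so exact ties are
    expected; ``tie_tolerance`` only guards against float noise.
    """
    if profile.x.shape[0] < 2:
        raise ValidationError("need at least 2 transcription factors")
    k = _kendall_rows(profile.x, profile.y)
    k_max = float(k.max())
    tied = np.abs(k - k_max) <= tie_tolerance
    return MasterRegulatorResult(
        k_per_tf=k,
        k_max=k_max,
        master_set=[str(t) for t in np.asarray(profile.tf_ids)[tied]],
        tf_ids=np.asarray(profile.tf_ids),
    )


def run_test_statistic(data: ExpressionDataset) -> MasterRegulatorResult:
    """Full observed statistic: profile + K_j's + max, no inference."""
    return master_statistic(connectivity_profile(data))


# ---------------------------------------------------------------------------
# Pairwise-complete path for data with missing values (opt-in at load time)
# ---------------------------------------------------------------------------

def _pairwise_complete_cross(
    a: np.ndarray, b: np.ndarray, min_overlap: int = 3
) -> np.ndarray:
    """Pearson correlations using pairwise-complete observations.

    Pairs with fewer than ``min_overlap`` jointly observed samples, or with
    zero variance on the overlap, get correlation 0 (with a warning).
    """
    import pandas as pd

    na, nb = a.shape[0], b.shape[0]
    stacked = pd.DataFrame(np.vstack([a, b]).T)
    corr = stacked.corr(min_periods=min_overlap).to_numpy()[:na, na:]
    bad = ~np.isfinite(corr)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} feature pair(s) with insufficient overlap or "
            "zero variance; correlations set to 0",
            ZeroVarianceWarning,
            stacklevel=3,
        )
        corr = np.where(bad, 0.0, corr)
    return np.clip(corr, -1.0, 1.0)
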