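"""Bootstrap significance of the max-concordance statistic.

The sampling distribution of K under the no-master-regulator null is not
tractable, so significance is assessed by resampling: columns are drawn from
the pooled case+control sample (ignoring the labels), the first r1 draws are
relabeled "case" and the rest "control", and the entire statistic — the
differential-connectivity vector, the pooled TF-TF correlation matrix and
the per-TF concordances — is recomputed on each replicate.  The p-value is
the fraction of replicates whose K_b strictly exceeds the observed K.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed

from .core import MasterRegulatorResult, _max_concordance, run_test_statistic
from .dataset import ExpressionDataset, ValidationError


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the resampling null.

    ``n_bootstrap`` is B; ``seed`` spawns one independent RNG substream per
    replicate, so the result is bit-identical for any ``n_workers``.
    ``method`` is ``"bootstrap"`` (columns drawn with replacement, the
    default) or ``"permutation"`` (a label shuffle without replacement, for
    sensitivity analysis).  ``corrected`` switches the p-value to the
    add-one form (1 + #exceedances) / (1 + B), which avoids exact zeros.
    """

    n_bootstrap: int = 500
    seed: int = 0
    n_workers: int = 1
    retain_distribution: bool = False
    method: str = "bootstrap"
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        if self.method not in ("bootstrap", "permutation"):
            raise ValidationError("method must be 'bootstrap' or 'permutation'")
        if self.n_workers < 1:
            raise ValidationError("n_workers must be >= 1")


def _replicate_stats(
    values: np.ndarray,
    is_tf: np.ndarray,
    r1: int,
    n: int,
    seeds,
    with_replacement: bool,
) -> np.ndarray:
    """Max statistic K_b for a batch of replicates (one RNG stream each)."""
    out = np.empty(len(seeds))
    for b, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if with_replacement:
            idx = rng.integers(0, n, size=n)
        else:
            idx = rng.permutation(n)
        out[b] = _max_concordance(values, is_tf, idx[:r1], idx[r1:]).max()
    return out


def bootstrap_distribution(
    data: ExpressionDataset, config: BootstrapConfig
) -> np.ndarray:
    """The B resampled max statistics K_b, in replicate order."""
    data.require_complete()
    if data.has_missing:
        raise ValidationError(
            "bootstrap inference requires a complete matrix; "
            "impute or drop features with missing values first"
        )
    n, r1 = data.n_samples, data.r1
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_bootstrap)
    with_repl = config.method == "bootstrap"
    if config.n_workers == 1:
        return _replicate_stats(data.values, data.is_tf, r1, n, seeds, with_repl)
    chunks = np.array_split(np.arange(config.n_bootstrap), config.n_workers)
    parts = Parallel(n_jobs=config.n_workers)(
        delayed(_replicate_stats)(
            data.values, data.is_tf, r1, n, [seeds[i] for i in chunk], with_repl
        )
        for chunk in chunks
        if len(chunk)
    )
    return np.concatenate(parts)


def pvalue_from_distribution(
    k_stats: np.ndarray, k_observed: float, corrected: bool = False
) -> float:
    """Eq.-style exceedance p-value: #{K_b > K} / B, strict inequality."""
    exceed = int((np.asarray(k_stats) > k_observed).sum())
    b = len(k_stats)
    if corrected:
        return (1 + exceed) / (1 + b)
    return exceed / b


def bootstrap_pvalue(
    data: ExpressionDataset,
    observed: MasterRegulatorResult | None = None,
    config: BootstrapConfig = BootstrapConfig(),
) -> MasterRegulatorResult:
    """Attach the bootstrap p-value to an observed max-concordance result.

    ``observed`` must have been computed on ``data`` (it is computed here
    when omitted).  Returns a new result with ``p_value`` (a multiple of
    1/B unless ``corrected``), ``n_bootstrap``, and — when
    ``config.retain_distribution`` — the full vector of K_b values.
    """
    if observed is None:
        observed = run_test_statistic(data)
    k_stats = bootstrap_distribution(data, config)
    p = pvalue_from_distribution(k_stats, observed.k_max, config.corrected)
    return replace(
        observed,
        p_value=p,
        n_bootstrap=config.n_bootstrap,
        bootstrap_stats=k_stats if config.retain_distribution else None,
    )
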