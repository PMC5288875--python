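"""Monte-Carlo drivers: empirical size, power curves, identification rate.

Each repetition simulates a fresh dataset from the hierarchical generator,
runs the full bootstrap test, and records the p-value; the size (under the
delta = 0 null) or power (delta > 0) estimate is the fraction of repetitions
with p below the nominal level.  ``empirical_size`` is literally
``power_at(0.0, ...)`` — the same code path — so the left endpoint of a
power curve reproduces the size estimate exactly under the same seed.

Defaults are desk-scale (hundreds of repetitions, hundreds of bootstrap
replicates, 200 subjects per group); the benchmark-scale study (1000
repetitions, B = 500, 500 subjects per group) is a matter of passing larger
numbers and CPU-hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .bootstrap import BootstrapConfig, bootstrap_pvalue
from .core import run_test_statistic
from .dataset import ValidationError
from .simulate import SimulationDesign, design_with, reference_design, simulate_dataset

_SEED_MAX = 2**31 - 1


@dataclass
class ExperimentResult:
    """One Monte-Carlo size or power estimate.

    ``estimate`` is exactly the fraction of repetitions with p < alpha;
    ``stderr`` is the binomial standard error sqrt(p(1-p)/n_mc).
    """

    estimate: float
    n_mc: int
    n_bootstrap: int
    alpha: float
    delta: float
    seed: int
    mc_pvalues: np.ndarray | None = None

    @property
    def stderr(self) -> float:
        p = self.estimate
        return float(np.sqrt(p * (1.0 - p) / self.n_mc))


def _resolve_design(
    delta: float,
    n_case: int,
    n_control: int,
    design_overrides: dict | None,
) -> SimulationDesign:
    design = reference_design(delta, n_case=n_case, n_control=n_control)
    if design_overrides:
        design = design_with(design, **design_overrides)
    return design


def _one_pvalue(design: SimulationDesign, sim_seed: int, boot_seed: int, b: int) -> float:
    data = simulate_dataset(design, seed=sim_seed)
    res = bootstrap_pvalue(data, config=BootstrapConfig(n_bootstrap=b, seed=boot_seed))
    return res.p_value


def power_at(
    delta: float,
    n_mc: int = 200,
    n_bootstrap: int = 200,
    n_case: int = 200,
    n_control: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    design_overrides: dict | None = None,
    n_workers: int = 1,
    retain_pvalues: bool = True,
) -> ExperimentResult:
    """Rejection rate of the test at one value of delta.

    Per repetition, a dataset is drawn from ``reference_design(delta)``
    (optionally with ``design_overrides`` applied), the bootstrap p-value is
    computed with ``n_bootstrap`` replicates, and a rejection is recorded
    when p < alpha.  Repetition seeds are pre-drawn from the master seed, so
    the estimate is bit-identical for any ``n_workers``.
    """
    if n_mc < 1:
        raise ValidationError("n_mc must be >= 1")
    design = _resolve_design(delta, n_case, n_control, design_overrides)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, _SEED_MAX, size=(n_mc, 2))
    if n_workers == 1:
        pvals = [
            _one_pvalue(design, int(s), int(t), n_bootstrap) for s, t in rep_seeds
        ]
    else:
        pvals = Parallel(n_jobs=n_workers)(
            delayed(_one_pvalue)(design, int(s), int(t), n_bootstrap)
            for s, t in rep_seeds
        )
    pvals = np.asarray(pvals)
    return ExperimentResult(
        estimate=float((pvals < alpha).mean()),
        n_mc=n_mc,
        n_bootstrap=n_bootstrap,
        alpha=alpha,
        delta=float(delta),
        seed=seed,
        mc_pvalues=pvals if retain_pvalues else None,
    )


def empirical_size(
    n_mc: int = 200,
    n_bootstrap: int = 200,
    n_case: int = 200,
    n_control: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    design_overrides: dict | None = None,
    n_workers: int = 1,
    retain_pvalues: bool = True,
) -> ExperimentResult:
    """Empirical type-I error under the exchangeable null (delta = 0)."""
    return power_at(
        0.0,
        n_mc=n_mc,
        n_bootstrap=n_bootstrap,
        n_case=n_case,
        n_control=n_control,
        alpha=alpha,
        seed=seed,
        design_overrides=design_overrides,
        n_workers=n_workers,
        retain_pvalues=retain_pvalues,
    )


def power_curve(
    deltas,
    n_mc: int = 200,
    n_bootstrap: int = 200,
    n_case: int = 200,
    n_control: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    design_overrides: dict | None = None,
    n_workers: int = 1,
) -> list:
    """Rejection rate at each delta, sharing the master seed across deltas.

    Sharing the seed gives common random numbers across the curve (lower
    Monte-Carlo noise on contrasts) and makes the delta = 0 point coincide
    exactly with :func:`empirical_size` run with the same arguments.
    """
    return [
        power_at(
            d,
            n_mc=n_mc,
            n_bootstrap=n_bootstrap,
            n_case=n_case,
            n_control=n_control,
            alpha=alpha,
            seed=seed,
            design_overrides=design_overrides,
            n_workers=n_workers,
        )
        for d in deltas
    ]


def identification_accuracy(
    delta: float,
    n_mc: int = 50,
    n_case: int = 500,
    n_control: int = 500,
    seed: int = 0,
    design_overrides: dict | None = None,
) -> float:
    """Fraction of repetitions in which the top TF alone is identified.

    No bootstrap is involved: per repetition the max-concordance argmax set
    is compared with the generative top-of-hierarchy TF.  Under the null
    (delta = 0) the argmax is diffuse over the M candidates; under a strong
    alternative it concentrates on the true master regulator.
    """
    design = _resolve_design(delta, n_case, n_control, design_overrides)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, _SEED_MAX, size=n_mc)
    hits = 0
    for s in rep_seeds:
        data = simulate_dataset(design, seed=int(s))
        result = run_test_statistic(data)
        top_tf = str(data.tf_ids[0])
        hits += result.master_set == [top_tf]
    return hits / n_mc


def isotonic_trend(estimates) -> np.ndarray:
    """Non-decreasing least-squares fit to a sequence of rates.

    Used to assert that a power curve trends upward without requiring raw
    Monte-Carlo estimates to be monotone point by point.
    """
    from sklearn.isotonic import IsotonicRegression

    est = np.asarray(estimates, dtype=float)
    return IsotonicRegression().fit_transform(np.arange(len(est)), est)
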