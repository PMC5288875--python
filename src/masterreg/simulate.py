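"""Hierarchical generative model for two-group expression data.

The generator emulates a three-layer regulatory cascade.  A top transcription
factor TF_1 is drawn i.i.d. Gaussian per subject (mean ``mu`` in cases,
``vartheta`` in controls, unit variance).  Each downstream factor is a noisy
copy of the top one,

    TF_i = (rho_i * TF_1 + V_i) / sqrt(1 + rho_i^2),    V_i ~ N(0, 1),

with ``rho_2 > rho_3 > ... > rho_M`` so that correlation with TF_1 decreases
down the hierarchy.  Genes come in consecutive blocks, one block per TF:
TF_1's block loads on TF_1 itself (loading gamma_1 in cases, gamma_2 in
controls) while TF_i's block (i != 1) loads on the idiosyncratic component
V_i (loading r_1i in cases, r_2i in controls); unit-variance Gaussian noise
is added everywhere.  Differential regulation between the groups is induced
by making the case loadings exceed the control ones.

The single knob ``delta`` in [0, 1] scales this difference in the reference
design: r_2i = (1 - delta) * r_1i and gamma_1 = gamma_2 + delta^2 * r_12, so
delta = 0 is the exchangeable null (no differential connectivity) and
delta = 1 the strongest alternative.

All population correlations implied by the construction are available in
closed form (``expected_tf_correlation``, ``expected_tf_gene_correlation``)
and are used as oracles by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import ExpressionDataset, ValidationError


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterization of the hierarchical generator.

    Attributes
    ----------
    n_tf, n_genes:
        Number of transcription factors M and of non-TF genes N.
    n_case, n_control:
        Group sample sizes r1 and r2.
    mean_case, mean_control:
        Means of TF_1 in the two groups (mu, vartheta); the variance is 1.
        Correlations are location-invariant, so the mean shift does not feed
        the statistic; it is part of the reference configuration regardless.
    tf_corr:
        Length M-1 vector (rho_2 .. rho_M), strictly decreasing, in (0, 1].
    block_sizes:
        Genes regulated per TF (m_1 .. m_M), summing to N.
    top_loading_case, top_loading_control:
        TF_1 -> gene loadings gamma_1 / gamma_2 for TF_1's block.
    branch_loading_case, branch_loading_control:
        Length M-1 loadings r_1i / r_2i of V_i on TF_i's block, i = 2..M.
    delta:
        Differential-connectivity magnitude in [0, 1]; informational except
        where a design is built through :func:`reference_design`.
    seed:
        Default RNG seed used by :func:`simulate_dataset` when no explicit
        seed is passed.
    """

    n_tf: int
    n_genes: int
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    tf_corr: tuple
    block_sizes: tuple
    top_loading_case: float
    top_loading_control: float
    branch_loading_case: tuple
    branch_loading_control: tuple
    delta: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tf_corr", tuple(float(r) for r in self.tf_corr))
        object.__setattr__(self, "block_sizes", tuple(int(m) for m in self.block_sizes))
        object.__setattr__(
            self, "branch_loading_case",
            tuple(float(r) for r in self.branch_loading_case),
        )
        object.__setattr__(
            self, "branch_loading_control",
            tuple(float(r) for r in self.branch_loading_control),
        )
        m = self.n_tf
        if m < 2:
            raise ValidationError("need at least 2 transcription factors")
        if len(self.tf_corr) != m - 1:
            raise ValidationError("tf_corr must have length M-1")
        rho = np.asarray(self.tf_corr)
        if np.any(rho <= 0) or np.any(rho > 1):
            raise ValidationError("tf_corr entries must lie in (0, 1]")
        if np.any(np.diff(rho) >= 0):
            raise ValidationError("tf_corr must be strictly decreasing")
        if len(self.block_sizes) != m:
            raise ValidationError("block_sizes must have length M")
        if any(b < 1 for b in self.block_sizes):
            raise ValidationError("every TF must regulate at least one gene")
        if sum(self.block_sizes) != self.n_genes:
            raise ValidationError(
                f"block sizes sum to {sum(self.block_sizes)}, expected N={self.n_genes}"
            )
        for name in ("branch_loading_case", "branch_loading_control"):
            if len(getattr(self, name)) != m - 1:
                raise ValidationError(f"{name} must have length M-1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValidationError("delta must lie in [0, 1]")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("both groups must be non-empty")

    @property
    def is_null(self) -> bool:
        """True when case and control generating laws coincide."""
        return (
            self.top_loading_case == self.top_loading_control
            and self.branch_loading_case == self.branch_loading_control
        )


#: reference configuration used throughout the size/power studies
_REFERENCE = dict(
    n_tf=10,
    n_genes=105,
    mean_case=50.0,
    mean_control=5.0,
    tf_corr=(0.95, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
    block_sizes=(30, 10, 10, 10, 10, 10, 10, 5, 5, 5),
    top_loading_control=0.5,
)
_REFERENCE_BRANCH_TOP = 0.45  # r_12; r_1i decreases by 0.05 down the cascade


def reference_design(
    delta: float,
    n_case: int = 500,
    n_control: int = 500,
    seed: int | None = None,
) -> SimulationDesign:
    """The benchmark design of the size/power studies, as a function of delta.

    M = 10 TFs, N = 105 genes in blocks (30, 10, ..., 5); rho descending
    from 0.95 to 0.1; gamma_2 = 0.5 and r_1i descending from 0.45 in steps
    of 0.05.  The alternative is parameterized by delta through

        r_2i    = (1 - delta) * r_1i
        gamma_1 = gamma_2 + delta^2 * r_12

    so ``delta = 0`` gives the exchangeable null (gamma_1 = gamma_2,
    r_1i = r_2i) and ``delta = 1`` zeroes every control branch loading.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValidationError("delta must lie in [0, 1]")
    branch_case = tuple(_REFERENCE_BRANCH_TOP - 0.05 * i for i in range(9))
    branch_control = tuple((1.0 - delta) * r for r in branch_case)
    gamma2 = _REFERENCE["top_loading_control"]
    gamma1 = gamma2 + delta**2 * _REFERENCE_BRANCH_TOP
    return SimulationDesign(
        n_case=n_case,
        n_control=n_control,
        top_loading_case=gamma1,
        branch_loading_case=branch_case,
        branch_loading_control=branch_control,
        delta=float(delta),
        seed=seed,
        **_REFERENCE,
    )


def _simulate_group(
    rng: np.random.Generator, design: SimulationDesign, n: int, case: bool
) -> np.ndarray:
    """One group's (M + N) x n expression block, TF rows first."""
    m = design.n_tf
    rho = np.asarray(design.tf_corr)
    mean = design.mean_case if case else design.mean_control
    gamma = design.top_loading_case if case else design.top_loading_control
    branch = np.asarray(
        design.branch_loading_case if case else design.branch_loading_control
    )

    tf1 = rng.normal(mean, 1.0, size=n)
    v = rng.normal(0.0, 1.0, size=(m - 1, n))
    tf_rest = (rho[:, None] * tf1 + v) / np.sqrt(1.0 + rho**2)[:, None]

    blocks = [tf1[None, :], tf_rest]
    sizes = design.block_sizes
    blocks.append(gamma * tf1 + rng.normal(size=(sizes[0], n)))
    for i in range(1, m):
        blocks.append(branch[i - 1] * v[i - 1] + rng.normal(size=(sizes[i], n)))
    return np.vstack(blocks)


def simulate_dataset(
    design: SimulationDesign, seed: int | None = None
) -> ExpressionDataset:
    """Draw one two-group dataset from the hierarchical model.

    Case columns come first, then control; group labels are carried
    explicitly so no downstream code relies on the ordering.  Generation is
    bit-reproducible for a fixed seed.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    case = _simulate_group(rng, design, design.n_case, case=True)
    ctl = _simulate_group(rng, design, design.n_control, case=False)

    m, n_genes = design.n_tf, design.n_genes
    tf_ids = [f"TF{i + 1:02d}" for i in range(m)]
    gene_ids = [f"G{i + 1:03d}" for i in range(n_genes)]
    sample_ids = [f"case_{i + 1:03d}" for i in range(design.n_case)] + [
        f"ctrl_{i + 1:03d}" for i in range(design.n_control)
    ]
    return ExpressionDataset(
        values=np.hstack([case, ctl]),
        feature_ids=np.array(tf_ids + gene_ids, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        group=np.array(
            ["case"] * design.n_case + ["control"] * design.n_control, dtype=object
        ),
        is_tf=np.array([True] * m + [False] * n_genes),
        case_label="case",
    )


def simulate_two_masters(
    design_a: SimulationDesign,
    design_b: SimulationDesign,
    seed: int | None = None,
) -> ExpressionDataset:
    """Two independent regulatory cascades measured on the same subjects.

    Each design contributes a disjoint block of TFs and genes; the blocks
    are generated independently, so every cross-block correlation is 0 in
    population.  Used to probe behavior when two master regulators coexist.
    """
    if (design_a.n_case, design_a.n_control) != (design_b.n_case, design_b.n_control):
        raise ValidationError("the two designs must share the group sample sizes")
    if seed is None:
        seed = design_a.seed
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = ss.spawn(2)
    ds_a = simulate_dataset(design_a, seed=seed_a)
    ds_b = simulate_dataset(design_b, seed=seed_b)
    return ExpressionDataset(
        values=np.vstack([ds_a.values, ds_b.values]),
        feature_ids=np.concatenate(
            [
                np.array([f"A:{f}" for f in ds_a.feature_ids], dtype=object),
                np.array([f"B:{f}" for f in ds_b.feature_ids], dtype=object),
            ]
        ),
        sample_ids=ds_a.sample_ids,
        group=ds_a.group,
        is_tf=np.concatenate([ds_a.is_tf, ds_b.is_tf]),
        case_label="case",
    )


# ---------------------------------------------------------------------------
# Closed-form population correlations implied by the construction
# ---------------------------------------------------------------------------

def expected_tf_correlation(design: SimulationDesign, j: int, k: int) -> float:
    """Population Corr(TF_j, TF_k) within a group (1-based indices).

    Corr(TF_1, TF_i) = rho_i / sqrt(1 + rho_i^2) and, for j, k != 1,
    Corr(TF_j, TF_k) = rho_j rho_k / (sqrt(1 + rho_j^2) sqrt(1 + rho_k^2)).
    """
    if j == k:
        return 1.0
    rho = {i + 2: r for i, r in enumerate(design.tf_corr)}
    if j == 1 or k == 1:
        r = rho[max(j, k)]
        return r / np.sqrt(1.0 + r**2)
    rj, rk = rho[j], rho[k]
    return rj * rk / (np.sqrt(1.0 + rj**2) * np.sqrt(1.0 + rk**2))


def expected_tf_gene_correlation(
    design: SimulationDesign, i: int, case: bool
) -> float:
    """Population Corr(TF_i, g) for genes in TF_i's own block (1-based i).

    For TF_1: gamma / sqrt(1 + gamma^2); for i != 1:
    r_i / (sqrt(1 + rho_i^2) sqrt(1 + r_i^2)), with the group's loadings.
    Genes outside TF_i's block are uncorrelated with it by construction.
    """
    if i == 1:
        g = design.top_loading_case if case else design.top_loading_control
        return g / np.sqrt(1.0 + g**2)
    rho = design.tf_corr[i - 2]
    r = (design.branch_loading_case if case else design.branch_loading_control)[i - 2]
    return r / (np.sqrt(1.0 + rho**2) * np.sqrt(1.0 + r**2))


def gene_blocks(design: SimulationDesign) -> list:
    """Consecutive index ranges (into the gene rows) of each TF's block."""
    edges = np.concatenate([[0], np.cumsum(design.block_sizes)])
    return [range(int(edges[i]), int(edges[i + 1])) for i in range(design.n_tf)]


def design_with(design: SimulationDesign, **overrides) -> SimulationDesign:
    """Copy of a design with the given fields replaced (re-validated)."""
    return replace(design, **overrides)
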