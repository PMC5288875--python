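"""Container for two-group expression data with transcription-factor annotation.

The universal input of the package: a features x samples matrix of (already
normalized, typically log-scale) expression values, a binary group label per
sample (case / control), and a boolean flag per feature marking which rows are
transcription factors (TFs).  All statistical operations consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when input data violate the contracts of the analysis."""


class ZeroVarianceWarning(UserWarning):
    """A feature is constant within a group; its correlations are set to 0."""


def _as_str_array(ids: Sequence[str], name: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class ExpressionDataset:
    """Expression matrix with group labels and TF/gene role flags.

    Parameters
    ----------
    values:
        Float matrix of shape ``(n_features, n_samples)``.
    feature_ids, sample_ids:
        Unique identifiers for rows and columns.
    group:
        Per-sample label with exactly two levels, or ``None`` while the
        dataset is still an unlabeled skeleton (as returned by the readers).
    is_tf:
        Boolean per-feature flag; ``None`` until TF annotation is attached.
    case_label:
        Which group level is treated as "case".  The test statistic is
        symmetric in the two groups; the label only fixes which bootstrap
        block has size ``r1``.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    group: np.ndarray | None = None
    is_tf: np.ndarray | None = None
    case_label: str | None = None
    allow_missing: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D features x samples matrix")
        self.feature_ids = _as_str_array(self.feature_ids, "feature_ids")
        self.sample_ids = _as_str_array(self.sample_ids, "sample_ids")
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {n_feat} matrix rows"
            )
        if len(self.sample_ids) != n_samp:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samp} matrix columns"
            )
        dup = _duplicates(self.feature_ids)
        if dup:
            raise ValidationError(f"duplicate feature ids: {sorted(dup)}")
        if not self.allow_missing and np.isnan(self.values).any():
            rows = self.feature_ids[np.isnan(self.values).any(axis=1)]
            raise ValidationError(
                "missing values in expression matrix "
                f"(features {list(rows[:5])}{'...' if len(rows) > 5 else ''}); "
                "pass allow_missing=True to enable pairwise-complete correlations"
            )
        if self.group is not None:
            self.group = _as_str_array(self.group, "group")
            if len(self.group) != n_samp:
                raise ValidationError("group labels must match the number of samples")
            levels = sorted(set(self.group))
            if len(levels) != 2:
                raise ValidationError(
                    f"exactly two group levels required, found {levels}"
                )
            if self.case_label is None:
                self.case_label = levels[0]
            elif self.case_label not in levels:
                raise ValidationError(
                    f"case label {self.case_label!r} not among group levels {levels}"
                )
        if self.is_tf is not None:
            self.is_tf = np.asarray(self.is_tf, dtype=bool)
            if len(self.is_tf) != n_feat:
                raise ValidationError("is_tf must match the number of features")
            if int(self.is_tf.sum()) < 2:
                raise ValidationError("at least 2 transcription factors required")
            if int((~self.is_tf).sum()) < 1:
                raise ValidationError("at least 1 non-TF gene required")

    # ------------------------------------------------------------------
    # Derived views
    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_tf(self) -> int:
        """Number of transcription factors, M."""
        self._require_tf()
        return int(self.is_tf.sum())

    @property
    def n_gene(self) -> int:
        """Number of non-TF genes, N."""
        self._require_tf()
        return int((~self.is_tf).sum())

    @property
    def tf_ids(self) -> np.ndarray:
        self._require_tf()
        return self.feature_ids[self.is_tf]

    @property
    def gene_ids(self) -> np.ndarray:
        self._require_tf()
        return self.feature_ids[~self.is_tf]

    @property
    def case_mask(self) -> np.ndarray:
        self._require_groups()
        return self.group == self.case_label

    @property
    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.case_mask)

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.case_mask)

    @property
    def r1(self) -> int:
        """Case group size."""
        return int(self.case_mask.sum())

    @property
    def r2(self) -> int:
        """Control group size."""
        return self.n_samples - self.r1

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def _require_groups(self) -> None:
        if self.group is None:
            raise ValidationError("dataset has no group labels attached")

    def _require_tf(self) -> None:
        if self.is_tf is None:
            raise ValidationError("dataset has no TF annotation attached")

    def require_complete(self) -> None:
        """Fail unless the dataset is fully labeled and annotated."""
        self._require_groups()
        self._require_tf()
        if self.r1 == 0 or self.r2 == 0:
            raise ValidationError("both groups must be non-empty")

    def subset_features(self, keep: np.ndarray) -> "ExpressionDataset":
        """Return a copy restricted to the boolean feature mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return replace(
            self,
            values=self.values[keep],
            feature_ids=self.feature_ids[keep],
            is_tf=None if self.is_tf is None else self.is_tf[keep],
        )


def _duplicates(ids: np.ndarray) -> set:
    seen: set = set()
    dup: set = set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup
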