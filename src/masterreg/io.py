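"""Delimited-text readers/writers, validation, and the analysis report.

Expression matrices travel as TSV/CSV with features in rows, a header row of
sample IDs and a first column of feature IDs (an orientation flag accepts
transposed files).  Group labels are a two-column file (sample_id, group)
with exactly two levels; TF annotation is a one-column list of feature IDs.

Also provides an opt-in convenience pre-filter (per-feature Welch t-test
with Benjamini-Hochberg FDR control).  This is generic plumbing for reducing
a matrix to differentially expressed features before testing; it is NOT an
empirical-Bayes moderated analysis (limma-style), and feature counts on real
data will differ from ones obtained with such tools.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import MasterRegulatorResult
from .dataset import ExpressionDataset, ValidationError

logger = logging.getLogger("masterreg")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path, samples_in_rows: bool = False, allow_missing: bool = False
) -> ExpressionDataset:
    """Read a delimited expression matrix into an unlabeled dataset skeleton.

    ``samples_in_rows`` reads a transposed file (samples as rows).  Duplicate
    feature IDs and non-numeric cells are rejected with the offending
    name/cell in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    )
    if samples_in_rows:
        df = df.T
    bad = df.columns[df.apply(lambda c: not pd.api.types.is_numeric_dtype(c))]
    if len(bad) == 0:
        values = df.to_numpy(dtype=float)
    else:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        introduced = numeric.isna() & df.notna()
        r, c = np.argwhere(introduced.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at feature {df.index[r]!r}, sample "
            f"{df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return ExpressionDataset(
        values=values,
        feature_ids=df.index.astype(str).to_numpy(dtype=object),
        sample_ids=df.columns.astype(str).to_numpy(dtype=object),
        allow_missing=allow_missing,
    )


def attach_groups_and_tfs(
    data: ExpressionDataset,
    groups_path,
    tfs_path,
    case_label: str | None = None,
) -> ExpressionDataset:
    """Attach group labels and TF flags from their side files.

    Every sample must be labeled with one of exactly two levels; every TF ID
    must be present in the matrix (missing ones are listed in the error).
    """
    groups_path, tfs_path = Path(groups_path), Path(tfs_path)
    gdf = pd.read_csv(
        groups_path, sep=_sep_for(groups_path), header=None, names=["sample", "group"]
    )
    if gdf["sample"].astype(str).iloc[0] in ("sample", "sample_id"):  # tolerate header
        gdf = gdf.iloc[1:]
    mapping = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
    missing = [s for s in data.sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"unlabeled sample(s): {missing[:10]}")
    group = np.array([mapping[s] for s in data.sample_ids], dtype=object)

    tf_ids = [
        line.strip()
        for line in Path(tfs_path).read_text().splitlines()
        if line.strip()
    ]
    if not tf_ids:
        raise ValidationError("TF list is empty")
    known = set(data.feature_ids)
    unknown = [t for t in tf_ids if t not in known]
    if unknown:
        raise ValidationError(f"TF id(s) not in expression matrix: {unknown[:10]}")
    tf_set = set(tf_ids)
    is_tf = np.array([f in tf_set for f in data.feature_ids])
    out = ExpressionDataset(
        values=data.values,
        feature_ids=data.feature_ids,
        sample_ids=data.sample_ids,
        group=group,
        is_tf=is_tf,
        case_label=case_label,
        allow_missing=data.allow_missing,
    )
    out.require_complete()
    return out


def write_expression(data: ExpressionDataset, path) -> None:
    path = Path(path)
    df = pd.DataFrame(data.values, index=data.feature_ids, columns=data.sample_ids)
    # %.17g keeps the text round trip value-exact for float64
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_groups(data: ExpressionDataset, path) -> None:
    path = Path(path)
    data._require_groups()
    pd.DataFrame({"sample": data.sample_ids, "group": data.group}).to_csv(
        path, sep=_sep_for(path), index=False, header=False
    )


def write_tfs(data: ExpressionDataset, path) -> None:
    Path(path).write_text("\n".join(str(t) for t in data.tf_ids) + "\n")


def prefilter_features(
    data: ExpressionDataset, alpha_fdr: float = 0.05
) -> ExpressionDataset:
    """Retain features differentially expressed between the groups.

    Per-feature Welch t-test across the two groups, Benjamini-Hochberg
    adjusted; features with adjusted p < ``alpha_fdr`` are kept (TF flags
    preserved).  Refuses to return a dataset with fewer than 2 TFs or 1
    gene, and advises skipping the filter when all TFs would be dropped.
    """
    data.require_complete()
    if data.r1 < 2 or data.r2 < 2:
        raise ValidationError("pre-filtering needs >= 2 samples per group")
    case = data.values[:, data.case_indices]
    ctl = data.values[:, data.control_indices]
    t, p = stats.ttest_ind(case, ctl, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)  # constant features: no evidence, keep out
    reject, _, _, _ = multipletests(p, alpha=alpha_fdr, method="fdr_bh")
    keep = reject if alpha_fdr < 1.0 else np.ones_like(reject, dtype=bool)
    n_tf_kept = int((keep & data.is_tf).sum())
    if n_tf_kept == 0:
        raise ValidationError(
            "pre-filtering removed every transcription factor; "
            "rerun without --prefilter or raise alpha_fdr"
        )
    if n_tf_kept < 2 or int((keep & ~data.is_tf).sum()) < 1:
        raise ValidationError(
            f"pre-filtering left {n_tf_kept} TF(s) and "
            f"{int((keep & ~data.is_tf).sum())} gene(s); the test needs >= 2 "
            "TFs and >= 1 gene — raise alpha_fdr or skip the filter"
        )
    logger.info(
        "prefilter: retained %d/%d features (%d TFs, %d genes) at FDR %.3g",
        int(keep.sum()), data.n_features, n_tf_kept,
        int((keep & ~data.is_tf).sum()), alpha_fdr,
    )
    return data.subset_features(keep)


# ---------------------------------------------------------------------------
# Analysis report
# ---------------------------------------------------------------------------

def _checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


@dataclass
class AnalysisReport:
    """JSON-serializable record of one full test run."""

    inputs: dict
    m_tf: int
    n_gene: int
    group_sizes: tuple
    result: MasterRegulatorResult
    seed: int
    n_bootstrap: int
    version: str
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        d = self.result.to_dict()
        return {
            "inputs": self.inputs,
            "m_tf": self.m_tf,
            "n_gene": self.n_gene,
            "group_sizes": list(self.group_sizes),
            "result": d,
            "seed": self.seed,
            "n_bootstrap": self.n_bootstrap,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        r = d["result"]
        tf_ids = np.array(list(r["k_per_tf"].keys()), dtype=object)
        result = MasterRegulatorResult(
            k_per_tf=np.array(list(r["k_per_tf"].values()), dtype=float),
            k_max=r["k_max"],
            master_set=list(r["master_set"]),
            tf_ids=tf_ids,
            p_value=r["p_value"],
            n_bootstrap=r["n_bootstrap"],
        )
        return cls(
            inputs=d["inputs"],
            m_tf=d["m_tf"],
            n_gene=d["n_gene"],
            group_sizes=tuple(d["group_sizes"]),
            result=result,
            seed=d["seed"],
            n_bootstrap=d["n_bootstrap"],
            version=d["version"],
            timestamp=d["timestamp"],
        )


def build_report(
    data: ExpressionDataset,
    result: MasterRegulatorResult,
    seed: int,
    input_paths: dict | None = None,
) -> AnalysisReport:
    from . import __version__

    inputs = {
        name: {"path": str(p), "md5": _checksum(p)}
        for name, p in (input_paths or {}).items()
    }
    return AnalysisReport(
        inputs=inputs,
        m_tf=data.n_tf,
        n_gene=data.n_gene,
        group_sizes=(data.r1, data.r2),
        result=result,
        seed=seed,
        n_bootstrap=result.n_bootstrap or 0,
        version=__version__,
    )
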