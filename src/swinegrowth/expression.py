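"""Relative qPCR quantification with the 2^-ddCt (Livak) method.

Per sample: dCt = Ct_target - Ct_reference; ddCt = dCt minus the mean dCt of
the calibrator group for the same gene; fold change = 2^-ddCt.  Technical
replicates (duplicate rows for the same sample/gene) are averaged at the Ct
level before dCt.  Group-level ``fold`` is 2^-(mean ddCt), i.e. the
geometric mean of per-sample folds, which is exactly 1 in the calibrator
group by construction; the arithmetic mean and SD of per-sample folds are
reported alongside as ``fold_mean`` / ``fold_sd``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["DdctResult", "delta_delta_ct"]


@dataclass(frozen=True)
class DdctResult:
    """Per-sample and per-group relative expression.

    ``per_sample`` columns: sample_id, group, gene, dct, ddct, fold.
    ``summary`` columns: gene, group, n, ddct (mean), fold (2^-mean ddct),
    fold_mean, fold_sd.
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    reference_gene: str
    calibrator_group: str


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> DdctResult:
    """Compute 2^-ddCt fold changes from a tidy Ct table.

    ``records`` needs columns ``sample_id, group, gene, ct`` with Ct in
    (0, 45).  Samples lacking the reference gene are dropped with a warning;
    a missing calibrator group (for any target gene) is an error.
    """
    required = ["sample_id", "group", "gene", "ct"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise SchemaError(f"Ct table missing column(s): {missing}")
    df = records[required].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    bad = df["ct"].isna() | (df["ct"] <= 0) | (df["ct"] >= 45)
    if bad.any():
        raise SchemaError(
            f"{int(bad.sum())} Ct value(s) outside (0, 45) or non-numeric"
        )

    # technical replicates -> one Ct per sample x gene
    ct = (
        df.groupby(["sample_id", "group", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index("sample_id")["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    has_ref = targets["sample_id"].isin(ref.index)
    if (~has_ref).any():
        dropped = sorted(targets.loc[~has_ref, "sample_id"].unique())
        warnings.warn(
            f"dropped sample(s) without reference gene {reference_gene!r}: "
            f"{dropped}",
            stacklevel=2,
        )
        targets = targets[has_ref]
    if targets.empty:
        raise SchemaError("no target-gene measurements with a reference Ct")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[
        targets["sample_id"]
    ].to_numpy()

    calib = targets[targets["group"] == calibrator_group]
    if calib.empty:
        raise SchemaError(f"calibrator group {calibrator_group!r} is empty")
    calib_mean = calib.groupby("gene")["dct"].mean()
    genes_missing = set(targets["gene"]) - set(calib_mean.index)
    if genes_missing:
        raise SchemaError(
            f"gene(s) absent from calibrator group: {sorted(genes_missing)}"
        )

    targets["ddct"] = targets["dct"].to_numpy() - calib_mean.loc[
        targets["gene"]
    ].to_numpy()
    targets["fold"] = np.exp2(-targets["ddct"])

    summary = (
        targets.groupby(["gene", "group"], sort=True)
        .agg(
            n=("fold", "size"),
            ddct=("ddct", "mean"),
            fold_mean=("fold", "mean"),
            fold_sd=("fold", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
        )
        .reset_index()
    )
    summary["fold"] = np.exp2(-summary["ddct"])
    summary = summary[["gene", "group", "n", "ddct", "fold", "fold_mean", "fold_sd"]]
    per_sample = targets[["sample_id", "group", "gene", "dct", "ddct", "fold"]]
    return DdctResult(
        per_sample=per_sample.reset_index(drop=True),
        summary=summary,
        reference_gene=reference_gene,
        calibrator_group=calibrator_group,
    )
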