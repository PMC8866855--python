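"""Relative quantification of qPCR cycle thresholds (ddCt method).

A long-format CT table holds one row per (sample, gene) measurement with a
role column marking the gene of interest (GOI) versus reference genes.
Per sample, reference CTs are averaged into CT_ref; the sample's
dCt = CT_ref - CT_goi (reference minus gene of interest, so higher
expression gives higher dCt); ddCt subtracts the control-group aggregate
dCt; and the fold change is E**ddCt with amplification efficiency E
(E = 2 for perfect doubling per cycle; measured primer efficiencies are
typically 1.95-1.99).

Technical replicates — multiple rows for the same (sample, gene) — are
averaged before any delta is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "FoldChangeResult",
    "read_ct_table",
    "reference_ct",
    "delta_ct",
    "fold_changes",
]

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "role", "ct")
VALID_ROLES = ("GOI", "reference")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format CT table from CSV."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    bad_roles = set(df["role"]) - set(VALID_ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}; expected {VALID_ROLES}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("CT values must be finite")
    return df


def _collapse_replicates(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.groupby(["sample_id", "group", "gene", "role"], as_index=False)["ct"]
        .mean()
    )


def reference_ct(sample_rows: pd.DataFrame) -> float:
    """CT_ref for one sample: arithmetic mean of its reference-gene CTs."""
    refs = sample_rows.loc[sample_rows["role"] == "reference", "ct"]
    if refs.empty:
        raise ValueError("sample has no reference-gene CT values")
    return float(refs.mean())


def delta_ct(sample_rows: pd.DataFrame) -> float:
    """dCt = CT_ref - CT_goi for one sample (reference minus GOI)."""
    goi = sample_rows.loc[sample_rows["role"] == "GOI", "ct"]
    if goi.empty:
        raise ValueError("sample has no gene-of-interest CT value")
    return reference_ct(sample_rows) - float(goi.mean())


@dataclass
class FoldChangeResult:
    """Per-sample dCt/ddCt/fold table plus the group-level summary."""

    per_sample: pd.DataFrame   # sample_id, group, ct_ref, ct_goi, dct, ddct, fold_change
    dct_control: float
    group_fold: float          # E**(aggregate dCt_treated - aggregate dCt_control)
    efficiency: float


def fold_changes(
    table: pd.DataFrame,
    efficiency: float = 2.0,
    control_group: str = "control",
    aggregate: str = "mean",
) -> FoldChangeResult:
    """Fold changes of every sample relative to the control group.

    ``aggregate`` ('mean' or 'median') sets how control dCt values are
    pooled before differencing.  Samples lacking a GOI or reference CT are
    skipped with a warning; an absent control group is an error.
    Fold change is ``efficiency**ddCt``, so ddCt = +1 at E = 2 doubles.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    df = _collapse_replicates(table)
    groups = set(df["group"])
    if control_group not in groups:
        raise ValueError(f"no samples in control group {control_group!r}")

    rows = []
    for (sample, group), sub in df.groupby(["sample_id", "group"], sort=False):
        try:
            dct = delta_ct(sub)
        except ValueError as exc:
            warnings.warn(f"skipping sample {sample!r}: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "sample_id": sample,
                "group": group,
                "ct_ref": reference_ct(sub),
                "ct_goi": float(sub.loc[sub["role"] == "GOI", "ct"].mean()),
                "dct": dct,
            }
        )
    per_sample = pd.DataFrame(rows)
    if per_sample.empty or control_group not in set(per_sample["group"]):
        raise ValueError("no usable control samples after skipping incomplete ones")

    agg = np.mean if aggregate == "mean" else np.median
    control_dct = float(agg(per_sample.loc[per_sample["group"] == control_group, "dct"]))
    per_sample["ddct"] = per_sample["dct"] - control_dct
    per_sample["fold_change"] = efficiency ** per_sample["ddct"]

    treated = per_sample.loc[per_sample["group"] != control_group, "dct"]
    group_fold = float(efficiency ** (agg(treated) - control_dct)) if len(treated) else 1.0
    return FoldChangeResult(
        per_sample=per_sample,
        dct_control=control_dct,
        group_fold=group_fold,
        efficiency=efficiency,
    )
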