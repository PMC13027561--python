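"""Lesional skin miRNA profiles: QC, imputation and differential expression.

Expression is array-scale (log2) miRNA x sample data with missing values.
QC keeps a miRNA only when valid measurements cover at least 75% of samples
(6 of 8 at the study's cohort size), imputes the remaining gaps with the
row median, and drops near-constant rows.  Differential expression between
lesional and control skin uses the shared moderated two-group linear model;
a miRNA is differentially expressed at FDR < 0.05, and only DE miRNAs with
|log2FC| > 1 qualify as drivers for the downstream regulatory bridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats

__all__ = ["MirnaMatrix", "qc_filter_impute", "de_mirnas", "de_summary"]


@dataclass
class MirnaMatrix:
    expr: pd.DataFrame  # miRNA x sample, log2 scale, no missing values
    group: pd.Series
    levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.group = self.group.reindex(self.expr.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        if not np.isfinite(self.expr.to_numpy()).all():
            raise ValueError("expression must be fully finite after QC/imputation")
        uniq = list(pd.unique(self.group))
        if self.levels is None and len(uniq) == 2:
            ref = [u for u in uniq if str(u).upper().startswith("HC")]
            self.levels = (ref[0], [u for u in uniq if u != ref[0]][0]) if ref else (uniq[0], uniq[1])


def qc_filter_impute(
    raw: pd.DataFrame,
    group: pd.Series,
    detection_rate: float = 0.75,
    variance_floor: float = 1e-8,
) -> MirnaMatrix:
    """Detection-rate filtering, row-median imputation, low-variance removal.

    Non-finite entries become missing; a row survives only if at least
    ``ceil(detection_rate * n_samples)`` values are finite (the 6-of-8 rule
    at n = 8); surviving missing values are replaced by the row median over
    finite entries; rows with variance at or below ``variance_floor`` are
    removed.
    """
    if group.value_counts().min() < 2:
        raise ValueError("need at least 2 samples per group")
    expr = raw.replace([np.inf, -np.inf], np.nan).astype(float)
    n = expr.shape[1]
    min_valid = math.ceil(detection_rate * n)
    keep = expr.notna().sum(axis=1) >= min_valid
    expr = expr.loc[keep]
    expr = expr.apply(lambda row: row.fillna(row.median()), axis=1)
    expr = expr.loc[expr.var(axis=1, ddof=1) > variance_floor]
    if expr.empty:
        raise ValueError("no miRNAs survive QC filtering")
    return MirnaMatrix(expr=expr, group=group)


def de_mirnas(
    data: MirnaMatrix,
    eb: bool = True,
    fdr_threshold: float = 0.05,
    driver_lfc: float = 1.0,
) -> pd.DataFrame:
    """Differential miRNA expression (case minus reference, log2 scale).

    Returns per-miRNA log2FC, p, BH q, ``is_de`` (q below the FDR
    threshold) and ``is_bridge_driver`` (DE and |log2FC| strictly above the
    driver threshold).  Constant rows get p = 1 and a ``flagged`` mark.
    """
    ref, case = data.levels
    g = (data.group == case).astype(float).to_numpy()
    fit = stats.fit_group_linear(data.expr.to_numpy(), g, eb=eb)
    out = pd.DataFrame(
        {
            "log2fc": fit.coef,
            "t_statistic": fit.t_statistic,
            "p_value": fit.p_value,
            "q_value": fit.q_value,
        },
        index=data.expr.index,
    )
    out["flagged"] = data.expr.var(axis=1).to_numpy() == 0
    out.loc[out["flagged"], ["p_value", "q_value"]] = 1.0
    out["is_de"] = out["q_value"] < fdr_threshold
    out["is_bridge_driver"] = out["is_de"] & (out["log2fc"].abs() > driver_lfc)
    return out


def de_summary(de: pd.DataFrame) -> dict[str, int]:
    """Up/down counts among DE calls; total always equals up + down."""
    sig = de[de["is_de"]]
    n_up = int((sig["log2fc"] > 0).sum())
    n_down = int((sig["log2fc"] <= 0).sum())
    summary = dict(n_de=len(sig), n_up=n_up, n_down=n_down)
    assert summary["n_de"] == n_up + n_down
    return summary
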