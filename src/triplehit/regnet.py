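"""Regulon-based TF activity and marker-based cell scores from bulk logCPM.

TF activity: expression is z-standardized per gene across samples, and each
transcription factor's raw activity in a sample is the signed-weight mean
of its regulon targets, sum(w * x) / sum(|w|).  A permutation null
(shuffling gene labels of the expression matrix) turns raw scores into
z-scores, and differential activity between groups uses an ordinary
two-group linear model with BH correction.

Cell scores: the mean logCPM of a population's marker genes per sample
(MCP-counter-style abundance scores), compared between groups with the
shared Wilcoxon rank-sum routine and BH across populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "Regulon",
    "read_regulon_table",
    "tf_activity",
    "differential_activity",
    "cell_scores",
]


@dataclass
class Regulon:
    tf_id: str
    targets: list[str]
    weights: np.ndarray  # signed mode-of-regulation weights

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.targets) != self.weights.size:
            raise ValueError("targets and weights must align")


def read_regulon_table(
    table: pd.DataFrame, confidence_levels: tuple[str, ...] = ("A", "B", "C")
) -> list[Regulon]:
    """Build regulons from a (tf, target, mode, confidence) table.

    ``confidence_levels`` keeps the high-to-intermediate confidence tiers
    (A-C by default) of curated regulon resources.
    """
    if "confidence" in table.columns:
        table = table[table["confidence"].isin(confidence_levels)]
    regs = []
    for tf, grp in table.groupby("tf", sort=True):
        regs.append(Regulon(tf_id=tf, targets=list(grp["target"]), weights=grp["mode"].to_numpy(float)))
    return regs


@dataclass
class TfActivity:
    scores: pd.DataFrame  # TF x sample permutation z-scores
    raw: pd.DataFrame  # TF x sample raw weighted-mean scores
    skipped: list[str] = field(default_factory=list)


def raw_weighted_mean(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """sum(w * x) / sum(|w|) over the target axis (targets x samples in)."""
    return weights @ x / np.abs(weights).sum()


def tf_activity(
    expr: pd.DataFrame,
    regulons: list[Regulon],
    n_perm: int = 1000,
    seed: int = 0,
    min_targets: int = 5,
    standardize: bool = True,
) -> TfActivity:
    """Permutation-normalized weighted-mean TF activity per sample.

    The null shuffles gene labels of the (standardized) expression matrix;
    the reported score is (raw - null mean) / null sd per TF and sample.
    Regulons with fewer than ``min_targets`` targets present in the matrix
    are skipped with a warning.
    """
    X = expr.to_numpy(float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    rng = np.random.default_rng(seed)
    n_genes = X.shape[0]
    # one gene-label permutation per iteration, shared across samples
    perms = np.array([rng.permutation(n_genes) for _ in range(n_perm)])

    raw_rows, z_rows, kept, skipped = [], [], [], []
    for reg in regulons:
        present = [(gene_pos[t], w) for t, w in zip(reg.targets, reg.weights) if t in gene_pos]
        if len(present) < min_targets:
            skipped.append(reg.tf_id)
            warnings.warn(
                f"regulon {reg.tf_id!r} skipped ({len(present)} targets in matrix)",
                stacklevel=2,
            )
            continue
        idx = np.array([p for p, _ in present])
        w = np.array([wt for _, wt in present])
        wnorm = np.abs(w).sum()
        raw = w @ X[idx] / wnorm
        null_idx = perms[:, idx]  # n_perm x k
        null = np.einsum("k,bks->bs", w, X[null_idx]) / wnorm  # n_perm x samples
        null_mu = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1)
        null_sd[null_sd == 0] = 1.0
        raw_rows.append(raw)
        z_rows.append((raw - null_mu) / null_sd)
        kept.append(reg.tf_id)
    if not kept:
        raise ValueError("no regulon had enough targets in the expression matrix")
    return TfActivity(
        scores=pd.DataFrame(z_rows, index=kept, columns=expr.columns),
        raw=pd.DataFrame(raw_rows, index=kept, columns=expr.columns),
        skipped=skipped,
    )


def differential_activity(
    activity: TfActivity, group: pd.Series, levels: tuple[str, str]
) -> pd.DataFrame:
    """Two-group OLS on TF activity z-scores with BH across TFs."""
    ref, case = levels
    g = (group.reindex(activity.scores.columns) == case).astype(float).to_numpy()
    fit = stats.fit_group_linear(activity.scores.to_numpy(), g, eb=False)
    return pd.DataFrame(
        {
            "diff_effect": fit.coef,
            "t_statistic": fit.t_statistic,
            "p_value": fit.p_value,
            "q_value": fit.q_value,
        },
        index=activity.scores.index,
    )


def cell_scores(
    expr: pd.DataFrame,
    markers: dict[str, list[str]],
    group: pd.Series,
    levels: tuple[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-mean cell scores per sample plus Wilcoxon/BH group tests.

    Score = arithmetic mean of the population's marker-gene logCPM rows; a
    population with no marker present in the matrix is skipped with a
    warning; missing markers of retained populations are reported in the
    test table.
    """
    ref, case = levels
    score_rows = {}
    missing: dict[str, list[str]] = {}
    for pop, genes in markers.items():
        present = [g for g in genes if g in expr.index]
        absent = [g for g in genes if g not in expr.index]
        if not present:
            warnings.warn(f"population {pop!r} skipped: no markers in matrix", stacklevel=2)
            continue
        missing[pop] = absent
        score_rows[pop] = expr.loc[present].mean(axis=0)
    if not score_rows:
        raise ValueError("no population had any marker present")
    scores = pd.DataFrame(score_rows).T
    group = group.reindex(scores.columns)
    rows = []
    for pop in scores.index:
        res = stats.rank_sum_test(
            scores.loc[pop, group == case].to_numpy(),
            scores.loc[pop, group == ref].to_numpy(),
        )
        med_diff = float(
            scores.loc[pop, group == case].median() - scores.loc[pop, group == ref].median()
        )
        rows.append(
            dict(population=pop, statistic=res.statistic, p_value=res.p_value,
                 effect=med_diff, n_missing_markers=len(missing[pop]))
        )
    tests = pd.DataFrame(rows).set_index("population")
    tests["q_value"] = stats.bh_adjust(tests["p_value"].to_numpy())
    return scores, tests
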