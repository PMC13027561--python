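"""Gut microbial functional-profile comparison and composite lipid scoring.

Inputs are KEGG pathway level-3 relative-abundance tables (pathway x sample)
from shotgun metagenomics, with a two-level group label per sample
(healthy controls vs. untreated psoriasis).  Two analyses are provided:

* per-pathway two-group Wilcoxon rank-sum tests with Benjamini-Hochberg
  correction, and
* a composite "lipid degradation functional score": for each sample the sum
  of cohort-wide z-scores of a small set of lipid-catabolism pathways
  (default: fatty acid degradation ko00071, glycerolipid metabolism ko00561,
  glycerophospholipid metabolism ko00564), compared between groups by the
  same Wilcoxon machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "DEFAULT_LIPID_SET",
    "PathwayAbundanceTable",
    "LipidScoreResult",
    "compare_pathways",
    "lipid_score",
]

DEFAULT_LIPID_SET: tuple[str, ...] = ("ko00071", "ko00561", "ko00564")


@dataclass
class PathwayAbundanceTable:
    """Compositional pathway x sample relative-abundance matrix with groups.

    ``levels`` orders the two group labels as (reference, case); effect signs
    are case minus reference.  Column sums are expected to be 1; externally
    supplied tables that deviate beyond 1e-6 trigger a warning, not an error.
    """

    abundances: pd.DataFrame
    group: pd.Series
    levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.group = self.group.reindex(self.abundances.columns)
        if self.group.isna().any():
            raise ValueError("every sample column needs a group label")
        if (self.abundances.values < 0).any():
            raise ValueError("relative abundances must be non-negative")
        uniq = list(pd.unique(self.group))
        if len(uniq) != 2:
            raise ValueError(f"exactly two groups required, got {uniq}")
        if self.levels is None:
            # put an HC-like label first as the reference when present
            ref = [u for u in uniq if str(u).upper().startswith("HC")]
            self.levels = (ref[0], [u for u in uniq if u != ref[0]][0]) if ref else (uniq[0], uniq[1])
        colsums = self.abundances.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            warnings.warn(
                "abundance columns do not sum to 1 within 1e-6; "
                "analyzing as provided (use renormalize() if intended)",
                stacklevel=2,
            )

    def renormalize(self) -> "PathwayAbundanceTable":
        closed = self.abundances.div(self.abundances.sum(axis=0), axis=1)
        return PathwayAbundanceTable(closed, self.group.copy(), self.levels)

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ref, case = self.levels
        return (
            self.abundances.loc[:, self.group == ref],
            self.abundances.loc[:, self.group == case],
        )


def compare_pathways(table: PathwayAbundanceTable) -> pd.DataFrame:
    """Per-pathway two-sided Wilcoxon rank-sum tests between the two groups.

    Returns one row per pathway with the Mann-Whitney U statistic, p, BH q,
    the sign of the case-minus-reference median difference, and that median
    difference.  Constant-zero pathways are flagged and assigned p = 1.
    """
    ref_df, case_df = table.split()
    if min(ref_df.shape[1], case_df.shape[1]) < 3:
        raise ValueError("each group needs at least 3 samples")
    rows = []
    for pw in table.abundances.index:
        x_case = case_df.loc[pw].to_numpy(float)
        x_ref = ref_df.loc[pw].to_numpy(float)
        flagged = bool(np.all(x_case == 0) and np.all(x_ref == 0))
        if flagged:
            stat, p = len(x_case) * len(x_ref) / 2.0, 1.0
        else:
            res = stats.rank_sum_test(x_case, x_ref)
            stat, p = res.statistic, res.p_value
        effect = float(np.median(x_case) - np.median(x_ref))
        rows.append(
            dict(
                pathway_id=pw,
                statistic=stat,
                p_value=p,
                direction=int(np.sign(effect)),
                effect=effect,
                flagged=flagged,
            )
        )
    out = pd.DataFrame(rows).set_index("pathway_id")
    out["q_value"] = stats.bh_adjust(out["p_value"].to_numpy())
    return out[["statistic", "p_value", "q_value", "direction", "effect", "flagged"]]


@dataclass
class LipidScoreResult:
    per_sample_score: pd.Series  # z-units, summed over the lipid set
    lipid_set: tuple[str, ...]
    group_p: float
    zero_variance: list[str] = field(default_factory=list)


def lipid_score(
    table: PathwayAbundanceTable,
    lipid_set: tuple[str, ...] = DEFAULT_LIPID_SET,
    ddof: int = 1,
) -> LipidScoreResult:
    """Composite lipid-catabolism score per sample.

    Score_j = sum over the lipid set of (X_ij - mu_i) / sigma_i, with mu_i
    and sigma_i computed across the entire cohort (sample sd, n-1
    denominator).  A zero-variance pathway contributes 0 to every sample and
    is recorded with a warning.  Group difference is tested by the shared
    Wilcoxon rank-sum routine.
    """
    missing = [p for p in lipid_set if p not in table.abundances.index]
    if missing:
        raise ValueError(f"lipid-set pathways absent from table: {missing}")
    sub = table.abundances.loc[list(lipid_set)]
    mu = sub.mean(axis=1)
    sigma = sub.std(axis=1, ddof=ddof)
    constant = (sub.max(axis=1) - sub.min(axis=1)) == 0  # exact, unlike sd ~ 1e-17
    sigma[constant] = 0.0
    zero_var = sigma.index[sigma == 0].tolist()
    if zero_var:
        warnings.warn(
            f"zero-variance lipid pathways contribute 0 to the score: {zero_var}",
            stacklevel=2,
        )
    safe_sigma = sigma.replace(0, np.inf)
    z = sub.sub(mu, axis=0).div(safe_sigma, axis=0)
    scores = z.sum(axis=0)
    ref, case = table.levels
    res = stats.rank_sum_test(
        scores[table.group == case].to_numpy(), scores[table.group == ref].to_numpy()
    )
    return LipidScoreResult(
        per_sample_score=scores,
        lipid_set=tuple(lipid_set),
        group_p=res.p_value,
        zero_variance=zero_var,
    )
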