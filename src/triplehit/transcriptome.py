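"""Bulk RNA-seq stage: TMM normalization, DEG calling, GSEA, axis summaries.

Counts are normalized between samples with the trimmed mean of M-values
(TMM): a reference sample is chosen by upper-quartile closeness to the
cohort mean, per-sample scaling factors are precision-weighted trimmed means
of gene-wise log-ratios against the reference, and factors are rescaled to
geometric mean 1.  Expression is then expressed as log2 counts-per-million
over effective library sizes with a small prior count.

Differential expression uses the shared two-group moderated linear model;
genes are flagged DEG at |log2FC| >= 1 and FDR <= 0.05.  Pathway-level
remodeling is assessed by pre-ranked GSEA (weighted Kolmogorov-Smirnov
running sum over a log2FC ranking, gene-label permutation null, signed
NES), and gene-set results are aggregated into keyword-defined biological
axes (inflammation, lipid metabolism, insulin/metabolic signaling) whose
significance is the median adjusted p of the member sets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import stats

__all__ = [
    "CountMatrix",
    "tmm_normalize",
    "de_genes",
    "preranked_gsea",
    "enrichment_score",
    "DEFAULT_AXES",
    "aggregate_axes",
]


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with group labels."""

    counts: pd.DataFrame
    group: pd.Series
    levels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.group = self.group.reindex(self.counts.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every sample needs a positive library size")
        uniq = list(pd.unique(self.group))
        if self.levels is None and len(uniq) == 2:
            ref = [u for u in uniq if str(u).upper().startswith(("HC", "AS"))]
            self.levels = (ref[0], [u for u in uniq if u != ref[0]][0]) if ref else (uniq[0], uniq[1])


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o = obs[ok] / lib_obs
    r = ref[ok] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[ok]) / (lib_obs * obs[ok]) + (lib_ref - ref[ok]) / (lib_ref * ref[ok])
    if np.allclose(m, m[0], atol=1e-10):
        return float(2.0 ** m[0])
    n = m.size
    # double trim on ranks of M and A, keeping the central band of each
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    inv_w = 1.0 / w[keep]
    f = (inv_w * m[keep]).sum() / inv_w.sum()
    return float(2.0**f)


def tmm_normalize(
    data: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    prior_count: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM scaling factors and the logCPM matrix.

    Returns ``(factors, logcpm)`` where factors have geometric mean 1 and
    logCPM uses effective library sizes (library size x factor) with a
    library-size-scaled prior count.
    """
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must be in [0, 0.5)")
    counts = data.counts.to_numpy(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("sample with zero total count")
    # reference: sample whose upper-quartile count fraction is closest to the mean
    f75 = np.array([np.percentile(counts[:, j][counts[:, j] > 0] if (counts[:, j] > 0).any() else counts[:, j], 75) / lib[j] for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = lib * factors
    prior = prior_count * eff_lib / eff_lib.mean()
    logcpm = np.log2((counts + prior[None, :]) / (eff_lib + 2 * prior)[None, :] * 1e6)
    return (
        pd.Series(factors, index=data.counts.columns, name="tmm_factor"),
        pd.DataFrame(logcpm, index=data.counts.index, columns=data.counts.columns),
    )


def de_genes(
    logcpm: pd.DataFrame,
    group: pd.Series,
    levels: tuple[str, str],
    eb: bool = True,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group moderated linear model on logCPM with DEG flags."""
    ref, case = levels
    g = (group.reindex(logcpm.columns) == case).astype(float).to_numpy()
    fit = stats.fit_group_linear(logcpm.to_numpy(), g, eb=eb)
    out = pd.DataFrame(
        {
            "log2fc": fit.coef,
            "t_statistic": fit.t_statistic,
            "p_value": fit.p_value,
            "q_value": fit.q_value,
        },
        index=logcpm.index,
    )
    out["is_deg"] = (out["log2fc"].abs() >= lfc_threshold) & (out["q_value"] <= fdr_threshold)
    return out


def enrichment_score(
    scores: np.ndarray, hit_positions: np.ndarray, weight_exponent: float = 1.0
) -> float:
    """Weighted KS enrichment score of a gene set against a sorted ranking.

    ``scores`` must be sorted in decreasing order; ``hit_positions`` are the
    0-based positions of set members in that ordering.  Hits increment the
    running sum proportionally to |score|^p, misses decrement uniformly;
    the ES is the running-sum value of maximum absolute deviation from zero.
    """
    n = scores.size
    k = hit_positions.size
    if k == 0 or k == n:
        raise ValueError("set must be a proper non-empty subset of the ranking")
    hit_positions = np.sort(hit_positions)
    w = np.abs(scores[hit_positions]) ** weight_exponent
    wsum = w.sum()
    if wsum == 0:
        w = np.ones(k)
        wsum = float(k)
    cum_hit = np.cumsum(w) / wsum
    miss = 1.0 / (n - k)
    # running sum immediately after each hit, and immediately before it
    misses_before = hit_positions - np.arange(k)
    after = cum_hit - misses_before * miss
    before = np.concatenate([[0.0], cum_hit[:-1]]) - misses_before * miss
    candidates = np.concatenate([after, before, [0.0]])
    return float(candidates[np.argmax(np.abs(candidates))])


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene -> score ranking (scores = log2FC).

    For each set the enrichment score is the maximum deviation of the
    weighted running sum; the null is built from ``n_perm`` random gene-label
    assignments of the same set size; NES = ES / mean(|null ES| of matching
    sign); p is the matching-sign null tail probability (with add-one
    smoothing); padj is BH across the returned sets.
    """
    if ranking.index.duplicated().any():
        raise ValueError("ranking has duplicate gene ids")
    order = ranking.sort_values(ascending=False, kind="mergesort")
    scores = order.to_numpy(float)
    pos_of = {g: i for i, g in enumerate(order.index)}
    n = scores.size
    rng = np.random.default_rng(seed)

    rows = []
    for set_id, genes in gene_sets.items():
        hits = np.array(sorted({pos_of[g] for g in genes if g in pos_of}), dtype=int)
        if hits.size < min_size or hits.size >= n:
            warnings.warn(f"gene set {set_id!r} skipped (in-ranking size {hits.size})", stacklevel=2)
            continue
        es = enrichment_score(scores, hits, weight_exponent)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_hits = rng.choice(n, size=hits.size, replace=False)
            null[b] = enrichment_score(scores, perm_hits, weight_exponent)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            nes, p = np.nan, 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        rows.append(dict(set_id=set_id, size=hits.size, es=es, nes=nes, p_value=p))
    out = pd.DataFrame(rows)
    if len(out):
        out = out.set_index("set_id")
        out["padj"] = stats.bh_adjust(out["p_value"].to_numpy())
    return out


#: keyword rules defining the three biological axes (case-insensitive,
#: non-alphanumeric characters ignored during matching)
DEFAULT_AXES: dict[str, list[str]] = {
    "inflammation": ["IL-17", "TNF", "Interferon", "NF-kB", "inflamm"],
    "lipid": ["lipid", "fatty", "sphingo", "cholesterol"],
    "insulin_metabolic": ["insulin", "PI3K", "AKT", "mTOR", "Glycolysis"],
}


def _norm(s: str) -> str:
    return re.sub(r"[^0-9a-z]", "", s.lower())


def aggregate_axes(
    gsea: pd.DataFrame,
    rules: dict[str, list[str]] = DEFAULT_AXES,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Group gene-set results into keyword-defined axes.

    A set joins every axis whose keyword list matches its name
    (case-insensitive substring after stripping non-alphanumerics; multi-axis
    membership is allowed and reported).  Axis NES is the median member NES;
    an axis is significant iff the median member padj is below the threshold.
    """
    if not rules:
        raise ValueError("keyword rules must be non-empty")
    rows = []
    for axis, keywords in rules.items():
        normed = [_norm(k) for k in keywords]
        members = [s for s in gsea.index if any(k in _norm(str(s)) for k in normed)]
        if members:
            sub = gsea.loc[members]
            med_padj = float(sub["padj"].median())
            rows.append(
                dict(
                    axis=axis,
                    member_sets=tuple(members),
                    n_members=len(members),
                    axis_nes=float(sub["nes"].median()),
                    median_padj=med_padj,
                    significant=bool(med_padj < padj_threshold),
                )
            )
        else:
            rows.append(
                dict(axis=axis, member_sets=(), n_members=0, axis_nes=float("nan"),
                     median_padj=float("nan"), significant=False)
            )
    return pd.DataFrame(rows).set_index("axis")
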