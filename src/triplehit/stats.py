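"""Shared statistical core.

Every module that compares two groups non-parametrically routes through
:func:`rank_sum_test`, and every feature-wise linear-model contrast routes
through :func:`fit_group_linear`; this keeps the Wilcoxon and moderated-t
behaviour identical across the gut, methylome, miRNA, transcriptome and
regulatory-network stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankSumResult",
    "rank_sum_test",
    "bh_adjust",
    "LinearFitResult",
    "fit_group_linear",
    "stouffer_combine",
]

#: largest per-group size at which the exact Mann-Whitney null is used
EXACT_N_MAX = 10


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    method: str  # "exact", "exact-ties", or "asymptotic"


def _exact_enumeration_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n1+n2, n1) group assignments.

    Handles ties correctly (average ranks are fixed by the pooled sample, so
    the permutation null is over which ranks land in group 1).  The U
    distribution is symmetric about n1*n2/2 under exchangeability, so the
    two-sided p is the probability of a deviation at least as large as the
    observed one.
    """
    n = pooled.size
    n2 = n - n1
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    mid = n1 * n2 / 2.0
    dev = abs(u_obs - mid)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mid) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both groups have at most
    ``EXACT_N_MAX`` observations (full enumeration when ties are present),
    and the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankSumResult(statistic=x.size * y.size / 2.0, p_value=1.0, method="degenerate")
    small = x.size <= EXACT_N_MAX and y.size <= EXACT_N_MAX
    has_ties = np.unique(pooled).size < pooled.size
    if small and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return RankSumResult(float(res.statistic), float(res.pvalue), "exact")
    if small and has_ties:
        u_obs = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
        p = _exact_enumeration_p(pooled, x.size, float(u_obs))
        return RankSumResult(float(u_obs), min(1.0, p), "exact-ties")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), "asymptotic")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma, same scheme limma uses for fitFDist
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Works on the log scale: log(s2) for s2 ~ s0^2 * chi2_df/df has known
    digamma/trigamma moments, giving closed-form estimates of the prior
    degrees of freedom ``d0`` and scale ``s0^2``.  Returns (d0, s0sq);
    d0 = inf means complete shrinkage to a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


@dataclass
class LinearFitResult:
    coef: np.ndarray  # group effect per feature
    t_statistic: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    df_residual: float
    df_total: np.ndarray  # residual df plus prior df when EB is on
    sigma2: np.ndarray  # (possibly shrunken) residual variance per feature
    prior_df: float
    prior_var: float


def fit_group_linear(
    y: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    eb: bool = False,
) -> LinearFitResult:
    """Feature-wise OLS of ``y`` on group plus optional covariates.

    Parameters
    ----------
    y
        features x samples response matrix.
    group
        binary (0/1) group indicator per sample; the reported coefficient is
        the group-1 minus group-0 effect adjusted for covariates.
    covariates
        optional samples x k numeric covariate matrix.
    eb
        if True, residual variances are shrunk toward a moment-matched
        scaled inverse-chi-square prior (empirical-Bayes moderated t).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    group = np.asarray(group, dtype=float)
    n = group.size
    if y.shape[1] != n:
        raise ValueError("y must be features x samples aligned with group")
    cols = [np.ones(n), group]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; check for collinear covariates "
            f"(rank {rank} < {X.shape[1]} columns)"
        )
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv.T  # features x p
    resid = y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    c_gg = xtx_inv[1, 1]
    coef = beta[:, 1]

    if eb:
        d0, s0sq = fit_f_dist(sigma2, df)
        if np.isinf(d0):
            sigma2_post = np.full_like(sigma2, s0sq)
            df_total = np.full_like(sigma2, np.inf)
        else:
            sigma2_post = (d0 * s0sq + df * sigma2) / (d0 + df)
            df_total = np.full_like(sigma2, d0 + df)
        prior_df, prior_var = d0, s0sq
    else:
        sigma2_post = sigma2
        df_total = np.full_like(sigma2, float(df))
        prior_df, prior_var = 0.0, np.nan

    se = np.sqrt(sigma2_post * c_gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.where(coef == 0, 0.0, np.inf * np.sign(coef)))
    finite_df = np.where(np.isinf(df_total), 1e6, df_total)
    p = 2.0 * sps.t.sf(np.abs(t), finite_df)
    p = np.where(np.isfinite(t), p, 0.0)
    # constant features: zero variance and zero effect -> uninformative
    degenerate = (se == 0) & (coef == 0)
    p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    return LinearFitResult(
        coef=coef,
        t_statistic=t,
        p_value=p,
        q_value=q,
        df_residual=float(df),
        df_total=df_total,
        sigma2=sigma2_post,
        prior_df=float(prior_df),
        prior_var=float(prior_var),
    )


def stouffer_combine(p_values: np.ndarray, signs: np.ndarray) -> float:
    """Equal-weight Stouffer combination of two-sided p-values with signs.

    Each p is converted to a signed z via the upper-tail quantile of its
    half-p, oriented by the corresponding effect sign; the combined two-sided
    p is returned.
    """
    p = np.clip(np.asarray(p_values, dtype=float), 1e-300, 1.0)
    s = np.sign(np.asarray(signs, dtype=float))
    s[s == 0] = 1.0
    z = s * sps.norm.isf(p / 2.0)
    z_comb = z.sum() / np.sqrt(z.size)
    return float(2.0 * sps.norm.sf(abs(z_comb)))
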