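"""Population-level statistics: correlations with FDR, PCA, Dunnett
many-to-one contrasts, and variance partitioning.

These operate on a line x trait BLUP matrix (treatment-suffixed trait
names) or, for Dunnett and variance partitioning, on plant-level values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError


# ---------------------------------------------------------------------------
# correlations

def correlations(tm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame,
                                            pd.DataFrame]:
    """Pairwise Pearson correlations with Benjamini-Hochberg adjustment.

    Pairs are tested two-tailed with listwise deletion per pair; the BH
    step-up adjustment runs over the set of off-diagonal pairs. Pairs
    involving a zero-variance column get NaN r and p.
    """
    cols = list(tm.columns)
    if len(tm) < 3:
        raise AnalysisError("need at least 3 lines for correlation tests")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    pairs, praw = [], []
    for i in range(k):
        for j in range(i + 1, k):
            sub = tm[[cols[i], cols[j]]].dropna()
            x, y = sub[cols[i]], sub[cols[j]]
            if len(sub) < 3 or x.std() == 0 or y.std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
            pairs.append((i, j))
            praw.append(pp)
    q = np.full((k, k), np.nan)
    np.fill_diagonal(q, 0.0)
    if praw:
        adj = multipletests(praw, method="fdr_bh")[1]
        for (i, j), qq in zip(pairs, adj):
            q[i, j] = q[j, i] = qq
    idx = pd.Index(cols)
    return (pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx),
            pd.DataFrame(q, idx, idx))


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    loadings: pd.DataFrame   # traits x components
    scores: pd.DataFrame     # lines x components
    explained: pd.Series     # variance share per component (sums to 1)


def pca(tm: pd.DataFrame, *, scaled: bool = True) -> PCAResult:
    """PCA of the trait matrix via SVD of the (scaled) centred data.

    ``scaled`` z-scores columns first (eigendecomposition of the
    correlation matrix); loading signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    if tm.shape[0] < 2 or tm.shape[1] < 2:
        raise AnalysisError("PCA needs >= 2 lines and >= 2 traits")
    X = tm.to_numpy(float)
    X = X - X.mean(axis=0)
    if scaled:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise AnalysisError("zero-variance trait column in PCA input")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign convention
    for c in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    var = s ** 2
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=tm.columns, columns=comp),
        scores=pd.DataFrame(U * s, index=tm.index, columns=comp),
        explained=pd.Series(var / var.sum(), index=comp, name="share"),
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons

def dunnett(obs: pd.DataFrame, control: str, *, value_col: str = "value",
            group_col: str = "line", seed: int | None = 0,
            n_draws: int = 100_000) -> pd.DataFrame:
    """Compare every line against the control with Dunnett's test.

    t statistics use the residual variance pooled across all groups.
    The family-wise adjustment evaluates the many-to-one multivariate-t
    reference by seeded Monte Carlo: ``n_draws`` samples of the maximum
    absolute null statistic max_i |(Zbar_i - Zbar_0) / (S c_i)|, sharing
    one chi-distributed scale S per draw, give
    adj_p_i = P(max |T| >= |t_i|). Adjusted p-values never fall below the
    raw two-sided p. Returns (line, n, estimate, t, raw_p, adj_p).
    """
    groups = {g: sub[value_col].to_numpy(float)
              for g, sub in obs.groupby(group_col)}
    if control not in groups:
        raise AnalysisError(f"control line {control!r} missing")
    ctrl = groups.pop(control)
    if len(ctrl) < 2:
        raise AnalysisError("control needs >= 2 replicates")
    names = sorted(groups)
    samples = [groups[g] for g in names]
    n_i = np.array([len(s) for s in samples], float)
    n_0 = float(len(ctrl))
    k = len(samples) + 1
    ss = sum(((s - s.mean()) ** 2).sum() for s in samples + [ctrl])
    df_resid = int(n_i.sum() + n_0) - k
    if df_resid <= 0:
        raise AnalysisError("no residual degrees of freedom")
    mse = ss / df_resid
    est = np.array([s.mean() for s in samples]) - ctrl.mean()
    c_i = np.sqrt(1 / n_i + 1 / n_0)
    t_obs = est / np.sqrt(mse) / c_i
    raw_p = 2 * stats.t.sf(np.abs(t_obs), df_resid)

    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws) / np.sqrt(n_0)
    zi = rng.standard_normal((n_draws, len(names))) / np.sqrt(n_i)
    s_scale = np.sqrt(rng.chisquare(df_resid, n_draws) / df_resid)
    max_t = np.max(np.abs(zi - z0[:, None]) / c_i, axis=1) / s_scale
    max_t.sort()
    exceed = n_draws - np.searchsorted(max_t, np.abs(t_obs), side="left")
    adj_p = np.minimum(1.0, np.maximum((exceed + 1) / (n_draws + 1), raw_p))

    rows = [(name, int(n), float(e), float(t), float(rp), float(ap))
            for name, n, e, t, rp, ap
            in zip(names, n_i, est, t_obs, raw_p, adj_p)]
    return pd.DataFrame(rows, columns=["line", "n", "estimate", "t",
                                       "raw_p", "adj_p"])


# ---------------------------------------------------------------------------
# variance partitioning

def variance_partition(obs: pd.DataFrame, *, value_col: str = "value",
                       factors=("treatment", "line")) -> pd.Series:
    """Sequential (type-I) ANOVA shares of the total sum of squares.

    Factors enter in the given order (treatment first, mirroring an
    analysis where the main water-treatment effect is removed before
    judging genotype), followed by their interaction; the result maps each
    term, plus Residual, to its percentage of the total SS.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    usable = [f for f in factors if obs[f].nunique() > 1]
    if not usable:
        raise AnalysisError("no factor with more than one level")
    terms = [f"C({f})" for f in usable]
    if len(usable) == 2:
        terms.append(f"C({usable[0]}):C({usable[1]})")
    data = obs.rename(columns={value_col: "_y"})
    model = smf.ols("_y ~ " + " + ".join(terms), data=data).fit()
    tab = anova_lm(model, typ=1)
    ss = tab["sum_sq"]
    share = 100.0 * ss / ss.sum()
    share.index = [i.replace("C(", "").replace(")", "") for i in share.index]
    share.name = "pct_ss"
    return share
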