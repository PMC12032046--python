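"""Micro-environmental correction, outliers, heritability and BLUPs.

Observations live in a "grid observation" frame with columns
``plant, line, treatment, row, col, value`` for one trait in one
treatment. Six correction methods are supported, mirroring common practice
in platform phenotyping:

  none            raw values
  rowcol_mixed    subtract fixed row+column effects estimated in a mixed
                  model with genotype as the random term
  ma_population   subtract the moving average of neighbours' deviations
                  from the population mean
  ma_genotype     same, with deviations from each neighbour's genotype mean
  rowcol_then_ma  mixed model first, then both moving averages
  ma_then_rowcol  both moving averages first, then the mixed model

All methods preserve the population mean exactly (corrections are pure
deviations, re-centred after application). The method kept for a trait is
the one maximizing entry-mean broad-sense heritability, ties broken by the
order above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError

METHODS = ("none", "rowcol_mixed", "ma_population", "ma_genotype",
           "rowcol_then_ma", "ma_then_rowcol")


# ---------------------------------------------------------------------------
# outliers

# finite-sample consistency factors for the MAD (Croux & Rousseeuw)
_MAD_BN = {2: 1.196, 3: 1.495, 4: 1.363, 5: 1.206, 6: 1.200, 7: 1.140,
           8: 1.129, 9: 1.107}


def _scaled_mad(v: np.ndarray) -> float:
    n = len(v)
    bn = _MAD_BN.get(n, n / (n - 0.8)) if n > 1 else 1.0
    return float(np.median(np.abs(v - np.median(v))) * 1.4826 * bn)


def detect_outliers(obs: pd.DataFrame, *, k: float = 3.5,
                    group_cols=("line", "treatment")) -> pd.Series:
    """Robust MAD rule within genotype-by-treatment cells.

    Flags values with |value - median| > k * sigma_hat, where sigma_hat is
    the MAD scaled by 1.4826 and the finite-sample consistency factor.
    When the MAD is zero (heavily tied cells) the scaled mean absolute
    deviation is the fallback spread; a constant cell flags nothing.
    """
    group_cols = [c for c in group_cols if c in obs.columns]
    flags = pd.Series(False, index=obs.index)
    for _, sub in obs.groupby(group_cols):
        v = sub["value"].to_numpy(float)
        med = np.median(v)
        dev = np.abs(v - med)
        mad = _scaled_mad(v)
        if mad == 0:
            mad = dev.mean() * 1.2533
        if mad == 0:
            continue
        flags.loc[sub.index[dev > k * mad]] = True
    return flags


# ---------------------------------------------------------------------------
# spatial correction

def _recenter(corrected: np.ndarray, original: np.ndarray) -> np.ndarray:
    return corrected + (original.mean() - corrected.mean())


def _rowcol_mixed(obs: pd.DataFrame) -> np.ndarray:
    """Centred fixed row+column effects from a genotype-random mixed model.

    Falls back to OLS on genotype-demeaned values if the REML fit fails,
    which yields the same row/column contrasts in balanced layouts.
    """
    import statsmodels.api as sm

    y = obs["value"].to_numpy(float)
    dummies = pd.get_dummies(obs[["row", "col"]].astype(str),
                             drop_first=True, dtype=float)
    exog = np.column_stack([np.ones(len(obs)), dummies.to_numpy()])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=obs["line"].to_numpy())
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        fe = exog @ np.asarray(fit.fe_params)
    except Exception:
        demeaned = y - obs.groupby("line")["value"].transform("mean").to_numpy()
        beta, *_ = np.linalg.lstsq(exog, demeaned, rcond=None)
        fe = exog @ beta
    return fe - fe.mean()


def _moving_average(obs: pd.DataFrame, deviations: np.ndarray,
                    radius: int) -> np.ndarray:
    """Mean neighbour deviation within a square window, self excluded."""
    rows = obs["row"].to_numpy(int)
    cols = obs["col"].to_numpy(int)
    R, C = rows.max() + 1, cols.max() + 1
    dev_grid = np.zeros((R + 2 * radius, C + 2 * radius))
    occ_grid = np.zeros_like(dev_grid)
    dev_grid[rows + radius, cols + radius] = deviations
    occ_grid[rows + radius, cols + radius] = 1.0
    acc = np.zeros(len(obs))
    cnt = np.zeros(len(obs))
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            acc += dev_grid[rows + radius + dr, cols + radius + dc]
            cnt += occ_grid[rows + radius + dr, cols + radius + dc]
    out = np.zeros(len(obs))
    has = cnt > 0
    out[has] = acc[has] / cnt[has]
    if (~has).any():
        warnings.warn(f"{(~has).sum()} isolated plants left uncorrected")
    return out


def correct_spatial(obs: pd.DataFrame, method: str, *,
                    radius: int = 1) -> pd.DataFrame:
    """Return a copy of ``obs`` with a ``corrected`` column added."""
    if method not in METHODS:
        raise AnalysisError(f"unknown correction method {method!r}")
    for col in ("row", "col"):
        if obs[col].isna().any():
            raise AnalysisError("grid positions required for every plant")
    value = obs["value"].to_numpy(float)

    def ma_pop(v):
        dev = v - v.mean()
        work = obs.assign(value=v)
        return v - _moving_average(work, dev, radius)

    def ma_gen(v):
        work = obs.assign(value=v)
        gmean = work.groupby("line")["value"].transform("mean").to_numpy()
        return v - _moving_average(work, v - gmean, radius)

    def rowcol(v):
        return v - _rowcol_mixed(obs.assign(value=v))

    steps = {
        "none": [],
        "rowcol_mixed": [rowcol],
        "ma_population": [ma_pop],
        "ma_genotype": [ma_gen],
        "rowcol_then_ma": [rowcol, ma_pop, ma_gen],
        "ma_then_rowcol": [ma_pop, ma_gen, rowcol],
    }[method]
    v = value
    for step in steps:
        v = step(v)
    out = obs.copy()
    out["corrected"] = _recenter(v, value) if steps else value.copy()
    return out


# ---------------------------------------------------------------------------
# heritability

@dataclass(frozen=True)
class VarianceDecomposition:
    """One-way random-effects decomposition on an entry-mean basis."""

    sigma2_G: float
    sigma2_e: float
    r_bar: float
    h2: float


def heritability(obs: pd.DataFrame, *, value_col: str = "value",
                 group_col: str = "line") -> VarianceDecomposition:
    """Entry-mean broad-sense heritability from one-way ANOVA estimators.

    sigma2_e = MS_within; sigma2_G = max(0, (MS_between - MS_within) / n0)
    with n0 the unbalanced-design effective replicate number
    (N - sum n_i^2 / N) / (k - 1); h2 = sigma2_G / (sigma2_G + sigma2_e/n0).
    """
    groups = obs.groupby(group_col)[value_col]
    k = groups.ngroups
    if k < 2:
        raise AnalysisError("heritability needs at least two genotypes")
    n_i = groups.size().to_numpy(float)
    if (n_i < 2).all():
        raise AnalysisError("heritability needs replicated genotypes")
    N = n_i.sum()
    means = groups.mean()
    grand = obs[value_col].mean()
    ss_between = float((n_i * (means.to_numpy() - grand) ** 2).sum())
    ss_within = float(((obs[value_col] - obs[group_col].map(means)) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (n_i ** 2).sum() / N) / (k - 1)
    sigma2_G = max(0.0, (ms_between - ms_within) / n0)
    sigma2_e = ms_within
    denom = sigma2_G + sigma2_e / n0
    h2 = float(np.clip(sigma2_G / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return VarianceDecomposition(sigma2_G=sigma2_G, sigma2_e=sigma2_e,
                                 r_bar=float(n0), h2=h2)


# ---------------------------------------------------------------------------
# method selection and BLUPs

@dataclass
class CorrectionSelection:
    method: str
    corrected: pd.DataFrame
    report: pd.DataFrame  # method, sigma2_G, sigma2_e, h2, selected


def select_correction(obs: pd.DataFrame, *, radius: int = 1,
                      methods=METHODS) -> CorrectionSelection:
    """Apply every method and keep the one with the highest heritability."""
    rows, frames = [], {}
    best, best_h2 = None, -np.inf
    for m in methods:
        corr = correct_spatial(obs, m, radius=radius)
        vd = heritability(corr, value_col="corrected")
        frames[m] = corr
        rows.append((m, vd.sigma2_G, vd.sigma2_e, vd.h2))
        if vd.h2 > best_h2:  # strict: earlier methods win ties
            best, best_h2 = m, vd.h2
    report = pd.DataFrame(rows, columns=["method", "sigma2_G", "sigma2_e", "h2"])
    report["selected"] = report["method"] == best
    return CorrectionSelection(method=best, corrected=frames[best],
                               report=report)


def blups(obs: pd.DataFrame, *, value_col: str = "value",
          group_col: str = "line",
          vd: VarianceDecomposition | None = None) -> pd.Series:
    """Genotype BLUPs: grand mean plus shrunken line deviations.

    BLUP_i = mu + w_i (ybar_i - mu), w_i = sigma2_G/(sigma2_G + sigma2_e/r_i).
    Lines with zero replicates are absent; shrinkage never moves a line
    past its own mean.
    """
    if vd is None:
        vd = heritability(obs, value_col=value_col, group_col=group_col)
    groups = obs.groupby(group_col)[value_col]
    mu = obs[value_col].mean()
    r_i = groups.size()
    denom = vd.sigma2_G + vd.sigma2_e / r_i
    w = (vd.sigma2_G / denom).where(denom > 0, 0.0)
    pred = mu + w * (groups.mean() - mu)
    pred.name = "blup"
    return pred
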