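"""Water-balance and growth traits derived from daily platform series.

All per-time traits are expressed in thermal days (T-days): one T-day is
the heat accumulated in 24 h at a constant 20 degC. The evaluation window
runs from the day the water-deficit target is reached to harvest; its
endpoints are inputs, located by linear interpolation on the thermal-time
axis.

Trait units follow the platform convention: biomass accumulation in g fresh
weight per T-day, daily water use in g per T-day, water-use efficiency in g
fresh biomass per 100 g transpired water, specific transpiration in
g/m2/T-day, early vigor in g, leaf appearance rate in leaves per T-day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import AnalysisError

DAILY_COLS = ["plant", "day", "temp", "biomass_fw", "leaf_area", "water",
              "leaves"]


@dataclass(frozen=True)
class EvaluationWindow:
    """Thermal-time interval over which window traits are computed."""

    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise AnalysisError("evaluation window must have t_end > t_start")


def linear_response(temp: np.ndarray) -> np.ndarray:
    """Default thermal response: linear degree-day above 0 degC."""
    return np.asarray(temp, dtype=float)


def thermal_days(temps, dt_days=1.0, response: Callable = linear_response,
                 ref_temp: float = 20.0) -> np.ndarray:
    """Cumulative thermal-time coordinate for a temperature series.

    tau_i = sum_{j<=i} f(T_j) dt_j / f(ref_temp). With the default linear
    response, 24 h at a constant 20 degC accumulate exactly one T-day and
    the result is independent of the response-function choice.
    """
    temps = np.asarray(temps, dtype=float)
    dt = np.broadcast_to(np.asarray(dt_days, dtype=float), temps.shape)
    if np.any(dt < 0):
        raise AnalysisError("negative time step")
    if np.any((temps < 0) | (temps > 45)):
        raise AnalysisError("temperature outside model validity (0-45 degC)")
    incr = response(temps) * dt / response(np.array(ref_temp))
    return np.cumsum(incr)


def _interp(tau, y, t):
    """Linear interpolation with hard bounds checking."""
    tau = np.asarray(tau, float)
    y = np.asarray(y, float)
    if t < tau[0] - 1e-9 or t > tau[-1] + 1e-9:
        raise AnalysisError(
            f"time {t:.3f} outside series range [{tau[0]:.3f}, {tau[-1]:.3f}]")
    return float(np.interp(t, tau, y))


def biomass_accumulation(tau, biomass, window: EvaluationWindow) -> float:
    """Fresh-biomass gain per T-day over the evaluation window."""
    db = _interp(tau, biomass, window.t_end) - _interp(tau, biomass, window.t_start)
    return db / (window.t_end - window.t_start)


def water_use(tau, water, window: EvaluationWindow) -> float:
    """Daily water use: total transpired water per T-day over the window.

    ``water`` holds per-interval amounts (g transpired since the previous
    observation); totals at window endpoints are interpolated on the
    cumulative curve.
    """
    cum = np.cumsum(np.asarray(water, float))
    dw = _interp(tau, cum, window.t_end) - _interp(tau, cum, window.t_start)
    return dw / (window.t_end - window.t_start)


def wue(tau, biomass, water, window: EvaluationWindow) -> float:
    """Water-use efficiency: g biomass gained per 100 g water transpired."""
    cum = np.cumsum(np.asarray(water, float))
    dw = _interp(tau, cum, window.t_end) - _interp(tau, cum, window.t_start)
    if dw <= 0:
        raise AnalysisError("no water transpired in window: WUE undefined")
    db = _interp(tau, biomass, window.t_end) - _interp(tau, biomass, window.t_start)
    return 100.0 * db / dw


def specific_transpiration(tau, water, leaf_area, window: EvaluationWindow,
                           *, ratio_of_totals: bool = False) -> float:
    """Transpiration per unit leaf area (g/m2/T-day) over the window.

    Default averages per-interval ratios water_i / mean-leaf-area_i / dtau_i
    over consecutive observation pairs inside the window; with
    ``ratio_of_totals`` the single ratio of window totals is used instead.
    """
    tau = np.asarray(tau, float)
    water = np.asarray(water, float)
    la = np.asarray(leaf_area, float)
    inside = (tau >= window.t_start - 1e-9) & (tau <= window.t_end + 1e-9)
    idx = np.flatnonzero(inside)
    if idx.size < 2:
        raise AnalysisError("fewer than two observations inside window")
    if np.any(la[idx] <= 0):
        raise AnalysisError("non-positive leaf area inside window")
    pairs = zip(idx[:-1], idx[1:])
    if ratio_of_totals:
        tot_w = water[idx[1:]].sum()
        mean_la = la[idx].mean()
        dtau = tau[idx[-1]] - tau[idx[0]]
        return float(tot_w / mean_la / dtau)
    vals = []
    for i, j in pairs:
        dtau = tau[j] - tau[i]
        if dtau <= 0:
            continue
        vals.append(water[j] / ((la[i] + la[j]) / 2.0) / dtau)
    if not vals:
        raise AnalysisError("no positive-length intervals inside window")
    return float(np.mean(vals))


def early_vigor(tau, biomass, leaves, stage: float = 8.0) -> float:
    """Fresh shoot biomass at the first crossing of the leaf stage.

    The crossing time is located by linear interpolation of the leaf-count
    series in thermal time, then biomass is interpolated at that time.
    """
    tau = np.asarray(tau, float)
    leaves = np.asarray(leaves, float)
    if leaves[0] >= stage:
        return float(np.asarray(biomass, float)[0])
    above = np.flatnonzero(leaves >= stage)
    if above.size == 0:
        raise AnalysisError(f"leaf stage {stage} never reached")
    j = above[0]
    i = j - 1
    frac = (stage - leaves[i]) / (leaves[j] - leaves[i])
    t_cross = tau[i] + frac * (tau[j] - tau[i])
    return _interp(tau, biomass, t_cross)


def leaf_appearance_rate(tau, leaves) -> float:
    """OLS slope of visible leaf count against thermal time (leaves/T-day)."""
    tau = np.asarray(tau, float)
    leaves = np.asarray(leaves, float)
    if tau.size < 3:
        raise AnalysisError("need at least 3 points for leaf appearance rate")
    slope = np.polyfit(tau, leaves, 1)[0]
    return float(slope)


def response_traits(line_ww: pd.Series, line_wd: pd.Series
                    ) -> pd.Series:
    """Per-line plasticity: ratio of treatment-standardized values ww / wd.

    Values are standardized by dividing by the treatment population mean,
    so the population mean of the response trait sits near 1.
    """
    mu_ww, mu_wd = line_ww.mean(), line_wd.mean()
    if mu_ww == 0 or mu_wd == 0:
        raise AnalysisError("zero treatment mean: response trait undefined")
    res = (line_ww / mu_ww) / (line_wd / mu_wd)
    if (line_wd == 0).any():
        raise AnalysisError("zero wd value: response trait undefined")
    return res


def root_to_shoot(root_dw, shoot_dw):
    """Embryonic root DW over shoot DW (mg/mg)."""
    root_dw = np.asarray(root_dw, float)
    shoot_dw = np.asarray(shoot_dw, float)
    if np.any(shoot_dw <= 0):
        raise AnalysisError("non-positive shoot dry weight")
    return root_dw / shoot_dw


# ---------------------------------------------------------------------------
# batch derivation over a long-format daily table

def derive_platform_traits(daily: pd.DataFrame, plants: pd.DataFrame,
                           window: EvaluationWindow, *,
                           leaf_stage: float = 8.0) -> pd.DataFrame:
    """Plant-level traits for every plant in a long daily table.

    ``daily`` has columns (plant, day, temp, biomass_fw, leaf_area, water,
    leaves); ``plants`` maps plant -> (line, treatment). Leaf appearance
    rate is derived for ww plants only. Returns a tidy frame with columns
    (plant, line, treatment, trait, value).
    """
    meta = plants.set_index("plant")
    rows = []
    for plant, sub in daily.groupby("plant", sort=True):
        sub = sub.sort_values("day")
        tau = thermal_days(sub["temp"].to_numpy())
        b = sub["biomass_fw"].to_numpy()
        w = sub["water"].to_numpy()
        la = sub["leaf_area"].to_numpy()
        lv = sub["leaves"].to_numpy()
        line = meta.at[plant, "line"]
        trt = meta.at[plant, "treatment"]
        vals = {
            "biomass": biomass_accumulation(tau, b, window),
            "water_use": water_use(tau, w, window),
            "wue": wue(tau, b, w, window),
            "transpiration": specific_transpiration(tau, w, la, window),
            "early_vigor": early_vigor(tau, b, lv, leaf_stage),
        }
        if trt == "ww":
            vals["leaf_app_rate"] = leaf_appearance_rate(tau, lv)
        for trait, v in vals.items():
            rows.append((plant, line, trt, trait, v))
    return pd.DataFrame(rows, columns=["plant", "line", "treatment",
                                       "trait", "value"])


def derive_seedling_traits(seedlings: pd.DataFrame) -> pd.DataFrame:
    """Tidy seedling traits (root_dw, shoot_dw, root_to_shoot) per plant."""
    out = []
    ratio = root_to_shoot(seedlings["root_dw"], seedlings["shoot_dw"])
    for (idx, row), r in zip(seedlings.iterrows(), ratio):
        for trait, v in (("root_dw", row["root_dw"]),
                         ("shoot_dw", row["shoot_dw"]),
                         ("root_to_shoot", r)):
            out.append((row["plant"], row["line"], "seedling", trait, float(v)))
    return pd.DataFrame(out, columns=["plant", "line", "treatment",
                                      "trait", "value"])
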