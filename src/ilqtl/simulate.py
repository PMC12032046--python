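"""Synthetic introgression-library genotypes and platform phenotypes.

The generator reproduces the statistical structure the analysis assumes:

* a library of inbred lines, each carrying a Poisson number (mean 3.3) of
  donor segments with truncated-exponential lengths placed uniformly on a
  10-chromosome genome, plus the two parents (all-recurrent, all-donor);
* a gridded greenhouse experiment with eight replicates per line in each of
  two watering treatments; daily fresh biomass follows exponential growth
  in thermal time up to the stress-onset day and linear gain afterwards,
  the per-plant gain rate combining a genotype main effect, a
  genotype-by-treatment effect, planted QTL effects of carried segments, a
  smooth spatial surface over the grid, and plant-level residual noise;
* seedling root and shoot dry weights with genotype plus residual
  components, through which root-to-shoot QTLs act.

Every draw flows from the single config seed via independent substreams,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig, QTLSpec, TREATMENTS
from .errors import InvalidConfigError
from .traits import EvaluationWindow, thermal_days

RECURRENT_PARENT = "P_recurrent"
DONOR_PARENT = "P_donor"


def line_names(config: SimulationConfig) -> list[str]:
    names = [f"IL{i + 1:02d}" for i in range(config.n_lines)]
    if config.include_parents:
        names += [RECURRENT_PARENT, DONOR_PARENT]
    return names


def il_names(config: SimulationConfig) -> list[str]:
    return [f"IL{i + 1:02d}" for i in range(config.n_lines)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), stream])


# ---------------------------------------------------------------------------
# genotypes

def _marker_positions(config: SimulationConfig) -> np.ndarray:
    """Evenly spaced marker positions (bp, 1-based) on one chromosome."""
    L = config.chrom_length_mb * 1e6
    m = config.markers_per_chrom
    return np.round((np.arange(m) + 0.5) * L / m).astype(np.int64) + 1


def _draw_intervals(rng, k, L_mb, mean_mb):
    """k uniform placements with truncated-exponential lengths, in Mb."""
    lengths = np.minimum(rng.exponential(mean_mb, size=k), L_mb)
    starts = rng.uniform(0, L_mb - lengths)
    return np.column_stack([starts, starts + lengths]) if k else np.empty((0, 2))


def simulate_library(config: SimulationConfig) -> pd.DataFrame:
    """Generate the marker table (markers x lines) for the whole library."""
    markers, _ = simulate_library_with_truth(config)
    return markers


def simulate_library_with_truth(config: SimulationConfig
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """As :func:`simulate_library`, also returning the true donor intervals.

    The truth table (line, chrom, start_mb, end_mb, forced) records every
    placed introgression before marker discretization; overlapping
    intervals on one chromosome appear separately here even though they
    merge into a single called segment downstream.
    """
    config.validate()
    rng = _rng(config, 0)
    ils = il_names(config)
    L = config.chrom_length_mb

    # true donor intervals per line: {line: {chrom: [(start_mb, end_mb)]}}
    intervals = {ln: {c: [] for c in range(1, config.n_chrom + 1)}
                 for ln in ils}
    truth_rows = []
    counts = rng.poisson(config.mean_introgressions_per_line, size=len(ils))
    for ln, k in zip(ils, counts):
        chroms = rng.integers(1, config.n_chrom + 1, size=k)
        for c in chroms:
            iv = _draw_intervals(rng, 1, L, config.segment_length_mean_mb)
            intervals[ln][int(c)].append((iv[0, 0], iv[0, 1]))
            truth_rows.append((ln, int(c), iv[0, 0], iv[0, 1], False))

    # guarantee a workable carrier count at every planted QTL position
    if config.min_qtl_carriers > 0:
        for chrom, pos in sorted({(q.chrom, q.pos_mb) for q in config.qtls}):
            cov = [ln for ln in ils
                   if any(s <= pos <= e for s, e in intervals[ln][chrom])]
            deficit = config.min_qtl_carriers - len(cov)
            if deficit > 0:
                pool = [ln for ln in ils if ln not in cov]
                extra = rng.choice(pool, size=min(deficit, len(pool)),
                                   replace=False)
                for ln in extra:
                    length = min(rng.exponential(
                        config.segment_length_mean_mb), L)
                    lo = max(0.0, pos - length)
                    hi = min(pos, L - length)
                    start = rng.uniform(lo, hi) if hi > lo else lo
                    intervals[ln][chrom].append((start, start + length))
                    truth_rows.append((ln, chrom, start, start + length,
                                       True))

    pos_bp = _marker_positions(config)
    pos_mb = pos_bp / 1e6
    cols = {}
    for ln in ils:
        calls = np.full(config.n_markers, "A", dtype="U1")
        for c in range(1, config.n_chrom + 1):
            off = (c - 1) * config.markers_per_chrom
            for s, e in intervals[ln][c]:
                inside = (pos_mb >= s) & (pos_mb <= e)
                calls[off:off + config.markers_per_chrom][inside] = "B"
        if config.het_rate > 0:
            flip = rng.random(config.n_markers) < config.het_rate
            calls[flip] = "H"
        if config.missing_rate > 0:
            miss = rng.random(config.n_markers) < config.missing_rate
            calls[miss] = "N"
        cols[ln] = calls
    if config.include_parents:
        cols[RECURRENT_PARENT] = np.full(config.n_markers, "A", dtype="U1")
        cols[DONOR_PARENT] = np.full(config.n_markers, "B", dtype="U1")

    meta = pd.DataFrame({
        "marker_id": [f"SNP_{c}_{i + 1:04d}"
                      for c in range(1, config.n_chrom + 1)
                      for i in range(config.markers_per_chrom)],
        "chrom": np.repeat(np.arange(1, config.n_chrom + 1),
                           config.markers_per_chrom),
        "pos_bp": np.tile(pos_bp, config.n_chrom),
    })
    markers = pd.concat([meta, pd.DataFrame(cols)], axis=1)
    truth = pd.DataFrame(truth_rows, columns=["line", "chrom", "start_mb",
                                              "end_mb", "forced"])
    return markers, truth


def qtl_carriers(markers: pd.DataFrame, chrom: int, pos_mb: float
                 ) -> set[str]:
    """Lines scored donor-homozygous at the marker nearest to a position.

    Missing calls fall back to the nearest non-missing marker on the same
    chromosome, mirroring how a geneticist would read a graphical genotype.
    """
    from .genotypes import line_columns
    sub = markers[markers["chrom"] == chrom].reset_index(drop=True)
    if sub.empty:
        raise InvalidConfigError(f"no markers on chromosome {chrom}")
    order = np.argsort(np.abs(sub["pos_bp"].to_numpy() - pos_mb * 1e6))
    carriers = set()
    for ln in line_columns(markers):
        codes = sub[ln].to_numpy(dtype="U1")
        for i in order:
            if codes[i] != "N":
                if codes[i] == "B":
                    carriers.add(ln)
                break
    return carriers


# ---------------------------------------------------------------------------
# platform experiment

@dataclass
class PlatformExperiment:
    """Synthetic platform run: plant metadata, daily series, thermal axis."""

    plants: pd.DataFrame      # plant, line, treatment, rep, row, col
    daily: pd.DataFrame       # plant, day, temp, biomass_fw, leaf_area, water, leaves
    window: EvaluationWindow
    tau: np.ndarray           # thermal-day coordinate per calendar day
    temps: np.ndarray


def _spatial_surface(rng, rows, cols):
    """Smooth low-order polynomial surface, standardized to unit variance."""
    r = (np.arange(rows)[:, None] - (rows - 1) / 2) / max(rows - 1, 1)
    c = (np.arange(cols)[None, :] - (cols - 1) / 2) / max(cols - 1, 1)
    a = rng.normal(size=5)
    s = a[0] * r + a[1] * c + a[2] * r * c + a[3] * r ** 2 + a[4] * c ** 2
    s = s - s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def _qtl_deltas(config: SimulationConfig, markers: pd.DataFrame,
                lines: list[str], trait: str, treatment: str) -> np.ndarray:
    """Summed planted effects of carried segments for one trait/treatment."""
    delta = np.zeros(len(lines))
    ix = {ln: i for i, ln in enumerate(lines)}
    for q in config.qtls:
        if q.trait != trait or not q.applies_to(treatment):
            continue
        for ln in qtl_carriers(markers, q.chrom, q.pos_mb):
            if ln in ix:
                delta[ix[ln]] += q.effect
    return delta


def simulate_platform(config: SimulationConfig, markers: pd.DataFrame
                      ) -> PlatformExperiment:
    """Simulate the gridded two-treatment platform experiment."""
    config.validate()
    rng = _rng(config, 1)
    lines = [c for c in markers.columns
             if c not in ("marker_id", "chrom", "pos_bp")]
    n_lines = len(lines)

    days = np.arange(config.n_days)
    temps = (config.temp_mean + config.temp_amplitude *
             np.sin(2 * np.pi * days / config.temp_period_days))
    tau = thermal_days(temps)
    t_on, t_end = float(tau[config.onset_day]), float(tau[-1])
    window = EvaluationWindow(t_on, t_end)

    # plant layout
    recs = []
    for ln in lines:
        for trt in TREATMENTS:
            for rep in range(1, config.n_reps + 1):
                recs.append((f"{ln}_{trt}{rep}", ln, trt, rep))
    plants = pd.DataFrame(recs, columns=["plant", "line", "treatment", "rep"])
    n_plants = len(plants)
    if n_plants > config.grid_rows * config.grid_cols:
        raise InvalidConfigError("grid cannot hold all plants")
    cells = rng.permutation(config.grid_rows * config.grid_cols)[:n_plants]
    plants["row"] = cells // config.grid_cols
    plants["col"] = cells % config.grid_cols

    surface = _spatial_surface(rng, config.grid_rows, config.grid_cols)
    s_plant = surface[plants["row"], plants["col"]]

    # per-plant underlying window parameters for each simulated trait
    params = {}
    trt_arr = plants["treatment"].to_numpy()
    line_idx = plants["line"].map({ln: i for i, ln in enumerate(lines)}).to_numpy()
    for trait, ts in config.platform_traits.items():
        G = rng.normal(0, np.sqrt(ts.sigma2_G), size=n_lines)
        GxE = {t: rng.normal(0, np.sqrt(ts.sigma2_GxE), size=n_lines)
               for t in TREATMENTS}
        e = rng.normal(0, np.sqrt(ts.sigma2_e), size=n_plants)
        qtl = {t: _qtl_deltas(config, markers, lines, trait, t)
               for t in TREATMENTS}
        gxe = np.where(trt_arr == "wd", GxE["wd"][line_idx],
                       GxE["ww"][line_idx])
        qd = np.where(trt_arr == "wd", qtl["wd"][line_idx],
                      qtl["ww"][line_idx])
        # the wd treatment scales the whole trait distribution (so
        # heritability is preserved across treatments); planted QTL
        # effects are stated on the scale of their own treatment and are
        # added unscaled
        mult = np.where(trt_arr == "wd", ts.wd_factor, 1.0)
        params[trait] = mult * (ts.baseline + G[line_idx] + gxe +
                                np.sqrt(ts.sigma2_spatial) * s_plant + e) + qd

    b_rate = np.maximum(params["biomass"], 0.1)
    w_rate = np.maximum(params["water_use"], 1.0)
    ev = np.maximum(params["early_vigor"], 1.0)
    leaf_rate = np.maximum(params["leaf_app_rate"], 1e-3)

    # planted WUE effects act through the water channel: shift each
    # carrier's WUE (= 100 b/w) by the summed effect at fixed biomass rate
    wue_delta = np.zeros(n_plants)
    for trt in TREATMENTS:
        d = _qtl_deltas(config, markers, lines, "wue", trt)[line_idx]
        wue_delta = np.where(trt_arr == trt, wue_delta + d, wue_delta)
    base_wue = 100.0 * b_rate / w_rate
    target_wue = np.maximum(base_wue + wue_delta, 0.1)
    w_rate = 100.0 * b_rate / target_wue

    # daily trajectories (plants x days), exponential then linear in tau
    dtau = np.diff(np.concatenate([[0.0], tau]))
    rel = tau[None, :] - t_on
    pre = ev[:, None] * np.exp(config.exp_growth_rate * rel)
    post = ev[:, None] + b_rate[:, None] * rel
    biomass = np.where(rel <= 0, pre, post)
    biomass = np.maximum(biomass, 0.1)
    leaf_area = config.leaf_area_per_g * biomass
    leaves = config.initial_leaves + leaf_rate[:, None] * tau[None, :]

    weights = leaf_area * dtau[None, :]
    win_w = weights[:, config.onset_day + 1:].sum(axis=1)
    scale = (w_rate * (t_end - t_on)) / win_w
    water = weights * scale[:, None]

    daily = pd.DataFrame({
        "plant": np.repeat(plants["plant"].to_numpy(), config.n_days),
        "day": np.tile(days, n_plants),
        "temp": np.tile(temps, n_plants),
        "biomass_fw": biomass.ravel(),
        "leaf_area": leaf_area.ravel(),
        "water": water.ravel(),
        "leaves": leaves.ravel(),
    })
    return PlatformExperiment(plants=plants, daily=daily, window=window,
                              tau=tau, temps=temps)


# ---------------------------------------------------------------------------
# seedling (paper-roll) experiment

def simulate_seedling(config: SimulationConfig, markers: pd.DataFrame
                      ) -> pd.DataFrame:
    """Seedling root/shoot dry weights (mg) with planted ratio QTLs.

    Root-to-shoot QTL effects (donor minus recurrent, in ratio units) act
    multiplicatively on the carrier's root dry weight, leaving shoot DW
    untouched, so a -0.2 effect at baseline ratio 0.87 scales roots by
    1 - 0.2/0.87.
    """
    config.validate()
    rng = _rng(config, 2)
    lines = [c for c in markers.columns
             if c not in ("marker_id", "chrom", "pos_bp")]
    root = config.seedling_traits["root_dw"]
    shoot = config.seedling_traits["shoot_dw"]
    base_ratio = root.baseline / shoot.baseline

    ratio_delta = np.zeros(len(lines))
    ix = {ln: i for i, ln in enumerate(lines)}
    for q in config.qtls:
        if q.trait != "root_to_shoot":
            continue
        for ln in qtl_carriers(markers, q.chrom, q.pos_mb):
            ratio_delta[ix[ln]] += q.effect
    mult = np.maximum(1.0 + ratio_delta / base_ratio, 0.05)

    G_r = rng.normal(0, np.sqrt(root.sigma2_G), size=len(lines))
    G_s = rng.normal(0, np.sqrt(shoot.sigma2_G), size=len(lines))
    rows = []
    for i, ln in enumerate(lines):
        e_r = rng.normal(0, np.sqrt(root.sigma2_e), size=config.seedling_reps)
        e_s = rng.normal(0, np.sqrt(shoot.sigma2_e), size=config.seedling_reps)
        for rep in range(config.seedling_reps):
            r = max((root.baseline + G_r[i] + e_r[rep]) * mult[i], 0.5)
            s = max(shoot.baseline + G_s[i] + e_s[rep], 0.5)
            rows.append((f"{ln}_s{rep + 1}", ln, rep + 1, r, s))
    return pd.DataFrame(rows, columns=["plant", "line", "rep",
                                       "root_dw", "shoot_dw"])
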