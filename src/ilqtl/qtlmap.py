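"""Segment-wise QTL engine: association scan, Bonferroni control,
stepwise multi-segment refinement, and LD-based QTL clusters.

The scan compares, for every unique introgressed segment and trait, the
line-level values (BLUPs) of carriers versus non-carriers with a pooled
two-sample t-test, Bonferroni-corrected over the segments actually tested
for that trait. Significant segments connected through high-LD edges are
grouped into QTL clusters when they associate with at least two traits;
linked segments with opposite effect signs on a shared trait are kept in
separate clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .genotypes import SegmentMatrix

RESULT_COLS = ["segment", "trait", "n_carriers", "n_noncarriers", "effect",
               "effect_pct", "t", "p_raw", "p_bonferroni"]


# ---------------------------------------------------------------------------
# association scan

def segment_scan(blup: pd.DataFrame, sm: SegmentMatrix, *,
                 min_carriers: int = 3, welch: bool = False
                 ) -> pd.DataFrame:
    """Carrier-versus-noncarrier t-test for every (segment, trait) pair.

    ``blup`` is lines x traits. Segments with fewer than ``min_carriers``
    carriers (or fewer than 2 non-carriers) among the scanned lines are
    skipped; the Bonferroni multiplicity per trait counts only the
    segments actually tested for that trait. ``effect`` is carrier mean
    minus non-carrier mean; ``effect_pct`` expresses it relative to the
    non-carrier mean. Zero-variance comparisons yield NaN statistics.
    """
    lines = [ln for ln in sm.lines if ln in blup.index]
    if len(lines) < min_carriers + 2:
        raise AnalysisError("too few lines shared between BLUPs and segments")
    M = sm.matrix[lines].to_numpy(dtype=float)  # segments x lines
    n1 = M.sum(axis=1)
    n = len(lines)
    n0 = n - n1
    out = []
    for trait in blup.columns:
        y = blup.loc[lines, trait].to_numpy(float)
        ok = ~np.isnan(y)
        if not ok.all():
            Mt, yt = M[:, ok], y[ok]
        else:
            Mt, yt = M, y
        c1 = Mt.sum(axis=1)
        c0 = ok.sum() - c1
        testable = (c1 >= min_carriers) & (c0 >= 2)
        s1 = Mt @ yt
        s0 = yt.sum() - s1
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = s1 / c1
            m0 = s0 / c0
            q1 = Mt @ yt ** 2 - c1 * m1 ** 2
            q0 = (yt ** 2).sum() - (Mt @ yt ** 2) - c0 * m0 ** 2
            if welch:
                v1 = q1 / (c1 - 1)
                v0 = q0 / (c0 - 1)
                se = np.sqrt(v1 / c1 + v0 / c0)
                df = (v1 / c1 + v0 / c0) ** 2 / (
                    (v1 / c1) ** 2 / (c1 - 1) + (v0 / c0) ** 2 / (c0 - 1))
            else:
                sp2 = (q1 + q0) / (c1 + c0 - 2)
                se = np.sqrt(sp2 * (1 / c1 + 1 / c0))
                df = c1 + c0 - 2
            t = (m1 - m0) / se
            p = 2 * stats.t.sf(np.abs(t), df)
        m_tests = int(testable.sum())
        for i, sid in enumerate(sm.segment_ids):
            if not testable[i]:
                continue
            eff = m1[i] - m0[i]
            eff_pct = 100.0 * eff / m0[i] if m0[i] != 0 else np.nan
            out.append((sid, trait, int(c1[i]), int(c0[i]), eff, eff_pct,
                        t[i], p[i],
                        min(1.0, m_tests * p[i]) if np.isfinite(p[i])
                        else np.nan))
    return pd.DataFrame(out, columns=RESULT_COLS)


# ---------------------------------------------------------------------------
# stepwise refinement

def _aic(rss: float, n: int, k: int) -> float:
    if rss <= 0:
        rss = 1e-300
    return n * np.log(rss / n) + 2 * (k + 1)


def _fit_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return float(((y - fitted) ** 2).sum())


@dataclass
class StepwiseResult:
    retained: list
    effects: pd.Series            # joint-model coefficients
    aliased: dict = field(default_factory=dict)  # dropped -> representative


def stepwise_refine(y: pd.Series, design: pd.DataFrame, *,
                    criterion: str = "aic", p_enter: float = 0.01,
                    p_drop: float = 0.05) -> StepwiseResult:
    """Forward-backward selection over significant segments for one trait.

    ``design`` holds 0/1 carrier columns (one per significant segment)
    indexed by line. Perfectly collinear duplicate-carrier columns are
    collapsed to one representative beforehand and reported as aliases.
    With ``criterion='aic'`` a step is taken when it lowers the AIC;
    ``criterion='pvalue'`` uses entry/stay thresholds instead.
    """
    if design.shape[1] == 0:
        return StepwiseResult(retained=[], effects=pd.Series(dtype=float))
    common = [ln for ln in design.index if ln in y.index]
    D = design.loc[common]
    yv = y.loc[common].to_numpy(float)
    n = len(common)

    # alias perfectly collinear carrier sets (deterministic: first kept)
    aliased, keep, seen = {}, [], {}
    for col in D.columns:
        key = tuple(D[col].to_numpy(int))
        if key in seen:
            aliased[col] = seen[key]
        else:
            seen[key] = col
            keep.append(col)
    D = D[keep]

    current: list = []
    ones = np.ones((n, 1))

    def model_rss(cols):
        X = np.hstack([ones, D[cols].to_numpy(float)]) if cols else ones
        return _fit_rss(X, yv)

    improved = True
    while improved:
        improved = False
        # forward
        if criterion == "aic":
            base = _aic(model_rss(current), n, len(current))
            best_col, best_score = None, base
            for col in D.columns:
                if col in current:
                    continue
                score = _aic(model_rss(current + [col]), n, len(current) + 1)
                if score < best_score - 1e-9:
                    best_col, best_score = col, score
            if best_col is not None:
                current.append(best_col)
                improved = True
            # backward
            base = _aic(model_rss(current), n, len(current))
            best_col, best_score = None, base
            for col in list(current):
                rest = [c for c in current if c != col]
                score = _aic(model_rss(rest), n, len(rest))
                if score < best_score - 1e-9:
                    best_col, best_score = col, score
            if best_col is not None:
                current.remove(best_col)
                improved = True
        else:  # p-value criterion
            rss0 = model_rss(current)
            best_col, best_p = None, p_enter
            for col in D.columns:
                if col in current:
                    continue
                rss1 = model_rss(current + [col])
                df2 = n - len(current) - 2
                if df2 <= 0 or rss1 <= 0:
                    continue
                f = (rss0 - rss1) / (rss1 / df2)
                pv = stats.f.sf(f, 1, df2)
                if pv < best_p:
                    best_col, best_p = col, pv
            if best_col is not None:
                current.append(best_col)
                improved = True
            rss_full = model_rss(current)
            worst_col, worst_p = None, p_drop
            for col in list(current):
                rest = [c for c in current if c != col]
                rss_r = model_rss(rest)
                df2 = n - len(current) - 1
                if df2 <= 0 or rss_full <= 0:
                    continue
                f = (rss_r - rss_full) / (rss_full / df2)
                pv = stats.f.sf(f, 1, df2)
                if pv > worst_p:
                    worst_col, worst_p = col, pv
            if worst_col is not None:
                current.remove(worst_col)
                improved = True

    if current:
        X = np.hstack([ones, D[current].to_numpy(float)])
        coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
        effects = pd.Series(coef[1:], index=current)
    else:
        effects = pd.Series(dtype=float)
    return StepwiseResult(retained=list(current), effects=effects,
                          aliased=aliased)


# ---------------------------------------------------------------------------
# QTL clusters

@dataclass
class QTLCluster:
    id: str
    members: list
    traits: dict                 # trait -> effect sign (+1/-1)
    chrom: int
    start_bp: int
    end_bp: int


def build_clusters(results: pd.DataFrame, ld_adj: pd.DataFrame,
                   meta: pd.DataFrame, *, alpha: float = 0.01
                   ) -> list[QTLCluster]:
    """Group significant, LD-linked segments into multi-trait QTL clusters.

    Segments with Bonferroni p < alpha for at least one trait form nodes;
    high-LD edges connect them unless the two segments show opposite
    effect signs on a shared significant trait (such pairs stay apart).
    A connected component qualifies as a cluster when the union of its
    members' associated traits has size >= 2. Members connected only
    through a conflicting pair are split greedily in canonical
    (chrom, start) order, so the output is independent of input order.
    """
    sig = results[results["p_bonferroni"] < alpha]
    if sig.empty:
        return []
    seg_traits: dict[str, dict] = {}
    for _, row in sig.iterrows():
        seg_traits.setdefault(row["segment"], {})[row["trait"]] = (
            1 if row["effect"] >= 0 else -1)
    nodes = sorted(seg_traits,
                   key=lambda s: (int(meta.loc[s, "chrom"]),
                                  int(meta.loc[s, "start_bp"]), s))

    def conflict(a: str, b: str) -> bool:
        shared = seg_traits[a].keys() & seg_traits[b].keys()
        return any(seg_traits[a][t] != seg_traits[b][t] for t in shared)

    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if a in ld_adj.index and b in ld_adj.columns and \
                    bool(ld_adj.loc[a, b]) and not conflict(a, b):
                G.add_edge(a, b)

    clusters = []
    for comp in nx.connected_components(G):
        members = sorted(comp, key=nodes.index)
        union_traits = set().union(*(seg_traits[m].keys() for m in members))
        if len(union_traits) < 2:
            continue
        # enforce the no-conflicting-pair invariant inside each cluster
        groups: list[list] = []
        for m in members:
            placed = False
            for g in groups:
                if not any(conflict(m, x) for x in g):
                    g.append(m)
                    placed = True
                    break
            if not placed:
                groups.append([m])
        for g in groups:
            traits: dict = {}
            for m in g:
                traits.update(seg_traits[m])
            clusters.append((g, traits))
    # canonical order and ids
    def span(g):
        ch = int(meta.loc[g[0], "chrom"])
        return (ch, int(min(meta.loc[m, "start_bp"] for m in g)),
                int(max(meta.loc[m, "end_bp"] for m in g)))

    clusters.sort(key=lambda ct: span(ct[0]) + (tuple(ct[0]),))
    out = []
    for i, (g, traits) in enumerate(clusters, start=1):
        ch, s, e = span(g)
        out.append(QTLCluster(id=f"Q{i}", members=g, traits=traits,
                              chrom=ch, start_bp=s, end_bp=e))
    return out


def scan_report(clusters: list[QTLCluster], results: pd.DataFrame
                ) -> pd.DataFrame:
    """Ranked per-cluster table with effects in units and percent.

    One row per cluster-trait, carrying the member segment with the
    smallest Bonferroni p for that trait; rows sorted by cluster min p,
    ties broken by segment label.
    """
    if not clusters:
        return pd.DataFrame(columns=["cluster", "chrom", "start_bp", "end_bp",
                                     "members", "trait", "segment", "effect",
                                     "effect_pct", "neg_log10_p"])
    keyed = results.set_index(["segment", "trait"])
    rows = []
    for cl in clusters:
        for trait in sorted(cl.traits):
            best = None
            for m in cl.members:
                if (m, trait) in keyed.index:
                    rec = keyed.loc[(m, trait)]
                    if best is None or rec["p_bonferroni"] < best[1]["p_bonferroni"]:
                        best = (m, rec)
            if best is None:
                continue
            m, rec = best
            p = max(rec["p_bonferroni"], 1e-300)
            rows.append((cl.id, cl.chrom, cl.start_bp, cl.end_bp,
                         ",".join(cl.members), trait, m, rec["effect"],
                         rec["effect_pct"], -np.log10(p)))
    rep = pd.DataFrame(rows, columns=["cluster", "chrom", "start_bp",
                                      "end_bp", "members", "trait",
                                      "segment", "effect", "effect_pct",
                                      "neg_log10_p"])
    order = rep.groupby("cluster")["neg_log10_p"].transform("max")
    rep = rep.assign(_o=-order).sort_values(["_o", "cluster", "segment"]) \
        .drop(columns="_o").reset_index(drop=True)
    return rep
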