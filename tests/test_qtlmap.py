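"""Segment association scan, stepwise refinement, QTL clusters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ilqtl import qtlmap as qm
from ilqtl.genotypes import SegmentMatrix


def make_sm(matrix: dict, meta_rows=None):
    """SegmentMatrix from {segment_id: {line: 0/1}}."""
    mat = pd.DataFrame(matrix).T
    ids = list(mat.index)
    if meta_rows is None:
        meta_rows = {sid: (1, 10 * i + 1, 10 * i + 5)
                     for i, sid in enumerate(ids)}
    meta = pd.DataFrame(
        {"chrom": [meta_rows[s][0] for s in ids],
         "start_bp": [meta_rows[s][1] for s in ids],
         "end_bp": [meta_rows[s][2] for s in ids],
         "state": "B", "label": ids}, index=pd.Index(ids, name="segment_id"))
    return SegmentMatrix(meta=meta, matrix=mat)


class TestSegmentScan:
    def test_hand_computed_pooled_t(self):
        lines = [f"L{i}" for i in range(6)]
        sm = make_sm({"s1": dict(zip(lines, [1, 1, 1, 0, 0, 0]))})
        blup = pd.DataFrame({"trait": [2, 3, 4, 4, 5, 6.0]}, index=lines)
        res = qm.segment_scan(blup, sm, min_carriers=3)
        row = res.iloc[0]
        assert row["effect"] == pytest.approx(-2.0)
        assert row["t"] == pytest.approx(-2.449, abs=1e-3)
        assert row["p_raw"] == pytest.approx(0.0705, abs=2e-3)
        ref = stats.ttest_ind([2, 3, 4], [4, 5, 6], equal_var=True)
        assert row["p_raw"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_bonferroni_counts_tested_segments(self):
        rng = np.random.default_rng(4)
        lines = [f"L{i}" for i in range(20)]
        cols = {}
        for i in range(12):
            cols[f"s{i}"] = dict(zip(lines, rng.integers(0, 2, 20)))
        cols["rare"] = dict(zip(lines, [1] + [0] * 19))  # skipped
        sm = make_sm(cols)
        blup = pd.DataFrame({"y": rng.normal(0, 1, 20)}, index=lines)
        res = qm.segment_scan(blup, sm, min_carriers=3)
        assert "rare" not in set(res["segment"])
        m = len(res)
        assert np.allclose(res["p_bonferroni"],
                           np.minimum(1.0, res["p_raw"] * m))

    def test_min_bonferroni_arithmetic(self):
        assert min(1.0, 399 * 0.0002) == pytest.approx(0.0798)

    def test_identical_groups_give_null_result(self):
        lines = [f"L{i}" for i in range(8)]
        sm = make_sm({"s1": dict(zip(lines, [1, 1, 1, 1, 0, 0, 0, 0]))})
        blup = pd.DataFrame({"y": [5, 6, 5, 6, 5, 6, 5, 6.0]}, index=lines)
        res = qm.segment_scan(blup, sm, min_carriers=3)
        assert res.iloc[0]["effect"] == pytest.approx(0.0)
        assert res.iloc[0]["p_raw"] == pytest.approx(1.0)

    def test_effect_pct_relative_to_noncarrier_mean(self):
        # a +0.76 effect on a 3.78 non-carrier mean reads as +20.1%
        lines = [f"L{i}" for i in range(10)]
        x = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y = np.where(x == 1, 3.78 + 0.76, 3.78)
        sm = make_sm({"s1": dict(zip(lines, x))})
        blup = pd.DataFrame({"y": y}, index=lines)
        res = qm.segment_scan(blup, sm, min_carriers=3)
        assert res.iloc[0]["effect_pct"] == pytest.approx(20.1, abs=0.05)

    def test_welch_option(self, rng):
        lines = [f"L{i}" for i in range(14)]
        x = rng.integers(0, 2, 14)
        while x.sum() < 3 or x.sum() > 11:
            x = rng.integers(0, 2, 14)
        y = rng.normal(0, 1, 14)
        sm = make_sm({"s1": dict(zip(lines, x))})
        blup = pd.DataFrame({"y": y}, index=lines)
        res = qm.segment_scan(blup, sm, welch=True)
        ref = stats.ttest_ind(y[x == 1], y[x == 0], equal_var=False)
        assert res.iloc[0]["p_raw"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestStepwise:
    def _exhaustive_best_subset(self, y, D):
        """AIC-best subset by full enumeration (oracle)."""
        n = len(y)
        best, best_aic = [], np.inf
        cols = list(D.columns)
        for k in range(len(cols) + 1):
            for combo in itertools.combinations(cols, k):
                X = np.column_stack([np.ones(n)] +
                                    [D[c].to_numpy(float) for c in combo])
                rss = float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0])
                             ** 2).sum())
                aic = n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)
                if aic < best_aic - 1e-9:
                    best, best_aic = list(combo), aic
        return sorted(best)

    def test_signal_segment_retained_noise_dropped(self):
        rng = np.random.default_rng(11)
        lines = [f"L{i}" for i in range(40)]
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        y = 3.0 * a + rng.normal(0, 0.5, 40)
        D = pd.DataFrame({"A": a, "B": b}, index=lines)
        ys = pd.Series(y, index=lines)
        out = qm.stepwise_refine(ys, D)
        assert out.retained == ["A"]
        assert sorted(out.retained) == self._exhaustive_best_subset(y, D)
        assert out.effects["A"] == pytest.approx(3.0, abs=0.5)

    def test_matches_exhaustive_oracle_random(self):
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            n = 30
            lines = [f"L{i}" for i in range(n)]
            D = pd.DataFrame({f"s{j}": rng.integers(0, 2, n)
                              for j in range(4)}, index=lines)
            beta = np.array([2.0, 0, 0, 1.5])
            y = D.to_numpy() @ beta + rng.normal(0, 0.8, n)
            out = qm.stepwise_refine(pd.Series(y, index=lines), D)
            oracle = self._exhaustive_best_subset(y, D)
            # greedy forward-backward can differ from best-subset in
            # principle; on these well-separated fixtures it must agree
            assert sorted(out.retained) == oracle

    def test_collinear_aliasing(self):
        rng = np.random.default_rng(2)
        lines = [f"L{i}" for i in range(20)]
        a = rng.integers(0, 2, 20)
        D = pd.DataFrame({"A": a, "Twin": a.copy()}, index=lines)
        y = pd.Series(2.0 * a + rng.normal(0, 0.3, 20), index=lines)
        out = qm.stepwise_refine(y, D)
        assert out.retained == ["A"]
        assert out.aliased == {"Twin": "A"}

    def test_empty_input_empty_output(self):
        out = qm.stepwise_refine(pd.Series(dtype=float),
                                 pd.DataFrame(index=[]))
        assert out.retained == []

    def test_retained_subset_and_rss_improvement(self, rng):
        lines = [f"L{i}" for i in range(30)]
        D = pd.DataFrame({f"s{j}": rng.integers(0, 2, 30)
                          for j in range(3)}, index=lines)
        y = pd.Series(D["s0"] * 2 + rng.normal(0, 1, 30), index=lines)
        out = qm.stepwise_refine(y, D)
        assert set(out.retained) <= set(D.columns)


def result_row(segment, trait, effect, p):
    return dict(segment=segment, trait=trait, n_carriers=5,
                n_noncarriers=10, effect=effect,
                effect_pct=effect * 10, t=3.0, p_raw=p / 100,
                p_bonferroni=p)


def make_meta(ids, chrom=1):
    return pd.DataFrame({"chrom": chrom,
                         "start_bp": [10 * i for i in range(len(ids))],
                         "end_bp": [10 * i + 5 for i in range(len(ids))],
                         "state": "B", "label": ids},
                        index=pd.Index(ids, name="segment_id"))


def adjacency(ids, edges):
    adj = pd.DataFrame(False, index=ids, columns=ids)
    for a, b in edges:
        adj.loc[a, b] = adj.loc[b, a] = True
    return adj


class TestClusters:
    def test_two_trait_rule_groups_linked_segments(self):
        res = pd.DataFrame([result_row("S1", "biomass", +1.0, 0.001),
                            result_row("S1", "wue", +0.5, 0.002),
                            result_row("S2", "wue", +0.4, 0.003)])
        out = qm.build_clusters(res, adjacency(["S1", "S2"], [("S1", "S2")]),
                                make_meta(["S1", "S2"]))
        assert len(out) == 1
        assert set(out[0].members) == {"S1", "S2"}
        assert set(out[0].traits) == {"biomass", "wue"}

    def test_single_trait_segment_is_not_a_cluster(self):
        res = pd.DataFrame([result_row("S1", "biomass", +1.0, 0.001)])
        out = qm.build_clusters(res, adjacency(["S1"], []),
                                make_meta(["S1"]))
        assert out == []

    def test_opposite_signs_split_linked_segments(self):
        res = pd.DataFrame([
            result_row("S1", "wue", +1.0, 0.001),
            result_row("S1", "biomass", +1.0, 0.001),
            result_row("S2", "wue", -1.0, 0.002),
            result_row("S2", "early_vigor", +1.0, 0.002),
        ])
        out = qm.build_clusters(res, adjacency(["S1", "S2"], [("S1", "S2")]),
                                make_meta(["S1", "S2"]))
        assert len(out) == 2
        assert {tuple(c.members) for c in out} == {("S1",), ("S2",)}

    def test_insignificant_segments_excluded(self):
        res = pd.DataFrame([result_row("S1", "biomass", 1.0, 0.5),
                            result_row("S1", "wue", 1.0, 0.4)])
        assert qm.build_clusters(res, adjacency(["S1"], []),
                                 make_meta(["S1"])) == []

    def test_order_invariance(self):
        rows = [result_row("S1", "biomass", +1, 0.001),
                result_row("S1", "wue", +1, 0.001),
                result_row("S2", "wue", +1, 0.002),
                result_row("S3", "biomass", -1, 0.003),
                result_row("S3", "early_vigor", -1, 0.003)]
        ids = ["S1", "S2", "S3"]
        adj = adjacency(ids, [("S1", "S2")])
        meta = make_meta(ids)
        a = qm.build_clusters(pd.DataFrame(rows), adj, meta)
        b = qm.build_clusters(pd.DataFrame(rows[::-1]), adj, meta)
        assert [(c.id, tuple(c.members)) for c in a] == \
            [(c.id, tuple(c.members)) for c in b]

    def test_conflict_via_intermediary_still_split(self):
        # S1(+) and S3(-) on wue conflict but are linked through S2
        res = pd.DataFrame([
            result_row("S1", "wue", +1, 0.001),
            result_row("S1", "biomass", +1, 0.001),
            result_row("S2", "biomass", +1, 0.002),
            result_row("S2", "early_vigor", +1, 0.002),
            result_row("S3", "wue", -1, 0.003),
            result_row("S3", "biomass", +1, 0.003),
        ])
        ids = ["S1", "S2", "S3"]
        out = qm.build_clusters(
            res, adjacency(ids, [("S1", "S2"), ("S2", "S3")]),
            make_meta(ids))
        for c in out:
            assert not ({"S1", "S3"} <= set(c.members))


class TestScanReport:
    def test_effect_pct_presentation(self):
        res = pd.DataFrame([result_row("S1", "biomass", +0.76, 0.001),
                            result_row("S1", "wue", +0.6, 0.004)])
        res.loc[0, "effect_pct"] = 100 * 0.76 / 3.78
        clusters = qm.build_clusters(res, adjacency(["S1"], []),
                                     make_meta(["S1"]))
        rep = qm.scan_report(clusters, res)
        row = rep[rep["trait"] == "biomass"].iloc[0]
        assert row["effect_pct"] == pytest.approx(20.1, abs=0.05)

    def test_empty_clusters_empty_table(self):
        rep = qm.scan_report([], pd.DataFrame(columns=qm.RESULT_COLS))
        assert rep.empty

    def test_sorted_by_significance(self):
        res = pd.DataFrame([
            result_row("S1", "biomass", 1, 0.009),
            result_row("S1", "wue", 1, 0.008),
            result_row("S9", "biomass", 1, 0.0001),
            result_row("S9", "wue", 1, 0.0002),
        ])
        clusters = qm.build_clusters(res, adjacency(["S1", "S9"], []),
                                     make_meta(["S1", "S9"]))
        rep = qm.scan_report(clusters, res)
        first_cluster = rep.iloc[0]["cluster"]
        members = rep[rep["cluster"] == first_cluster]["segment"]
        assert set(members) == {"S9"}
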