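"""Marker filtering, segment calling, unique-segment matrix, coverage, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ilqtl import genotypes as gt
from ilqtl.errors import AnalysisError

from conftest import make_marker_table


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_force_segments(codes, positions, ids, bridge=True, max_bridge=2):
    """Independent run-length scan over one chromosome's codes."""
    segs = []
    i, n = 0, len(codes)
    while i < n:
        if codes[i] in ("B", "H"):
            state = codes[i]
            j = i
            last_good = i
            k = i + 1
            while k < n:
                if codes[k] == state:
                    last_good = k
                    k += 1
                elif codes[k] == "N":
                    # look ahead: may bridge up to max_bridge Ns
                    run_n = 0
                    kk = k
                    while kk < n and codes[kk] == "N":
                        run_n += 1
                        kk += 1
                    if bridge and run_n <= max_bridge and kk < n and \
                            codes[kk] == state:
                        last_good = kk
                        k = kk + 1
                    else:
                        break
                else:
                    break
            segs.append((positions[j], positions[last_good], state, ids[j]))
            i = last_good + 1
        else:
            i += 1
    return segs


# ---------------------------------------------------------------------------
# filter_markers

class TestFilterMarkers:
    def test_missing_rule_strict_boundary(self):
        # 10 lines: exactly 10% missing retained, 11%+ (i.e. 2/10) dropped
        lines = {f"L{i}": "AB"[i % 2] for i in range(10)}
        tbl = make_marker_table({ln: c * 3 for ln, c in lines.items()})
        as_np = tbl.copy()
        as_np.loc[0, "L0"] = "N"                    # 10% missing -> keep
        as_np.loc[1, "L0"] = "N"
        as_np.loc[1, "L2"] = "N"                    # 20% missing -> drop
        kept, report = gt.filter_markers(as_np, max_missing=0.10)
        assert list(kept["marker_id"]) == ["SNP1", "SNP3"]
        assert report["missing_gt_threshold"] == 1

    def test_monomorphic_and_no_position_dropped(self):
        tbl = make_marker_table({"L1": "AAB", "L2": "ABA"})
        tbl.loc[2, "pos_bp"] = np.nan
        kept, report = gt.filter_markers(tbl)
        # marker 1 all-A monomorphic, marker 3 lacks position
        assert list(kept["marker_id"]) == ["SNP2"]
        assert report["monomorphic"] == 1 and report["no_position"] == 1

    def test_idempotent(self, small_library):
        once, _ = gt.filter_markers(small_library)
        twice, rep = gt.filter_markers(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep["retained"] == rep["input"]

    def test_empty_result_raises(self):
        tbl = make_marker_table({"L1": "AAA", "L2": "AAA"})
        with pytest.raises(AnalysisError, match="no markers retained"):
            gt.filter_markers(tbl)


# ---------------------------------------------------------------------------
# call_segments

class TestCallSegments:
    def test_hand_example_two_states(self):
        tbl = make_marker_table({"L1": "ABBAHA"})
        segs = gt.call_segments(tbl, "L1")
        assert len(segs) == 2
        b, h = segs.iloc[0], segs.iloc[1]
        assert (b["state"], b["start_bp"], b["end_bp"], b["label"]) == \
            ("B", 2_000_000, 3_000_000, "SNP2")
        assert (h["state"], h["start_bp"], h["end_bp"], h["label"]) == \
            ("H", 5_000_000, 5_000_000, "SNP5")

    def test_missing_bridging(self):
        tbl = make_marker_table({"L1": "ABNBA"})
        segs = gt.call_segments(tbl, "L1", bridge_missing=True)
        assert len(segs) == 1
        assert segs.iloc[0]["start_bp"] == 2_000_000
        assert segs.iloc[0]["end_bp"] == 4_000_000
        unbridged = gt.call_segments(tbl, "L1", bridge_missing=False)
        assert len(unbridged) == 2

    def test_all_recurrent_line_empty(self):
        tbl = make_marker_table({"L1": "AAAA"})
        assert gt.call_segments(tbl, "L1").empty

    def test_unsorted_input_raises(self):
        tbl = make_marker_table({"L1": "AB"}, pos=[2_000_000, 1_000_000])
        with pytest.raises(AnalysisError, match="sorted"):
            gt.call_segments(tbl, "L1")

    def test_midpoint_extension(self):
        tbl = make_marker_table({"L1": "ABBA"})
        segs = gt.call_segments(tbl, "L1", extend_midpoint=True)
        assert segs.iloc[0]["start_bp"] == 1_500_000
        assert segs.iloc[0]["end_bp"] == 3_500_000

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 50))
        codes = "".join(rng.choice(list("ABHN"), size=n,
                                   p=[0.55, 0.25, 0.1, 0.1]))
        tbl = make_marker_table({"L1": codes})
        segs = gt.call_segments(tbl, "L1")
        expected = brute_force_segments(
            list(codes), tbl["pos_bp"].tolist(), tbl["marker_id"].tolist())
        got = [(r["start_bp"], r["end_bp"], r["state"], r["label"])
               for _, r in segs.iterrows()]
        assert got == expected

    def test_losslessness(self, small_library):
        """Segments plus recurrent gaps reconstruct the genotype vector."""
        filtered, _ = gt.filter_markers(small_library)
        line = gt.line_columns(filtered)[3]
        segs = gt.call_segments(filtered, line)
        rebuilt = pd.Series("A", index=filtered.index)
        for _, s in segs.iterrows():
            on = (filtered["chrom"] == s["chrom"]) & \
                 (filtered["pos_bp"] >= s["start_bp"]) & \
                 (filtered["pos_bp"] <= s["end_bp"])
            rebuilt[on] = s["state"]
        orig = filtered[line]
        ok = (orig == "N") | (rebuilt == orig)
        # bridged missing positions are the only allowed mismatches
        assert ok[orig != "N"].all()


# ---------------------------------------------------------------------------
# build_segment_matrix

class TestSegmentMatrix:
    def _segs(self, rows):
        return pd.DataFrame(rows, columns=gt.SEGMENT_COLS)

    def test_identical_spans_merge(self):
        segs = self._segs([
            ("L1", 1, 100, 200, "B", "S1", 2),
            ("L2", 1, 100, 200, "B", "S1", 2),
        ])
        sm = gt.build_segment_matrix(segs)
        assert len(sm.meta) == 1
        assert sm.matrix.iloc[0].sum() == 2

    def test_disjoint_spans_distinct(self):
        segs = self._segs([
            ("L1", 1, 100, 200, "B", "S1", 2),
            ("L2", 1, 300, 400, "B", "S2", 2),
        ])
        sm = gt.build_segment_matrix(segs)
        assert len(sm.meta) == 2

    def test_containment_assigns_carriers(self):
        segs = self._segs([
            ("L1", 1, 100, 500, "B", "S1", 5),
            ("L2", 1, 200, 300, "B", "S2", 2),
        ])
        sm = gt.build_segment_matrix(segs, containment=True)
        inner = sm.meta.index[sm.meta["start_bp"] == 200][0]
        assert set(sm.carriers(inner)) == {"L1", "L2"}
        sm_exact = gt.build_segment_matrix(segs, containment=False)
        inner = sm_exact.meta.index[sm_exact.meta["start_bp"] == 200][0]
        assert set(sm_exact.carriers(inner)) == {"L2"}

    def test_matches_pairwise_oracle(self, rng):
        rows = []
        for li in range(8):
            for _ in range(rng.integers(1, 4)):
                s = int(rng.integers(0, 900))
                e = s + int(rng.integers(10, 300))
                rows.append((f"L{li}", 1, s, e, "B", f"S{s}", 1))
        segs = self._segs(rows)
        sm = gt.build_segment_matrix(segs, containment=True)
        for sid, meta in sm.meta.iterrows():
            for line in sm.lines:
                mine = [r for r in rows if r[0] == line]
                expect = any(r[2] <= meta["start_bp"] and
                             r[3] >= meta["end_bp"] for r in mine)
                assert bool(sm.matrix.loc[sid, line]) == expect


# ---------------------------------------------------------------------------
# coverage

class TestCoverage:
    def test_disjoint_union(self):
        segs = pd.DataFrame([
            ("L1", 1, 1, 40_000_000, "B", "S1", 5),
            ("L2", 1, 50_000_000, 90_000_000, "B", "S2", 5),
        ], columns=gt.SEGMENT_COLS)
        out = gt.coverage_stats(segs, {1: 100_000_000})
        assert out["coverage"] == pytest.approx(0.79999999, abs=1e-6)

    def test_identical_spans(self):
        segs = pd.DataFrame([
            ("L1", 1, 10, 30, "B", "S1", 2),
            ("L2", 1, 10, 30, "B", "S1", 2),
        ], columns=gt.SEGMENT_COLS)
        out = gt.coverage_stats(segs, {1: 100})
        assert out["coverage"] == pytest.approx(0.2)

    def test_matches_discretized_oracle(self, rng):
        genome = {1: 100_000, 2: 80_000}
        rows = []
        for li in range(6):
            for c in (1, 2):
                s = int(rng.integers(0, genome[c] - 1000))
                e = s + int(rng.integers(500, 20_000))
                rows.append((f"L{li}", c, s, min(e, genome[c]), "B", "S", 1))
        segs = pd.DataFrame(rows, columns=gt.SEGMENT_COLS)
        out = gt.coverage_stats(segs, genome)
        covered = 0
        for c, L in genome.items():
            grid = np.zeros(L, dtype=bool)
            for r in rows:
                if r[1] == c:
                    grid[r[2]:r[3]] = True
            covered += grid.sum()
        assert out["coverage"] == pytest.approx(covered / sum(genome.values()),
                                                rel=1e-9)

    def test_zero_genome_raises(self):
        segs = pd.DataFrame(columns=gt.SEGMENT_COLS)
        with pytest.raises(AnalysisError):
            gt.coverage_stats(segs, {1: 0})


# ---------------------------------------------------------------------------
# Fisher LD

class TestSegmentLD:
    def test_perfect_association_table(self):
        # carriers split 5/5 with perfect co-occurrence: p = 2/C(10,5)
        assert gt.fisher_exact_two_sided(5, 0, 0, 5) == \
            pytest.approx(2 / 252, abs=1e-12)

    def test_independent_table(self):
        assert gt.fisher_exact_two_sided(3, 2, 2, 3) == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = gt.fisher_exact_two_sided(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_matrix_symmetric_unit_diagonal(self):
        mat = pd.DataFrame(
            [[1, 1, 0, 0, 1, 0], [1, 1, 0, 0, 1, 0], [0, 1, 1, 0, 0, 1]],
            index=["s1", "s2", "s3"], columns=list("ABCDEF"))
        meta = pd.DataFrame({"chrom": [1, 1, 1], "start_bp": [1, 2, 3],
                             "end_bp": [5, 6, 7], "state": "B",
                             "label": ["s1", "s2", "s3"]},
                            index=["s1", "s2", "s3"])
        sm = gt.SegmentMatrix(meta=meta, matrix=mat)
        p, adj, degen = gt.segment_ld(sm)
        assert np.allclose(p.to_numpy(), p.to_numpy().T)
        assert np.allclose(np.diag(p.to_numpy()), 1.0)
        assert not degen

    def test_degenerate_segment_flagged(self):
        mat = pd.DataFrame([[1, 1, 1], [1, 0, 1]],
                           index=["all", "s2"], columns=list("XYZ"))
        meta = pd.DataFrame({"chrom": 1, "start_bp": [1, 2],
                             "end_bp": [3, 4], "state": "B",
                             "label": ["all", "s2"]}, index=["all", "s2"])
        p, adj, degen = gt.segment_ld(gt.SegmentMatrix(meta=meta, matrix=mat))
        assert degen == ["all"]
        assert p.loc["all", "s2"] == 1.0
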