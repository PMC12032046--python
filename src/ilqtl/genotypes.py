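"""Marker QC, introgression-segment calling, coverage and segment LD.

A genotype table holds one row per SNP marker with three metadata columns
(``marker_id``, ``chrom``, ``pos_bp``) followed by one column per line.
Calls are single characters: ``A`` recurrent-parent homozygote, ``B`` donor
homozygote, ``H`` heterozygote, ``N`` missing.

Coordinates are 1-based closed spans in bp; segment lengths are reported as
``(end - start) / 1e6`` Mb.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ParseError

META_COLS = ["marker_id", "chrom", "pos_bp"]
VALID_CODES = frozenset("ABHN")

SEGMENT_COLS = ["line", "chrom", "start_bp", "end_bp", "state", "label",
                "n_markers"]


def line_columns(markers: pd.DataFrame) -> list[str]:
    """Names of the per-line genotype columns."""
    return [c for c in markers.columns if c not in META_COLS]


def _check_sorted(markers: pd.DataFrame) -> None:
    key = markers[["chrom", "pos_bp"]]
    if not (key.sort_values(["chrom", "pos_bp"]).index == key.index).all():
        raise AnalysisError("marker table must be sorted by (chrom, pos_bp)")


# ---------------------------------------------------------------------------
# marker QC

def filter_markers(markers: pd.DataFrame, max_missing: float = 0.10
                   ) -> tuple[pd.DataFrame, dict]:
    """Drop markers that cannot inform segment calling.

    A marker is removed when it is monomorphic across lines (all non-missing
    calls identical), when its physical position is unknown, or when its
    missing fraction exceeds ``max_missing`` (strict inequality: a marker
    missing in exactly 10% of lines is retained at the default threshold).

    Returns the filtered table and a per-reason report; a marker failing
    several rules is counted under each.
    """
    lines = line_columns(markers)
    if not lines:
        raise ParseError("marker table has no line columns")
    calls = markers[lines].to_numpy(dtype="U1")

    no_pos = markers["pos_bp"].isna().to_numpy() | markers["chrom"].isna().to_numpy()
    missing_frac = (calls == "N").mean(axis=1)
    too_missing = missing_frac > max_missing

    mono = np.ones(len(markers), dtype=bool)
    for code in "ABH":
        has = (calls == code).any(axis=1)
        other = ((calls != code) & (calls != "N")).any(axis=1)
        mono &= ~(has & other)

    drop = no_pos | too_missing | mono
    report = {
        "input": len(markers),
        "monomorphic": int(mono.sum()),
        "no_position": int(no_pos.sum()),
        "missing_gt_threshold": int(too_missing.sum()),
        "retained": int((~drop).sum()),
    }
    kept = markers.loc[~drop].reset_index(drop=True)
    if kept.empty:
        raise AnalysisError("no markers retained after filtering")
    return kept, report


# ---------------------------------------------------------------------------
# segment calling

def call_segments(markers: pd.DataFrame, line: str, *,
                  bridge_missing: bool = True, max_bridge: int = 2,
                  extend_midpoint: bool = False) -> pd.DataFrame:
    """Call donor introgression segments for one line.

    A segment is a maximal run of consecutive same-chromosome SNPs with an
    identical non-recurrent score (``B`` or ``H``), labelled by its first
    SNP. Missing calls inside a run bridge it when ``bridge_missing`` is on
    and at most ``max_bridge`` consecutive ``N`` separate two like calls.
    Segment boundaries sit on the first/last donor-scored SNP; with
    ``extend_midpoint`` they are pushed halfway toward the flanking
    recurrent SNP.
    """
    _check_sorted(markers)
    if line not in markers.columns:
        raise KeyError(f"unknown line {line!r}")
    out = []
    for chrom, sub in markers.groupby("chrom", sort=True):
        codes = sub[line].to_numpy(dtype="U1")
        pos = sub["pos_bp"].to_numpy(dtype=np.int64)
        ids = sub["marker_id"].to_numpy()
        nonmiss = np.flatnonzero(codes != "N")
        runs = []  # (state, first_idx, last_idx, n_markers)
        run = None
        for j in nonmiss:
            c = codes[j]
            if run is not None:
                state, first, last, cnt = run
                gap = j - last - 1  # all intervening markers are N
                if c == state and (gap == 0 or
                                   (bridge_missing and gap <= max_bridge)):
                    run = (state, first, j, cnt + 1)
                    continue
                runs.append(run)
                run = None
            if c != "A":
                run = (c, j, j, 1)
        if run is not None:
            runs.append(run)
        recurrent = np.flatnonzero(codes == "A")
        for state, first, last, cnt in runs:
            start, end = int(pos[first]), int(pos[last])
            if extend_midpoint:
                prev_a = recurrent[recurrent < first]
                next_a = recurrent[recurrent > last]
                if prev_a.size:
                    start = int((pos[prev_a[-1]] + pos[first]) // 2)
                if next_a.size:
                    end = int((pos[next_a[0]] + pos[last]) // 2)
            out.append((line, chrom, start, end, state, str(ids[first]), cnt))
    return pd.DataFrame(out, columns=SEGMENT_COLS)


def call_all_segments(markers: pd.DataFrame, **kw) -> pd.DataFrame:
    """Segment calls for every line, concatenated."""
    frames = [call_segments(markers, ln, **kw) for ln in line_columns(markers)]
    if not frames:
        return pd.DataFrame(columns=SEGMENT_COLS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# unique-segment matrix

@dataclass
class SegmentMatrix:
    """Unique donor segments x lines carrier matrix (the QTL design matrix).

    ``meta`` holds one row per unique segment (chrom, span, state, label);
    ``matrix`` is a 0/1 DataFrame indexed by segment id with one column per
    line.
    """

    meta: pd.DataFrame
    matrix: pd.DataFrame

    @property
    def segment_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def lines(self) -> list[str]:
        return list(self.matrix.columns)

    def carriers(self, segment_id: str) -> list[str]:
        row = self.matrix.loc[segment_id]
        return list(row.index[row == 1])


def build_segment_matrix(segments: pd.DataFrame, lines: list[str] | None = None,
                         *, containment: bool = True,
                         states: tuple = ("B", "H")) -> SegmentMatrix:
    """Collapse per-line segment calls into a unique-segment carrier matrix.

    Segments with identical ``(chrom, start_bp, end_bp, state)`` merge into
    one unique segment, labelled by (the first occurrence of) its first SNP.
    With ``containment`` (default) a line carries a unique segment when any
    of its own same-state segments spans it entirely; otherwise only
    exact-span identity counts. Containment is what gives short unique
    segments multiple carriers when long introgressions overlap them.
    """
    segs = segments[segments["state"].isin(states)]
    if lines is None:
        lines = sorted(segments["line"].unique())
    uniq = (segs.drop_duplicates(["chrom", "start_bp", "end_bp", "state"])
            .sort_values(["chrom", "start_bp", "end_bp", "state"])
            .reset_index(drop=True))
    seg_ids, rows = [], []
    seen = {}
    for _, u in uniq.iterrows():
        sid = str(u["label"])
        if sid in seen:  # same first SNP, different span
            seen[sid] += 1
            sid = f"{sid}.{seen[u['label']]}"
        else:
            seen[sid] = 0
        seg_ids.append(sid)
    carriers = np.zeros((len(uniq), len(lines)), dtype=np.int8)
    line_ix = {ln: k for k, ln in enumerate(lines)}
    by_chrom_state = {k: v for k, v in segs.groupby(["chrom", "state"])}
    for i, u in uniq.iterrows():
        pool = by_chrom_state[(u["chrom"], u["state"])]
        if containment:
            hit = pool[(pool["start_bp"] <= u["start_bp"]) &
                       (pool["end_bp"] >= u["end_bp"])]
        else:
            hit = pool[(pool["start_bp"] == u["start_bp"]) &
                       (pool["end_bp"] == u["end_bp"])]
        for ln in hit["line"].unique():
            if ln in line_ix:
                carriers[i, line_ix[ln]] = 1
    meta = uniq[["chrom", "start_bp", "end_bp", "state", "label"]].copy()
    meta.insert(0, "segment_id", seg_ids)
    meta["length_mb"] = (meta["end_bp"] - meta["start_bp"]) / 1e6
    meta = meta.set_index("segment_id")
    matrix = pd.DataFrame(carriers, index=meta.index, columns=lines)
    # a unique segment with no carrier among `lines` (e.g. parents excluded)
    keep = matrix.sum(axis=1) > 0
    return SegmentMatrix(meta=meta.loc[keep], matrix=matrix.loc[keep])


# ---------------------------------------------------------------------------
# coverage

def coverage_stats(segments: pd.DataFrame, chrom_lengths_bp: dict) -> dict:
    """Donor-genome coverage of the library and segment-size summaries.

    Coverage is the union of all lines' donor (``B``) spans divided by total
    genome length; lengths in Mb use the (end - start) convention.
    """
    total = float(sum(chrom_lengths_bp.values()))
    if total <= 0:
        raise AnalysisError("genome length must be positive")
    donor = segments[segments["state"] == "B"]
    covered = 0.0
    for chrom, sub in donor.groupby("chrom"):
        iv = sub[["start_bp", "end_bp"]].sort_values("start_bp").to_numpy()
        cur_s, cur_e = None, None
        for s, e in iv:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            covered += cur_e - cur_s
    lengths_mb = (donor["end_bp"] - donor["start_bp"]) / 1e6
    per_line = donor.groupby("line").size()
    return {
        "coverage": covered / total,
        "mean_segments_per_line": float(per_line.mean()) if len(per_line) else 0.0,
        "mean_length_mb": float(lengths_mb.mean()) if len(lengths_mb) else 0.0,
        "min_length_mb": float(lengths_mb.min()) if len(lengths_mb) else 0.0,
        "max_length_mb": float(lengths_mb.max()) if len(lengths_mb) else 0.0,
        "n_segments": int(len(donor)),
    }


# ---------------------------------------------------------------------------
# linkage disequilibrium between segments

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding that of the observed table (with the usual
    1 + 1e-7 relative tolerance against ties lost to rounding).
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0  # a zero margin admits a single table
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def segment_ld(sm: SegmentMatrix, alpha: float = 0.01
               ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise two-sided Fisher-exact LD between unique segments.

    For each segment pair the 2x2 carrier/non-carrier table is tested with
    the two-sided Fisher exact test (sum of hypergeometric probabilities at
    most that of the observed table, margins fixed). Returns the symmetric
    p-value matrix (unit diagonal), the boolean high-LD adjacency at
    ``p < alpha``, and the ids of degenerate segments (carried by all or no
    lines) whose pairs are assigned p = 1.
    """
    M = sm.matrix.to_numpy(dtype=np.int64)
    n_seg, n_lines = M.shape
    if n_seg < 2:
        raise AnalysisError("need at least two segments for LD")
    ids = sm.segment_ids
    counts = M.sum(axis=1)
    degenerate = [ids[i] for i in range(n_seg)
                  if counts[i] == 0 or counts[i] == n_lines]
    both = M @ M.T
    p = np.ones((n_seg, n_seg))
    cache: dict[tuple, float] = {}
    for i in range(n_seg):
        if counts[i] in (0, n_lines):
            continue
        for j in range(i + 1, n_seg):
            if counts[j] in (0, n_lines):
                continue
            a = int(both[i, j])
            b = int(counts[i] - a)
            c = int(counts[j] - a)
            d = int(n_lines - a - b - c)
            key = (a, b, c, d)
            if key not in cache:
                cache[key] = fisher_exact_two_sided(a, b, c, d)
            p[i, j] = p[j, i] = cache[key]
    pmat = pd.DataFrame(p, index=ids, columns=ids)
    adj = (pmat < alpha) & ~np.eye(n_seg, dtype=bool)
    return pmat, adj, degenerate
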