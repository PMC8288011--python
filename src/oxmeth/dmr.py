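"""Differentially (hydroxy)methylated region calling.

Candidate regions come from recursive binary segmentation of the per-site
case-minus-control mean difference signal (a circular-binary-segmentation
style change-point search), with a valley rule that splits candidates at
interior sites whose |difference| dips below a floor.  Each candidate is
then tested twice — a two-sample two-dimensional Kolmogorov–Smirnov test on
(relative position, level) point clouds and a Mann–Whitney U test on the
pooled per-site levels — and retained regions are Benjamini–Hochberg
adjusted per channel.

Default thresholds: |mean difference| > 0.2 (strict), coverage >= 5,
>= 5 CpGs per region, valley filter 0.05, both raw p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class DmrParams:
    diff_threshold: float = 0.2
    min_coverage: int = 5
    min_cpg: int = 5
    valley_filter: float = 0.05
    p_threshold: float = 0.001
    max_seg_len: int = 2000
    strict_coverage: bool = False  # require coverage in every sample, not just one per group

    def __post_init__(self):
        if min(self.diff_threshold, self.valley_filter, self.p_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.valley_filter >= self.diff_threshold:
            raise ValueError("valley_filter must be below diff_threshold")
        if self.min_cpg < 1 or self.min_coverage < 0:
            raise ValueError("invalid count parameters")


@dataclass
class MethMatrix:
    """Per-site methylation levels for two sample groups on one channel.

    ``levels``/``depth`` are (n_sites, n_samples); levels in [0,1] or NaN.
    Positions must be strictly increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    levels: np.ndarray
    groups: np.ndarray  # per-sample label, 'case' or 'control'
    depth: np.ndarray | None = None
    samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.levels = np.asarray(self.levels, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.levels.shape[0] != len(self.pos):
            raise ValueError("levels rows must match number of sites")
        if self.levels.shape[1] != len(self.groups):
            raise ValueError("levels columns must match number of samples")
        for g in ("case", "control"):
            if not np.any(self.groups == g):
                raise ValueError(f"group {g!r} is empty")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def case_idx(self):
        return np.where(self.groups == "case")[0]

    @property
    def control_idx(self):
        return np.where(self.groups == "control")[0]

    def swapped(self) -> "MethMatrix":
        g = np.where(self.groups == "case", "control", "case")
        return MethMatrix(self.chrom, self.pos, self.levels, g, self.depth, list(self.samples))


# ---------------------------------------------------------------------------
# statistics


def ks2d_test(case_points: np.ndarray, control_points: np.ndarray) -> tuple[float, float]:
    """Two-sample two-dimensional Kolmogorov–Smirnov test.

    The statistic is the maximum, over every data point of either sample
    taken as origin and over the four quadrants it defines (<=/> splits on
    each axis), of the absolute difference between the two samples'
    quadrant fractions.  The p-value uses the large-sample one-dimensional
    KS tail with the Fasano–Franceschini correlation correction.

    Returns (statistic, p).  Requires >= 3 points per sample; otherwise
    returns (nan, nan).
    """
    a = np.atleast_2d(np.asarray(case_points, dtype=float))
    b = np.atleast_2d(np.asarray(control_points, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        return float("nan"), float("nan")
    origins = np.vstack([a, b])

    def quadrant_fracs(pts):
        lex = pts[:, 0][:, None] <= origins[:, 0][None, :]
        ley = pts[:, 1][:, None] <= origins[:, 1][None, :]
        n = pts.shape[0]
        return (
            np.count_nonzero(lex & ley, axis=0) / n,
            np.count_nonzero(lex & ~ley, axis=0) / n,
            np.count_nonzero(~lex & ley, axis=0) / n,
            np.count_nonzero(~lex & ~ley, axis=0) / n,
        )

    fa = quadrant_fracs(a)
    fb = quadrant_fracs(b)
    d = max(float(np.max(np.abs(x - y))) for x, y in zip(fa, fb))

    n1, n2 = a.shape[0], b.shape[0]
    n_eff = n1 * n2 / (n1 + n2)

    def _corr(pts):
        if np.std(pts[:, 0]) == 0 or np.std(pts[:, 1]) == 0:
            return 0.0
        return float(np.corrcoef(pts[:, 0], pts[:, 1])[0, 1])

    r1, r2 = _corr(a), _corr(b)
    rr = np.sqrt(max(0.0, 1.0 - 0.5 * (r1 * r1 + r2 * r2)))
    sn = np.sqrt(n_eff)
    lam = sn * d / (1.0 + rr * (0.25 - 0.75 / sn))
    p = float(np.clip(kolmogorov(lam), 0.0, 1.0))
    return d, p


def mwu_test(case_levels, control_levels) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when the pooled sample is small (n1+n2 <= 12)
    and tie-free; normal approximation with tie correction otherwise.
    Fully tied data returns p = 1.
    """
    x = np.asarray(case_levels, dtype=float)
    y = np.asarray(control_levels, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y)) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = min(float(res.statistic), len(x) * len(y) - float(res.statistic))
    return u, float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# segmentation


def _best_split(diff: np.ndarray) -> tuple[int, float]:
    """Split index k (1..n-1) maximizing |mean(left) - mean(right)|."""
    n = len(diff)
    cum = np.cumsum(diff)
    k = np.arange(1, n)
    mean_l = cum[:-1] / k
    mean_r = (cum[-1] - cum[:-1]) / (n - k)
    contrast = np.abs(mean_l - mean_r)
    i = int(np.argmax(contrast))  # ties -> first (lowest) split
    return i + 1, float(contrast[i])


def _valley_runs(mask_good: np.ndarray):
    """Maximal runs of True in mask_good, as (start, end) half-open index pairs."""
    runs = []
    n = len(mask_good)
    i = 0
    while i < n:
        if mask_good[i]:
            j = i
            while j < n and mask_good[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def segment(matrix: MethMatrix, params: DmrParams = DmrParams()) -> pd.DataFrame:
    """Candidate differential regions from the mean-difference signal.

    Returns a frame with chrom, start, end (bp, half-open over member CpGs),
    start_idx/end_idx (site indices into the matrix) and mean_diff.
    """
    case_mean = np.nanmean(matrix.levels[:, matrix.case_idx], axis=1)
    ctrl_mean = np.nanmean(matrix.levels[:, matrix.control_idx], axis=1)
    diff = case_mean - ctrl_mean
    rows = []
    for chrom in pd.unique(matrix.chrom):
        sel = np.where(matrix.chrom == chrom)[0]
        d = diff[sel]
        pos = matrix.pos[sel]
        keep = np.isfinite(d)
        d, pos, site_ix = d[keep], pos[keep], sel[keep]
        _segment_recurse(d, 0, len(d), params, rows, chrom, pos, site_ix)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "start_idx", "end_idx", "n_cpg", "mean_diff"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _segment_recurse(d, lo0, hi0, params, rows, chrom, pos, site_ix):
    # explicit stack: splits can be arbitrarily unbalanced on long chromosomes
    stack = [(lo0, hi0)]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < params.min_cpg:
            continue
        seg = d[lo:hi]
        mean = float(np.mean(seg))
        if n <= params.max_seg_len and abs(mean) >= params.diff_threshold:
            good = np.abs(seg) >= params.valley_filter
            if good.all():
                rows.append(
                    (
                        chrom,
                        int(pos[lo]),
                        int(pos[hi - 1]) + 1,
                        int(site_ix[lo]),
                        int(site_ix[hi - 1]) + 1,
                        n,
                        mean,
                    )
                )
                continue
            # valley split: continue on maximal runs of non-valley sites
            for s, e in _valley_runs(good):
                stack.append((lo + s, lo + e))
            continue
        if n < 2:
            continue
        k, contrast = _best_split(seg)
        if contrast <= 0:
            continue  # flat signal, nothing to find
        stack.append((lo, lo + k))
        stack.append((lo + k, hi))


# ---------------------------------------------------------------------------
# full caller


def _coverage_ok(matrix: MethMatrix, params: DmrParams) -> np.ndarray:
    """Per-site flag for the coverage filter (>= min_coverage reads).

    Default: satisfied in at least one sample of each group; strict mode
    requires it in every sample.
    """
    if matrix.depth is None:
        return np.ones(len(matrix.pos), dtype=bool)
    dep = np.asarray(matrix.depth, dtype=float)
    ok = dep >= params.min_coverage
    if params.strict_coverage:
        return ok.all(axis=1)
    return ok[:, matrix.case_idx].any(axis=1) & ok[:, matrix.control_idx].any(axis=1)


def call_dmrs(matrix: MethMatrix, params: DmrParams = DmrParams(), channel: str = "5mC") -> pd.DataFrame:
    """Segment, test and BH-adjust; returns the reported DMR/DhMR table.

    A region is reported when both tests give p < p_threshold, its
    |mean_diff| exceeds diff_threshold (strict), and it spans >= min_cpg
    covered CpGs.  q-values are BH over all retained candidates of this
    channel/contrast.  Direction is 'hyper' (case gains the mark) or 'hypo'.
    """
    ok = _coverage_ok(matrix, params)
    if ok.all():
        sub = matrix
    else:
        sub = MethMatrix(
            matrix.chrom[ok], matrix.pos[ok], matrix.levels[ok], matrix.groups,
            None if matrix.depth is None else np.asarray(matrix.depth)[ok],
            list(matrix.samples),
        )
    cands = segment(sub, params)
    records = []
    for row in cands.itertuples(index=False):
        sl = slice(row.start_idx, row.end_idx)
        pos = sub.pos[sl].astype(float)
        span = max(float(pos[-1] - pos[0]), 1.0)
        rel = (pos - pos[0]) / span
        lv = sub.levels[sl]

        def points(cols):
            pts = []
            for j in cols:
                v = lv[:, j]
                m = np.isfinite(v)
                pts.append(np.column_stack([rel[m], v[m]]))
            return np.vstack(pts) if pts else np.empty((0, 2))

        cpts = points(sub.case_idx)
        kpts = points(sub.control_idx)
        if len(cpts) < 3 or len(kpts) < 3:
            continue
        _, p_ks = ks2d_test(cpts, kpts)
        _, p_mwu = mwu_test(cpts[:, 1], kpts[:, 1])
        if not (np.isfinite(p_ks) and np.isfinite(p_mwu)):
            continue
        if p_ks >= params.p_threshold or p_mwu >= params.p_threshold:
            continue
        if abs(row.mean_diff) <= params.diff_threshold:
            continue
        if row.n_cpg < params.min_cpg:
            continue
        records.append(
            {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n_cpg": row.n_cpg,
                "mean_diff": row.mean_diff,
                "p_ks2d": p_ks,
                "p_mwu": p_mwu,
                "direction": "hyper" if row.mean_diff > 0 else "hypo",
                "channel": channel,
            }
        )
    out = pd.DataFrame(
        records,
        columns=[
            "chrom", "start", "end", "n_cpg", "mean_diff",
            "p_ks2d", "p_mwu", "direction", "channel",
        ],
    )
    if len(out):
        out["q_value"] = bh_adjust(np.maximum(out["p_ks2d"], out["p_mwu"]))
    else:
        out["q_value"] = pd.Series(dtype=float)
    cols = ["chrom", "start", "end", "n_cpg", "mean_diff", "p_ks2d", "p_mwu", "q_value", "direction", "channel"]
    return out[cols]
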