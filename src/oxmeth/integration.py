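"""Integration of the methylome with copy number, variants and chromatin.

Copy number comes from fixed-width read-depth bins (33 kb default, matching
read-depth CNV calling on shallow bisulfite data), segmented by recursive
binary change-point splitting of the log2 case/normal depth ratio; gain and
loss calls use the conventional copy-number cutoffs >= 2.68 and <= 1.38.
Methylation is summarized per bin as M = log2(mean beta) — note this is the
log2-of-beta convention, not the logit M-value — and both tracks are
standardized against the matched normal using the case sample's own SD:

    z_meth = (M_case - M_normal) / SD_case
    z_cnv  = (logR_case - logR_normal) / SD_case

The module also tests mutation-type composition against cytosine
modification class (Fisher exact per C>A / C>G / C>T type) and extracts
meta-profiles over histone peaks (length-normalized body +/- fixed-width
flanks) and strand-aware boundary windows stratified by expression class.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact, spearmanr

GAIN_CUTOFF = 2.68
LOSS_CUTOFF = 1.38
M_EPS = 1e-3


def bin_genome(chrom_sizes: dict[str, int], bin_bp: int = 33_000) -> pd.DataFrame:
    """Half-open fixed-width tiling; the terminal partial bin is retained."""
    if bin_bp < 1:
        raise ValueError("bin_bp must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has nonpositive size")
        starts = np.arange(0, size, bin_bp, dtype=np.int64)
        ends = np.minimum(starts + bin_bp, size)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), bool(e - s < bin_bp)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def m_value(beta, eps: float = M_EPS):
    """The log2-of-beta M value, flooring beta at ``eps`` (exact above it)."""
    beta = np.asarray(beta, dtype=float)
    if eps > 0:
        beta = np.maximum(beta, eps)
    with np.errstate(divide="ignore"):
        return np.log2(beta)


def _best_inner_segment(x: np.ndarray, min_bins: int):
    """Circular scan: best inner window [i, j) against the rest of the segment.

    Maximizes the t-like contrast |mean_in - mean_out| * sqrt(harmonic n)
    over all windows with >= min_bins bins on the small side; windows
    touching either segment end reduce to ordinary binary splits.  Returns
    (i, j, t) or None.
    """
    n = len(x)
    if n < 2 * min_bins:
        return None
    cum = np.concatenate([[0.0], np.cumsum(x)])
    total = cum[-1]
    i_idx = np.arange(0, n - min_bins + 1)
    best = None
    for i in i_idx:
        j = np.arange(i + min_bins, n + 1)
        if i == 0:
            j = j[j < n]  # [0, n) is the whole segment, not a split
            if len(j) == 0:
                continue
        n_in = j - i
        n_out = n - n_in
        ok = n_out >= min_bins
        j, n_in, n_out = j[ok], n_in[ok], n_out[ok]
        if len(j) == 0:
            continue
        s_in = cum[j] - cum[i]
        mean_in = s_in / n_in
        mean_out = (total - s_in) / n_out
        t = np.abs(mean_in - mean_out) * np.sqrt(1.0 / (1.0 / n_in + 1.0 / n_out))
        k = int(np.argmax(t))
        if best is None or t[k] > best[2]:
            best = (int(i), int(j[k]), float(t[k]))
    return best


def _cbs_recurse(x, lo0, hi0, min_bins, t_floor, cuts):
    stack = [(lo0, hi0)]
    while stack:
        lo, hi = stack.pop()
        res = _best_inner_segment(x[lo:hi], min_bins)
        if res is None:
            continue
        i, j, t = res
        if t < t_floor:
            continue
        for cut in (lo + i, lo + j):
            if lo < cut < hi:
                cuts.append(cut)
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        for a, b in pieces:
            if b - a > 0 and (a, b) != (lo, hi):
                stack.append((a, b))


def cbs_copy_number(depth_case, depth_normal, bins: pd.DataFrame,
                    gain_cutoff: float = GAIN_CUTOFF, loss_cutoff: float = LOSS_CUTOFF,
                    min_bins: int = 3, split_z: float = 6.0) -> pd.DataFrame:
    """Segment per-bin depth ratios into copy-number segments with calls.

    Copy number per bin is 2 * (case/normal), normalized so the genome-wide
    median ratio is neutral; segmentation recursively splits the log2 ratio
    at the point maximizing a t-like mean contrast and stops when that
    statistic falls below ``split_z`` noise units, where the per-bin noise
    scale is estimated robustly from successive bin-to-bin differences
    (median |diff| / (0.6745 * sqrt(2))).  Zero-depth normal bins are
    masked.
    """
    case = np.asarray(depth_case, dtype=float)
    normal = np.asarray(depth_normal, dtype=float)
    if len(case) != len(bins) or len(normal) != len(bins):
        raise ValueError("depth vectors must match the bin grid")
    rows = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        ix = bins.index.get_indexer(sub.index)
        c, m = case[ix], normal[ix]
        mask = m > 0
        if mask.sum() == 0:
            continue
        ratio = np.full(len(ix), np.nan)
        ratio[mask] = c[mask] / m[mask]
        med = np.nanmedian(ratio)
        if med <= 0 or not np.isfinite(med):
            med = 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.log2(ratio / med)
        good = np.isfinite(logr)
        gx = np.where(good)[0]
        if len(gx) == 0:
            continue
        x = logr[gx]
        if len(x) > 1:
            sigma = float(np.median(np.abs(np.diff(x)))) / (0.6745 * np.sqrt(2.0))
        else:
            sigma = 0.0
        sigma = max(sigma, 1e-6)  # constructed noise-free inputs
        cuts: list[int] = []
        _cbs_recurse(x, 0, len(x), min_bins, split_z * sigma, cuts)
        edges = [0] + sorted(cuts) + [len(x)]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for a, b in zip(edges[:-1], edges[1:]):
            seg_bins = gx[a:b]
            copy = float(2.0 * 2.0 ** np.mean(x[a:b]))
            if copy >= gain_cutoff:
                call = "gain"
            elif copy <= loss_cutoff:
                call = "loss"
            else:
                call = "neutral"
            rows.append((chrom, int(starts[seg_bins[0]]), int(ends[seg_bins[-1]]),
                         len(seg_bins), copy, call))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bins", "copy_number", "call"])


def zscores(M_case, M_normal, logR_case, logR_normal,
            sd_meth: float | None = None, sd_cnv: float | None = None) -> pd.DataFrame:
    """Per-bin standardized methylation and CNV scores.

    The divisor is the case sample's own per-track standard deviation over
    bins, computed here unless passed explicitly.
    """
    M_case = np.asarray(M_case, dtype=float)
    M_normal = np.asarray(M_normal, dtype=float)
    logR_case = np.asarray(logR_case, dtype=float)
    logR_normal = np.asarray(logR_normal, dtype=float)
    sd_m = float(np.nanstd(M_case, ddof=1)) if sd_meth is None else float(sd_meth)
    sd_r = float(np.nanstd(logR_case, ddof=1)) if sd_cnv is None else float(sd_cnv)
    if sd_m == 0 or sd_r == 0 or not np.isfinite(sd_m) or not np.isfinite(sd_r):
        warnings.warn("degenerate case SD; z-scores undefined")
        nan = np.full_like(M_case, np.nan)
        return pd.DataFrame({"z_meth": nan, "z_cnv": nan})
    return pd.DataFrame(
        {
            "z_meth": (M_case - M_normal) / sd_m,
            "z_cnv": (logR_case - logR_normal) / sd_r,
        }
    )


def correlate_tracks(z_cnv, z_meth) -> tuple[float, float]:
    """Spearman correlation between the two standardized bin tracks."""
    a = np.asarray(z_cnv, dtype=float)
    b = np.asarray(z_meth, dtype=float)
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 3:
        return float("nan"), float("nan")
    rho, p = spearmanr(a[m], b[m])
    return float(rho), float(p)


def distance_correlation(cnv_profiles, meth_profiles) -> tuple[float, float]:
    """Correlation of within-stage pairwise Euclidean distances.

    ``*_profiles`` are (n_samples, n_bins) arrays for one stage; the two
    condensed distance vectors are Spearman-correlated.  Requires >= 3
    samples (>= 3 pairs).
    """
    cnv = np.atleast_2d(np.asarray(cnv_profiles, dtype=float))
    meth = np.atleast_2d(np.asarray(meth_profiles, dtype=float))
    if cnv.shape[0] != meth.shape[0]:
        raise ValueError("profile matrices must have matching samples")
    if cnv.shape[0] < 3:
        raise ValueError("need >= 3 samples per stage for distance correlation")
    d_cnv = pdist(cnv, metric="euclidean")
    d_meth = pdist(meth, metric="euclidean")
    rho, p = spearmanr(d_cnv, d_meth)
    return float(rho), float(p)


MUTATION_TYPES = ("C>A", "C>G", "C>T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def normalize_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Normalize G-strand cytosine variants to the C strand (G>X -> C>comp(X))."""
    out = variants.copy()
    ref = out["ref"].str.upper()
    alt = out["alt"].str.upper()
    if not ref.isin(["C", "G"]).all():
        raise ValueError("variants must have cytosine (C or G) reference")
    flip = ref == "G"
    out.loc[flip, "alt"] = alt[flip].map(_COMP)
    out.loc[flip, "ref"] = "C"
    out["mutation_type"] = "C>" + out["alt"].str.upper()
    return out


def classify_sites(estimates: pd.DataFrame, pos_threshold: float = 0.0) -> pd.Series:
    """Modification class per site: 5hmC-positive, 5mC-only or unmodified."""
    ph = estimates["p_h"].to_numpy()
    pm = estimates["p_m"].to_numpy()
    cls = np.where(ph > pos_threshold, "5hmC-positive",
                   np.where(pm > pos_threshold, "5mC-only", "unmodified"))
    return pd.Series(cls, index=estimates.index, name="mod_class")


def variant_context_test(variants: pd.DataFrame, estimates: pd.DataFrame,
                         pos_threshold: float = 0.0) -> pd.DataFrame:
    """Per mutation-type 2x2 test of association with 5hmC positivity.

    Table: [this type vs other types] x [5hmC-positive vs not]; Fisher
    exact two-sided p; odds ratio with Haldane +0.5 correction when any
    cell is zero.  Variants are matched to estimate rows by (chrom, pos).
    """
    var = normalize_variants(variants)
    est = estimates.copy()
    est["mod_class"] = classify_sites(est, pos_threshold)
    merged = var.merge(est[["chrom", "pos", "mod_class"]], on=["chrom", "pos"], how="inner")
    rows = []
    hmc = merged["mod_class"] == "5hmC-positive"
    for t in MUTATION_TYPES:
        is_t = merged["mutation_type"] == t
        a = int((is_t & hmc).sum())
        b = int((is_t & ~hmc).sum())
        c = int((~is_t & hmc).sum())
        d = int((~is_t & ~hmc).sum())
        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
            p = 1.0
        else:
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if 0 in (a, b, c, d):
            orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        else:
            orr = a * d / (b * c)
        rows.append((t, a, b, c, d, float(orr), float(p)))
    return pd.DataFrame(rows, columns=["mutation_type", "n_type_hmc", "n_type_other",
                                       "n_rest_hmc", "n_rest_other", "odds_ratio", "p_fisher"])


def peak_meta_profile(estimates: pd.DataFrame, peaks: pd.DataFrame,
                      level_col: str = "p_m", flank_bp: int = 15_000,
                      n_body_bins: int = 20, n_flank_bins: int = 15) -> pd.DataFrame:
    """Mean level across peaks: fixed-width flank bins + length-scaled body.

    Bin indices run 0..n_flank-1 (upstream), n_flank..n_flank+n_body-1
    (body), then downstream.  Bins without CpGs are NaN.
    """
    if len(peaks) == 0:
        warnings.warn("no peaks supplied; empty profile")
        return pd.DataFrame(columns=["bin_index", "zone", "mean_level", "n_sites"])
    n_total = 2 * n_flank_bins + n_body_bins
    sums = np.zeros(n_total)
    counts = np.zeros(n_total, dtype=np.int64)
    flank_w = flank_bp / n_flank_bins
    by_chrom = {c: sub.sort_values("pos") for c, sub in estimates.groupby("chrom", sort=False)}
    for pk in peaks.itertuples(index=False):
        sub = by_chrom.get(pk.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lv = sub[level_col].to_numpy()
        lo, hi = pk.start - flank_bp, pk.end + flank_bp
        i0, i1 = np.searchsorted(pos, [lo, hi])
        p, v = pos[i0:i1], lv[i0:i1]
        m = np.isfinite(v)
        p, v = p[m], v[m]
        upstream = p < pk.start
        body = (p >= pk.start) & (p < pk.end)
        down = p >= pk.end
        bidx = np.empty(len(p), dtype=np.int64)
        bidx[upstream] = np.clip(((p[upstream] - lo) / flank_w).astype(np.int64), 0, n_flank_bins - 1)
        width = max(pk.end - pk.start, 1)
        bidx[body] = n_flank_bins + np.clip(
            ((p[body] - pk.start) / width * n_body_bins).astype(np.int64), 0, n_body_bins - 1)
        bidx[down] = n_flank_bins + n_body_bins + np.clip(
            ((p[down] - pk.end) / flank_w).astype(np.int64), 0, n_flank_bins - 1)
        np.add.at(sums, bidx, v)
        np.add.at(counts, bidx, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    zone = (["flank_up"] * n_flank_bins + ["body"] * n_body_bins + ["flank_down"] * n_flank_bins)
    return pd.DataFrame({"bin_index": np.arange(n_total), "zone": zone,
                         "mean_level": mean, "n_sites": counts})


def boundary_profile(estimates: pd.DataFrame, anchors: pd.DataFrame,
                     expression_classes: pd.Series | dict,
                     level_col: str = "p_m", window_bp: int = 150,
                     n_bins: int = 20,
                     allowed_classes: tuple[str, ...] = ("high", "low", "no")) -> pd.DataFrame:
    """Strand-aware mean level in bins around anchors, per expression class.

    ``anchors`` needs chrom, pos, strand and a key column (``gene``) mapping
    into ``expression_classes`` (gene -> high/low/no by |fold change| >= 2).
    Minus-strand windows are mirrored so bin 0 is always 5'-most.
    """
    cls_map = dict(expression_classes) if not isinstance(expression_classes, dict) else expression_classes
    bad = set(cls_map.values()) - set(allowed_classes)
    if bad:
        raise ValueError(f"unknown expression class labels: {sorted(bad)}")
    sums = {c: np.zeros(n_bins) for c in allowed_classes}
    counts = {c: np.zeros(n_bins, dtype=np.int64) for c in allowed_classes}
    by_chrom = {c: sub.sort_values("pos") for c, sub in estimates.groupby("chrom", sort=False)}
    bin_w = 2 * window_bp / n_bins
    for a in anchors.itertuples(index=False):
        cls = cls_map.get(a.gene)
        if cls is None:
            continue
        sub = by_chrom.get(a.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lv = sub[level_col].to_numpy()
        i0, i1 = np.searchsorted(pos, [a.pos - window_bp, a.pos + window_bp])
        p, v = pos[i0:i1], lv[i0:i1]
        m = np.isfinite(v)
        p, v = p[m], v[m]
        if len(p) == 0:
            continue
        offset = p - (a.pos - window_bp)
        bidx = np.clip((offset / bin_w).astype(np.int64), 0, n_bins - 1)
        if a.strand == "-":
            bidx = n_bins - 1 - bidx
        np.add.at(sums[cls], bidx, v)
        np.add.at(counts[cls], bidx, 1)
    rows = []
    for c in allowed_classes:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[c] > 0, sums[c] / np.maximum(counts[c], 1), np.nan)
        for i in range(n_bins):
            rows.append((i, c, mean[i], int(counts[c][i])))
    return pd.DataFrame(rows, columns=["bin_index", "expr_class", "mean_level", "n_sites"])
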