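"""Joint 5mC/5hmC quantification from paired BS/oxBS counts.

Bisulfite sequencing (BS) reads both 5mC and 5hmC as "methylated", while
oxidative bisulfite sequencing (oxBS) first oxidizes 5hmC so that only 5mC
survives conversion.  At one CpG with modification proportions
``(p_u, p_m, p_h)`` (unmodified, 5mC, 5hmC; summing to 1) and conversion
rates ``bs_conv`` (unmodified C -> T under bisulfite) and ``ox_conv``
(5hmC -> T under the oxidative step), the per-read "methylated" probability
in each channel is

    q_bs = p_m + p_h + p_u * (1 - bs_conv)
    q_ox = p_m + p_h * (1 - ox_conv) + p_u * (1 - bs_conv)

``mlml_estimate`` maximizes the product of the two binomial likelihoods over
the probability simplex.  The interior solution is the closed-form moment
inversion of the two observed proportions; when that falls outside the
simplex the maximizer lies on an active boundary (p_h = 0, p_m = 0 or
p_u = 0), each of which is a one-dimensional concave problem solved exactly
or by golden-section search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlog1py, xlogy

_SIMPLEX_TOL = 1e-12

BOUNDARY_INTERIOR = "interior"
BOUNDARY_H_ZERO = "h_zero"
BOUNDARY_M_ZERO = "m_zero"
BOUNDARY_U_ZERO = "u_zero"


@dataclass(frozen=True)
class ConversionRates:
    """Spike-in-estimated conversion probabilities.

    bs_conv: probability an unmodified C reads as T (bisulfite conversion).
    ox_conv: probability a 5hmC reads as T under oxidative bisulfite.
    """

    bs_conv: float = 0.9992
    ox_conv: float = 0.9657

    def __post_init__(self):
        for name in ("bs_conv", "ox_conv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bs_conv < 0.95:
            warnings.warn(f"low bisulfite conversion rate {self.bs_conv:.4f}")
        if self.ox_conv < 0.90:
            warnings.warn(f"low oxidative conversion rate {self.ox_conv:.4f}")


@dataclass(frozen=True)
class SiteEstimate:
    p_u: float
    p_m: float
    p_h: float
    loglik: float
    boundary: str
    pass_qc: bool


def beta_value(meth_count, total_count):
    """Beta value: methylated read count over total read count.

    Returns NaN where total_count is 0 (missing marker).  Accepts scalars
    or numpy arrays.
    """
    meth = np.asarray(meth_count, dtype=float)
    total = np.asarray(total_count, dtype=float)
    if np.any(total < 0):
        raise ValueError("total_count must be >= 0")
    if np.any(meth < 0) or np.any(meth > total):
        raise ValueError("meth_count must satisfy 0 <= meth <= total")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, meth / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(meth_count) and np.isscalar(total_count):
        if total_count == 0:
            raise ValueError("beta value undefined at zero depth")
        return float(out)
    return out


def estimate_conversion(spikein_counts: pd.DataFrame, control_kind: str) -> float:
    """Pooled conversion-rate estimate from spike-in control cytosines.

    control_kind='unmethylated_bs': fully unmodified control, BS channel;
    conversion = 1 - sum(bs_meth)/sum(bs_depth).
    control_kind='hydroxymethylated_ox': fully hydroxymethylated control,
    oxBS channel; conversion = 1 - sum(ox_meth)/sum(ox_depth).
    """
    if control_kind == "unmethylated_bs":
        meth, depth = "bs_meth", "bs_depth"
    elif control_kind == "hydroxymethylated_ox":
        meth, depth = "ox_meth", "ox_depth"
    else:
        raise ValueError(f"unknown control kind {control_kind!r}")
    total = float(spikein_counts[depth].sum())
    if total <= 0:
        raise ValueError("spike-in control has zero total depth")
    return 1.0 - float(spikein_counts[meth].sum()) / total


def _channel_probs(p_m, p_h, rates: ConversionRates):
    p_u = 1.0 - p_m - p_h
    q_bs = p_m + p_h + p_u * (1.0 - rates.bs_conv)
    q_ox = p_m + p_h * (1.0 - rates.ox_conv) + p_u * (1.0 - rates.bs_conv)
    return q_bs, q_ox


def _binom_loglik(k, n, q):
    """log Binom(k; n, q) including the combinatorial constant; vectorized."""
    q = np.clip(q, 0.0, 1.0)
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return const + xlogy(k, q) + xlog1py(n - k, -q)


def _loglik(bs_meth, bs_depth, ox_meth, ox_depth, p_m, p_h, rates):
    q_bs, q_ox = _channel_probs(p_m, p_h, rates)
    return _binom_loglik(bs_meth, bs_depth, q_bs) + _binom_loglik(ox_meth, ox_depth, q_ox)


def _golden_max(f, lo, hi, iters=80):
    """Vectorized golden-section maximization of a concave 1-D function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full_like(np.asarray(lo, dtype=float), lo) if np.isscalar(lo) else lo.astype(float)
    b = np.full_like(a, hi) if np.isscalar(hi) else hi.astype(float)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        take_left = fc >= fd
        b = np.where(take_left, d, b)
        a = np.where(take_left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    x = 0.5 * (a + b)
    return x


def mlml_table(
    bs_meth,
    bs_depth,
    ox_meth,
    ox_depth,
    rates: ConversionRates = ConversionRates(),
    min_depth: int = 5,
) -> pd.DataFrame:
    """Vectorized constrained MLE of (p_u, p_m, p_h) per site.

    Sites with zero depth in either channel get NaN estimates.  ``pass_qc``
    flags sites with depth >= min_depth in both channels (coverage QC; such
    sites are excluded from region calling downstream but retained here).
    """
    bs_meth = np.asarray(bs_meth, dtype=float)
    bs_depth = np.asarray(bs_depth, dtype=float)
    ox_meth = np.asarray(ox_meth, dtype=float)
    ox_depth = np.asarray(ox_depth, dtype=float)
    if np.any(bs_meth > bs_depth) or np.any(ox_meth > ox_depth):
        raise ValueError("methylated counts exceed depth")
    n = bs_meth.shape[0]
    c_bs, c_ox = rates.bs_conv, rates.ox_conv
    if c_ox <= 0 or c_bs <= 0:
        raise ValueError("conversion rates must be positive for estimation")

    valid = (bs_depth > 0) & (ox_depth > 0)
    qb = np.where(valid, bs_meth / np.where(bs_depth > 0, bs_depth, 1), np.nan)
    qo = np.where(valid, ox_meth / np.where(ox_depth > 0, ox_depth, 1), np.nan)

    # moment inversion (interior candidate)
    p_h0 = (qb - qo) / c_ox
    p_mh = (qb - (1.0 - c_bs)) / c_bs  # p_m + p_h
    p_m0 = p_mh - p_h0
    p_u0 = 1.0 - p_mh

    with np.errstate(invalid="ignore"):
        interior = valid & (p_h0 >= -_SIMPLEX_TOL) & (p_m0 >= -_SIMPLEX_TOL) & (p_u0 >= -_SIMPLEX_TOL)

    p_m = np.where(interior, np.clip(p_m0, 0.0, 1.0), np.nan)
    p_h = np.where(interior, np.clip(p_h0, 0.0, 1.0), np.nan)
    boundary = np.full(n, BOUNDARY_INTERIOR, dtype=object)

    need = valid & ~interior
    if np.any(need):
        bm, bd = bs_meth[need], bs_depth[need]
        om, od = ox_meth[need], ox_depth[need]

        def ll(pm, ph):
            q_bs, q_ox = _channel_probs(pm, ph, rates)
            return _binom_loglik(bm, bd, q_bs) + _binom_loglik(om, od, q_ox)

        # boundary p_h = 0: both channels share q = (1-c_bs) + p_m*c_bs,
        # so the MLE pools the two channels.
        q_pool = (bm + om) / (bd + od)
        pm_h0 = np.clip((q_pool - (1.0 - c_bs)) / c_bs, 0.0, 1.0)
        ll_h0 = ll(pm_h0, np.zeros_like(pm_h0))

        # boundary p_m = 0: concave 1-D problem in p_h (golden section)
        ph_m0 = _golden_max(lambda ph: ll(np.zeros_like(ph), ph), np.zeros_like(q_pool), 1.0)
        # polish against the exact endpoints
        cand_ph = np.stack([ph_m0, np.zeros_like(ph_m0), np.ones_like(ph_m0)])
        ll_cand = np.stack([ll(np.zeros_like(p), p) for p in cand_ph])
        best = np.argmax(ll_cand, axis=0)
        ph_m0 = cand_ph[best, np.arange(len(ph_m0))]
        ll_m0 = ll_cand[best, np.arange(len(ph_m0))]

        # boundary p_u = 0: q_bs = 1 fixed, q_ox = 1 - p_h*c_ox -> closed form
        ph_u0 = np.clip((1.0 - om / od) / c_ox, 0.0, 1.0)
        ll_u0 = ll(1.0 - ph_u0, ph_u0)

        lls = np.stack([ll_h0, ll_m0, ll_u0])
        which = np.argmax(lls, axis=0)
        pm_best = np.choose(which, [pm_h0, np.zeros_like(pm_h0), 1.0 - ph_u0])
        ph_best = np.choose(which, [np.zeros_like(ph_m0), ph_m0, ph_u0])
        flag = np.array([BOUNDARY_H_ZERO, BOUNDARY_M_ZERO, BOUNDARY_U_ZERO], dtype=object)[which]

        p_m[need] = pm_best
        p_h[need] = ph_best
        boundary[need] = flag

    p_u = 1.0 - p_m - p_h
    # numerical closure of the simplex
    p_u = np.clip(p_u, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        total = p_u + p_m + p_h
        renorm = valid & (np.abs(total - 1.0) > 1e-15) & (total > 0)
    if np.any(renorm):
        p_u[renorm] /= total[renorm]
        p_m[renorm] /= total[renorm]
        p_h[renorm] /= total[renorm]

    loglik = np.full(n, np.nan)
    if np.any(valid):
        loglik[valid] = _loglik(
            bs_meth[valid], bs_depth[valid], ox_meth[valid], ox_depth[valid],
            p_m[valid], p_h[valid], rates,
        )
    boundary[~valid] = "missing"

    pass_qc = (bs_depth >= min_depth) & (ox_depth >= min_depth)
    return pd.DataFrame(
        {
            "p_u": p_u,
            "p_m": p_m,
            "p_h": p_h,
            "loglik": loglik,
            "boundary": boundary,
            "pass_qc": pass_qc,
        }
    )


def mlml_estimate(
    bs_meth: int,
    bs_depth: int,
    ox_meth: int,
    ox_depth: int,
    rates: ConversionRates = ConversionRates(),
    min_depth: int = 5,
) -> SiteEstimate:
    """Single-site convenience wrapper around :func:`mlml_table`."""
    if bs_depth < 1 or ox_depth < 1:
        raise ValueError("mlml_estimate requires depth >= 1 in both channels")
    row = mlml_table(
        np.array([bs_meth]), np.array([bs_depth]),
        np.array([ox_meth]), np.array([ox_depth]),
        rates=rates, min_depth=min_depth,
    ).iloc[0]
    return SiteEstimate(
        p_u=float(row.p_u), p_m=float(row.p_m), p_h=float(row.p_h),
        loglik=float(row.loglik), boundary=str(row.boundary), pass_qc=bool(row.pass_qc),
    )


def estimate_sample(counts: pd.DataFrame, rates: ConversionRates = ConversionRates(),
                    min_depth: int = 5) -> pd.DataFrame:
    """Run the joint MLE over a SiteCounts table; returns sites + estimates."""
    est = mlml_table(
        counts["bs_meth"].to_numpy(), counts["bs_depth"].to_numpy(),
        counts["ox_meth"].to_numpy(), counts["ox_depth"].to_numpy(),
        rates=rates, min_depth=min_depth,
    )
    keep = counts[["chrom", "pos", "strand", "bs_meth", "bs_depth", "ox_meth", "ox_depth"]].reset_index(drop=True)
    return pd.concat([keep, est], axis=1)


def summarize_genome(estimates: pd.DataFrame, min_depth: int = 5,
                     pos_threshold: float = 0.0,
                     full_threshold: float = 0.9) -> dict:
    """Global per-sample summary of the C/mC/hmC decomposition.

    Means are over QC-passing sites; 'positive' means estimate strictly
    above ``pos_threshold`` (default: any nonzero MLE mass).  Fractions with
    an empty denominator are reported as NaN and flagged.
    """
    if "pass_qc" in estimates.columns:
        ok = estimates[estimates["pass_qc"].astype(bool)]
    else:
        ok = estimates
    ok = ok.dropna(subset=["p_m", "p_h"])
    if len(ok) == 0:
        warnings.warn("no passing sites; empty summary")
        return {
            "n_sites": 0, "mean_5mC": np.nan, "mean_5hmC": np.nan,
            "mc_over_hmc_ratio": np.nan, "frac_5mC_pos_also_5hmC": np.nan,
            "frac_5hmC_pos_also_5mC": np.nan, "fully_methylated_frac": np.nan,
        }
    pm = ok["p_m"].to_numpy()
    ph = ok["p_h"].to_numpy()
    m_pos = pm > pos_threshold
    h_pos = ph > pos_threshold
    mean_m = float(pm.mean())
    mean_h = float(ph.mean())
    return {
        "n_sites": int(len(ok)),
        "mean_5mC": mean_m,
        "mean_5hmC": mean_h,
        "mc_over_hmc_ratio": mean_m / mean_h if mean_h > 0 else np.nan,
        "frac_5mC_pos_also_5hmC": float(h_pos[m_pos].mean()) if m_pos.any() else np.nan,
        "frac_5hmC_pos_also_5mC": float(m_pos[h_pos].mean()) if h_pos.any() else np.nan,
        "fully_methylated_frac": float((pm >= full_threshold).mean()),
    }
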