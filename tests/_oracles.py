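"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (grid search, full enumeration,
quadratic sweeps) and shares no code with the package internals.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import xlogy


@lru_cache(maxsize=4)
def simplex_grid(step: float = 1e-3):
    """All (p_m, p_h) pairs on the simplex lattice with the given step."""
    vals = np.round(np.arange(0.0, 1.0 + step / 2, step), 9)
    pm, ph = np.meshgrid(vals, vals, indexing="ij")
    mask = pm + ph <= 1.0 + 1e-12
    return pm[mask], ph[mask]


def grid_mle(bs_meth, bs_depth, ox_meth, ox_depth, bs_conv, ox_conv, step=1e-3):
    """Exhaustive likelihood maximization over the simplex lattice."""
    pm, ph = simplex_grid(step)
    pu = 1.0 - pm - ph
    qb = pm + ph + pu * (1.0 - bs_conv)
    qo = pm + ph * (1.0 - ox_conv) + pu * (1.0 - bs_conv)
    qb = np.clip(qb, 0.0, 1.0)
    qo = np.clip(qo, 0.0, 1.0)
    ll = (
        xlogy(bs_meth, qb)
        + xlogy(bs_depth - bs_meth, 1.0 - qb)
        + xlogy(ox_meth, qo)
        + xlogy(ox_depth - ox_meth, 1.0 - qo)
    )
    i = int(np.argmax(ll))
    return float(pu[i]), float(pm[i]), float(ph[i])


def ks2d_stat_bruteforce(a, b):
    """Max quadrant-fraction discrepancy by explicit loops over all origins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for origin in np.vstack([a, b]):
        ox, oy = origin
        for qx in (True, False):  # x <= ox vs x > ox
            for qy in (True, False):
                fa = np.mean([(p[0] <= ox) == qx and (p[1] <= oy) == qy for p in a])
                fb = np.mean([(p[0] <= ox) == qx and (p[1] <= oy) == qy for p in b])
                best = max(best, abs(fa - fb))
    return best


def overlap_bruteforce(regions, features):
    """Quadratic any-overlap check with half-open semantics."""
    flags = []
    for r in regions.itertuples(index=False):
        hit = False
        for f in features.itertuples(index=False):
            if r.chrom == f.chrom and r.start < f.end and f.start < r.end:
                hit = True
                break
        flags.append(hit)
    return np.array(flags)


def km_bruteforce(times, events):
    """Product-limit survival at each distinct event time, recomputed directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    for ut in sorted(set(times[events == 1])):
        s = 1.0
        for t in sorted(set(times[events == 1])):
            if t > ut:
                break
            n_risk = np.sum(times >= t)
            d = np.sum((times == t) & (events == 1))
            s *= 1.0 - d / n_risk
        out.append((ut, s))
    return out


def logrank_bruteforce(times_a, events_a, times_b, events_b):
    """Hand-tabulated O/E/V log-rank chi-square."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    is_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    o_e, var = 0.0, 0.0
    for ut in sorted(set(all_t[all_e == 1])):
        risk = all_t >= ut
        n, na = risk.sum(), (risk & is_a).sum()
        d = ((all_t == ut) & (all_e == 1)).sum()
        da = ((all_t == ut) & (all_e == 1) & is_a).sum()
        o_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_e**2 / var
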