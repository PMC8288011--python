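"""Marker–survival association: KM curves, log-rank, cutpoint, Cox.

A continuous marker (region methylation level or gene expression) is
dichotomized at the optimal cutpoint — the threshold maximizing the
absolute standardized log-rank statistic over all admissible splits — and
the two groups are compared by Kaplan–Meier curves and the log-rank test;
a univariate Cox proportional-hazards fit (Breslow tie handling) gives the
continuous-marker hazard ratio.

Caveat (deliberate, matching common practice in the source literature):
the log-rank p at the selected cutpoint is NOT corrected for the maximal
selection, which makes it anti-conservative under the null.  Pass
``correct='permutation'`` to :func:`optimal_cutpoint` for a permutation-
calibrated p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm


@dataclass(frozen=True)
class CutpointResult:
    cutpoint: float
    statistic: float  # standardized log-rank z at the cutpoint
    n_low: int
    n_high: int
    logrank_chi2: float
    logrank_p: float
    corrected_p: float | None = None


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("survival times must be >= 0")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit (Kaplan–Meier) estimator.

    Returns one row per distinct event time: (time, n_risk, n_events,
    survival).  Censored times shrink the risk set without a step.
    """
    t, e = _check_surv(times, events)
    if len(t) == 0:
        raise ValueError("need >= 1 record")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n = len(t)
    for ut in np.unique(t[e == 1]):
        at_risk = int(np.sum(t >= ut))
        d = int(np.sum((t == ut) & (e == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(ut), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "survival"])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Standard (unit-weight) two-group log-rank test.

    chi2 = (sum(O - E))^2 / sum(V) over distinct event times, with the
    hypergeometric variance; p from chi-square(1).  Zero total variance
    (no usable events) gives p = 1.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n_a = int((at_risk & grp_a).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d_a = int(((t == ut) & (e == 1) & grp_a).sum())
        exp_a = d * n_a / n
        o_minus_e += d_a - exp_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def _logrank_z(times, events, high_mask) -> float:
    """Signed standardized log-rank statistic for high-vs-low groups."""
    t, e = _check_surv(times, events)
    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t[e == 1]):
        at_risk = t >= ut
        n = int(at_risk.sum())
        n_h = int((at_risk & high_mask).sum())
        d = int(((t == ut) & (e == 1)).sum())
        d_h = int(((t == ut) & (e == 1) & high_mask).sum())
        o_minus_e += d_h - d * n_h / n
        if n > 1:
            var += d * (n_h / n) * (1 - n_h / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


def optimal_cutpoint(times, events, marker, minprop: float = 0.1,
                     correct: str | None = None, n_perm: int = 1000,
                     seed=None) -> CutpointResult:
    """Marker threshold maximizing |standardized log-rank statistic|.

    Candidate cutpoints are midpoints between consecutive sorted unique
    marker values; each side must hold >= minprop of the samples.  Ties in
    |z| break toward the lower cutpoint.  The scan depends on the marker
    only through ranks, so the chosen grouping is invariant to strictly
    monotone marker transforms.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(marker, dtype=float)
    n = len(x)
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise ValueError("marker must take >= 2 distinct values")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    min_n = int(np.ceil(minprop * n))
    best = None
    for c in mids:
        high = x > c
        if high.sum() < min_n or (~high).sum() < min_n:
            continue
        z = _logrank_z(t, e, high)
        if best is None or abs(z) > abs(best[1]) + 1e-15:
            best = (float(c), float(z))
    if best is None:
        raise ValueError("no admissible cutpoint under minprop")
    cut, z = best
    high = x > cut
    chi2, p = logrank_test(t[high], e[high], t[~high], e[~high])
    corrected = None
    if correct == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            xp = rng.permutation(x)
            zmax = 0.0
            for c in mids:
                hp = xp > c
                if hp.sum() < min_n or (~hp).sum() < min_n:
                    continue
                zmax = max(zmax, abs(_logrank_z(t, e, hp)))
            if zmax >= abs(z):
                hits += 1
        corrected = (hits + 1) / (n_perm + 1)
    return CutpointResult(cut, z, int((~high).sum()), int(high.sum()), chi2, p, corrected)


def cox_univariate(times, events, marker, max_iter: int = 50,
                   tol: float = 1e-9) -> dict:
    """Univariate Cox proportional hazards by Newton–Raphson.

    Breslow handling of tied event times; returns beta, hazard ratio,
    standard error, Wald p and a convergence flag.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(marker, dtype=float)
    if e.sum() < 2:
        raise ValueError("need >= 2 events")
    if np.all(x == x[0]):
        raise ValueError("marker must vary")
    # center for numerical stability; beta is unaffected
    xc = x - x.mean()
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    t_o, e_o, x_o = t[order], e[order], xc[order]

    def score_info(beta):
        # risk sets accumulate as time decreases
        w = np.exp(beta * x_o)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x_o)
        s2 = np.cumsum(w * x_o**2)
        # Breslow: for each event, risk set = all with time >= event time
        # handle ties: use the cumulative sums at the last index sharing the time
        idx_last = np.searchsorted(-t_o, -t_o, side="right") - 1
        ll = 0.0
        u = 0.0
        info = 0.0
        ev = e_o == 1
        i = idx_last[ev]
        ll = float(np.sum(beta * x_o[ev] - np.log(s0[i])))
        u = float(np.sum(x_o[ev] - s1[i] / s0[i]))
        info = float(np.sum(s2[i] / s0[i] - (s1[i] / s0[i]) ** 2))
        return ll, u, info

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, u, info = score_info(beta)
        if info <= 0:
            break
        step = u / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol:
            converged = True
            break
    _, _, info = score_info(beta)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    z = beta / se if se > 0 else float("nan")
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return {
        "beta": float(beta),
        "hazard_ratio": float(np.exp(beta)),
        "se": se,
        "wald_p": p,
        "converged": converged,
    }


def survival_association(clinical: pd.DataFrame, marker_col: str = "marker",
                         minprop: float = 0.1) -> dict:
    """One-stop association of a marker with overall survival.

    Runs the optimal-cutpoint dichotomization, the log-rank test at that
    cutpoint and a continuous-marker univariate Cox fit; returns a flat
    result dict plus the per-group KM curves.
    """
    t = clinical["time"].to_numpy(dtype=float)
    e = clinical["event"].to_numpy(dtype=int)
    x = clinical[marker_col].to_numpy(dtype=float)
    cut = optimal_cutpoint(t, e, x, minprop=minprop)
    cox = cox_univariate(t, e, x)
    high = x > cut.cutpoint
    return {
        "cutpoint": cut.cutpoint,
        "logrank_chi2": cut.logrank_chi2,
        "logrank_p": cut.logrank_p,
        "n_low": cut.n_low,
        "n_high": cut.n_high,
        "cox_beta": cox["beta"],
        "hazard_ratio": cox["hazard_ratio"],
        "cox_wald_p": cox["wald_p"],
        "cox_converged": cox["converged"],
        "km_high": km_curve(t[high], e[high]),
        "km_low": km_curve(t[~high], e[~high]),
    }
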