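"""Associate a methylation marker with overall survival.

A 300-subject validation cohort draws its survival times from an
exponential model whose log-hazard rises with the marker; the analysis
dichotomizes at the optimal log-rank cutpoint, compares the groups by
Kaplan-Meier / log-rank and fits a univariate Cox model on the continuous
marker.
"""

import numpy as np

from oxmeth.cohort import simulate_survival
from oxmeth.survival import survival_association

rng = np.random.default_rng(6)
marker = rng.beta(0.7 * 10, 0.3 * 10, 300)  # promoter methylation levels
clinical = simulate_survival(marker, log_hr=3.0, censor_time=1825.0, rng=rng)
print(f"events observed: {clinical['event'].sum()} / 300 within 5 years")

res = survival_association(clinical)
print(f"optimal cutpoint: {res['cutpoint']:.3f} "
      f"({res['n_low']} low vs {res['n_high']} high)")
print(f"log-rank chi2 = {res['logrank_chi2']:.2f}, p = {res['logrank_p']:.2e}")
print(f"Cox: beta = {res['cox_beta']:.3f}, HR = {res['hazard_ratio']:.2f} "
      f"per unit marker (Wald p = {res['cox_wald_p']:.2e})")
km = res["km_high"]
print(f"high-group survival at last event: {km['survival'].iloc[-1]:.3f}")
# The Cox slope should recover the generating log-hazard coefficient (3.0)
# within sampling error, and the dichotomized groups separate clearly.
# Note: the log-rank p at the scanned cutpoint is not corrected for the
# maximal selection (pass correct='permutation' to optimal_cutpoint for a
# calibrated p).
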