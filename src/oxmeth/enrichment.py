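"""Genomic-feature enrichment of DMRs/DhMRs against a random-region null.

For each query region a random region of identical length is placed
uniformly over the genome (chromosome chosen proportionally to the number
of valid start positions).  For every feature class we count query and
random regions with/without any overlap, compute the enrichment fold
(observed in-rate over random in-rate) and an upper-tail hypergeometric p
on the pooled 2x2 construction: population = query + random regions,
successes = regions overlapping the feature, draws = the query set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import as_intervals, overlap_any

STAR_LEVELS = ((0.001, "$"), (0.01, "#"), (0.05, "*"))


@dataclass(frozen=True)
class EnrichmentResult:
    feature_class: str
    n_obs_in: int
    n_obs_out: int
    n_rand_in: int
    n_rand_out: int
    fold: float
    p_hyper: float
    stars: str


def random_regions(query_regions: pd.DataFrame, chrom_sizes: dict[str, int],
                   seed=None, n_draws: int = 1) -> pd.DataFrame:
    """Length-matched random regions, ``n_draws`` per query region.

    Placement is uniform over all valid start positions genome-wide: the
    chromosome is picked with probability proportional to size - L + 1.
    """
    query_regions = as_intervals(query_regions)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    rows = []
    lengths = (query_regions["end"] - query_regions["start"]).to_numpy()
    for L in np.repeat(lengths, n_draws):
        avail = sizes - L + 1
        avail = np.maximum(avail, 0)
        if avail.sum() == 0:
            raise ValueError(f"region of length {L} exceeds every chromosome")
        probs = avail / avail.sum()
        ci = rng.choice(len(chroms), p=probs)
        start = int(rng.integers(0, avail[ci]))
        rows.append((chroms[ci], start, start + int(L)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlap_flag(regions: pd.DataFrame, feature_intervals: pd.DataFrame) -> np.ndarray:
    """True per region iff it intersects >= 1 bp of the feature set."""
    return overlap_any(regions, feature_intervals)


def hypergeom_enrichment(n_obs_in: int, n_obs_out: int,
                         n_rand_in: int, n_rand_out: int) -> tuple[float, float]:
    """(fold, p) for one feature class.

    p = P(X >= n_obs_in) with X ~ Hypergeom(N = all regions,
    K = all in-feature regions, n = query regions).
    fold = (obs in-rate)/(rand in-rate); +inf when the random set has no
    overlap but the observed set does, NaN when neither has any.
    """
    for v in (n_obs_in, n_obs_out, n_rand_in, n_rand_out):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    n_obs = n_obs_in + n_obs_out
    n_rand = n_rand_in + n_rand_out
    if n_obs == 0 or n_rand == 0:
        raise ValueError("observed and random sets must be nonempty")
    N = n_obs + n_rand
    K = n_obs_in + n_rand_in
    p = float(hypergeom.sf(n_obs_in - 1, N, K, n_obs))
    obs_rate = n_obs_in / n_obs
    rand_rate = n_rand_in / n_rand
    if rand_rate > 0:
        fold = obs_rate / rand_rate
    elif obs_rate > 0:
        fold = float("inf")
    else:
        fold = float("nan")
    return fold, min(p, 1.0)


def _stars(p: float) -> str:
    for thr, sym in STAR_LEVELS:
        if p < thr:
            return sym
    return ""


def enrich_all(query_regions: pd.DataFrame, catalog: dict[str, pd.DataFrame],
               chrom_sizes: dict[str, int], seed=None, n_draws: int = 1) -> pd.DataFrame:
    """Evaluate every feature class against one shared random draw.

    Returns a frame with per-class counts, fold, hypergeometric p and
    significance stars (* p<0.05, # p<0.01, $ p<0.001).
    """
    query_regions = as_intervals(query_regions)
    rand = random_regions(query_regions, chrom_sizes, seed=seed, n_draws=n_draws)
    rows = []
    for cls, feats in catalog.items():
        if len(feats) == 0:
            rows.append(EnrichmentResult(cls, 0, len(query_regions), 0, len(rand),
                                         float("nan"), 1.0, ""))
            continue
        obs_in = int(overlap_flag(query_regions, feats).sum())
        rand_in = int(overlap_flag(rand, feats).sum())
        fold, p = hypergeom_enrichment(obs_in, len(query_regions) - obs_in,
                                       rand_in, len(rand) - rand_in)
        rows.append(EnrichmentResult(cls, obs_in, len(query_regions) - obs_in,
                                     rand_in, len(rand) - rand_in, fold, p, _stars(p)))
    return pd.DataFrame([r.__dict__ for r in rows])
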