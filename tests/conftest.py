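import numpy as np
import pytest
from hypothesis import settings

from oxmeth import cohort

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_genome():
    """A 2 x 300 kb toy genome reused across tests (read-only)."""
    return cohort.simulate_genome(seed=11, n_chrom=2, chrom_len_bp=300_000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_two_group_matrix(rng, n_sites=120, n_per_group=4, depth=30,
                          base=0.5, effect=0.0, planted=None, spacing=50):
    """Beta-count matrix for DMR tests; ``planted`` is a (start, end) site
    slice receiving ``effect`` on the case side."""
    from oxmeth.dmr import MethMatrix

    pos = np.arange(n_sites) * spacing + 100
    mu = np.full(n_sites, base)
    levels = np.empty((n_sites, 2 * n_per_group))
    depths = np.full((n_sites, 2 * n_per_group), float(depth))
    for j in range(2 * n_per_group):
        m = mu.copy()
        if planted is not None and j < n_per_group:  # case columns first
            m[planted[0]:planted[1]] = np.clip(m[planted[0]:planted[1]] + effect, 0, 1)
        k = rng.binomial(depth, m)
        levels[:, j] = k / depth
    groups = np.array(["case"] * n_per_group + ["control"] * n_per_group)
    return MethMatrix(np.array(["chr1"] * n_sites), pos, levels, groups, depths,
                      [f"s{j}" for j in range(2 * n_per_group)])
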