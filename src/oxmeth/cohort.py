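"""Synthetic BS/oxBS cohort generator with known ground truth.

Emulates the study design the pipeline is built for: a small cervical
cohort spanning healthy tissue, the CIN1/2/3 precancerous grades, cervical
cancer (CC) and adjacent paracancer tissue, profiled by paired
whole-genome bisulfite (BS) and oxidative bisulfite (oxBS) libraries.

What is generated, and with what defaults:

* a toy genome with clustered CpGs (island-like dense stretches) and a
  consistent annotation catalog (islands, +/-1 kb shores, shelves, genes
  with exons/introns/UTRs, promoters, boundaries, 1-5 kb flanks,
  enhancers, intergenic);
* per-sample truth methylomes (p_u, p_m, p_h per CpG): Beta-distributed
  site levels around per-stage mean 5mC/5hmC levels (defaults are the
  observed stage averages: 5mC 76.58/78.57/79.84/72.13/68.66% and 5hmC
  1.83/1.141/0.82/3.62/0.94% for healthy/CIN1/CIN2/CIN3/CC), with planted
  DMR/DhMR regions of configurable effect size and direction;
* paired binomial read counts per channel with realistic conversion error
  (bisulfite 99.92%, oxidative 96.57%) plus two spike-in control contigs
  (fully unmodified; fully hydroxymethylated) mirroring lambda/CEGX
  controls;
* Poisson per-bin read-depth tracks with planted copy-number segments;
* gene expression anti-correlated with promoter methylation, and a
  survival validation cohort whose exponential log-hazard is linear in a
  marker level.

Everything is driven by numpy Generator seeds: identical seed + config
give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import complement_intervals, merge_intervals

DEFAULT_STAGES = ("healthy", "CIN1", "CIN2", "CIN3", "CC", "paracancer")

# Observed per-stage global means (proportions).  Two healthy presets are
# exposed because the study reports both a per-stage average (76.58/1.83)
# and a trend-sentence average (72.45/3.31) for the healthy group.
STAGE_MEAN_PRESETS = {
    "stage_list": {
        "5mC": {"healthy": 0.7658, "CIN1": 0.7857, "CIN2": 0.7984,
                "CIN3": 0.7213, "CC": 0.6866, "paracancer": 0.72},
        "5hmC": {"healthy": 0.0183, "CIN1": 0.01141, "CIN2": 0.0082,
                 "CIN3": 0.0362, "CC": 0.0094, "paracancer": 0.015},
    },
    "trend": {
        "5mC": {"healthy": 0.7245, "CIN1": 0.7857, "CIN2": 0.7984,
                "CIN3": 0.7213, "CC": 0.6866, "paracancer": 0.72},
        "5hmC": {"healthy": 0.0331, "CIN1": 0.01141, "CIN2": 0.0082,
                 "CIN3": 0.0362, "CC": 0.0094, "paracancer": 0.015},
    },
}

SPIKE_UNMETH = "spikein_unmeth"
SPIKE_HMC = "spikein_hmc"


@dataclass(frozen=True)
class CohortConfig:
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_per_stage: int = 2
    stage_mean_5mC: dict = field(default_factory=lambda: dict(STAGE_MEAN_PRESETS["stage_list"]["5mC"]))
    stage_mean_5hmC: dict = field(default_factory=lambda: dict(STAGE_MEAN_PRESETS["stage_list"]["5hmC"]))
    bs_conv: float = 0.9992
    ox_conv: float = 0.9657
    depth_mean: float = 10.0
    concentration: float = 30.0  # Beta concentration of site-level noise
    seed: int = 0

    def __post_init__(self):
        if self.n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")
        for name in ("bs_conv", "ox_conv"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for st in self.stages:
            m = self.stage_mean_5mC[st]
            h = self.stage_mean_5hmC[st]
            if not (0.0 <= m <= 1.0 and 0.0 <= h <= 1.0):
                raise ValueError(f"stage means for {st} outside [0, 1]")
            if m + h > 1.0:
                raise ValueError(f"stage 5mC+5hmC exceeds 1 for {st}")

    @classmethod
    def preset(cls, name: str = "stage_list", **kwargs) -> "CohortConfig":
        p = STAGE_MEAN_PRESETS[name]
        return cls(stage_mean_5mC=dict(p["5mC"]), stage_mean_5hmC=dict(p["5hmC"]), **kwargs)

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for st in self.stages:
            for i in range(self.n_per_stage):
                rows.append((f"{st}_{i + 1}", st))
        return pd.DataFrame(rows, columns=["sample", "stage"])


@dataclass(frozen=True)
class PlantSpec:
    """A planted differential region: effect applied to target stages."""

    n_cpg: int
    effect: float
    direction: str  # 'hyper' | 'hypo'
    channel: str  # '5mC' | '5hmC'
    stages: tuple[str, ...]
    chrom: str | None = None

    def __post_init__(self):
        if self.n_cpg < 1:
            raise ValueError("plant must span >= 1 CpG")
        if not 0.0 < self.effect <= 1.0:
            raise ValueError("effect size must lie in (0, 1]")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be hyper or hypo")
        if self.channel not in ("5mC", "5hmC"):
            raise ValueError("channel must be 5mC or 5hmC")


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    cpg_pos: dict[str, np.ndarray]
    catalog: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    spikein_sizes: dict[str, int]
    spikein_pos: dict[str, np.ndarray]
    promoters: pd.DataFrame | None = None  # chrom,start,end,strand,gene

    @property
    def n_cpg(self) -> int:
        return sum(len(p) for p in self.cpg_pos.values())

    def sites(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"chrom": c, "pos": p}) for c, p in self.cpg_pos.items()]
        return pd.concat(frames, ignore_index=True)


def _geometric_positions(rng, length, mean_gap, start=0):
    n_guess = int(length / mean_gap * 1.5) + 20
    gaps = rng.geometric(1.0 / mean_gap, size=n_guess)
    pos = start + np.cumsum(gaps)
    while pos[-1] < start + length:
        extra = rng.geometric(1.0 / mean_gap, size=n_guess)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos < start + length]


def simulate_genome(seed: int = 0, n_chrom: int = 2, chrom_len_bp: int = 1_000_000,
                    island_spacing: int = 20_000, gene_spacing: int = 50_000,
                    bg_cpg_gap: float = 120.0, island_cpg_gap: float = 12.0) -> Genome:
    """Toy genome: clustered CpGs plus a self-consistent annotation catalog.

    Island/gene placement uses fixed grids with seeded jitter, which keeps
    every per-class interval set free of self-overlap by construction
    (shores/shelves of neighboring islands cannot collide).
    """
    if n_chrom < 1:
        raise ValueError("need >= 1 chromosome")
    if chrom_len_bp < 10_000:
        raise ValueError("chromosomes must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": int(chrom_len_bp) for i in range(n_chrom)}

    islands, genes_rows = [], []
    enhancers = []
    gene_id = 0
    for chrom, size in chrom_sizes.items():
        # CpG islands on a coarse grid; >= ~17 kb gaps keep shelves disjoint
        for g0 in range(6_000, size - 8_000, island_spacing):
            start = g0 + int(rng.integers(0, island_spacing // 8))
            length = int(rng.integers(600, 1400))
            if start + length + 3_000 >= size:
                continue
            islands.append((chrom, start, start + length))
        # genes on their own grid, alternating strand
        for g0 in range(12_000, size - 30_000, gene_spacing):
            start = g0 + int(rng.integers(0, 4_000))
            length = int(rng.integers(10_000, 22_000))
            strand = "+" if gene_id % 2 == 0 else "-"
            genes_rows.append((chrom, start, start + length, strand, f"gene{gene_id:04d}"))
            gene_id += 1
            enh = start + length + int(rng.integers(6_000, 10_000))
            if enh + 600 < size:
                enhancers.append((chrom, enh, enh + 600))

    islands_df = pd.DataFrame(islands, columns=["chrom", "start", "end"])
    genes_df = pd.DataFrame(genes_rows, columns=["chrom", "start", "end", "strand", "gene"])

    # shores: +/- 1 kb island flanks; shelves: the next 2 kb outward
    shores, shelves = [], []
    for r in islands_df.itertuples(index=False):
        shores += [(r.chrom, r.start - 1_000, r.start), (r.chrom, r.end, r.end + 1_000)]
        shelves += [(r.chrom, r.start - 3_000, r.start - 1_000),
                    (r.chrom, r.end + 1_000, r.end + 3_000)]
    shores_df = pd.DataFrame(shores, columns=["chrom", "start", "end"])
    shelves_df = pd.DataFrame(shelves, columns=["chrom", "start", "end"])

    exons, introns, promoters, utr5, utr3, boundaries, flanks = [], [], [], [], [], [], []
    for g in genes_df.itertuples(index=False):
        n_ex = int(rng.integers(3, 7))
        # split the gene into alternating exon/intron blocks
        edges = np.sort(rng.choice(np.arange(g.start + 200, g.end - 200, 50),
                                   size=2 * n_ex - 2, replace=False))
        blocks = np.concatenate([[g.start], edges, [g.end]])
        ex_list = []
        for i in range(0, len(blocks) - 1, 2):
            ex_list.append((int(blocks[i]), int(blocks[i + 1])))
        for i in range(1, len(blocks) - 1, 2):
            introns.append((g.chrom, int(blocks[i]), int(blocks[i + 1])))
        for s, e in ex_list:
            exons.append((g.chrom, s, e))
            for edge in (s, e):
                boundaries.append((g.chrom, max(edge - 150, 0), edge + 150))
        if g.strand == "+":
            promoters.append((g.chrom, g.start - 1_000, g.start, g.strand, g.gene))
            utr5.append((g.chrom, ex_list[0][0], min(ex_list[0][0] + 120, ex_list[0][1])))
            utr3.append((g.chrom, max(ex_list[-1][1] - 150, ex_list[-1][0]), ex_list[-1][1]))
        else:
            promoters.append((g.chrom, g.end, g.end + 1_000, g.strand, g.gene))
            utr5.append((g.chrom, max(ex_list[-1][1] - 120, ex_list[-1][0]), ex_list[-1][1]))
            utr3.append((g.chrom, ex_list[0][0], min(ex_list[0][0] + 150, ex_list[0][1])))
        flanks += [(g.chrom, max(g.start - 5_000, 0), max(g.start - 1_000, 0)),
                   (g.chrom, g.end + 1_000, g.end + 5_000)]

    promoters_df = pd.DataFrame(promoters, columns=["chrom", "start", "end", "strand", "gene"])
    catalog = {
        "CpG_island": islands_df,
        "CpG_shore": shores_df,
        "CpG_shelf": shelves_df,
        "gene_body": genes_df[["chrom", "start", "end"]].copy(),
        "exon": merge_intervals(pd.DataFrame(exons, columns=["chrom", "start", "end"])),
        "intron": merge_intervals(pd.DataFrame(introns, columns=["chrom", "start", "end"])),
        "promoter": promoters_df[["chrom", "start", "end"]].copy(),
        "5UTR": merge_intervals(pd.DataFrame(utr5, columns=["chrom", "start", "end"])),
        "3UTR": merge_intervals(pd.DataFrame(utr3, columns=["chrom", "start", "end"])),
        "boundary": merge_intervals(pd.DataFrame(boundaries, columns=["chrom", "start", "end"])),
        "flank_1_5kb": merge_intervals(pd.DataFrame(flanks, columns=["chrom", "start", "end"])),
        "enhancer": pd.DataFrame(enhancers, columns=["chrom", "start", "end"]),
    }
    covered = pd.concat(
        [genes_df[["chrom", "start", "end"]], promoters_df[["chrom", "start", "end"]],
         catalog["flank_1_5kb"]], ignore_index=True)
    catalog["intergenic"] = complement_intervals(covered, chrom_sizes)

    cpg_pos = {}
    for chrom, size in chrom_sizes.items():
        bg = _geometric_positions(rng, size, bg_cpg_gap)
        dense = []
        for r in islands_df[islands_df["chrom"] == chrom].itertuples(index=False):
            dense.append(_geometric_positions(rng, r.end - r.start, island_cpg_gap, start=r.start))
        pos = np.unique(np.concatenate([bg] + dense)) if dense else np.unique(bg)
        cpg_pos[chrom] = pos.astype(np.int64)

    # dense control contigs: ~800 CpGs each so pooled conversion estimates
    # resolve rates of order 1e-3 at modest depth
    spike_sizes = {SPIKE_UNMETH: 4_000, SPIKE_HMC: 4_000}
    spike_pos = {k: np.arange(10, v, 5, dtype=np.int64) for k, v in spike_sizes.items()}
    return Genome(chrom_sizes, cpg_pos, catalog, genes_df, spike_sizes, spike_pos,
                  promoters=promoters_df)


def _beta_around(rng, mean, conc, size):
    """Beta draw with the given mean and concentration; degenerate at 0/1."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    out = np.empty(size)
    interior = (mean > 0.0) & (mean < 1.0)
    out[~interior] = mean[~interior]
    if interior.any():
        a = mean[interior] * conc
        b = (1.0 - mean[interior]) * conc
        out[interior] = rng.beta(a, b)
    return out


def place_plants(genome: Genome, plant_specs: list[PlantSpec], rng) -> pd.DataFrame:
    """Assign each plant a run of consecutive CpGs; runs never overlap."""
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.cpg_pos}
    rows = []
    for k, spec in enumerate(plant_specs):
        chroms = [spec.chrom] if spec.chrom else list(genome.cpg_pos)
        placed = False
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = genome.cpg_pos[chrom]
            if len(pos) < spec.n_cpg:
                continue
            i0 = int(rng.integers(0, len(pos) - spec.n_cpg + 1))
            i1 = i0 + spec.n_cpg
            if any(not (i1 <= a or i0 >= b) for a, b in taken[chrom]):
                continue
            taken[chrom].append((i0, i1))
            rows.append((k, chrom, int(pos[i0]), int(pos[i1 - 1]) + 1, i0, i1,
                         spec.n_cpg, spec.effect, spec.direction, spec.channel,
                         ",".join(spec.stages)))
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place plant {k} (genome too small?)")
    return pd.DataFrame(rows, columns=["plant_id", "chrom", "start", "end", "cpg_i0",
                                       "cpg_i1", "n_cpg", "effect", "direction",
                                       "channel", "stages"])


def make_truth(config: CohortConfig, genome: Genome,
               plant_specs: list[PlantSpec] | None = None,
               rng=None) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample truth methylomes (p_u, p_m, p_h per CpG) plus plant table.

    Site levels are Beta-distributed around the per-stage means; planted
    regions shift the target channel's mean by +/- effect in the target
    stages (clipped to [0,1] with a warning if the shift leaves the unit
    interval).  p_u + p_m + p_h = 1 everywhere.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    plants = place_plants(genome, plant_specs or [], rng)
    sites = genome.sites()
    n = len(sites)
    chrom_arr = sites["chrom"].to_numpy()
    truth: dict[str, pd.DataFrame] = {}
    for _, (sample, stage) in config.sample_table().iterrows():
        mu_m = np.full(n, config.stage_mean_5mC[stage])
        mu_h = np.full(n, config.stage_mean_5hmC[stage])
        for pl in plants.itertuples(index=False):
            if stage not in pl.stages.split(","):
                continue
            mask = np.where(chrom_arr == pl.chrom)[0][pl.cpg_i0:pl.cpg_i1]
            delta = pl.effect if pl.direction == "hyper" else -pl.effect
            target = mu_m if pl.channel == "5mC" else mu_h
            shifted = target[mask] + delta
            if np.any((shifted < 0) | (shifted > 1)):
                warnings.warn(f"plant {pl.plant_id} effect clipped to [0, 1] in {sample}")
            target[mask] = np.clip(shifted, 0.0, 1.0)
        p_m = _beta_around(rng, mu_m, config.concentration, n)
        p_h = _beta_around(rng, mu_h, config.concentration, n)
        over = p_m + p_h > 1.0
        if over.any():  # rare: rescale onto the simplex
            s = p_m[over] + p_h[over]
            p_m[over] /= s
            p_h[over] /= s
        truth[sample] = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "pos": sites["pos"].to_numpy(),
                "p_u": 1.0 - p_m - p_h,
                "p_m": p_m,
                "p_h": p_h,
            }
        )
    return truth, plants


def channel_probs(p_u, p_m, p_h, bs_conv, ox_conv):
    """Per-read methylated-call probabilities of the BS and oxBS channels."""
    q_bs = p_m + p_h + p_u * (1.0 - bs_conv)
    q_ox = p_m + p_h * (1.0 - ox_conv) + p_u * (1.0 - bs_conv)
    return q_bs, q_ox


def simulate_counts(truth: dict[str, pd.DataFrame], config: CohortConfig,
                    genome: Genome | None = None, depth_mean: float | None = None,
                    rng=None) -> dict[str, pd.DataFrame]:
    """Binomial BS/oxBS count tables per sample, spike-in contigs included.

    Depth is Poisson per site per channel; zero-depth rows are retained.
    Spike-in truth: the unmethylated control has p_u = 1, the oxidation
    control p_h = 1.
    """
    depth_mean = config.depth_mean if depth_mean is None else depth_mean
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    counts: dict[str, pd.DataFrame] = {}
    for sample, tr in truth.items():
        frames = [tr]
        if genome is not None:
            sp = []
            for contig, pos in genome.spikein_pos.items():
                p_u = 1.0 if contig == SPIKE_UNMETH else 0.0
                p_h = 1.0 if contig == SPIKE_HMC else 0.0
                sp.append(pd.DataFrame({"chrom": contig, "pos": pos,
                                        "p_u": p_u, "p_m": 0.0, "p_h": p_h}))
            frames = [tr] + sp
        full = pd.concat(frames, ignore_index=True)
        q_bs, q_ox = channel_probs(full["p_u"].to_numpy(), full["p_m"].to_numpy(),
                                   full["p_h"].to_numpy(), config.bs_conv, config.ox_conv)
        q_bs = np.clip(q_bs, 0.0, 1.0)  # guard float round-off at the simplex edge
        q_ox = np.clip(q_ox, 0.0, 1.0)
        n = len(full)
        bs_depth = rng.poisson(depth_mean, size=n)
        ox_depth = rng.poisson(depth_mean, size=n)
        bs_meth = rng.binomial(bs_depth, q_bs)
        ox_meth = rng.binomial(ox_depth, q_ox)
        counts[sample] = pd.DataFrame(
            {
                "chrom": full["chrom"],
                "pos": full["pos"],
                "strand": "+",
                "bs_meth": bs_meth,
                "bs_depth": bs_depth,
                "ox_meth": ox_meth,
                "ox_depth": ox_depth,
            }
        )
    return counts


def simulate_meth_matrix(n_sites: int = 200, n_per_group: int = 4, depth: int = 30,
                         base_mean: float = 0.5, effect: float = 0.0,
                         plant: tuple[int, int] | None = None,
                         concentration: float = 30.0, spacing: int = 50,
                         rng=None):
    """Two-group site-by-sample level matrix for power/null studies.

    Per site and sample, a truth level is drawn Beta(mean, concentration)
    — case samples shifted by ``effect`` inside the planted site slice —
    and observed as a binomial proportion at the given read depth.  Returns
    a :class:`oxmeth.dmr.MethMatrix` (case columns first).
    """
    from .dmr import MethMatrix

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pos = np.arange(n_sites) * spacing + 100
    n_samples = 2 * n_per_group
    levels = np.empty((n_sites, n_samples))
    for j in range(n_samples):
        mu = np.full(n_sites, base_mean)
        if plant is not None and j < n_per_group:
            mu[plant[0]:plant[1]] = np.clip(mu[plant[0]:plant[1]] + effect, 0.0, 1.0)
        truth = _beta_around(rng, mu, concentration, n_sites)
        levels[:, j] = rng.binomial(depth, truth) / depth
    groups = np.array(["case"] * n_per_group + ["control"] * n_per_group)
    depths = np.full((n_sites, n_samples), float(depth))
    return MethMatrix(np.array(["chr1"] * n_sites), pos, levels, groups, depths,
                      [f"s{j}" for j in range(n_samples)])


@dataclass(frozen=True)
class CnvPlant:
    chrom: str
    start_bin: int
    n_bins: int
    copy_number: float  # diploid = 2

    def __post_init__(self):
        if self.n_bins < 1 or self.copy_number < 0:
            raise ValueError("invalid CNV plant")


def simulate_depth_track(genome_or_sizes, cnv_plants: list[CnvPlant] | None = None,
                         bin_bp: int = 33_000, baseline_depth: float = 100.0,
                         seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson per-bin read depths with planted copy-number segments.

    Returns (bin table with 'depth', truth segment table).  Overlapping
    plants are rejected.
    """
    from .integration import bin_genome

    if bin_bp < 1_000:
        raise ValueError("bin_bp must be >= 1000")
    sizes = genome_or_sizes.chrom_sizes if isinstance(genome_or_sizes, Genome) else dict(genome_or_sizes)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bins = bin_genome(sizes, bin_bp)
    ratio = np.ones(len(bins))
    plants = cnv_plants or []
    seen: list[tuple[str, int, int]] = []
    truth_rows = []
    for pl in plants:
        ix = np.where(bins["chrom"] == pl.chrom)[0]
        if pl.start_bin + pl.n_bins > len(ix):
            raise ValueError(f"CNV plant exceeds {pl.chrom}")
        a, b = pl.start_bin, pl.start_bin + pl.n_bins
        for (c0, a0, b0) in seen:
            if c0 == pl.chrom and not (b <= a0 or a >= b0):
                raise ValueError("overlapping CNV plants")
        seen.append((pl.chrom, a, b))
        ratio[ix[a:b]] = pl.copy_number / 2.0
        truth_rows.append((pl.chrom, int(bins.iloc[ix[a]]["start"]),
                           int(bins.iloc[ix[b - 1]]["end"]), pl.copy_number))
    depth = rng.poisson(baseline_depth * ratio)
    out = bins.copy()
    out["depth"] = depth
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "copy_number"])
    return out, truth


def promoter_methylation(truth: dict[str, pd.DataFrame], genome: Genome) -> pd.DataFrame:
    """Mean truth p_m per promoter per sample (genes x samples)."""
    proms = genome.promoters
    any_truth = next(iter(truth.values()))
    chrom_arr = any_truth["chrom"].to_numpy()
    pos_arr = any_truth["pos"].to_numpy()
    rows = {}
    for g in proms.itertuples(index=False):
        mask = (chrom_arr == g.chrom) & (pos_arr >= g.start) & (pos_arr < g.end)
        rows[g.gene] = mask
    data = {}
    for sample, tr in truth.items():
        pm = tr["p_m"].to_numpy()
        data[sample] = {gene: (float(pm[mask].mean()) if mask.any() else np.nan)
                        for gene, mask in rows.items()}
    return pd.DataFrame(data)


def simulate_expression(promoter_meth: pd.DataFrame, baseline: float = 10.0,
                        slope: float = 5.0, noise_sd: float = 0.5,
                        rng=None) -> pd.DataFrame:
    """Expression anti-correlated with promoter methylation.

    expression = baseline - slope * (promoter mean 5mC) + Normal(0, noise_sd).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    vals = baseline - slope * promoter_meth.to_numpy(dtype=float)
    vals = vals + rng.normal(0.0, noise_sd, size=vals.shape) if noise_sd > 0 else vals
    return pd.DataFrame(vals, index=promoter_meth.index, columns=promoter_meth.columns)


def classify_expression(expr_case, expr_ref, fold_change: float = 2.0) -> pd.Series:
    """high/low/no expression classes by |fold change| >= the cutoff."""
    case = np.asarray(expr_case, dtype=float)
    ref = np.asarray(expr_ref, dtype=float)
    eps = 1e-9
    fc = (case + eps) / (ref + eps)
    cls = np.where(fc >= fold_change, "high", np.where(fc <= 1.0 / fold_change, "low", "no"))
    idx = expr_case.index if isinstance(expr_case, pd.Series) else None
    return pd.Series(cls, index=idx, name="expr_class")


def simulate_survival(marker, log_hr: float = 0.7, base_rate: float = 1.0 / 1000.0,
                      censor_time: float = 1825.0, rng=None,
                      ids=None) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in the (centered) marker.

    time = min(Exp(rate), censor_time); event = 1 if the raw time falls
    before administrative censoring.  Times are in days by convention.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = np.asarray(marker, dtype=float)
    rate = base_rate * np.exp(log_hr * (x - x.mean()))
    raw = rng.exponential(1.0 / rate)
    time = np.minimum(raw, censor_time)
    event = (raw <= censor_time).astype(int)
    ids = ids if ids is not None else [f"subj{i:04d}" for i in range(len(x))]
    return pd.DataFrame({"sample": ids, "time": time, "event": event, "marker": x})


def simulate_expression_survival(truth: dict[str, pd.DataFrame], config: CohortConfig,
                                 genome: Genome, n_subjects: int = 300,
                                 log_hr: float = 0.7, rng=None
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression table for the cohort + a survival validation cohort.

    The validation cohort (default n=300, emulating an external array
    cohort) draws its marker — a promoter methylation level — from a Beta
    around the cohort-wide promoter mean, and couples the hazard to it.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    prom = promoter_methylation(truth, genome)
    expr = simulate_expression(prom, rng=rng)
    overall = float(np.nanmean(prom.to_numpy()))
    overall = min(max(overall, 0.05), 0.95)
    marker = rng.beta(overall * 10.0, (1.0 - overall) * 10.0, size=n_subjects)
    clinical = simulate_survival(marker, log_hr=log_hr, rng=rng)
    return expr, clinical
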