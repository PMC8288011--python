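"""Simulate a small BS/oxBS cervical cohort with known ground truth.

Builds a 2 x 1 Mb toy genome with CpG islands and gene annotations, draws
per-stage truth methylomes (healthy -> CIN1/2/3 -> cancer -> paracancer),
plants one hyper-DMR in the cancer samples and emits paired binomial
BS/oxBS read counts at ~10x depth.
"""

import numpy as np

from oxmeth.cohort import CohortConfig, PlantSpec, make_truth, simulate_counts, simulate_genome

genome = simulate_genome(seed=1, n_chrom=2, chrom_len_bp=1_000_000)
config = CohortConfig(n_per_stage=2, seed=1)
plant = PlantSpec(n_cpg=25, effect=0.3, direction="hyper", channel="5mC", stages=("CC",))
truth, plants = make_truth(config, genome, [plant])
counts = simulate_counts(truth, config, genome=genome)

print(f"genome: {genome.n_cpg} CpGs on {len(genome.chrom_sizes)} chromosomes, "
      f"{len(genome.catalog)} annotation classes")
print(f"planted DMR: {plants.iloc[0]['chrom']}:{plants.iloc[0]['start']}-"
      f"{plants.iloc[0]['end']} ({plants.iloc[0]['n_cpg']} CpGs, effect +0.3 in CC)")
for sample in ("healthy_1", "CIN3_1", "CC_1"):
    tr = truth[sample]
    ct = counts[sample]
    bs_beta = ct["bs_meth"].sum() / ct["bs_depth"].sum()
    print(f"{sample:12s} truth mean 5mC={tr['p_m'].mean():.4f} "
          f"5hmC={tr['p_h'].mean():.4f}  observed BS beta={bs_beta:.4f}")
# The truth means track the configured per-stage averages; the BS beta
# exceeds the 5mC mean because bisulfite reads 5mC + 5hmC as methylated.
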