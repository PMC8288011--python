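"""Stage orchestration: simulate -> estimate -> dmr -> enrich -> integrate -> survival.

Each stage reads only files written by upstream stages, writes its outputs
atomically (temp + rename) and records a manifest JSON with input/output
hashes, parameters and the seed, so a run is reproducible from the
manifest chain alone.  All randomness derives deterministically from the
single pipeline seed.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, dmr, enrichment, integration, io, quant, survival

STAGES = ("simulate", "estimate", "dmr", "enrich", "integrate", "survival")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome": {"n_chrom": 2, "chrom_len_bp": 1_000_000},
    "cohort": {
        "n_per_stage": 2,
        "depth_mean": 10.0,
        "bs_conv": 0.9992,
        "ox_conv": 0.9657,
        "preset": "stage_list",
    },
    "plants": [
        {"n_cpg": 25, "effect": 0.3, "direction": "hyper", "channel": "5mC", "stages": ["CC"]},
        {"n_cpg": 25, "effect": 0.3, "direction": "hypo", "channel": "5mC", "stages": ["CC"]},
        {"n_cpg": 25, "effect": 0.3, "direction": "hyper", "channel": "5hmC", "stages": ["CIN3"]},
    ],
    "cnv": {
        "bin_bp": 33_000,
        "baseline_depth": 100.0,
        "plants": [
            {"chrom": "chr1", "start_bin": 5, "n_bins": 10, "copy_number": 4.0},
            {"chrom": "chr2", "start_bin": 12, "n_bins": 8, "copy_number": 1.0},
        ],
        "case_stage": "CC",
    },
    "variants": {"n": 300},
    "dmr": {
        "case_stage": "CC",
        "control_stage": "healthy",
        "diff_threshold": 0.2,
        "min_coverage": 5,
        "min_cpg": 5,
        "valley_filter": 0.05,
        "p_threshold": 0.001,
    },
    "enrich": {"n_draws": 1},
    "survival": {"n_subjects": 300, "log_hr": 3.0, "minprop": 0.1},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def deep_update(base, upd):
        for k, v in upd.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                deep_update(base[k], v)
            else:
                base[k] = v

    if path is not None:
        deep_update(cfg, io.read_yaml(path) or {})
    if overrides:
        deep_update(cfg, overrides)
    return cfg


class MissingUpstream(RuntimeError):
    def __init__(self, artifact, producer):
        super().__init__(
            f"missing upstream artifact {artifact}; run the '{producer}' stage first")
        self.producer = producer


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise MissingUpstream(path, producer)
    return Path(path)


def _cohort_config(cfg: dict) -> cohort.CohortConfig:
    c = cfg["cohort"]
    return cohort.CohortConfig.preset(
        c.get("preset", "stage_list"),
        n_per_stage=int(c["n_per_stage"]),
        depth_mean=float(c["depth_mean"]),
        bs_conv=float(c["bs_conv"]),
        ox_conv=float(c["ox_conv"]),
        seed=int(cfg["seed"]),
    )


def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    seed = int(cfg["seed"])
    config = _cohort_config(cfg)
    genome = cohort.simulate_genome(seed=seed, **cfg["genome"])
    specs = [cohort.PlantSpec(n_cpg=int(p["n_cpg"]), effect=float(p["effect"]),
                              direction=p["direction"], channel=p["channel"],
                              stages=tuple(p["stages"]))
             for p in cfg.get("plants", [])]
    truth, plants = cohort.make_truth(config, genome, specs,
                                      rng=np.random.default_rng(seed))
    counts = cohort.simulate_counts(truth, config, genome=genome,
                                    rng=np.random.default_rng(seed + 1))
    outputs = []
    samples = config.sample_table()
    outputs.append(io.write_tsv(samples, outdir / "samples.tsv"))
    for sample, tr in truth.items():
        outputs.append(io.write_tsv(tr, outdir / "truth" / f"{sample}.tsv"))
    outputs.append(io.write_tsv(plants, outdir / "truth" / "plants.tsv"))
    for sample, ct in counts.items():
        outputs.append(io.write_site_counts(ct, outdir / "counts" / f"{sample}.tsv"))
    outputs.append(io.write_annotations_bed(genome.catalog, outdir / "annotations.bed"))
    outputs.append(io.write_tsv(genome.genes, outdir / "genes.tsv"))
    outputs.append(io.write_tsv(genome.promoters, outdir / "promoters.tsv"))
    outputs.append(io.write_yaml(
        {"chrom_sizes": {k: int(v) for k, v in genome.chrom_sizes.items()},
         "spikein_sizes": {k: int(v) for k, v in genome.spikein_sizes.items()}},
        outdir / "genome.yaml"))

    # read-depth tracks: CNV plants in the case stage, flat elsewhere
    cnv = cfg["cnv"]
    plants_cnv = [cohort.CnvPlant(p["chrom"], int(p["start_bin"]), int(p["n_bins"]),
                                  float(p["copy_number"])) for p in cnv.get("plants", [])]
    rng_depth = np.random.default_rng(seed + 3)
    cnv_truth = None
    for _, (sample, stage) in samples.iterrows():
        pl = plants_cnv if stage == cnv["case_stage"] else []
        track, tru = cohort.simulate_depth_track(
            genome, pl, bin_bp=int(cnv["bin_bp"]),
            baseline_depth=float(cnv["baseline_depth"]), seed=rng_depth)
        if stage == cnv["case_stage"] and cnv_truth is None:
            cnv_truth = tru
        outputs.append(io.write_tsv(track, outdir / "depth" / f"{sample}.tsv"))
    outputs.append(io.write_tsv(
        cnv_truth if cnv_truth is not None else pd.DataFrame(
            columns=["chrom", "start", "end", "copy_number"]),
        outdir / "truth" / "cnv_segments.tsv"))

    # variants at cytosines; hmC-positive truth sites favor C>A / C>G
    rng_var = np.random.default_rng(seed + 4)
    case_sample = samples[samples["stage"] == cnv["case_stage"]]["sample"].iloc[0]
    tr = truth[case_sample]
    n_var = min(int(cfg["variants"]["n"]), len(tr))
    pick = rng_var.choice(len(tr), size=n_var, replace=False)
    ph = tr["p_h"].to_numpy()[pick]
    alts = np.empty(n_var, dtype=object)
    for i, h in enumerate(ph):
        probs = [0.45, 0.35, 0.20] if h > 0.02 else [0.20, 0.20, 0.60]
        alts[i] = rng_var.choice(["A", "G", "T"], p=probs)
    variants = pd.DataFrame({
        "chrom": tr["chrom"].to_numpy()[pick],
        "pos": tr["pos"].to_numpy()[pick],
        "ref": "C",
        "alt": alts,
    }).sort_values(["chrom", "pos"]).reset_index(drop=True)
    outputs.append(io.write_tsv(variants, outdir / "variants.tsv"))

    expr, clinical = cohort.simulate_expression_survival(
        truth, config, genome,
        n_subjects=int(cfg["survival"]["n_subjects"]),
        log_hr=float(cfg["survival"]["log_hr"]),
        rng=np.random.default_rng(seed + 5))
    outputs.append(io.write_tsv(expr.reset_index().rename(columns={"index": "gene"}),
                                outdir / "expression.tsv"))
    outputs.append(io.write_tsv(clinical, outdir / "clinical.tsv"))
    io.write_manifest(outdir / "manifest_simulate.json", "simulate", [],
                      outputs, cfg, seed, base=outdir)
    return outputs


def stage_estimate(cfg: dict, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    samples = pd.read_csv(_require(outdir / "samples.tsv", "simulate"), sep="\t")
    inputs, outputs = [], []
    conv_rows = []
    for sample in samples["sample"]:
        cpath = _require(outdir / "counts" / f"{sample}.tsv", "simulate")
        inputs.append(cpath)
        counts = io.read_site_counts(cpath)
        spikes = counts["chrom"].str.startswith("spikein")
        bs_conv = quant.estimate_conversion(
            counts[counts["chrom"] == cohort.SPIKE_UNMETH], "unmethylated_bs")
        ox_conv = quant.estimate_conversion(
            counts[counts["chrom"] == cohort.SPIKE_HMC], "hydroxymethylated_ox")
        conv_rows.append((sample, bs_conv, ox_conv))
        rates = quant.ConversionRates(bs_conv, ox_conv)
        est = quant.estimate_sample(counts[~spikes].reset_index(drop=True), rates,
                                    min_depth=int(cfg["dmr"]["min_coverage"]))
        outputs.append(io.write_tsv(est, outdir / "estimates" / f"{sample}.tsv"))
        for ch in ("5mC", "5hmC"):
            outputs.append(io.write_estimates_bedgraph(
                est, outdir / "estimates" / f"{sample}.{ch}.bedGraph", ch))
    outputs.append(io.write_tsv(
        pd.DataFrame(conv_rows, columns=["sample", "bs_conv", "ox_conv"]),
        outdir / "conversion_rates.tsv"))
    io.write_manifest(outdir / "manifest_estimate.json", "estimate", inputs,
                      outputs, cfg["dmr"], cfg["seed"], base=outdir)
    return outputs


def _load_matrix(outdir: Path, samples: pd.DataFrame, case_stage: str,
                 control_stage: str, channel: str) -> dmr.MethMatrix:
    col = {"5mC": "p_m", "5hmC": "p_h"}[channel]
    use = samples[samples["stage"].isin([case_stage, control_stage])]
    levels, depths, names, groups = [], [], [], []
    ref = None
    for _, (sample, stage) in use.iterrows():
        est = pd.read_csv(_require(outdir / "estimates" / f"{sample}.tsv", "estimate"),
                          sep="\t")
        if ref is None:
            ref = est[["chrom", "pos"]]
        lv = est[col].to_numpy(dtype=float)
        lv = np.where(est["pass_qc"].to_numpy(), lv, np.nan)
        levels.append(lv)
        depths.append(np.minimum(est["bs_depth"], est["ox_depth"]).to_numpy(dtype=float))
        names.append(sample)
        groups.append("case" if stage == case_stage else "control")
    return dmr.MethMatrix(
        ref["chrom"].to_numpy(), ref["pos"].to_numpy(),
        np.column_stack(levels), np.array(groups),
        np.column_stack(depths), names)


def stage_dmr(cfg: dict, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    samples = pd.read_csv(_require(outdir / "samples.tsv", "simulate"), sep="\t")
    d = cfg["dmr"]
    params = dmr.DmrParams(
        diff_threshold=float(d["diff_threshold"]), min_coverage=int(d["min_coverage"]),
        min_cpg=int(d["min_cpg"]), valley_filter=float(d["valley_filter"]),
        p_threshold=float(d["p_threshold"]))
    inputs = [outdir / "samples.tsv"]
    outputs = []
    for channel in ("5mC", "5hmC"):
        mat = _load_matrix(outdir, samples, d["case_stage"], d["control_stage"], channel)
        calls = dmr.call_dmrs(mat, params, channel=channel)
        outputs.append(io.write_tsv(calls, outdir / "dmr" / f"{channel}.tsv"))
        outputs.append(io.write_dmr_bed(calls, outdir / "dmr" / f"{channel}.bed"))
    io.write_manifest(outdir / "manifest_dmr.json", "dmr", inputs, outputs,
                      d, cfg["seed"], base=outdir)
    return outputs


def stage_enrich(cfg: dict, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    genome_meta = io.read_yaml(_require(outdir / "genome.yaml", "simulate"))
    catalog = io.read_annotations_bed(_require(outdir / "annotations.bed", "simulate"))
    outputs = []
    for channel in ("5mC", "5hmC"):
        dmr_path = _require(outdir / "dmr" / f"{channel}.tsv", "dmr")
        calls = pd.read_csv(dmr_path, sep="\t")
        if len(calls) == 0:
            res = pd.DataFrame(columns=["feature_class", "n_obs_in", "n_obs_out",
                                        "n_rand_in", "n_rand_out", "fold", "p_hyper", "stars"])
        else:
            res = enrichment.enrich_all(
                calls[["chrom", "start", "end"]], catalog,
                genome_meta["chrom_sizes"], seed=int(cfg["seed"]) + 10,
                n_draws=int(cfg["enrich"]["n_draws"]))
        outputs.append(io.write_tsv(res, outdir / "enrichment" / f"{channel}.tsv"))
    io.write_manifest(outdir / "manifest_enrich.json", "enrich",
                      [outdir / "dmr" / "5mC.tsv", outdir / "dmr" / "5hmC.tsv"],
                      outputs, cfg["enrich"], cfg["seed"], base=outdir)
    return outputs


def stage_integrate(cfg: dict, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    samples = pd.read_csv(_require(outdir / "samples.tsv", "simulate"), sep="\t")
    case_stage = cfg["cnv"]["case_stage"]
    control_stage = cfg["dmr"]["control_stage"]
    case = samples[samples["stage"] == case_stage]["sample"].iloc[0]
    normal = samples[samples["stage"] == control_stage]["sample"].iloc[0]
    outputs = []

    dep_case = pd.read_csv(_require(outdir / "depth" / f"{case}.tsv", "simulate"), sep="\t")
    dep_norm = pd.read_csv(_require(outdir / "depth" / f"{normal}.tsv", "simulate"), sep="\t")
    bins = dep_case[["chrom", "start", "end", "partial"]]
    segs = integration.cbs_copy_number(dep_case["depth"], dep_norm["depth"], bins)
    outputs.append(io.write_tsv(segs, outdir / "integrate" / "cnv_segments.tsv"))

    est_case = pd.read_csv(_require(outdir / "estimates" / f"{case}.tsv", "estimate"), sep="\t")
    est_norm = pd.read_csv(_require(outdir / "estimates" / f"{normal}.tsv", "estimate"), sep="\t")

    def bin_m(est, bins):
        vals = np.full(len(bins), np.nan)
        for i, b in enumerate(bins.itertuples(index=False)):
            sub = est[(est["chrom"] == b.chrom) & (est["pos"] >= b.start) & (est["pos"] < b.end)]
            sub = sub[sub["pass_qc"]]
            if len(sub):
                vals[i] = integration.m_value(float(sub["p_m"].mean()))
        return vals

    m_case = bin_m(est_case, bins)
    m_norm = bin_m(est_norm, bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        total_c, total_n = dep_case["depth"].sum(), dep_norm["depth"].sum()
        logr_case = np.log2(dep_case["depth"].to_numpy() / total_c * len(bins) + 1e-9)
        logr_norm = np.log2(dep_norm["depth"].to_numpy() / total_n * len(bins) + 1e-9)
    z = integration.zscores(m_case, m_norm, logr_case, logr_norm)
    track = bins.copy()
    track["read_depth"] = dep_case["depth"]
    track["logR"] = logr_case - logr_norm
    track["M"] = m_case
    track["z_meth"] = z["z_meth"]
    track["z_cnv"] = z["z_cnv"]
    outputs.append(io.write_tsv(track, outdir / "integrate" / "bin_track.tsv"))
    rho, p = integration.correlate_tracks(z["z_cnv"], z["z_meth"])
    outputs.append(io.write_tsv(pd.DataFrame([{"sample": case, "rho": rho, "p": p}]),
                                outdir / "integrate" / "cnv_meth_correlation.tsv"))

    variants = pd.read_csv(_require(outdir / "variants.tsv", "simulate"), sep="\t")
    vt = integration.variant_context_test(variants, est_case)
    outputs.append(io.write_tsv(vt, outdir / "integrate" / "variant_context.tsv"))

    catalog = io.read_annotations_bed(_require(outdir / "annotations.bed", "simulate"))
    prof = integration.peak_meta_profile(est_case.dropna(subset=["p_m"]),
                                         catalog["enhancer"], flank_bp=15_000)
    outputs.append(io.write_tsv(prof, outdir / "integrate" / "enhancer_profile_5mC.tsv"))

    proms = pd.read_csv(_require(outdir / "promoters.tsv", "simulate"), sep="\t")
    expr = pd.read_csv(_require(outdir / "expression.tsv", "simulate"), sep="\t")
    expr = expr.set_index("gene")
    classes = cohort.classify_expression(expr[case], expr[normal])
    genes = pd.read_csv(_require(outdir / "genes.tsv", "simulate"), sep="\t")
    anchors = pd.DataFrame({
        "chrom": genes["chrom"],
        "pos": np.where(genes["strand"] == "+", genes["start"], genes["end"]),
        "strand": genes["strand"],
        "gene": genes["gene"],
    })
    bp = integration.boundary_profile(est_case.dropna(subset=["p_m"]), anchors,
                                      dict(zip(expr.index, classes)))
    outputs.append(io.write_tsv(bp, outdir / "integrate" / "tss_profile_by_expression.tsv"))
    io.write_manifest(outdir / "manifest_integrate.json", "integrate",
                      [outdir / "variants.tsv"], outputs, cfg["cnv"], cfg["seed"], base=outdir)
    return outputs


def stage_survival(cfg: dict, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    clinical = pd.read_csv(_require(outdir / "clinical.tsv", "simulate"), sep="\t")
    res = survival.survival_association(clinical, minprop=float(cfg["survival"]["minprop"]))
    km_high = res.pop("km_high")
    km_low = res.pop("km_low")
    km_high["group"] = "high"
    km_low["group"] = "low"
    outputs = [
        io.write_tsv(pd.DataFrame([res]), outdir / "survival" / "association.tsv"),
        io.write_tsv(pd.concat([km_low, km_high], ignore_index=True),
                     outdir / "survival" / "km_curves.tsv"),
    ]
    io.write_manifest(outdir / "manifest_survival.json", "survival",
                      [outdir / "clinical.tsv"], outputs, cfg["survival"], cfg["seed"], base=outdir)
    return outputs


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "estimate": stage_estimate,
    "dmr": stage_dmr,
    "enrich": stage_enrich,
    "integrate": stage_integrate,
    "survival": stage_survival,
}


def run_stage(stage: str, cfg: dict, outdir) -> list[Path]:
    if stage == "all":
        out = []
        for s in STAGES:
            out.extend(STAGE_FUNCS[s](cfg, outdir))
        return out
    if stage not in STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return STAGE_FUNCS[stage](cfg, outdir)
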