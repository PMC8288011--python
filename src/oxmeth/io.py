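"""Plain-text readers/writers for the pipeline's on-disk formats.

Formats (all TSV-family, 0-based half-open coordinates):

* SiteCounts TSV: chrom, pos, strand, bs_meth, bs_depth, ox_meth, ox_depth
* CpG-report-like TSV (single channel): chrom, pos, strand, meth, unmeth
* Estimate table: SiteCounts columns + p_u, p_m, p_h, loglik, boundary,
  pass_qc; also exported as per-channel bedGraph (chrom, start, end, value)
* Annotations: BED6 with the feature class in the name column
* DMRs: BED6+ with score = -log10(q)
* Clinical table: sample, stage/marker, time, event
* Manifest: JSON with input hashes, parameters and seed

Floats are written with a fixed "%.10g" format so that reruns with the
same seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FLOAT_FMT = "%.10g"

COUNT_COLS = ["chrom", "pos", "strand", "bs_meth", "bs_depth", "ox_meth", "ox_depth"]


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format=FLOAT_FMT)
    tmp.replace(path)
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_site_counts(df: pd.DataFrame, path) -> Path:
    return write_tsv(df[COUNT_COLS], path)


def read_site_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in COUNT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"site-count table {path} lacks columns {missing}")
    return df


def read_cpg_report(path, channel: str = "bs") -> pd.DataFrame:
    """Read a Bismark-CpG-report-like table (chrom, pos, strand, meth, unmeth).

    Returns a half SiteCounts frame for one channel with meth/depth named
    ``{channel}_meth`` / ``{channel}_depth``.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "strand", "meth", "unmeth"])
    out = df[["chrom", "pos", "strand"]].copy()
    out[f"{channel}_meth"] = df["meth"]
    out[f"{channel}_depth"] = df["meth"] + df["unmeth"]
    return out


def merge_channels(bs: pd.DataFrame, ox: pd.DataFrame) -> pd.DataFrame:
    """Join the two single-channel frames into a SiteCounts table."""
    merged = bs.merge(ox, on=["chrom", "pos", "strand"], how="inner")
    return merged[COUNT_COLS]


def write_annotations_bed(catalog: dict[str, pd.DataFrame], path) -> Path:
    rows = []
    for cls, df in catalog.items():
        for r in df.itertuples(index=False):
            rows.append((r.chrom, int(r.start), int(r.end), cls, 0, "."))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    bed = bed.sort_values(["name", "chrom", "start"]).reset_index(drop=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_annotations_bed(path) -> dict[str, pd.DataFrame]:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return {cls: sub[["chrom", "start", "end"]].reset_index(drop=True)
            for cls, sub in bed.groupby("name", sort=True)}


def write_estimates_bedgraph(est: pd.DataFrame, path, channel: str = "5mC") -> Path:
    col = {"5mC": "p_m", "5hmC": "p_h"}[channel]
    bg = pd.DataFrame(
        {
            "chrom": est["chrom"],
            "start": est["pos"].astype(np.int64),
            "end": est["pos"].astype(np.int64) + 1,
            "value": est[col],
        }
    ).dropna(subset=["value"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bg.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)
    return path


def write_dmr_bed(dmrs: pd.DataFrame, path) -> Path:
    """BED6+ : chrom, start, end, name, score=-log10(q), '.', extras."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"].astype(np.int64),
            "end": dmrs["end"].astype(np.int64),
            "name": [f"{c}_{d}_{i}" for i, (c, d) in
                     enumerate(zip(dmrs["channel"], dmrs["direction"]))],
            "score": -np.log10(np.maximum(dmrs["q_value"].to_numpy(dtype=float), 1e-300)),
            "strand": ".",
            "mean_diff": dmrs["mean_diff"],
            "n_cpg": dmrs["n_cpg"],
            "p_ks2d": dmrs["p_ks2d"],
            "p_mwu": dmrs["p_mwu"],
            "q_value": dmrs["q_value"],
            "direction": dmrs["direction"],
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)
    return path


def read_bed3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stage: str, inputs: list, outputs: list,
                   params: dict, seed, base=None) -> Path:
    """Stage manifest: hashes of inputs/outputs, parameters and seed.

    Paths are recorded relative to ``base`` (the run directory) and no
    timestamps are written, so reruns are byte-identical wherever the run
    directory lives.
    """

    def rel(p):
        p = Path(p)
        if base is not None:
            try:
                return str(p.resolve().relative_to(Path(base).resolve()))
            except ValueError:
                pass
        return str(p)

    doc = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {rel(p): file_sha256(p) for p in sorted(inputs, key=lambda q: rel(q))},
        "outputs": {rel(p): file_sha256(p) for p in sorted(outputs, key=lambda q: rel(q))},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    tmp.replace(path)
    return path
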