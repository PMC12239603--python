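"""Readers and writers for the pipeline's tabular and HDF5 formats.

All tables are plain TSV with a header row; genotype probabilities go to
HDF5 (one dataset per chromosome, samples x founders x markers) with a TSV
fallback.  Writers use a fixed float format so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .genome import FOUNDER_LETTERS, GenomeMap
from .simdata import GenotypeProbs

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_map(gmap: GenomeMap, path: str | Path) -> None:
    write_table(gmap.markers[["marker", "chrom", "cM", "Mbp"]], path)


def read_map(path: str | Path) -> GenomeMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomeMap(df)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    out = cov.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_probs_hdf5(probs: GenotypeProbs, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["samples"] = [s.encode() for s in probs.samples]
        for chrom in probs.gmap.chromosomes:
            idx = probs.gmap.chrom_index(chrom)
            g = f.create_group(f"chr{chrom}")
            g.create_dataset("probs", data=probs.probs[:, :, idx])
            g.create_dataset(
                "markers",
                data=[m.encode() for m in probs.gmap.markers["marker"].iloc[idx]],
            )


def read_probs_hdf5(path: str | Path, gmap: GenomeMap) -> GenotypeProbs:
    with h5py.File(path, "r") as f:
        samples = [s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["samples"]]
        arr = np.zeros((len(samples), 8, gmap.n_markers))
        for chrom in gmap.chromosomes:
            idx = gmap.chrom_index(chrom)
            arr[:, :, idx] = f[f"chr{chrom}"]["probs"][...]
    return GenotypeProbs(arr, samples, gmap)


def write_probs_tsv(probs: GenotypeProbs, path: str | Path) -> None:
    """Long-format TSV fallback: one row per (sample, marker) with 8 dosage columns."""
    markers = probs.gmap.markers["marker"].to_numpy()
    n_s, _, n_m = probs.probs.shape
    flat = probs.probs.transpose(0, 2, 1).reshape(n_s * n_m, 8)
    df = pd.DataFrame(flat, columns=[f"p_{c}" for c in FOUNDER_LETTERS])
    df.insert(0, "marker", np.tile(markers, n_s))
    df.insert(0, "sample", np.repeat(probs.samples, n_m))
    write_table(df, path)


def read_probs_tsv(path: str | Path, gmap: GenomeMap) -> GenotypeProbs:
    df = pd.read_csv(path, sep="\t")
    samples = list(dict.fromkeys(df["sample"]))
    n_m = gmap.n_markers
    cols = [f"p_{c}" for c in FOUNDER_LETTERS]
    arr = df[cols].to_numpy().reshape(len(samples), n_m, 8).transpose(0, 2, 1)
    return GenotypeProbs(arr, samples, gmap)


def spec_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_run_metadata(config: dict, seed: int, path: str | Path) -> None:
    meta = {"seed": seed, "config_hash": spec_hash(config), "config": config}
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
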