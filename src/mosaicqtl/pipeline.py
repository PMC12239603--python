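"""End-to-end synthetic-mode pipeline: simulate, preprocess, scan, dissect.

`run_pipeline` drives the whole analysis on simulated data — genome and
expression simulation, count-level normalisation, LOCO mixed-model scans with
permutation thresholds, peak calling with founder-effect BLUPs, hotspot
detection, eigengene mapping, same- and cross-cell-type mediation, partial
correlation, and shared-eQTL classification — writing every table to an
output directory.  All randomness derives from the single config seed, so
two runs with the same config produce byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import crosscell, hotspots as hs_mod, io, mediation as med_mod, preprocess, scan as scan_mod
from .genome import FOUNDER_LETTERS, default_map
from .simdata import (
    ArchitectureSpec,
    default_architecture,
    latent_to_counts,
    simulate_dataset,
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_samples": 186,
    "n_shared_samples": 127,
    "map": {"n_chrom": 5, "chrom_length_cm": 100.0, "n_markers_per_chrom": 200, "mbp_per_cm": 2.0},
    "architecture": {
        "n_local": 40,
        "n_targets": 30,
        "mediator_cell_type": "B",
        "local_cell_types": ["A", "B"],
    },
    "expression_stage": "counts",  # "counts" exercises the full normalisation chain
    "scan": {
        "n_perm": 20,
        "n_perm_phenos": 10,
        "significant_alpha": 0.05,
        "suggestive_alpha": 0.2,
    },
    "hotspots": {"top_fraction": 0.005, "min_members": 20},
    "mediation": {"window_mbp": 10.0},
}


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _process_expression(latent: pd.DataFrame, covariates: pd.DataFrame, stage: str, seed: int):
    """Latent -> counts -> filter -> UQ -> batch-correct -> rankZ (or a latent shortcut)."""
    cov = covariates.loc[latent.columns]
    if stage == "counts":
        counts = latent_to_counts(latent, seed=seed)
        kept = preprocess.filter_genes(preprocess.tpm_like(counts))
        counts = counts.loc[kept]
        normed = preprocess.upper_quartile_normalize(counts)
        corrected = preprocess.remove_covariate_effects(normed, cov[["batch"]])
    elif stage == "latent":
        corrected = preprocess.remove_covariate_effects(latent, cov[["batch"]])
    else:
        raise ValueError(f"unknown expression stage {stage!r}")
    return preprocess.rankz(corrected)


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    cfg = _merged(config)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]

    gmap = default_map(**cfg["map"])
    arch = default_architecture(
        gmap,
        n_local=cfg["architecture"]["n_local"],
        n_targets=cfg["architecture"]["n_targets"],
        mediator_cell_type=cfg["architecture"]["mediator_cell_type"],
        local_cell_types=tuple(cfg["architecture"]["local_cell_types"]),
        seed=seeds[0],
    )
    data = simulate_dataset(
        gmap,
        n_samples=int(cfg["n_samples"]),
        n_shared_samples=int(cfg["n_shared_samples"]),
        spec=arch,
        seed=seeds[1],
    )
    probs, cov = data["probs"], data["covariates"]
    annotation = data["truth"]["annotations"]

    stage = cfg["expression_stage"]
    rz_b = _process_expression(data["expr_b"], cov, stage, seeds[2])
    rz_a = _process_expression(data["expr_a"], cov, stage, seeds[3])

    kinship = scan_mod.calc_kinship(probs, mode="loco")
    kinship_a = scan_mod.calc_kinship(probs.subset(list(rz_a.columns)), mode="loco")
    sex = cov[["sex"]]

    # --- genome scans -------------------------------------------------------
    lods_b = scan_mod.scan_genes(rz_b, probs, kinship, sex.loc[rz_b.columns])
    probs_a = probs.subset(list(rz_a.columns))
    lods_a = scan_mod.scan_genes(rz_a, probs_a, kinship_a, sex.loc[rz_a.columns])

    sc = cfg["scan"]
    perm_phenos = rz_b.iloc[: int(sc["n_perm_phenos"])].to_numpy()
    thresholds = scan_mod.permutation_threshold(
        perm_phenos,
        probs,
        kinship,
        sex.loc[rz_b.columns],
        n_perm=int(sc["n_perm"]),
        alphas=(float(sc["significant_alpha"]), float(sc["suggestive_alpha"])),
        seed=seeds[4],
    )
    sig_lod = thresholds.threshold(float(sc["significant_alpha"]))
    sug_lod = thresholds.threshold(float(sc["suggestive_alpha"]))

    def peak_table(lods, expr, pr, kin, cov_s):
        peaks = scan_mod.find_and_classify_peaks(lods, gmap, annotation, sug_lod)
        peaks = scan_mod.add_blup_effects(peaks, expr, pr, kin, cov_s)
        peaks["perm_p"] = thresholds.perm_pvalue(peaks["lod"].to_numpy())
        if len(peaks):
            peaks["q"], _ = scan_mod.qvalues(peaks["perm_p"].to_numpy())
        else:
            peaks["q"] = pd.Series(dtype=float)
        return peaks.sort_values(["gene", "chrom"]).reset_index(drop=True)

    peaks_b = peak_table(lods_b, rz_b, probs, kinship, sex.loc[rz_b.columns])
    peaks_a = peak_table(lods_a, rz_a, probs_a, kinship_a, sex.loc[rz_a.columns])
    sig_b = peaks_b[peaks_b["lod"] >= sig_lod]

    # --- hotspots and eigengene --------------------------------------------
    hcfg = cfg["hotspots"]
    distant_sig = sig_b[sig_b["class"] == "distant"]
    hotspot_list = hs_mod.call_hotspots(
        distant_sig,
        gmap,
        top_fraction=float(hcfg["top_fraction"]),
        min_members=int(hcfg["min_members"]),
    )
    for h in hotspot_list:
        hs_mod.attach_targets_and_eigengene(h, peaks_b, rz_b)

    eigengene_results = []
    mediation_same = mediation_cross = partial_corr = None
    shared_calls = summary_cc = None
    for h in hotspot_list:
        if h.eigengene is None:
            continue
        escan = scan_mod.scan1(
            h.eigengene.loc[rz_b.columns], probs, kinship, sex.loc[rz_b.columns]
        )
        peak_marker, peak_lod = escan.peak()
        peak_row = gmap.markers.iloc[gmap.marker_index(peak_marker)]
        effs = scan_mod.blup_effects(
            h.eigengene.loc[rz_b.columns].to_numpy(),
            probs.at_marker(peak_marker),
            kinship,
            str(peak_row["chrom"]),
            sex.loc[rz_b.columns],
        )
        eigengene_results.append(
            {
                "hotspot": f"chr{h.chrom}:{h.start_cm}-{h.end_cm}",
                "peak_marker": peak_marker,
                "chrom": str(peak_row["chrom"]),
                "Mbp": float(peak_row["Mbp"]),
                "lod": peak_lod,
                "scores": h.eigengene,
                "effects": effs,
            }
        )

    mcfg = cfg["mediation"]
    if eigengene_results:
        eg = eigengene_results[0]
        target = eg["scores"]
        dos = pd.DataFrame(probs.at_marker(eg["peak_marker"]), index=probs.samples)
        mediation_same = med_mod.mediation_scan(
            target, dos, rz_b, sex, peak_marker=eg["peak_marker"]
        )
        mediation_same = med_mod.mediation_significance(
            mediation_same,
            annotation,
            peak_mbp=eg["Mbp"],
            peak_chrom=eg["chrom"],
            window_mbp=float(mcfg["window_mbp"]),
        )
        mediation_cross = med_mod.mediation_scan(
            target, dos, rz_a, sex, peak_marker=eg["peak_marker"]
        )
        mediation_cross = med_mod.mediation_significance(
            mediation_cross,
            annotation,
            peak_mbp=eg["Mbp"],
            peak_chrom=eg["chrom"],
            window_mbp=float(mcfg["window_mbp"]),
        )
        # partition inferred from the sign of the eigengene founder effects
        pos = tuple(int(i) for i in np.flatnonzero(eg["effects"] >= 0))
        neg = tuple(int(i) for i in np.flatnonzero(eg["effects"] < 0))
        classes = med_mod.classify_genotype(dos, (neg, pos))
        mid = (annotation["start"] + annotation["end"]) / 2.0
        near = annotation[
            (annotation["chrom"].astype(str) == eg["chrom"])
            & ((mid - eg["Mbp"]).abs() <= float(mcfg["window_mbp"]))
        ]["gene"]
        cand_b = rz_b.loc[rz_b.index.intersection(near)]
        cand_a = rz_a.loc[rz_a.index.intersection(near)]
        pc_parts = []
        for cell, cand in (("B", cand_b), ("A", cand_a)):
            if len(cand):
                pc = med_mod.partial_correlation(cand, target, classes)
                pc.insert(1, "cell_type", cell)
                pc_parts.append(pc)
        partial_corr = pd.concat(pc_parts, ignore_index=True) if pc_parts else None

    # --- cross-cell-type shared eQTL ---------------------------------------
    relaxed_a = peaks_a  # A table already includes suggestive-level peaks
    shared_calls, summary_cc = crosscell.match_shared_eqtl(
        sig_b, relaxed_a, expressed_in_b=list(rz_a.index)
    )

    results = {
        "config": cfg,
        "gmap": gmap,
        "probs": probs,
        "covariates": cov,
        "truth": data["truth"],
        "rankz_a": rz_a,
        "rankz_b": rz_b,
        "thresholds": thresholds,
        "significant_lod": sig_lod,
        "suggestive_lod": sug_lod,
        "peaks_a": peaks_a,
        "peaks_b": peaks_b,
        "hotspots": hotspot_list,
        "eigengene": eigengene_results,
        "mediation_same": mediation_same,
        "mediation_cross": mediation_cross,
        "partial_correlation": partial_corr,
        "shared_calls": shared_calls,
        "shared_summary": summary_cc,
    }
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(res: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_map(res["gmap"], outdir / "map.tsv")
    io.write_probs_hdf5(res["probs"], outdir / "probs.h5")
    io.write_covariates(res["covariates"], outdir / "covariates.tsv")
    io.write_expression(res["rankz_b"], outdir / "expression_B_rankz.tsv")
    io.write_expression(res["rankz_a"], outdir / "expression_A_rankz.tsv")
    io.write_table(res["truth"]["eqtl"], outdir / "truth_eqtl.tsv")
    io.write_table(res["truth"]["annotations"], outdir / "annotations.tsv")
    io.write_table(res["peaks_b"], outdir / "peaks_B.tsv")
    io.write_table(res["peaks_a"], outdir / "peaks_A.tsv")
    hs_rows = [
        (
            h.chrom,
            h.start_cm,
            h.end_cm,
            h.start_mbp,
            h.end_mbp,
            h.n_members,
            len(h.targets),
            h.eigengene_variance_fraction,
        )
        for h in res["hotspots"]
    ]
    io.write_table(
        pd.DataFrame(
            hs_rows,
            columns=[
                "chrom",
                "start_cM",
                "end_cM",
                "start_Mbp",
                "end_Mbp",
                "n_significant",
                "n_suggestive",
                "eigengene_var_fraction",
            ],
        ),
        outdir / "hotspots.tsv",
    )
    if res["eigengene"]:
        eg = res["eigengene"][0]
        io.write_table(
            eg["scores"].rename("score").reset_index().rename(columns={"index": "sample"}),
            outdir / "eigengene.tsv",
        )
        io.write_table(
            pd.DataFrame(
                {"founder": list(FOUNDER_LETTERS), "effect": eg["effects"]}
            ),
            outdir / "eigengene_effects.tsv",
        )
    for key, name in (
        ("mediation_same", "mediation_same.tsv"),
        ("mediation_cross", "mediation_cross.tsv"),
        ("partial_correlation", "partial_correlation.tsv"),
        ("shared_calls", "shared_calls.tsv"),
    ):
        if res[key] is not None:
            io.write_table(res[key], outdir / name)
    meta = {
        "significant_lod": res["significant_lod"],
        "suggestive_lod": res["suggestive_lod"],
        "shared_summary": res["shared_summary"],
    }
    io.write_run_metadata(res["config"], int(res["config"]["seed"]), outdir / "metadata.json")
    (outdir / "summary.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
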