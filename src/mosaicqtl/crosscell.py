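"""Shared-eQTL classification between two donor-matched cell types.

An eQTL detected in the focal cell type (A) is called *shared* with the
comparison cell type (B) when B has an eQTL for the same gene on the same
chromosome within 5 Mbp whose 8-founder effect vector correlates
significantly (BH-adjusted p < 0.1) with A's.  Genes absent from B's
expressed set are reported separately, since an eQTL cannot be tested in a
cell type where the gene is not measured.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import FOUNDER_LETTERS

_EFF_COLS = [f"eff_{c}" for c in FOUNDER_LETTERS]


def _effects(row: pd.Series) -> np.ndarray:
    eff = row[_EFF_COLS].to_numpy(float)
    if eff.shape != (8,) or np.isnan(eff).any():
        raise ValueError("peak rows must carry 8 founder-effect columns eff_A..eff_H")
    return eff


def match_shared_eqtl(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    expressed_in_b: list[str] | None = None,
    max_dist_mbp: float = 5.0,
    alpha: float = 0.1,
) -> tuple[pd.DataFrame, dict]:
    """Classify each A-cell-type eQTL as shared / not mapped / not expressed in B.

    ``peaks_b`` is typically taken at a relaxed LOD threshold so that borderline
    B-cell-type eQTL can still corroborate an A peak.  If several B peaks
    qualify for one A peak, the closest wins, ties broken by higher LOD.
    Pearson correlation of the two 8-founder effect vectors is tested
    two-sided at n = 8 and BH-adjusted across all tested pairs.
    """
    calls = []
    tested_r, tested_p = [], []
    for _, arow in peaks_a.iterrows():
        gene = arow["gene"]
        if expressed_in_b is not None and gene not in expressed_in_b:
            calls.append((gene, arow["class"], "not_expressed_in_B", np.nan, np.nan, None))
            continue
        cand = peaks_b[
            (peaks_b["gene"] == gene)
            & (peaks_b["chrom"].astype(str) == str(arow["chrom"]))
        ].copy()
        if len(cand):
            cand["dist"] = (cand["Mbp"] - float(arow["Mbp"])).abs()
            cand = cand[cand["dist"] <= max_dist_mbp]
        if len(cand) == 0:
            calls.append((gene, arow["class"], "not_mapped_in_B", np.nan, np.nan, None))
            continue
        cand = cand.sort_values(["dist", "lod"], ascending=[True, False])
        brow = cand.iloc[0]
        r, p = stats.pearsonr(_effects(arow), _effects(brow))
        tested_r.append(r)
        tested_p.append(p)
        calls.append((gene, arow["class"], "tested", float(brow["dist"]), float(r), float(p)))
    df = pd.DataFrame(
        calls, columns=["gene", "class", "status", "dist_mbp", "r", "p"]
    )
    df["p_adj"] = np.nan
    tested_mask = df["status"] == "tested"
    if tested_mask.any():
        df.loc[tested_mask, "p_adj"] = multipletests(
            df.loc[tested_mask, "p"].to_numpy(), method="fdr_bh"
        )[1]
    verdict = np.where(
        df["status"] == "not_expressed_in_B",
        "not_expressed_in_B",
        np.where(
            tested_mask & (df["p_adj"] < alpha),
            "shared",
            "not_mapped_in_B",
        ),
    )
    df["verdict"] = verdict
    df["effect_sign"] = np.where(
        df["verdict"].eq("shared") & (df["r"] < 0), "opposing", np.where(df["verdict"].eq("shared"), "concordant", "")
    )
    summary = {}
    for cls in ("local", "distant"):
        sub = df[df["class"] == cls]
        summary[f"shared_fraction_{cls}"] = (
            float((sub["verdict"] == "shared").mean()) if len(sub) else np.nan
        )
        summary[f"n_{cls}"] = int(len(sub))
    return df, summary
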