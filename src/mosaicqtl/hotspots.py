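"""Distant-eQTL hotspot detection and eigengene construction.

Distant eQTL peaks are counted in 1 cM sliding windows shifted by 0.25 cM;
windows in the top fraction of counts are merged into candidate hotspot
intervals, gated on a minimum number of significant distant members.  The
targets of a hotspot (genes whose suggestive distant peak falls inside the
interval) are summarised by their first principal component — the eigengene —
which serves as a composite phenotype for hotspot-level mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeMap


@dataclass
class Hotspot:
    """A merged hotspot interval with its member and target eQTL."""

    chrom: str
    start_cm: float
    end_cm: float
    start_mbp: float
    end_mbp: float
    members: pd.DataFrame  # significant distant peaks inside the interval
    targets: list[str] = field(default_factory=list)  # suggestive target genes
    eigengene: pd.Series | None = None
    eigengene_variance_fraction: float | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def contains_cm(self, cm: float) -> bool:
        return self.start_cm <= cm <= self.end_cm


def window_counts(
    distant_peaks: pd.DataFrame,
    gmap: GenomeMap,
    window_cm: float = 1.0,
    shift_cm: float = 0.25,
) -> pd.DataFrame:
    """Distant-eQTL counts in sliding windows across the genome.

    Windows are half-open ``[start, start + window)`` in cM, so away from
    chromosome ends each peak falls in exactly ``window/shift`` bins.
    """
    rows = []
    for chrom in gmap.chromosomes:
        length = gmap.chrom_lengths_cm[chrom]
        pos = distant_peaks.loc[
            distant_peaks["chrom"].astype(str) == chrom, "cM"
        ].to_numpy(float)
        starts = np.arange(0.0, length, shift_cm)
        for s in starts:
            count = int(((pos >= s) & (pos < s + window_cm)).sum())
            rows.append((chrom, float(s), float(s + window_cm), count))
    return pd.DataFrame(rows, columns=["chrom", "start_cm", "end_cm", "count"])


def call_hotspots(
    distant_peaks: pd.DataFrame,
    gmap: GenomeMap,
    top_fraction: float = 0.005,
    min_members: int = 20,
    window_cm: float = 1.0,
    shift_cm: float = 0.25,
) -> list[Hotspot]:
    """Call hotspots from a table of significant distant eQTL peaks.

    The bin-count threshold is the value at the (1 - ``top_fraction``)
    quantile of window counts (never below one peak); all bins at or above it
    are selected, overlapping or abutting selected bins are merged, and merged
    intervals with at most ``min_members`` significant members are dropped.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    if len(distant_peaks) == 0:
        return []
    wc = window_counts(distant_peaks, gmap, window_cm, shift_cm)
    cut = max(float(np.quantile(wc["count"], 1.0 - top_fraction)), 1.0)
    selected = wc[wc["count"] >= cut]
    hotspots: list[Hotspot] = []
    for chrom, sub in selected.groupby("chrom", sort=False):
        sub = sub.sort_values("start_cm")
        start, end = None, None
        intervals = []
        for row in sub.itertuples(index=False):
            if start is None:
                start, end = row.start_cm, row.end_cm
            elif row.start_cm <= end:  # overlap or abutment
                end = max(end, row.end_cm)
            else:
                intervals.append((start, end))
                start, end = row.start_cm, row.end_cm
        if start is not None:
            intervals.append((start, end))
        chrom_peaks = distant_peaks[distant_peaks["chrom"].astype(str) == str(chrom)]
        for s, e in intervals:
            members = chrom_peaks[(chrom_peaks["cM"] >= s) & (chrom_peaks["cM"] < e)]
            if len(members) <= min_members:
                continue
            hotspots.append(
                Hotspot(
                    chrom=str(chrom),
                    start_cm=float(s),
                    end_cm=float(e),
                    start_mbp=float(gmap.cm_to_mbp(chrom, s)),
                    end_mbp=float(gmap.cm_to_mbp(chrom, e)),
                    members=members.reset_index(drop=True),
                )
            )
    return hotspots


def hotspot_targets(hotspot: Hotspot, suggestive_peaks: pd.DataFrame) -> list[str]:
    """Genes with a suggestive distant peak inside the hotspot interval (deduplicated)."""
    sub = suggestive_peaks[
        (suggestive_peaks["chrom"].astype(str) == hotspot.chrom)
        & (suggestive_peaks["cM"] >= hotspot.start_cm)
        & (suggestive_peaks["cM"] < hotspot.end_cm)
        & (suggestive_peaks["class"] == "distant")
    ]
    return list(dict.fromkeys(sub["gene"]))


def eigengene(expr_targets: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of hotspot-target expression as a composite phenotype.

    ``expr_targets`` is targets x samples (rankZ stage); genes are centred
    before the decomposition and the score sign is oriented so that the
    eigengene correlates positively with mean target expression.
    """
    if expr_targets.shape[0] < 3:
        raise ValueError("need at least 3 target genes for an eigengene")
    X = expr_targets.to_numpy(float)
    X = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = Vt[0] * s[0]
    var_fraction = float(s[0] ** 2 / (s**2).sum())
    mean_expr = X.mean(axis=0)
    if np.corrcoef(scores, mean_expr)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr_targets.columns, name="eigengene"), var_fraction


def attach_targets_and_eigengene(
    hotspot: Hotspot, suggestive_peaks: pd.DataFrame, expr: pd.DataFrame
) -> Hotspot:
    """Fill in a hotspot's target set and eigengene from a suggestive peak table."""
    targets = hotspot_targets(hotspot, suggestive_peaks)
    hotspot.targets = targets
    present = [t for t in targets if t in expr.index]
    if len(present) >= 3:
        scores, vf = eigengene(expr.loc[present])
        hotspot.eigengene = scores
        hotspot.eigengene_variance_fraction = vf
    return hotspot
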