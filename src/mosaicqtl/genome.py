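"""Marker maps for multiparent-population genome scans.

A :class:`GenomeMap` carries the ordered marker grid in both genetic (cM) and
physical (Mbp) coordinates.  Genetic coordinates drive recombination and the
sliding-window hotspot bins; physical coordinates drive the local/distant
classification of QTL peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FOUNDERS = 8

#: Conventional one-letter codes for the eight founder strains of the
#: Diversity Outbred population (A/J, C57BL/6J, 129S1, NOD, NZO, CAST, PWK, WSB).
FOUNDER_LETTERS = tuple("ABCDEFGH")


@dataclass(frozen=True)
class GenomeMap:
    """Ordered marker map over one or more chromosomes.

    Parameters
    ----------
    markers :
        Data frame with columns ``marker``, ``chrom``, ``cM``, ``Mbp``;
        positions must be strictly increasing within each chromosome in
        both coordinate systems.
    """

    markers: pd.DataFrame
    chrom_lengths_cm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cM", "Mbp"}
        missing = required - set(self.markers.columns)
        if missing:
            raise ValueError(f"marker table missing columns: {sorted(missing)}")
        if len(self.markers) == 0:
            raise ValueError("marker table is empty")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            for col in ("cM", "Mbp"):
                pos = sub[col].to_numpy(float)
                if not np.all(np.diff(pos) > 0):
                    raise ValueError(
                        f"{col} positions not strictly increasing on chromosome {chrom}"
                    )
        if not self.chrom_lengths_cm:
            lengths = {
                str(c): float(s["cM"].max()) for c, s in self.markers.groupby("chrom", sort=False)
            }
            object.__setattr__(self, "chrom_lengths_cm", lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"].astype(str)))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Positional indices (into the genome-wide marker order) of one chromosome."""
        return np.flatnonzero((self.markers["chrom"].astype(str) == str(chrom)).to_numpy())

    def marker_index(self, marker: str) -> int:
        idx = np.flatnonzero((self.markers["marker"] == marker).to_numpy())
        if idx.size == 0:
            raise KeyError(f"marker {marker!r} not in map")
        return int(idx[0])

    def cm_to_mbp(self, chrom: str, cm: float | np.ndarray) -> np.ndarray:
        """Interpolate physical position from genetic position on one chromosome.

        Linear interpolation between markers; extrapolation is clamped to the
        terminal markers, which is adequate for interval endpoints.
        """
        sub = self.markers[self.markers["chrom"].astype(str) == str(chrom)]
        if len(sub) == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return np.interp(cm, sub["cM"].to_numpy(float), sub["Mbp"].to_numpy(float))


def default_map(
    n_chrom: int = 5,
    chrom_length_cm: float = 100.0,
    n_markers_per_chrom: int = 200,
    mbp_per_cm: float = 2.0,
) -> GenomeMap:
    """Desk-scale synthetic marker map: evenly spaced markers, linear cM-Mbp relation.

    The default (5 chromosomes x 100 cM x 200 markers, 2 Mbp/cM) keeps genome
    scans fast while leaving room for both local and distant architecture;
    ``full_scale_map()`` provides a 20-chromosome preset.
    """
    rows = []
    for c in range(1, n_chrom + 1):
        # offset from 0 so the first marker is not exactly at the chromosome start
        cm = np.linspace(0, chrom_length_cm, n_markers_per_chrom + 1)[1:]
        for j, pos in enumerate(cm):
            rows.append((f"c{c}m{j + 1}", str(c), float(pos), float(pos * mbp_per_cm)))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "Mbp"])
    lengths = {str(c): float(chrom_length_cm) for c in range(1, n_chrom + 1)}
    return GenomeMap(markers, lengths)


def full_scale_map(chrom_length_cm: float = 90.0, n_markers_per_chrom: int = 200) -> GenomeMap:
    """20-autosome preset mirroring a mouse-sized genome."""
    return default_map(
        n_chrom=20, chrom_length_cm=chrom_length_cm, n_markers_per_chrom=n_markers_per_chrom
    )
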