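"""Sliding-window chromosomal landscapes of non-syntenic gene density.

The profile is the proportion of non-syntenic genes among all genes in
windows of ``window`` bp advanced by ``step`` bp (10 Mb / 1 Mb for a
wheat-scale chromosome; smaller for compact genomes). Gene position is
the midpoint of the gene span; empty windows are recorded as missing
rather than zero. The headline statistic is the Pearson correlation
between a window's proportion and its distance to the centromere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass
class WindowProfile:
    chromosome: str
    window: int
    step: int
    chrom_length: int
    centromere: Optional[int]
    midpoints: np.ndarray = field(default_factory=lambda: np.array([]))
    gene_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    nonsyntenic_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    proportions: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "window_mid": self.midpoints,
                "gene_count": self.gene_counts,
                "nonsyntenic_count": self.nonsyntenic_counts,
                "proportion": self.proportions,
            }
        )


def sliding_proportion(
    positions: Sequence[float],
    classes: Sequence[str],
    window: int,
    step: int,
    chrom_length: int,
    centromere: Optional[int] = None,
    chromosome: str = "",
) -> WindowProfile:
    """Windowed non-syntenic proportion along one chromosome.

    A gene belongs to a window iff its midpoint lies in
    ``[w_start, w_start + window)``. Window starts advance by ``step``
    from position 1 until the chromosome end is covered (the last window
    may be truncated). Windows with no genes get proportion NaN.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    positions = np.asarray(positions, dtype=float)
    is_ns = np.asarray([c == "non-syntenic" for c in classes], dtype=bool)
    if positions.size and (positions.min() < 1 or positions.max() > chrom_length):
        raise ValueError("gene positions outside chromosome bounds")
    starts = []
    s = 1
    while True:
        starts.append(s)
        if s + window - 1 >= chrom_length:
            break
        s += step
    starts_arr = np.array(starts, dtype=float)
    mids = np.minimum(starts_arr + window / 2.0, (starts_arr + chrom_length) / 2.0)
    counts = np.zeros(len(starts), dtype=int)
    ns_counts = np.zeros(len(starts), dtype=int)
    # each gene can fall in up to window/step consecutive windows
    for i, w_start in enumerate(starts):
        in_win = (positions >= w_start) & (positions < w_start + window)
        counts[i] = int(in_win.sum())
        ns_counts[i] = int((in_win & is_ns).sum())
    with np.errstate(invalid="ignore"):
        props = np.where(counts > 0, ns_counts / np.maximum(counts, 1), np.nan)
    return WindowProfile(
        chromosome=chromosome,
        window=window,
        step=step,
        chrom_length=chrom_length,
        centromere=centromere,
        midpoints=mids,
        gene_counts=counts,
        nonsyntenic_counts=ns_counts,
        proportions=props,
    )


def centromere_distance_correlation(profile: WindowProfile) -> float:
    """Pearson r between |window midpoint - centromere| and the window
    proportion, over non-missing windows. NaN (flagged by the caller)
    when either side has zero variance; error with < 3 usable windows."""
    if profile.centromere is None:
        raise ValueError("profile has no centromere position")
    ok = ~np.isnan(profile.proportions)
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-missing windows for a correlation")
    dist = np.abs(profile.midpoints[ok] - profile.centromere)
    prop = profile.proportions[ok]
    if np.ptp(dist) == 0 or np.ptp(prop) == 0:
        return float("nan")
    r, _ = pearsonr(dist, prop)
    return float(r)


def age_stratified_profiles(
    positions: dict[str, float],
    strata: dict[str, str],
    representatives: set[str],
    window: int,
    step: int,
    chrom_length: int,
    centromere: Optional[int] = None,
    chromosome: str = "",
) -> dict[str, WindowProfile]:
    """Separate recent/old landscapes using one representative per
    duplicate family. ``positions`` maps gene id to midpoint; ``strata``
    maps gene id to "recent" or "old". All genes (any stratum) form the
    denominator of each profile; the stratum members are the numerator,
    mirroring a proportion-per-total-genes plot."""
    out = {}
    for stratum in ("recent", "old"):
        pos = []
        cls = []
        for gid, p in positions.items():
            if gid in strata and gid not in representatives:
                continue  # non-representative duplicates excluded
            pos.append(p)
            cls.append(
                "non-syntenic" if strata.get(gid) == stratum else "syntenic"
            )
        out[stratum] = sliding_proportion(
            pos, cls, window, step, chrom_length, centromere, chromosome
        )
    return out
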