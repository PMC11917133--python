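"""Rank-based outlier calling: FST/d_XY outliers, OGDs and sweep loci.

All thresholds are percentile rules, applied per population pair (FST,
d_XY; top 2%) or per population genome-wide over CLR grid points (top
0.05%).  A window is an OGD when it is simultaneously an FST outlier and
a d_XY outlier for the same pair.  A sweep locus is a maximal run of >= 2
consecutive above-threshold grid points; singleton peaks are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd


def top_fraction(ids, values, fraction: float) -> set:
    """Ids of the ceil(fraction * N) largest values; ties at the cut kept.

    Undefined (NaN) values are excluded before ranking, so N counts only
    defined entries.  Empty input gives an empty set.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    ids = list(ids)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if not ok.any():
        return set()
    ids = [i for i, keep in zip(ids, ok) if keep]
    values = values[ok]
    k = math.ceil(fraction * len(values))
    threshold = np.sort(values)[::-1][k - 1]
    return {i for i, v in zip(ids, values) if v >= threshold}


def call_ogd(fst_outliers: set, dxy_outliers: set) -> set:
    """OGD = windows that are both FST and d_XY outliers (intersection)."""
    return set(fst_outliers) & set(dxy_outliers)


@dataclass(frozen=True)
class SweepLocus:
    """A called sweep target: a run of consecutive outlier grid points,
    padded by half a grid step on each side (half-open bp interval)."""

    chrom: str
    grid_start: int
    grid_end: int  # inclusive grid indices
    start: float
    end: float


def call_sweep_loci(scan: pd.DataFrame, fraction: float = 0.0005) -> list[SweepLocus]:
    """Apply the top-fraction + >= 2-consecutive-grids rule to a CLR scan.

    ``scan`` is the DataFrame from :func:`divscan.sweep.clr_scan` (one
    population, all chromosomes); the threshold is taken over all grid
    points genome-wide.
    """
    ids = list(zip(scan["chrom"], scan["grid_index"]))
    hits = top_fraction(ids, scan["clr"].to_numpy(), fraction)
    loci: list[SweepLocus] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("grid_index")
        gi = sub["grid_index"].to_numpy()
        pos = sub["pos"].to_numpy()
        step = pos[1] - pos[0] if len(pos) > 1 else 1.0
        above = np.array([(chrom, int(i)) in hits for i in gi])
        run_start = None
        for t in range(len(gi) + 1):
            if t < len(gi) and above[t]:
                if run_start is None:
                    run_start = t
                continue
            if run_start is not None:
                if t - run_start >= 2:  # minimum of two consecutive grids
                    loci.append(SweepLocus(
                        chrom=str(chrom),
                        grid_start=int(gi[run_start]),
                        grid_end=int(gi[t - 1]),
                        start=float(pos[run_start] - step / 2.0),
                        end=float(pos[t - 1] + step / 2.0),
                    ))
                run_start = None
    return loci


def loci_to_windows(loci, windows: pd.DataFrame) -> set:
    """Window ids (row indices of ``windows``) overlapping any locus.

    Overlap is half-open interval intersection on the bp scale.
    """
    out: set = set()
    chroms = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy(dtype=float)
    ends = windows["end"].to_numpy(dtype=float)
    for loc in loci:
        hit = (chroms == loc.chrom) & (starts < loc.end) & (loc.start < ends)
        out.update(windows.index[hit])
    return out


def outlier_calls(stats: pd.DataFrame, fraction: float = 0.02):
    """FST/d_XY/OGD flags for one pair's WindowStatsTable.

    ``stats`` must carry columns fst and dxy indexed by window.  Returns
    (fst_set, dxy_set, ogd_set) of window row indices plus a flag frame.
    """
    ids = list(stats.index)
    fst_set = top_fraction(ids, stats["fst"].to_numpy(), fraction)
    dxy_set = top_fraction(ids, stats["dxy"].to_numpy(), fraction)
    ogd = call_ogd(fst_set, dxy_set)
    flags = pd.DataFrame(index=stats.index)
    flags["fst_outlier"] = [i in fst_set for i in ids]
    flags["dxy_outlier"] = [i in dxy_set for i in ids]
    flags["ogd"] = [i in ogd for i in ids]
    return fst_set, dxy_set, ogd, flags
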