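"""Windowed population-genetic statistics: pi, d_XY and Weir-Cockerham FST.

All three statistics are computed from alternate-allele counts among the
*called* chromosomes at each site (missing genotypes shrink the per-site
sample size, as vcftools does).  Windows tile each contig without overlap;
the trailing partial window is retained and flagged.  Windows with no
variant sites report pi = 0 (a monomorphic stretch is informative for
diversity) but NaN for FST and d_XY (no information about differentiation).

Per site, with ``j`` alternate alleles among ``n`` called chromosomes:

* pi_site   = 2 j (n - j) / (n (n - 1))               (within a population)
* dxy_site  = p_A (1 - p_B) + p_B (1 - p_A)           (between populations)

Window values divide the summed per-site quantities by the window length in
bp.  FST uses the Weir & Cockerham (1984) variance components a, b, c for
r = 2 populations with observed heterozygote counts, combined as the
ratio-of-sums theta = sum(a) / sum(a + b + c) over contributing sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import MISSING, PopulationMap, VariantTable


def make_windows(ci: dict[str, int], size: int) -> pd.DataFrame:
    """Tile each contig with consecutive [k*size, (k+1)*size) windows.

    Coordinates are 0-based half-open.  The final window of a contig is
    truncated at the contig end and flagged ``partial``.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in ci.items():
        starts = np.arange(0, length, size)
        for s in starts:
            e = min(s + size, length)
            rows.append((chrom, int(s), int(e), e - s < size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def _pop_columns(vt: VariantTable, pm: PopulationMap, pop: str) -> np.ndarray:
    return vt.sample_indices(pm.samples_for(pop))


def allele_counts(vt: VariantTable, cols: np.ndarray):
    """Per-site (alt count j, called chromosomes n) for a sample subset."""
    g = vt.genotypes[:, cols]
    called = g != MISSING
    n = 2 * called.sum(axis=1)
    j = np.where(called, g, 0).sum(axis=1)
    return j.astype(np.int64), n.astype(np.int64)


def site_pi(j: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2 j (n-j) / (n (n-1)); NaN for n < 2."""
    j = np.asarray(j, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * j * (n - j) / (n * (n - 1.0))
    out = np.where(n >= 2, out, np.nan)
    return out


def site_dxy(jA, nA, jB, nB) -> np.ndarray:
    """Per-site absolute divergence p_A(1-p_B) + p_B(1-p_A); NaN if a
    population has no called chromosome at the site."""
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = np.asarray(jA, float) / np.asarray(nA, float)
        pB = np.asarray(jB, float) / np.asarray(nB, float)
    out = pA * (1.0 - pB) + pB * (1.0 - pA)
    return np.where((np.asarray(nA) > 0) & (np.asarray(nB) > 0), out, np.nan)


def _window_index(vt: VariantTable, windows: pd.DataFrame) -> np.ndarray:
    """Map each site to a window row index (-1 when outside every window)."""
    idx = np.full(vt.n_sites, -1, dtype=np.intp)
    for chrom, wdf in windows.groupby("chrom", sort=False):
        sel = np.flatnonzero(vt.chrom == chrom)
        if sel.size == 0:
            continue
        pos0 = vt.pos[sel] - 1  # 0-based
        starts = wdf["start"].to_numpy()
        ends = wdf["end"].to_numpy()
        k = np.searchsorted(starts, pos0, side="right") - 1
        ok = (k >= 0) & (pos0 < ends[np.clip(k, 0, len(ends) - 1)])
        idx[sel[ok]] = wdf.index.to_numpy()[k[ok]]
    return idx


def _window_sum(values: np.ndarray, widx: np.ndarray, n_windows: int):
    """Sum per-site values into windows, ignoring NaN; also count sites."""
    ok = (widx >= 0) & ~np.isnan(values)
    sums = np.bincount(widx[ok], weights=values[ok], minlength=n_windows)
    counts = np.bincount(widx[ok], minlength=n_windows)
    return sums, counts


def window_pi(vt: VariantTable, pm: PopulationMap, windows: pd.DataFrame,
              pops=None) -> pd.DataFrame:
    """Per-window per-population pi = (sum of site pi) / window length."""
    pops = list(pops) if pops is not None else pm.populations
    out = windows[["chrom", "start", "end"]].copy()
    lengths = (out["end"] - out["start"]).to_numpy(dtype=float)
    widx = _window_index(vt, windows)
    nw = len(windows)
    for pop in pops:
        j, n = allele_counts(vt, _pop_columns(vt, pm, pop))
        s, cnt = _window_sum(site_pi(j, n), widx, nw)
        out[f"pi_{pop}"] = s / lengths
        out[f"n_sites_{pop}"] = cnt
    return out


def window_dxy(vt: VariantTable, pm: PopulationMap, windows: pd.DataFrame,
               popA: str, popB: str) -> pd.DataFrame:
    """Per-window d_XY; NaN where no site has calls in both populations."""
    jA, nA = allele_counts(vt, _pop_columns(vt, pm, popA))
    jB, nB = allele_counts(vt, _pop_columns(vt, pm, popB))
    widx = _window_index(vt, windows)
    s, cnt = _window_sum(site_dxy(jA, nA, jB, nB), widx, len(windows))
    out = windows[["chrom", "start", "end"]].copy()
    lengths = (out["end"] - out["start"]).to_numpy(dtype=float)
    # no contributing site -> no information about divergence: NaN, never 0
    out["dxy"] = np.where(cnt > 0, s / lengths, np.nan)
    out["n_sites"] = cnt
    return out


def wc_site_components(gA: np.ndarray, gB: np.ndarray):
    """Weir-Cockerham (1984) per-site variance components for r = 2.

    Parameters are genotype matrices (sites x diploids, codes 0/1/2,
    MISSING allowed).  Returns arrays ``(a, b, c)``; sites where either
    population has fewer than two called diploids get NaN components.
    """
    r = 2.0

    def _summ(g):
        called = g != MISSING
        n = called.sum(axis=1).astype(float)          # diploids
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called, g, 0).sum(axis=1) / (2.0 * n)
            h = (g == 1).sum(axis=1) / n              # observed het freq
        return n, p, h

    nA, pA, hA = _summ(gA)
    nB, pB, hB = _summ(gB)
    valid = (nA >= 2) & (nB >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_theta_from_components(a, b, c) -> float:
    """Ratio-of-sums theta; NaN when no site contributes variance."""
    tot = a + b + c
    ok = ~np.isnan(tot) & (tot != 0)
    denom = tot[ok].sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def wc_fst(vt: VariantTable, pm: PopulationMap, popA: str, popB: str,
           windows: pd.DataFrame | None = None):
    """Weir-Cockerham theta between two populations.

    With ``windows=None`` returns the genome-wide scalar; otherwise a
    DataFrame with per-window theta (NaN where no site contributes).
    """
    gA = vt.genotypes[:, _pop_columns(vt, pm, popA)]
    gB = vt.genotypes[:, _pop_columns(vt, pm, popB)]
    a, b, c = wc_site_components(gA, gB)
    if windows is None:
        return wc_theta_from_components(a, b, c)
    widx = _window_index(vt, windows)
    tot = a + b + c
    contrib = (widx >= 0) & ~np.isnan(tot) & (tot != 0)
    nw = len(windows)
    num = np.bincount(widx[contrib], weights=a[contrib], minlength=nw)
    den = np.bincount(widx[contrib], weights=tot[contrib], minlength=nw)
    cnt = np.bincount(widx[contrib], minlength=nw)
    out = windows[["chrom", "start", "end"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fst"] = np.where(den != 0, num / den, np.nan)
    out.loc[cnt == 0, "fst"] = np.nan
    out["n_sites"] = cnt
    return out


def aggregate_windows(fine: pd.DataFrame, coarse: pd.DataFrame,
                      value_cols) -> pd.DataFrame:
    """Length-weighted mean of fine-window values over coarse windows.

    Used to lift 100-kb pi onto the 500-kb FST/d_XY windows.  Fine windows
    are assumed nested in (or at least fully assignable by start position
    to) the coarse tiling of the same contigs.
    """
    value_cols = list(value_cols)
    out = coarse[["chrom", "start", "end"]].copy()
    acc = {c: np.zeros(len(coarse)) for c in value_cols}
    wsum = np.zeros(len(coarse))
    coarse_idx = {}
    for i, row in coarse.iterrows():
        coarse_idx.setdefault(row["chrom"], []).append(i)
    for chrom, fdf in fine.groupby("chrom", sort=False):
        rows = coarse_idx.get(chrom, [])
        if not rows:
            continue
        starts = coarse.loc[rows, "start"].to_numpy()
        ends = coarse.loc[rows, "end"].to_numpy()
        k = np.searchsorted(starts, fdf["start"].to_numpy(), side="right") - 1
        ok = (k >= 0) & (fdf["start"].to_numpy() < ends[np.clip(k, 0, len(ends) - 1)])
        lengths = (fdf["end"] - fdf["start"]).to_numpy(dtype=float)
        tgt = np.asarray(rows)[k[ok]]
        np.add.at(wsum, tgt, lengths[ok])
        for c in value_cols:
            np.add.at(acc[c], tgt, (fdf[c].to_numpy() * lengths)[ok])
    for c in value_cols:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[c] = np.where(wsum > 0, acc[c] / wsum, np.nan)
    return out


def kendall_tau(x, y):
    """Tie-corrected Kendall tau-b with its p-value.

    Exact enumeration for small samples without ties, normal approximation
    otherwise (scipy's 'auto' policy).  Returns (nan, nan) when either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("kendall_tau needs two equal-length vectors, n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = _stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)
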