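"""Composite-likelihood selective-sweep scan (SweepFinder/SweeD family).

The scan contrasts, at each position of a fixed per-chromosome grid, a
hitchhiking model against the genome-wide background site frequency
spectrum (SFS).  The background is the empirical *folded* spectrum (no
outgroup polarization), down-projected by hypergeometric sampling to the
smallest common chromosome count when genotypes are missing.

Sweep model.  A site at distance ``d`` from the sweep has per-lineage
escape probability ``p_e = 1 - exp(-alpha * d)``, where ``alpha`` is the
sweep intensity per bp (large alpha = narrow footprint).  Of ``n`` sampled
lineages, ``E ~ Binomial(n, p_e)`` escape the sweep and each carries the
derived allele independently with the background frequency ``p``; the
``n - E`` swept lineages descend from the single hitchhiking haplotype
(star genealogy) and are all derived or all ancestral together, with
probability ``p``.  Summing over the background spectrum, the escapee
count and the block outcome gives the sampling distribution of derived
counts, which is folded and conditioned on polymorphism (VCF input carries
variant sites only).

CLR(x) = 2 * (max_alpha log L_sweep(alpha; sites near x) - log L_0), with
the neutral model included in the maximization so CLR >= 0 everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import PopulationMap, VariantTable
from .windows import allele_counts

#: default alpha grid: log-spaced per-bp intensities bracketing escape
#: probabilities from ~0 to ~1 across distances of 1 bp to 10 Mb
DEFAULT_ALPHA_GRID = np.logspace(-8, -1, 24)


@dataclass
class FoldedSFS:
    """Folded background spectrum: P(minor count = m), m = 1..n//2."""

    n: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.n // 2:
            raise ValueError(f"need {self.n // 2} classes for n={self.n}")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("folded SFS must be a probability vector")

    @property
    def n_classes(self) -> int:
        return self.n // 2


def escape_prob(alpha, d):
    """p_e = 1 - exp(-alpha * d): chance a lineage recombines off the sweep."""
    alpha = np.asarray(alpha, dtype=float)
    d = np.asarray(d, dtype=float)
    if (alpha < 0).any() if alpha.ndim else alpha < 0:
        raise ValueError("alpha must be >= 0")
    return -np.expm1(-alpha * d)


def project_folded(j: np.ndarray, n: np.ndarray, m: int) -> np.ndarray:
    """Hypergeometric projection of per-site counts to sample size ``m``.

    For each site with ``j[i]`` alternate alleles among ``n[i]`` called
    chromosomes, returns the expected folded spectrum contribution over
    minor classes 1..m//2 (monomorphic projections dropped).  Output shape
    ``(len(j), m//2)``; rows need not sum to 1.
    """
    j = np.asarray(j)
    n = np.asarray(n)
    ii = np.arange(m + 1)
    # P(i of m | j of n) for every site; hypergeom.pmf broadcasts
    pm = _stats.hypergeom.pmf(ii[None, :], n[:, None], j[:, None], m)
    ncls = m // 2
    folded = np.zeros((len(j), ncls))
    for c in range(1, ncls + 1):
        folded[:, c - 1] = pm[:, c]
        if c != m - c:
            folded[:, c - 1] += pm[:, m - c]
    return folded


def background_sfs(vt: VariantTable, pm: PopulationMap, pop: str) -> FoldedSFS:
    """Empirical folded SFS of one population over its polymorphic sites.

    Sites with missing calls are down-projected to the smallest chromosome
    count seen among polymorphic sites, so every site contributes on a
    common sample size.
    """
    cols = vt.sample_indices(pm.samples_for(pop))
    j, n = allele_counts(vt, cols)
    poly = (j > 0) & (j < n) & (n >= 2)
    if poly.sum() < 2:
        raise ValueError(f"population {pop!r} has <2 polymorphic sites")
    j, n = j[poly], n[poly]
    m = int(n.min())
    counts = np.zeros(m // 2)
    pairs, mult = np.unique(np.stack([j, n], axis=1), axis=0, return_counts=True)
    contrib = project_folded(pairs[:, 0], pairs[:, 1], m)
    counts = (contrib * mult[:, None]).sum(axis=0)
    total = counts.sum()
    if total <= 0:
        raise ValueError("projection left no polymorphic mass")
    return FoldedSFS(m, counts / total)


def _fold(k: int, n: int) -> int:
    return min(k, n - k)


def sweep_count_probs_given_p(n: int, p, pe) -> np.ndarray:
    """P(k derived | true frequency p, escape probability pe), k = 0..n.

    The site-level hitchhiking kernel: E ~ Binomial(n, pe) escapees are
    derived independently with probability p; the n-E swept lineages are
    all derived (probability p) or all ancestral.  Vectorized over sites:
    ``p`` and ``pe`` are equal-length arrays; returns shape (S, n+1).
    Mixing this kernel over the background spectrum gives the scan model.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    pe = np.atleast_1d(np.asarray(pe, dtype=float))
    ks = np.arange(n + 1)
    Es = np.arange(n + 1)
    WE = _stats.binom.pmf(Es[None, :], n, pe[:, None])            # (S, E)
    V = _stats.binom.pmf(ks[None, None, :], Es[None, :, None],
                         p[:, None, None])                        # (S, E, k)
    out = np.zeros((len(p), n + 1))
    for E in range(n + 1):
        nb = n - E  # swept-block size; a derived block shifts counts by nb
        term = (1.0 - p)[:, None] * V[:, E, :]
        term[:, nb:] += p[:, None] * V[:, E, : E + 1]
        out += WE[:, E][:, None] * term
    return out


class SweepModel:
    """Sampling distributions of allele counts under the hitchhiking model.

    Precomputes, for a fixed background spectrum, the matrix M[E, k] =
    P(k derived | E escapees) mixed over the unfolded background classes,
    so the count distribution for any escape probability is a single
    binomial-weighted matrix product.
    """

    def __init__(self, sfs: FoldedSFS):
        self.sfs = sfs
        n = sfs.n
        # unfold symmetrically: derived count j and n-j share the folded mass
        w = np.zeros(n + 1)
        for c in range(1, n // 2 + 1):
            if c == n - c:
                w[c] = sfs.probs[c - 1]
            else:
                w[c] = w[n - c] = sfs.probs[c - 1] / 2.0
        ks = np.arange(n + 1)
        M = np.zeros((n + 1, n + 1))  # [E, k]
        for jj in range(1, n):
            if w[jj] == 0:
                continue
            p = jj / n
            for E in range(n + 1):
                esc = _stats.binom.pmf(ks, E, p)  # zero beyond k > E
                v = (1.0 - p) * esc
                nb = n - E  # block size; block derived adds nb to the count
                v[nb:] += p * esc[: n + 1 - nb]
                M[E] += w[jj] * v
        self._M = M
        self._n = n

    def count_probs(self, pe: float) -> np.ndarray:
        """Unconditioned P(k derived), k = 0..n, at escape probability pe."""
        n = self._n
        wE = _stats.binom.pmf(np.arange(n + 1), n, pe)
        return wE @ self._M

    def folded_conditional(self, pe: float) -> np.ndarray:
        """P(minor class m | polymorphic), m = 1..n//2."""
        n = self._n
        P = self.count_probs(pe)
        ncls = n // 2
        out = np.zeros(ncls)
        for c in range(1, ncls + 1):
            out[c - 1] = P[c] + (P[n - c] if c != n - c else 0.0)
        mass = out.sum()
        if mass < 1e-300:
            raise FloatingPointError("sweep model: polymorphic mass underflow")
        return out / mass


def sweep_site_probs(sfs: FoldedSFS, alpha: float, d: float) -> np.ndarray:
    """Folded, polymorphism-conditioned site distribution at distance d.

    Exact enumeration over escapee counts and block outcomes; this is the
    reference path the tabulated scan is checked against.
    """
    pe = float(escape_prob(alpha, d))
    if pe <= 0.0:
        # the non-escaped block swallows every lineage: monomorphic a.s.,
        # so the polymorphism-conditioned distribution is the pe->0+ limit
        pe = 1e-12
    return SweepModel(sfs).folded_conditional(pe)


class _ScanTable:
    """Conditional log-probabilities tabulated on a linear p_e grid."""

    def __init__(self, model: SweepModel, bins: int = 2048):
        self.bins = bins
        pes = np.linspace(0.0, 1.0, bins)
        pes[0] = 1e-9  # pe = 0 has no polymorphic outcome; use the limit
        rows = np.stack([model.folded_conditional(pe) for pe in pes])
        with np.errstate(divide="ignore"):
            self.logT = np.log(rows)

    def lookup(self, pe: np.ndarray) -> np.ndarray:
        return np.rint(pe * (self.bins - 1)).astype(np.intp)


def clr_at_grid(positions, classes, grid_positions, sfs: FoldedSFS,
                alpha_grid=None, max_window: float = 1_000_000.0,
                table: "_ScanTable | None" = None):
    """CLR and fitted alpha at arbitrary grid positions.

    ``positions`` (bp, sorted ascending) and ``classes`` (0-based folded
    minor class per site) describe one chromosome's polymorphic sites for
    the focal population.  Returns ``(clr, alpha_hat)`` arrays.
    """
    alphas = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    positions = np.asarray(positions, dtype=float)
    classes = np.asarray(classes, dtype=np.intp)
    if np.any(np.diff(positions) < 0):
        raise ValueError("site positions must be sorted")
    model = SweepModel(sfs)
    table = table or _ScanTable(model)
    with np.errstate(divide="ignore"):
        lognull = np.log(sfs.probs)

    clr = np.zeros(len(grid_positions))
    alpha_hat = np.full(len(grid_positions), np.nan)
    for g, x in enumerate(grid_positions):
        lo = np.searchsorted(positions, x - max_window)
        hi = np.searchsorted(positions, x + max_window, side="right")
        if hi <= lo:
            continue
        d = np.abs(positions[lo:hi] - x)
        cls = classes[lo:hi]
        ll0 = lognull[cls].sum()
        best = -np.inf
        best_a = np.nan
        for a in alphas:
            pe = -np.expm1(-a * d)
            ll = table.logT[table.lookup(pe), cls].sum()
            if ll > best:
                best, best_a = ll, a
        if best > ll0:
            clr[g] = 2.0 * (best - ll0)
            alpha_hat[g] = best_a
    return clr, alpha_hat


def default_grid(length: int, grid: int) -> np.ndarray:
    """``grid`` equally spaced positions (bin midpoints) along a contig."""
    step = length / grid
    return (np.arange(grid) + 0.5) * step


def clr_scan(vt: VariantTable, pm: PopulationMap, pop: str,
             ci: dict[str, int], grid: int = 1000, alpha_grid=None,
             max_window: float = 1_000_000.0,
             sfs: FoldedSFS | None = None) -> pd.DataFrame:
    """Composite-likelihood sweep scan for one population.

    The grid of ``grid`` positions is laid per chromosome.  Only sites
    polymorphic in the population contribute; sites with missing calls are
    excluded from scoring (the background SFS still uses them through
    projection).  Returns a DataFrame (chrom, grid_index, pos, clr,
    alpha_hat); chromosomes with no polymorphic site yield CLR = 0 rows
    and a warning.
    """
    if sfs is None:
        sfs = background_sfs(vt, pm, pop)
    cols = vt.sample_indices(pm.samples_for(pop))
    j, n = allele_counts(vt, cols)
    usable = (j > 0) & (j < n) & (n == sfs.n)
    table = _ScanTable(SweepModel(sfs))

    frames = []
    for chrom, length in ci.items():
        gx = default_grid(length, grid)
        sel = usable & (vt.chrom == chrom)
        out = pd.DataFrame({
            "chrom": chrom,
            "grid_index": np.arange(grid),
            "pos": gx,
            "clr": 0.0,
            "alpha_hat": np.nan,
        })
        if not sel.any():
            warnings.warn(f"no polymorphic sites on {chrom} for {pop}; empty scan")
        else:
            pos = vt.pos[sel].astype(float)
            cls = np.minimum(j[sel], n[sel] - j[sel]) - 1
            clr, ah = clr_at_grid(pos, cls, gx, sfs, alpha_grid, max_window, table)
            out["clr"] = clr
            out["alpha_hat"] = ah
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
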