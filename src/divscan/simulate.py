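"""Synthetic structured-population data with planted sweeps and annotations.

Genotypes follow the Balding-Nichols model: each site has an ancestral
frequency p ~ Uniform(0.05, 0.95); population k draws its own frequency
p_k ~ Beta(p (1-F_k)/F_k, (1-p)(1-F_k)/F_k), so E[p_k] = p and
Var[p_k] = F_k p (1-p) — F_k is the population's differentiation level and
is what a Weir-Cockerham scan should recover.  Diploid genotypes are
Binomial(2, p_k); sites are unlinked.

Two kinds of selection signal can be planted:

* ``divergent_regions`` — inside the region the target population's
  ancestral frequency is pulled toward the reversed allele (the locally
  favored allele is the one rare elsewhere), emulating a deep local split
  under divergent selection.  This raises both FST and d_XY, which drift
  alone cannot do (drift preserves E[d_XY]).
* ``sweep_specs`` — a hitchhiking sweep injected through the *same*
  star-genealogy model the CLR scan fits (see :mod:`divscan.sweep`), so
  sweep-location recovery is a well-posed estimation problem.  The sweep
  crushes local diversity and skews the SFS toward extreme classes without
  changing expected allele frequencies.

Gene annotations place genes uniformly; inside sweep-target regions the
focal family's probability is multiplied by ``enrich_factor``
(renormalized), and the focal family carries one dedicated GO term —
emulating a detoxification-gene cluster sitting under a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PopulationMap, VariantTable
from .sweep import FoldedSFS, background_sfs, sweep_count_probs_given_p

_NUC = np.array(list("ACGT"))


@dataclass
class SweepSpec:
    pop: str
    chrom: str
    center: int
    alpha: float  # per-bp sweep intensity


@dataclass
class DivergentRegion:
    """Local deep split under divergent selection: inside the region the
    target population's ancestral frequency is pulled toward the reversed
    allele, p -> (1-strength) * p + strength * (1-p).  At strength 1 the
    locally favored allele is exactly the one rare elsewhere, raising both
    FST and d_XY — which drift alone cannot do."""

    pop: str
    chrom: str
    start: int  # 0-based half-open, like every region in the pipeline
    end: int
    strength: float = 1.0


@dataclass
class FamilySpec:
    """Gene-annotation scenario: family mix and sweep-region enrichment."""

    n_genes: int = 1200  # ~1 gene per 5 kb on the reference genome scale
    family_probs: dict = field(
        default_factory=lambda: {"CYP": 0.05, "MDR": 0.05, "other": 0.90}
    )
    focal_family: str = "CYP"
    enrich_factor: float = 20.0
    gene_length: int = 2000
    family_go: dict = field(
        default_factory=lambda: {"CYP": ("GO:0005506",), "MDR": ("GO:0008559",)}
    )
    go_pool_size: int = 30  # generic terms sprinkled over all genes


@dataclass
class SimScenario:
    """Full description of one synthetic study; fixed seed => fixed output."""

    pop_names: tuple = ("SA", "ML", "EGT")
    diploids_per_pop: tuple = (10, 10, 11)
    F: tuple = (0.04, 0.04, 0.04)
    n_chrom: int = 6
    chrom_length: int = 1_000_000
    n_sites: int = 1200  # per chromosome, before position deduplication
    sweep_specs: list = field(default_factory=list)
    divergent_regions: list = field(default_factory=list)
    family_spec: FamilySpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.pop_names) == len(self.diploids_per_pop) == len(self.F)):
            raise ValueError("pop_names, diploids_per_pop and F must align")
        if any(d <= 0 for d in self.diploids_per_pop):
            raise ValueError("diploid counts must be positive")
        if any(not (0.0 < f < 1.0) for f in self.F):
            raise ValueError("Balding-Nichols F must lie in (0, 1)")
        if self.n_chrom <= 0 or self.chrom_length <= 0 or self.n_sites <= 0:
            raise ValueError("counts and lengths must be positive")
        for s in self.sweep_specs:
            if not (0 <= s.center <= self.chrom_length):
                raise ValueError(f"sweep center {s.center} outside chromosome")

    @property
    def contigs(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}


def reference_scenario(seed: int = 0) -> SimScenario:
    """The package's reference study: three populations of 10-11 diploids
    at genome-wide differentiation ~0.04, one divergent region on chr1
    carrying a population-specific sweep in SA, and a CYP-enriched gene
    cluster inside it."""
    return SimScenario(
        pop_names=("SA", "ML", "EGT"),
        diploids_per_pop=(10, 10, 11),
        F=(0.04, 0.04, 0.04),
        n_chrom=6,
        chrom_length=1_000_000,
        n_sites=1200,
        sweep_specs=[SweepSpec("SA", "chr1", 500_000, 2e-5)],
        divergent_regions=[DivergentRegion("SA", "chr1", 400_000, 600_000)],
        family_spec=FamilySpec(),
        seed=seed,
    )


def simulate_structured_genotypes(scn: SimScenario):
    """Draw genotypes under the scenario (without sweep injection).

    Returns ``(VariantTable, PopulationMap, contig index)``.  Sweep specs
    are applied separately by :func:`inject_sweep` /
    :func:`simulate_scenario` because injection needs the pre-sweep SFS.
    """
    rng = np.random.default_rng(scn.seed)
    samples, labels = [], []
    for pop, nd in zip(scn.pop_names, scn.diploids_per_pop):
        for i in range(nd):
            samples.append(f"{pop}_{i:02d}")
            labels.append(pop)
    pm = PopulationMap(dict(zip(samples, labels)))
    ci = scn.contigs

    chroms, poss, refs, alts, gts = [], [], [], [], []
    for chrom in ci:
        pos = np.unique(rng.integers(1, scn.chrom_length + 1, size=scn.n_sites))
        S = len(pos)
        p = rng.uniform(0.05, 0.95, size=S)
        cols = []
        for pop, nd, F in zip(scn.pop_names, scn.diploids_per_pop, scn.F):
            p_anc = p.copy()
            for reg in scn.divergent_regions:
                if reg.pop != pop or reg.chrom != chrom:
                    continue
                inside = (pos - 1 >= reg.start) & (pos - 1 < reg.end)
                if inside.any():
                    p_anc[inside] = ((1 - reg.strength) * p_anc[inside]
                                     + reg.strength * (1 - p_anc[inside]))
            scale = (1.0 - F) / F
            pk = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
            cols.append(rng.binomial(2, pk[:, None], size=(S, nd)))
        g = np.concatenate(cols, axis=1).astype(np.int8)
        ref_idx = rng.integers(0, 4, size=S)
        alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
        chroms.append(np.full(S, chrom, dtype=object))
        poss.append(pos)
        refs.append(_NUC[ref_idx])
        alts.append(_NUC[alt_idx])
        gts.append(g)

    vt = VariantTable(
        np.concatenate(chroms), np.concatenate(poss), np.concatenate(refs),
        np.concatenate(alts), np.vstack(gts), samples,
    )
    return vt, pm, ci


def inject_sweep(vt: VariantTable, pm: PopulationMap, pop: str, chrom: str,
                 center: int, alpha: float, sfs: FoldedSFS,
                 rng: np.random.Generator) -> VariantTable:
    """Redraw the target population's genotypes on one chromosome from the
    hitchhiking model centred at ``center`` with intensity ``alpha``.

    Each site's allele count is redrawn conditional on the site's own
    pre-sweep frequency ``p``: ``E ~ Binomial(n, p_e)`` lineages escape and
    are derived independently with probability p, while the ``n - E``
    swept lineages are all derived or all ancestral together (probability
    p).  Marginalized over sites — whose frequencies realize the background
    SFS — this is exactly the mixture distribution the CLR scan fits, so
    recovery of the planted sweep is a well-posed estimation problem; far
    sites (p_e near 1) are merely resampled binomially from their own
    frequency, leaving cross-population structure intact.  Counts are then
    assorted randomly into diploids.  Other populations and chromosomes are
    untouched.  Requires full calls in the target population.
    """
    cols = vt.sample_indices(pm.samples_for(pop))
    sel = np.flatnonzero(vt.chrom == chrom)
    if sel.size == 0:
        raise KeyError(f"no sites on {chrom}")
    g = vt.genotypes.copy()
    sub = g[np.ix_(sel, cols)]
    if (sub < 0).any():
        raise ValueError("sweep injection requires full calls in the target pop")
    n = 2 * len(cols)
    if sfs.n != n:
        raise ValueError(f"SFS sample size {sfs.n} != target pop chromosomes {n}")

    d = np.abs(vt.pos[sel].astype(float) - center)
    pe = -np.expm1(-alpha * d)
    phat = sub.sum(axis=1) / n
    P = sweep_count_probs_given_p(n, phat, pe)
    u = rng.random(len(sel))
    k = (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
    # random assortment of k derived alleles over n chromosome slots
    ranks = np.argsort(rng.random((len(sel), n)), axis=1)
    derived = ranks < k[:, None]
    new = (derived[:, 0::2].astype(np.int8) + derived[:, 1::2].astype(np.int8))
    g[np.ix_(sel, cols)] = new
    out = VariantTable(vt.chrom, vt.pos, vt.ref, vt.alt, g, vt.samples, vt.info)
    return out


def simulate_annotations(ci: dict[str, int], sweep_regions, spec: FamilySpec,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Place genes uniformly; enrich the focal family inside sweep regions.

    ``sweep_regions`` is an iterable of (chrom, start, end) half-open
    intervals.  Returns a GeneTable DataFrame (gene_id, chrom, start, end,
    family, go_terms) with ``go_terms`` a frozenset per gene.
    """
    if spec.enrich_factor < 1:
        raise ValueError("enrich_factor must be >= 1")
    chrom_names = list(ci)
    lengths = np.array([ci[c] for c in chrom_names], dtype=float)
    cprob = lengths / lengths.sum()
    fam_names = list(spec.family_probs)
    base = np.array([spec.family_probs[f] for f in fam_names], dtype=float)
    base = base / base.sum()
    boosted = base.copy()
    if spec.focal_family in fam_names:
        boosted[fam_names.index(spec.focal_family)] *= spec.enrich_factor
        boosted = boosted / boosted.sum()
    regions = [(c, int(s), int(e)) for c, s, e in sweep_regions]

    N = spec.n_genes
    ci_idx = rng.choice(len(chrom_names), size=N, p=cprob)
    span = np.maximum(1, lengths[ci_idx].astype(int) - spec.gene_length)
    starts = (rng.random(N) * span).astype(int)
    ends = np.minimum(starts + spec.gene_length, lengths[ci_idx].astype(int))
    chroms = np.array(chrom_names, dtype=object)[ci_idx]
    in_region = np.zeros(N, dtype=bool)
    for c, rs, re in regions:
        in_region |= (chroms == c) & (starts < re) & (rs < ends)
    # family draw: inverse-CDF against the plain or boosted mix
    u = rng.random(N)
    fam_idx = np.where(
        in_region,
        np.searchsorted(np.cumsum(boosted), u, side="right"),
        np.searchsorted(np.cumsum(base), u, side="right"),
    )
    fam_idx = np.clip(fam_idx, 0, len(fam_names) - 1)
    families = np.array(fam_names, dtype=object)[fam_idx]
    # 1-3 generic GO terms per gene plus the family's dedicated terms
    n_generic = rng.integers(1, 4, size=N)
    order = np.argsort(rng.random((N, spec.go_pool_size)), axis=1)[:, :3]
    rows = []
    for i in range(N):
        terms = set(spec.family_go.get(families[i], ()))
        terms.update(f"GO:G{j:04d}" for j in order[i, : n_generic[i]])
        rows.append((f"gene{i + 1:05d}", chroms[i], int(starts[i]),
                     int(ends[i]), families[i], frozenset(terms)))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "family", "go_terms"]
    )


def simulate_scenario(scn: SimScenario):
    """Run the full generator: genotypes, sweeps, annotations.

    Returns ``(vt, pm, ci, genes, sweep_regions)`` where ``sweep_regions``
    are the planted target intervals (the divergent regions when present,
    otherwise +-100 kb around each sweep centre) used for gene enrichment.
    """
    vt, pm, ci = simulate_structured_genotypes(scn)
    rng = np.random.default_rng(np.random.SeedSequence([scn.seed, 7]))
    for s in scn.sweep_specs:
        sfs = background_sfs(vt, pm, s.pop)
        vt = inject_sweep(vt, pm, s.pop, s.chrom, s.center, s.alpha, sfs, rng)
    regions = [(r.chrom, r.start, r.end) for r in scn.divergent_regions]
    if not regions:
        regions = [
            (s.chrom, max(0, s.center - 100_000),
             min(scn.chrom_length, s.center + 100_000))
            for s in scn.sweep_specs
        ]
    genes = None
    if scn.family_spec is not None:
        genes = simulate_annotations(ci, regions, scn.family_spec, rng)
    return vt, pm, ci, genes, regions
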