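# Methods

## Scope and data model

The pipeline starts at a VCF of biallelic SNVs with diploid genotypes.
Genotypes are coded as alternate-allele counts {0, 1, 2}, with half-called
or uncalled genotypes treated as missing (conservative: a half call gives
no reliable diploid state).  Positions are 1-based internally (VCF
convention); every window, region and locus written out is 0-based
half-open (BED convention).  The boundary is crossed exactly once, at
output.

Site-level filters follow standard short-read hard-filtering practice: a
site is removed when QD < 2.0, FS > 60.0, MQ < 40.0, MQRankSum < −12.5 or
ReadPosRankSum < −8.0.  A missing INFO key cannot fire its criterion —
the filter refuses to exclude what it cannot evaluate.  An optional
drop-missing step keeps only sites called in every sample; both
missingness-filtered and unfiltered paths are available because windowed
statistics handle per-site sample-size variation natively (per-site *n*
is the count of called chromosomes, vcftools-style).

## Windowed statistics

Windows tile each contig without overlap; the final partial window is
kept and flagged.  With *j* alternate alleles among *n* called
chromosomes at a site:

* π (within a population): per-site heterozygosity 2j(n−j)/(n(n−1)),
  summed over sites and divided by the window length in bp.  Computed
  natively at the π window size (default 100 kb) and lifted to the
  F_ST/d_XY windows (default 500 kb) by length-weighted mean; the two
  routes agree to 1e-12 by construction and by test.
* d_XY (between populations A, B): per-site p_A(1−p_B) + p_B(1−p_A)
  summed and divided by the window length.  This equals the mean
  difference over all between-population chromosome pairs; dividing by
  window length (not variant count) keeps d_XY on the standard per-bp
  scale.  Windows with no site callable in both populations report NaN —
  never a fabricated zero, since absent variants are informative for
  diversity but not for divergence ratios.
* F_ST: Weir & Cockerham's (1984) variance components a, b, c for r = 2
  populations, using observed heterozygote counts (the full estimator,
  not the allele-frequency-only approximation), combined as the
  ratio-of-sums θ = Σa / Σ(a+b+c) over contributing sites.  Sites where a
  population has fewer than two called diploids, or where a+b+c = 0, do
  not contribute; windows with no contributing site report NaN.  θ may be
  slightly negative under panmixia — that is the estimator working, not
  an error.

The d_XY–π relationship is summarized by tie-corrected Kendall τ-b
(exact small-sample p, asymptotic otherwise), between window d_XY and the
mean of the two populations' π lifted to the same windows.

## Composite-likelihood sweep scan

The scan is a SweepFinder/SweeD-family CLR on a per-chromosome grid
(default 1,000 equally spaced positions, matching the scale at which a
genome-wide top-0.05% rule yields a handful of outliers on a ~30
chromosome genome).

**Background.**  The empirical folded SFS of the focal population over
its polymorphic sites.  No outgroup polarization is assumed (folded
spectra need none).  Sites with missing calls are down-projected to the
smallest common chromosome count by hypergeometric projection, so every
site contributes on one sample size.

**Sweep model.**  A site at distance d from a sweep of intensity α
(per bp) has per-lineage escape probability p_e = 1 − e^(−αd).  Of n
sampled lineages, E ~ Binomial(n, p_e) escape and carry the derived
allele independently with the background frequency p; the n−E swept
lineages descend from the hitchhiking haplotype (star genealogy) and are
all derived or all ancestral together with probability p.  Mixing over
the background spectrum (unfolded symmetrically), folding, and
conditioning on polymorphism gives the site distribution.  The
polymorphism conditioning reflects the input: a VCF carries variant
sites only.  This is a deliberate divergence from
SweepFinder-with-invariant-sites; it shifts absolute CLR magnitudes but
not rank-based outlier calling.

**Maximization.**  CLR(x) = 2·(max_α Σ log P_sweep − Σ log P_0) over
sites within 1 Mb of the grid point x (beyond that, escape probabilities
saturate and sites carry no positional signal; both model and null terms
are omitted symmetrically).  α ranges over 24 log-spaced values in
[1e-8, 1e-1] per bp — bracketing p_e from ~0 to ~1 across 1 bp–10 Mb
distances — plus a neutral sentinel, so CLR ≥ 0 everywhere by
construction.

**Numerics.**  The conditional site distribution depends on (α, d) only
through p_e, so it is tabulated once per population on a 2,048-point
linear p_e grid (exact at the nodes; nearest-neighbor lookup; the p_e = 0
node holds the analytic limit, all mass on singletons).  The direct
enumeration path (`sweep_site_probs`) stays exact and is what tests check
against brute-force path enumeration.

**Calling.**  Sweep loci are maximal runs of ≥ 2 consecutive grid points
above the genome-wide top-0.05% CLR threshold for that population;
singleton peaks are discarded.  Run intervals are padded by half a grid
step per side before window projection (half-open intersection).

## Outlier and OGD rules

All thresholds are rank rules, not parametric: top 2% of windows for
F_ST and for d_XY per population pair (NaN windows excluded before
ranking; ties at the cut all included, so calls are order-independent),
top 0.05% of grid points for CLR per population genome-wide.  A window is
an **OGD** when it is in both the F_ST and the d_XY outlier set of the
same pair — set intersection, nothing more.

## Permutation tests

Both tests report the +1-corrected estimator
p = (1 + #{null ≥ observed}) / (reps + 1), which is never exactly zero;
"p < 0.001" at 1,000 replications means the observed value beat every
draw.

* Genome-wide F_ST significance: population labels are shuffled over the
  pooled samples (group sizes preserved — shuffling labels, not
  genotypes, keeps within-individual structure) and θ recomputed per
  replicate; default 100 replications.
* OGD × sweep association: the observed statistic is the overlap count
  |OGD ∩ sweep windows|; each replicate redraws |sweep windows| windows
  uniformly without replacement from the universe (windows with defined
  F_ST in every pair) and recounts.  Uniform placement makes the null
  exactly hypergeometric, which the tests exploit as an oracle; default
  1,000 replications.  OGDs are pooled across pairs for the association
  universe; sweep windows are per population.

## Enrichment

One-tailed (greater) Fisher exact tests on the 2×2 gene table.  The
target set is the genes overlapping sweep-targeted OGD windows
(half-open overlap; a gene overlapping several windows counts once).
The universe is every annotated gene on the analyzed contigs.  GO terms
are flat labels (no graph propagation); only terms carried by at least
one target gene are tested — untestable terms would merely inflate the
Benjamini–Hochberg denominator — and BH-adjusted q < 0.1 is reported.

## Synthetic data

The generator provides the statistical structure the analysis assumes,
at desk scale, with closed-form targets for recovery tests:

* **Structure** — Balding–Nichols: ancestral frequency
  p ~ Uniform(0.05, 0.95) per site; population k draws
  p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), so Var[p_k] = F_k p(1−p)
  and Weir–Cockerham θ should recover F_k.  Genotypes are
  Binomial(2, p_k); sites are unlinked (none of the implemented
  statistics model LD).
* **Divergent regions** — inside a region the target population's
  ancestral frequency is pulled toward the reversed allele
  (p → (1−w)p + w(1−p)): divergent selection favors the allele rare
  elsewhere.  This is the only mechanism in the generator that raises
  expected d_XY; drift (any F) and sweeps preserve E[p] and hence
  E[d_XY], which is precisely why the OGD rule demands a d_XY outlier on
  top of an F_ST outlier.
* **Sweeps** — injected through the same hitchhiking kernel the scan
  fits, conditioned on each site's own pre-sweep frequency (block and
  escapees derived with probability p̂).  Marginalized over sites this
  reproduces the scan's mixture model exactly (generative–inferential
  duality), so sweep-position recovery is a well-posed estimation
  problem; far sites, where p_e ≈ 1, are merely resampled binomially
  from their own frequency and population structure is untouched.
  Conditioning on the site's frequency rather than drawing from the
  marginal background spectrum is essential: a marginal redraw would
  decouple the swept population's frequencies from the others at every
  redrawn site and manufacture chromosome-wide differentiation.
* **Annotations** — genes placed uniformly (default 1,200 genes of 2 kb
  on a 6-Mb genome, ~1 per 5 kb, matching dense insect gene
  neighborhoods); inside target regions the focal family's probability
  is multiplied by the enrichment factor (default 20) and renormalized.
  The focal family carries one dedicated GO term; every gene carries 1–3
  generic terms so the FDR correction has a realistic denominator.

The **reference scenario** is three populations (SA, ML, EGT; 10, 10, 11
diploids) at F = 0.04 each — genome-wide pairwise θ ≈ 0.03–0.06 — on six
1-Mb chromosomes with 1,200 sites each; one divergent region
(chr1:400–600 kb, SA) carrying a sweep (center 500 kb, α = 2×10⁻⁵/bp) and
the CYP-enriched cluster.  The matching run configuration scales windows
to the chromosome length (100-kb scan windows, 20-kb π windows) while
keeping every fraction, grid size and replication count at its canonical
default.  The dedicated localization scenario uses α = 5×10⁻⁵ and 3
sites/kb, chosen by a design-time power analysis so that the likelihood
surface carries enough information for grid-step-level localization.

What the generator does **not** emulate: linkage disequilibrium and
recombination maps, demography (growth, migration, admixture),
mutation-rate variation, sequencing/genotyping error, and annotation
transfer error.  Passing tests therefore demonstrate estimator and
pipeline correctness under the model's assumptions — not robustness to
the misspecification real data brings.

## Reproducibility

A single run seed fans out to per-stage child seeds through
`numpy.random.SeedSequence.spawn`, so stages can be rerun or reordered
without seed collisions; all seeds are logged in the run report, and
identical configurations produce byte-identical result tables.

## Known limitations

* The variants-only CLR discards the missing-polymorphism signal of very
  strong sweeps: center CLR is not monotone in α (stronger sweeps
  sterilize more nearby sites, and the informative ring shrinks as 1/α).
  Detection and localization are unaffected at the intensities tested;
  absolute CLR values are not comparable to SweeD's invariant-site
  likelihood.
* The background SFS is estimated from the scanned data itself; on a
  genome dominated by a single swept region (e.g. a one-chromosome
  simulation with a genome-wide footprint) the background absorbs the
  sweep and the contrast vanishes.  Real multi-chromosome genomes are
  unaffected.
* d_XY per window uses window length in bp as denominator and so assumes
  the VCF reports all variable sites in the window (no accessibility
  mask).
* Permutation p-values are discrete; with tiny outlier sets the
  uniform-null approximation is coarse (the +1 correction keeps them
  conservative).
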