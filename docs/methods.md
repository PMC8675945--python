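# Methods

This note records the models implemented in `chronosoil`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one construction
was defensible.

## Eco-enzymatic stoichiometry

Microbial investment into resource acquisition is summarised from five
hydrolase activities (BG, CBH: carbon; NAG, LAP: nitrogen; AP:
phosphorus), in nmol g⁻¹ dry soil h⁻¹.

Two summaries are computed.  The **ratio plane** uses untransformed
activity ratios; the quadrant classifier on (C:N, N:P) uses boundaries at
ratio = 1 on both axes by default.  Unity boundaries are a convention (the
global-mean enzymatic stoichiometry argument), not a measured constant,
and are configurable; ties on a boundary fall into the N quadrant by the
documented ≤/≥ rule, so the classifier is total.

The **vector representation** uses
x = ln(BG+CBH)/ln(AP), y = ln(BG+CBH)/ln(NAG+LAP), L = √(x²+y²),
A = degrees(atan2(y, x)).  Two conventions of `ATAN2` argument order exist
across software; the order here is fixed by the biology: A must exceed 45°
exactly when phosphatase investment exceeds N-enzyme investment (y > x).
Because the coordinates are ratios of logarithms, they are **not**
invariant under a change of activity units.  The module therefore requires
BG+CBH, NAG+LAP and AP all > 1 in working units (every log strictly
positive) and refuses the input otherwise rather than adding a
pseudo-offset, since any offset silently shifts both L and A.  The plain
activity ratios, in contrast, are exactly scale-invariant, and the test
suite asserts both properties.  An untransformed-activity variant of the
vector is exposed (`log_transform=False`) for users who select the
transform by the kurtosis of the angle distribution.

## Community assembly (βMNTD / βNTI / RC_bray)

For samples k, l with within-sample relative abundances f and patristic
distances d on a rooted, branch-length-bearing tree:

βMNTD(k,l) = ½ [ Σᵢ f_ik · min_{j∈l} d(i,j) + Σⱼ f_jl · min_{i∈k} d(i,j) ].

Taxa shared by both samples contribute zero (their nearest relative in the
other community is themselves); abundance weighting is the default and can
be disabled.  **βNTI** standardises the observed βMNTD against a null that
shuffles tip labels across the entire tree — equivalently, permutes the
rows/columns of the patristic matrix — holding the abundance table fixed,
with 999 replicates by default.  Pairs whose null distribution has zero
spread (e.g. a star phylogeny, or two samples sharing all taxa) are
reported as NaN, logged, and excluded from downstream fractions.  The null
permutations are evaluated vectorised in chunks bounded to ~20 M temporary
elements, so 999 replicates on a 600-taxon pool run in about a minute.

**RC_bray** follows the stochastic-assembly null: each sample's observed
richness is drawn from the species pool with probability proportional to
occupancy frequency, each selected taxon is seeded with one read, and the
remaining reads are distributed multinomially proportional to pool
relative abundance; RC = 2·((#null BC < obs BC) + ½·ties)/n_null − 1,
ties at half weight.  One set of null communities is drawn per sample and
shared across pairs (each pair's null distribution remains valid; draws
are correlated across pairs, which only matters for joint inference across
pairs, not for per-pair classification).  The pool is estimated from the
table by default and can be overridden when a larger survey defines it.
A plug-in pool estimated from few samples makes RC conservative-to-biased
in a direction that depends on the data; the calibration test therefore
generates data from the null process itself with a known pool, where
|RC| > 0.95 occurs at close to the nominal rate.

**Classification** is the strict-threshold rule: βNTI > 2 variable
selection; βNTI < −2 homogeneous selection; otherwise RC < −0.95
homogenizing dispersal, RC > 0.95 dispersal limitation, else undominated.
Boundary values (βNTI = ±2, RC = ±0.95) fall on the undominated side,
matching the strict inequalities.  Process fractions are computed over
within-group sample pairs only; between-group pairs are excluded.

The Mantel test of βNTI against the Euclidean distance of a soil variable
uses Pearson correlation over the lower triangle with simultaneous
row/column permutation (999 by default), one-sided upper tail.

## Co-occurrence networks

**sparCC.**  Log-ratio variances t_ij = var log(x_i/x_j) are computed on
Dirichlet-posterior fraction draws (pseudocount 1, 20 draws, median of the
per-draw estimates).  Basis variances solve the linear system implied by
the sparsity assumption; the most strongly correlated pair above the
exclusion threshold (0.1) is removed from the system and the solution
iterated (10 rounds).  Correlations are clipped to [−1, 1].  The draws are
attached to sample identities (one RNG substream per sample id), so the
estimate is invariant under sample reordering.  Significance comes from a
permutation null — each OTU's counts shuffled independently across
samples, destroying between-taxon association while preserving marginals —
with p = (1 + exceedances)/(n_null + 1), two-sided on |r|; 100 null tables
by default.

**RMT threshold.**  For each candidate cutoff (default scan 0.30–0.90,
step 0.01) the thresholded matrix's eigenvalue spacings are unfolded by a
degree-5 polynomial fit of the cumulative spectral density and tested
against the exponential (Poisson) law by a chi-square goodness-of-fit on
equal-probability bins (up to 20 bins, at least 5 spacings per bin; small
matrices get proportionally fewer bins since 20 populated bins need ≳100
spacings).  The returned threshold is the smallest cutoff with GOF
p > 0.05 — the point where level repulsion (noise, Wigner–Dyson) gives way
to uncorrelated spacings (modular structure).  Degenerate spectra (zero
spread) yield no test and, if no cutoff passes, an error advising a wider
scan range.

**Graph stage.**  An edge requires |r| ≥ threshold AND p < 0.05; isolated
nodes are dropped; signs are recorded and the positive-link fraction
reported.  Per-sample subnetworks are induced subgraphs on the taxa present
(count > 0) in that sample.  Topology: global transitivity, average degree
2E/N, mean normalized betweenness, average shortest-path length over
reachable pairs only (unweighted), density.  Modules come from greedy
modularity agglomeration on absolute edge weights — chosen over stochastic
multi-level methods so module counts are reproducible — with ids ordered
by module size.  Zi is the within-module degree z-score (population sd;
modules with zero spread give Zi = 0 by convention, logged); Pi = 1 −
Σ_s (k_is/k_i)².  Roles partition the plane exclusively: network hub
(Zi > 2.5 and Pi > 0.62), module hub (Zi > 2.5 only), connector
(Pi > 0.62 only), peripheral otherwise; boundary equality falls to the
lower role.  The published role definitions for this plane overlap (module
hubs defined by Zi alone would swallow network hubs; connectors defined by
Pi alone lack a Zi bound); the disjoint partition above is the standard
resolution and is what a well-defined classifier requires.  Module hubs,
network hubs and connectors are flagged as putative keystones.

## Community statistics

Rarefaction subsamples without replacement (multivariate hypergeometric)
to exactly the requested depth, dropping shallower samples with a warning.
Shannon diversity uses natural logarithms.  Bray–Curtis is Σ|x−y|/Σ(x+y).
PCoA is Gower double-centering plus eigendecomposition; negative
eigenvalues are reported, not corrected, and coordinates are returned for
positive axes (the identity that full-dimension coordinates reproduce
Euclidean input distances is asserted in the tests).

**PERMDISP** embeds the distance matrix in full dimension, keeping
imaginary axes for negative eigenvalues (squared distances on those axes
subtract), computes each sample's distance to its group centroid (spatial
median optional), and takes the one-way ANOVA F on those distances.  The
permutation p-value relabels samples and **recomputes the centroids and
distances under every relabelling** rather than permuting the observed
distance values: the shortcut of shuffling precomputed distances is
slightly liberal because those distances depend on the original grouping,
while full recomputation gives a type-I error at the nominal rate (the
acceptance suite verifies 0.03–0.07 at α = 0.05 over 1,000 simulations).
The per-group mean centroid distances are reported alongside, serving as
the dispersion-index table.

**RDA** Hellinger-transforms the community matrix by default (raw counts
violate the linearity RDA assumes), centres it, standardises predictors,
rejects collinear designs (condition number > 1e8, naming the worst pair),
and scores each predictor by its marginal F — added explained variance
given all other predictors over full-model residual variance — with a
permutation p from permuting response rows (999 by default).

## Synthetic data: what it emulates, and what it does not

The generators provide ground truth for every stage and define the
conditions under which the test suite's statistical claims hold.

* **Trees** are birth–death simulations (default pure birth) with 600 tips
  by default, ultrametric, deterministically seeded.
* **Metacommunity**: log-normal species-abundance distribution with log-sd
  2.5 over 600 taxa.  At the default depth of 6,996 reads per sample — a
  typical rarefaction depth for soil 16S surveys — samples then share
  their abundant taxa but differ in which rare taxa they capture
  (per-sample richness roughly 100–450 depending on regime), which is what
  gives the nearest-taxon and Raup–Crick nulls something to measure.  Real
  soil tables have thousands of OTUs; 600 is a deliberate scale-down that
  keeps 999-replicate null models within test budgets while preserving
  richness ≪ pool size.
* **Neutral regime**: every sample is one multinomial draw from the shared
  metacommunity.  This is the βNTI calibration condition (no
  phylogeny–abundance association).  Note that such samples are far more
  similar than the Raup–Crick membership-resampling null expects, so
  RC → −1 and neutral pairs classify as homogenizing dispersal — the
  coherent label for communities more homogeneous than chance.
* **Habitat filtering**: habitat optima evolve by Brownian motion on the
  tree, then are mapped rank-uniformly onto [−1, 1].  The rank map fixes
  the niche-axis scale across trees (raw Brownian optima are typically
  bimodal across the root split) while preserving the phylogenetic
  conservatism of the ordering — without conservatism a tip-shuffling null
  has no power, which is why the trait is evolved on the tree rather than
  drawn i.i.d.  Per-sample weights multiply the metacommunity by a
  Gaussian kernel around the sample's environment value; the default
  kernel sd of 0.05 admits roughly a twentieth of the niche axis (strong
  selection).  Homogeneous selection is demonstrated with a shared extreme
  environment (e.g. −0.8), which selects inside one conserved clade; a
  shared central environment sits on the boundary between the root clades,
  where the selected taxa are phylogenetically scattered and the signal is
  intrinsically weak.
* **Dispersal-limited drift**: per-sample metacommunities drawn from a
  low-concentration Dirichlet (default concentration 2 ≪ 600) around the
  shared pool; communities are dominated by different taxa, and pairs land
  in the stochastic classes.
* **Compositional counts with planted correlations**: multivariate
  log-normal basis abundances (unit log-variance) with the planted
  correlation matrix, closed to compositions, multinomially sampled.
* **Enzyme profiles**: solve x = L·cos A, y = L·sin A, fix
  ln(BG+CBH) = 2, set ln AP = ln(BG+CBH)/x and ln(NAG+LAP) = ln(BG+CBH)/y,
  split within-group sums evenly, then apply multiplicative log-normal
  noise.

Not emulated: sequencing error, chimeras, PCR/copy-number bias, spatial
autocorrelation between samples, overdispersion beyond the optional
Dirichlet-multinomial switch (off by default), and taxon-specific depth
variation (all samples share one depth).  Passing tests therefore show
that the estimators recover truth under clean compositional sampling at
realistic depth and pool structure — not that they are robust to
sequencing artefacts.

## Reproducibility

All stochastic stages take explicit seeds.  The pipeline splits its single
top-level seed into fixed per-stage substreams (`SeedSequence` spawn keys),
so enabling or disabling one stage never changes another stage's draws;
identical configurations produce byte-identical outputs.  Problem sizes in
the test and acceptance suites (600-taxon pools, 12 samples, 999 nulls for
the calibration runs; 50 samples for sparCC recovery; 1,000 simulations at
199 permutations for the PERMDISP error rate; exhaustive graph enumeration
to 6 nodes) were chosen as the smallest scales at which the statistical
claims are meaningfully exercised.

## Known limitations

* βNTI pairs with degenerate nulls (identical supports, star trees) are
  NaN rather than forced to 0; downstream fractions exclude them.
* The RC_bray pool is a plug-in estimate unless supplied; with few samples
  the resulting RC values are biased relative to the known-pool ideal.
* The RMT spacing test needs enough nonzero eigenvalue spread; very sparse
  or very small matrices (< 20 nodes) are rejected rather than guessed at.
* sparCC assumes a sparse true correlation structure; dense strong
  correlation networks violate the basis-variance approximation.
* RDA's marginal permutation test permutes raw response rows (not reduced-
  model residuals); with strongly collinear near-threshold designs the
  marginal p-values are approximate.
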