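# Methods

This note documents the models implemented in the package, the numerical
choices behind them, what the synthetic-data generators emulate, and the
known limitations.

## Sequence distances

Distances operate on a rectangular nucleotide alignment over
`A C G T - N ?`; gap and ambiguity characters are missing data and every
pairwise quantity uses **pairwise deletion** (a site counts only when both
rows carry an unambiguous base). This matches the common default of
distance software and the way the study's within-clade substitution counts
are expressed against the full 1,140-bp cyt *b* frame.

The TN93 estimator uses the transition proportions P₁ (A↔G) and P₂ (C↔T),
the transversion proportion Q, and base frequencies π pooled over the two
sequences being compared (an `freqs="alignment"` switch pools over the whole
alignment instead; the pairwise form is the distance-literature default and
the packaged default). The gamma-corrected form replaces each −ln *w* with
α(*w*^(−1/α) − 1); α → ∞ recovers the plain estimator (verified to 1e−6 in
tests). When any *w* argument is non-positive the distance is not estimable
and a saturation error carries the offending terms; corrected distances are
never below the *p* distance of the same pair. The study's shape for
distance correction is α = 1.4964 (unitless, the ML estimate for this
alignment); it is a parameter everywhere it is used.

Haplotype collapsing treats two rows as the same haplotype when they agree
at all mutually non-missing sites, assigning rows greedily to the first
compatible haplotype in input order; labels run A, B, C, … in first-seen
order. Ambiguity-only differences therefore never split a haplotype.
Group-mean distance matrices are simple arithmetic means of the between-
group pairwise entries (within-group: distinct pairs; a singleton group's
within-group mean is undefined and reported as NaN). Whether the published
clade tables used simple or net (between − within) means is not stated;
simple means are used.

## Parsimony

Fitch (unordered, equal-cost) counting with gaps/ambiguities as missing.
The consistency index is CI = (Σ per-site minimum conceivable changes)/length
with the per-site minimum = (number of observed states − 1); the retention
index uses the per-site maximum (total unambiguous rows − modal state
count). A zero-length tree reports CI = RI = 1 by convention. The heuristic
search is stepwise addition in taxon-label order keeping, at every addition
step, all placements within 1 step of the best (a min-mini-flavoured beam,
"search factor 1"), followed by NNI hill-climbing and a sweep of the
equal-length NNI neighbourhood so all co-minimal topologies found are
returned. The beam is capped at 200 partial trees (a deterministic
seed-driven subsample beyond that); like the original min-mini heuristic,
global optimality is not guaranteed, but the search matches exhaustive
enumeration over all 10,395 8-taxon topologies in the test suite.

## Likelihood

TN93 rate matrix with empirical base frequencies (ML-optimizing frequencies
is deliberately omitted — the convention of the software the study used),
normalized to mean rate 1 so branch lengths are expected substitutions per
site. Rate heterogeneity: discrete gamma with *k* equal-probability
categories and **category-mean** rates (computed from the incomplete gamma
function; verified against direct numerical integration); invariant sites
mix a rate-0 class with probability p_inv, the gamma rates rescaled by
1/(1 − p_inv) so the total mean rate stays 1. The study's ML model is
α = 0.453, p_inv = 0.52275, 5 categories. Pruning uses per-node rescaling
(log-scalers accumulated per site pattern), so valid inputs cannot
underflow to −inf; site patterns are compressed once per alignment and
cached. Ambiguous characters contribute partial likelihood 1 for every
compatible state.

Branch lengths are optimized by cyclic Brent line search on the log scale
(never accepting a worsening step; convergence when a full cycle improves
lnL by < 1e−6, capped at 20 cycles with a warning). The ML topology search
is greedy NNI from a parsimony starting tree, mirroring the protocol of
seeding likelihood searches with MP trees. Bootstrap supports resample
alignment columns and rebuild each replicate with neighbor joining on *p*
distances — chosen over corrected distances because resampled replicates of
diverged data can saturate the correction — and report the percentage of
replicates containing each split of the full-data NJ tree.

## DEC biogeography

State space: all subsets of the area set (≤ 16 areas, bitmask-feasible;
the study uses 7) or, under constraints, all non-empty subsets of the six
listed adjacent-area composites, deduplicated; the empty range is always a
state and is absorbing (global extinction; the likelihood is **not**
conditioned on survival, following the original implementation's
convention). Anagenesis: gain of area *a* at rate d·Σ_{b∈range} m[b→a],
loss at rate *e*. Epoch-stratified models tile [0, root age] with 0/1
multiplier matrices; branch transition matrices multiply per-epoch segment
exponentials oldest → youngest (Chapman–Kolmogorov consistency to 1e−10 in
tests). Per-(d, e) the epoch rate matrices are eigendecomposed once and
propagators cached per segment duration, falling back to
scaling-and-squaring `expm` when the reconstruction error exceeds 1e−10 of
the matrix scale. Cladogenesis: single-area ranges are inherited by both
daughters; a k-area range splits by subset sympatry ({a} vs full range,
both orders) or vicariance ({a} vs remainder), deduplicated ordered
scenarios with uniform weights; scenarios whose daughters fall outside a
constrained range set are dropped and the weights renormalized. Root prior:
uniform over allowed non-empty ranges.

Fitting is Nelder–Mead on (log d, log e) from (log 0.01, log 0.01), with
three jittered restarts, rates clipped to [e^−25, e^5]; rates are reported
in events · lineage⁻¹ · My⁻¹ for a chronogram in Mya. Ancestral-range
reports list, per internal node, every (range, daughter split) scenario
within 2 log-likelihood units of that node's optimum, computed from inside
(post-order) and outside (pre-order) partial likelihoods.

The packaged chronogram is an **approximation built for desk-scale runs**:
the published clade-level topology with the Ujiji divergence at 3.55 Mya,
the Hanang/Mbulu divergence at 2.36 Mya and the root at 10.5 Mya; all other
internal ages are equal subdivisions of the enclosing intervals, and tip
ranges are a plausible one-or-two-area coding of each clade (shipped as an
editable CSV, `fukomys/data/tip_ranges.csv`). On this fixture the
stratified model scores highest of the three and dispersal estimates rise
from M0 to stratified, as in the study; unlike the study, the constrained
models do not drive extinction to zero — under the shipped coding several
single-area tips can only be reached with anagenetic range loss, and
forcing e → 0 costs ~18 log-units. Conclusions about the real data should
not be read off this fixture; it exists to exercise the engine end-to-end.

The stratified dispersal matrices are encoded from the narrative
constraints of the four periods (12–8: movement only to/from SZ and SL;
8–5: no movement out of WA, none into WA from ER/MTJ, none into SL except
from SZ; 5–2: additionally none northward out of SZ/SL; 2–0: only ER→MTJ,
MTJ↔EK, WK→SZ/SL, SZ↔SL). Where the narrative is silent (e.g. self-
dispersal) entries default to 1; the JSON config is editable.

## Morphometrics

GPA: center, scale to unit centroid size, rotate to the running consensus
(SVD with determinant correction — reflections excluded, because skull
photographs share an orientation), consensus re-normalized each iteration,
convergence at RMS change < 1e−8. Relative warps are the PCA of aligned
coordinates about their mean (α = 0, i.e. no bending-energy weighting — the
default of the ordination software named in the study; the weighted variant
is out of scope). Axis signs are fixed by making each axis's largest-
magnitude loading positive. Replicates are averaged **after** alignment and
re-normalized, then ordinated once; in the small-noise regime this is
numerically indistinguishable from averaging per-replicate scores (checked
to 2e−3). Thin-plate splines solve the standard bordered system with kernel
U(r) = r² log r²; bending energy is Σ_dim wᵀKw, zero exactly on affine maps;
collinear references are rejected. Missing landmarks are not supported; a
record with a landmark-count mismatch is rejected with a message.

## Specimen statistics

SEM uses the n−1 sample standard deviation. The sexual-dimorphism test is
Student's pooled two-sample t (df = n₁+n₂−2, two-sided); tentative sexes
(M?, F?) count with their base sex, breeding females (BrF) as female,
unknown (na) excluded — this reproduces the published n = 19 males /
10 females. "Adult" means: for the Hanang/Mbulu species, any animal whose
known age class is not 1 (unknown retained); for the Ujiji species, known
age class ≥ 2 — each as defined where the respective summary is quoted.
Pillai's trace is computed from the between/within cross-product matrices
with the standard F approximation (s = min(p, g−1)); with one response it
reduces exactly to one-way ANOVA, and the multivariate case is cross-
checked against statsmodels' MANOVA at 1e−10. The Bonferroni multiplier
defaults to the number of measurements tested (23 of the 24 craniometric
variables; M5 was never recorded) and is configurable.

## Synthetic data

Generators are seeded (`numpy.random.Generator` per call; identical
arguments ⇒ bit-identical output) and their outputs satisfy the consuming
module's input contracts.

- `sim_tree`: constant-rate pure-birth (Yule) process, rescaled so the
  first split sits at the requested root age — matching the tree prior
  class of the study's dating analysis, though not its relaxed clock.
- `sim_sequences`: evolves sites down the tree under TN93(+G+I), site rates
  drawn once from the discrete mixture. The estimator-consistency study
  uses 64 categories as a near-continuous gamma, because the distance
  estimator assumes continuous rates.
- `sim_dec_history`: forward Gillespie simulation of the DEC process with
  epoch switching; cladogenetic splits drawn from the model's scenario
  weights. By default replicates with a globally extinct lineage are
  redrawn (conditioning on all tips surviving); `keep_extinct=True` keeps
  them with empty tip ranges.
- `sim_landmarks`: mean shape + per-group displacement + isotropic noise,
  with optional replicate "photographs" (one third of the specimen noise).
  Planted displacements used in calibration are projected into the shape
  tangent space (net translation, scale and rotation components removed),
  since superimposition removes those components by construction.
- `sim_specimens`: normal body weights per group, floored at 1 g.

What passing these suites shows — and does not. The generators draw from
the implemented models themselves, so the calibration studies demonstrate
internal consistency (estimator consistency, parameter recovery, planted-
effect recovery), not robustness to model violation: real cyt *b* has
codon structure and saturation, real skulls have correlated landmark noise
and allometry, and real range histories need not follow DEC.

## Study conditions and problem sizes

- Distance-estimator consistency: 2 × 100 kb sequences, true path length
  2t = 0.1 (the order of the inter-species divergences), α = 1.4964,
  50 replicates; the mean estimate is required within 2 Monte-Carlo SEs.
- DEC recovery: 20 replicates of a 100-tip Yule chronogram (root 10 My),
  d = 0.03, e = 0.005 on 4 unconstrained areas (16 states — a desk-scale
  state space that keeps each ML fit to ~2 s); the median d̂ must fall
  within a factor of 2 of truth.
- Landmark recovery: 15 landmarks, 2 × 15 specimens, tangent-space planted
  displacement ≈ 0.2 Procrustes units, noise SD 0.02; recovery within 5 %.
- Analysis drivers simulate 1,140-bp alignments (the cyt *b* length) on
  8–12 taxon trees.

## Limitations

- The min-mini-style parsimony search and the NNI likelihood search are
  heuristics; neither guarantees the global optimum on hard instances.
- The published sequence statistics (site classes 674/325/141, tree length
  883, CI 0.466, the distance tables, lnL −5146.172) require the public
  GenBank alignment as input; it is not packaged. Model selection among
  substitution models, the molecular-clock test and Bayesian dating are out
  of scope — chronograms are consumed, not estimated.
- Lagrange-convention choices (unconditioned likelihood, uniform root
  prior, renormalized constrained cladogenesis) are fixed defaults;
  alternatives exist in the literature and would shift absolute lnL values.
- MANOVA requires complete cases; bootstrap supports are NJ-based rather
  than full ML per replicate.
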