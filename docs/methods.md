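# Methods

## The problem and the model

Wild populations of a candidate aquaculture species differ genetically in
key traits for aquaculture (KTA): larval survival, specific growth rate,
swim-bladder inflation, deformity rate, and behaviour (activity,
inter-individual distance, aggressiveness). Common-garden bioassays expose
those genetic differences but are too costly to run for every pair of
populations. `popproxy` evaluates whether cheap pairwise *proxy* distances —
genetic (Φ<sub>ST</sub>), habitat, geographic, hydrologic — predict pairwise
trait divergence, and turns multi-proxy distance sums into a shortlist of
population pairs worth assaying.

All quantities are pairwise, so the whole analysis lives on distance
matrices. A trait measured in T tanks per population gives an
(nT × nT) replicate-level Euclidean distance matrix; proxies are
population-level (n × n) and are expanded block-wise to replicate level
(within-population blocks zero) before regression.

## Trait metrics

Per tank: survival = Nf·100/(Ni − Ns); swim-bladder inflation = 100·SB⁺/Nf;
deformity = 100·Nm/Nf; aggressiveness = (Ne + Nt)/Nd (a proportion, not a
percent); SGR = 100·(ln L̄f − ln L̄i)/ΔT using tank-mean lengths; growth
heterogeneity = CV(Lf)/CV(Li) with the sample (n−1) standard-deviation
convention. Behavioural metrics come from arena images: inter-individual
distance is the per-image mean of each individual's mean distance to the
others, averaged over images (no identity tracking needed); activity is the
mean per-second displacement over 6-image 1-s series (identity within a
series required). Arena images with a wrong individual count are dropped
with a warning rather than failing the replicate; behavioural replicates are
aggregated to tank means before distance construction.

## Differentiation screen

Traits showing no significant inter-population differentiation carry no
pairwise signal and are excluded. Per trait: Shapiro–Wilk on residuals and
Levene (mean-centred) across populations; on failure, natural-log transform
and retest; if assumptions still fail (or values are non-positive),
Kruskal–Wallis, otherwise one-way ANOVA; retain when p < α = 0.05. The
tank-as-random-effect model comparison is deliberately not implemented: the
screen operates on tank-level replicate values with fixed-effect tests only.
Whether a log transform is natural or base-10 does not matter for the
rank-based fallback and barely matters for the threshold decision; natural
log is used.

## Distance builders

* **Trait**: d(i,j) = |x_i − x_j| per scalar trait at replicate level.
* **Habitat**: variables z-scored (so each has unit variance); principal
  axes from the covariance eigendecomposition; axes retained while their
  eigenvalue exceeds the mean eigenvalue (Kaiser–Guttman; for a correlation
  matrix this is "eigenvalue > 1"); Bray–Curtis Σ|x−y|/Σ(x+y) on the
  retained scores. Bray–Curtis is ill-defined for negative coordinates, so
  the default mode shifts each retained axis to a zero minimum, keeping the
  distance in [0, 1]; a "raw" mode applies the formula to signed scores for
  sensitivity checks. Replicates inherit their site's scores, so
  within-population distances are exactly zero.
* **Geographic**: Vincenty's inverse iteration on the WGS84 ellipsoid
  (tolerance 1e-12 rad, ≤200 iterations), in km. Nearly-antipodal
  non-convergence falls back to the spherical great circle on the mean
  radius with a logged warning — irrelevant at continental scale.
* **Hydrologic**: the raster is a conductance graph — one node per cell,
  4-neighbour edges with conductance the arithmetic mean of the two cell
  conductances (an 8-neighbour variant was considered and rejected to keep
  the river a 1-cell-wide channel meaningful). Effective resistance between
  site cells comes from the eigendecomposition-based pseudoinverse of the
  graph Laplacian (the SVD route is numerically unreliable on these
  Laplacians; the Hermitian path reconstructs L to ~1e-14). Disconnected
  site sets raise an error naming the components. River cells conduct
  1 + k with k = 100 by default; ranks of the resulting distances are
  essentially invariant over k ∈ {10, 100, 1000}.
* **Genetic**: pairwise Φ<sub>ST</sub> by two-level AMOVA on haplotype
  pairwise-difference counts (used as squared molecular distances):
  SSD within/among → variance components σ²_w, σ²_a →
  Φ<sub>ST</sub> = σ²_a/(σ²_a + σ²_w). Zero total variance gives 0 by
  convention. Finite-sample estimates can be slightly negative; the matrix
  clamps them to 0 (raw values available via `pairwise_phi_st`). Gaps count
  as a fifth character state; repeat-array mutations are assumed
  pre-collapsed to single sites in the input alignment.

## MRDM, commonality analysis, suppressors

Matrices are unfolded to strict-lower-triangle vectors (row-major);
predictors are z-scored. OLS gives R², per-proxy simple correlation r and
standardised weight β. Inference permutes the *units* of the response matrix
(joint row/column relabelling) before re-unfolding — element-wise shuffling
would destroy the dependence structure of distances — with the add-one
estimator p = (1 + #{R²_perm ≥ R²}) / (1 + n_perm), 1000 permutations by
default.

Commonality analysis computes R² for every predictor subset and the
2^p − 1 commonality coefficients by inclusion–exclusion,
C(S) = −Σ_{T⊆S} (−1)^{|T|} R²((P∖S) ∪ T); they sum to the full-model R²
exactly (asserted to 1e-10). U_i is the singleton coefficient, C_i the sum
over subsets of size ≥ 2 containing i.

A proxy is a *total suppressor* when its unique contribution is
counter-balanced by a negative common contribution (classical: C_i < 0 and
U_i + C_i ≤ tol, tol = 1e-9) or when β and r disagree in sign with both
clearly non-zero (cross-over). All flagged proxies are removed each round
and the model refitted until a round flags nothing or one predictor remains
(termination within p rounds is guaranteed). Significance of a proxy:
final-model permutation p below α after Benjamini–Hochberg adjustment
*across the trait models of a run*, and U > 0.05. BH across the trait family
(rather than per-trait) was chosen as the stricter reading of a single
corrected decision per run.

Mantel tests (9999 permutations, one-sided, same unit-permutation null)
provide the one-proxy-at-a-time view alongside the joint model.

## Prioritisation

Each matrix is standardised by (x − min)/(max − min) over *off-diagonal*
entries (the structural zero diagonal would otherwise pin the minimum);
standardisation happens at the native replicate level first, then distances
are averaged over all cross-population replicate pairs to one value per
population pair (the reverse order is available as a flag). Per-pair values
are summed across proxies, and separately across traits. The sums are
clustered by 1-D k-means: Lloyd's algorithm with 50 seeded restarts,
verified against (and, for the returned labels, replaced by) the exact
dynamic-programming optimum, which exists because optimal 1-D clusters are
contiguous in sorted order — this removes all stochastic flakiness. k is
chosen by the Elbow rule operationalised as the k maximising the
perpendicular distance from (k, WSS(k)) to the chord joining (1, WSS(1)) and
(k_max, WSS(k_max)), on the exact WSS curve (monotone by nesting). Clusters
are lettered A, B, C… by strictly descending mean sum (ties broken by
descending maximum, logged); trait-side clusters are numbered 1, 2, 3… the
same way.

## Synthetic studies

The generator emulates a 7-population × 3-tank common-garden design with
controllable proxy–trait coupling and one RNG substream per component
(sites, environment, sequences, raster, traits, census), all derived from
one master seed — the same seed reproduces the study byte for byte, and
adding a component never perturbs the others.

* **Sites** sit on a common meridian with irregular latitudinal spacing
  (45–62°N). A meridian is a single geodesic, so geographic distances are
  exactly 1-D Euclidean-embeddable; the first principal coordinate then
  recovers the configuration exactly, which is what makes noiseless
  coupling to the geographic proxy achieve Mantel r = 1 rather than
  approximately 1.
* **Coupling**: a coupled trait's population value is
  weight × (z-scored first classical-MDS axis of the proxy matrix); each
  tank adds Normal(0, noise_sd). Uncoupled traits are pure noise (the
  weight-0 case). An affine per-trait display scale maps values to
  realistic units (e.g. survival ≈ 50 ± 10%) without touching any
  correlation. Default noise_sd = 0.3; the parameter-recovery simulations
  use 0.1 ("low tank noise": one tenth of the between-population scale) and
  couple to the genetic proxy.
* **Haplotypes**: a star model — per-population private mutation counts
  fitted to the requested pairwise divergence steps by non-negative least
  squares — plus at most one extra private mutation per individual
  (probability `within_variation`, default 0.5), so within-population
  haplotypes are identical or one step apart. Default per-population counts
  (i·3 mod n) are deliberately spread and decoupled from the latitudinal
  order, and sized so pairwise Φ<sub>ST</sub> spans a wide range rather
  than saturating near 1. No coalescent or demographic realism is intended.
* **Raster**: background conductance 1; an axis-aligned river polyline
  visits every site cell in latitudinal order with conductance 1 + k.
  Because the river follows the transect, hydrologic and geographic
  distances are strongly collinear — deliberately so, as this reproduces
  the suppressor/commonality dynamics the inference stage exists to handle.
* **Census**: per-tank integer counts derived from the trait table where
  rate traits are present, otherwise drawn within their invariant bounds.

What passing tests on synthetic data do *not* show: real environmental
tables have spatially autocorrelated, non-Gaussian variables; real mtDNA
genealogies are not star-shaped; real river networks branch. The synthetic
study validates the machinery and its statistical calibration, not
field-data effect sizes.

## Numerical choices and degenerate inputs

* Permutation p-values use the add-one convention (never zero).
* Distance-matrix symmetry/diagonal round-off is cleaned at 1e-9 tolerance;
  anything worse is rejected.
* All-identical ANOVA input is a 0/0 error; zero within-group variance with
  distinct means returns the +inf sentinel with p = 0. Constant traits fall
  through Kruskal–Wallis with H = 0, p = 1.
* Min–max standardisation rejects matrices with constant off-diagonal.
* k-means rejects k above the number of distinct values; the Elbow rule
  lowers k_max with a warning when distinct values run out.
* Problem sizes in the test and acceptance simulations (e.g. 300–500
  calibration runs of 200 permutations; 60–100 recovery seeds at 199
  permutations) are chosen to estimate rates and KS statistics to the
  precision the assertions need.

## Known limitations

* The linear-mixed-model tank-effect path and post-hoc letter displays are
  out of scope; the screen is fixed-effects only.
* Yolk-sac volume is consumed as a pre-computed column if present, never
  computed.
* Vincenty's fallback for antipodal pairs is spherical, not a convergent
  ellipsoidal algorithm; no study-scale pair comes near that regime.
* Commonality analysis enumerates 2^p subsets and is capped at p = 10.
* The Φ<sub>ST</sub> estimator treats the concatenated alignment per-site;
  alternative weightings of multi-region concatenations are not offered.
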