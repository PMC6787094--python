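# Methods

`consdyn` implements an analysis chain for characterising how loss of
consciousness changes the brain's functional integration and diversity, as
measured with resting-state fMRI. The chain runs from denoised regional
BOLD timeseries through static and dynamic functional connectivity (FC),
decomposition of the dynamic FC into integrated and segregated states,
state-specific graph and entropy metrics, and group statistics that isolate
connectivity changes common to two independent routes into unconsciousness
(anaesthesia and brain injury). Because no clinical data ship with the
package, a first-class synthetic-data module generates cohorts with planted
effects so every stage can be validated against known ground truth.

## Preprocessing model

Regional timeseries are assumed to be motion-corrected and spatially
normalised upstream; the package performs only the purely computational
denoising steps, in this order:

1. **Despiking** (optional): `x -> c * tanh(x / c)` around the series
   median, with `c` = 4 x the median absolute deviation. The squashing
   scale is not standardised in the field; the MAD rule is scale-free and
   leaves typical fluctuations (|x| ≲ c) essentially untouched.
2. **Nuisance regression**: one joint OLS removing an intercept, a linear
   trend, and any confound columns (motion parameters, aCompCor
   principal-component noise timecourses from `extract_noise_components`).
   Doing detrending and confound regression jointly avoids the classic
   pitfall of a later step reintroducing variance removed by an earlier
   one.
3. **Band-pass**: zero-phase (forward-backward) 4th-order Butterworth,
   default 0.008-0.09 Hz — the standard resting-state band. Zero-phase
   filtering preserves series length and timing. After filtering, residual
   mean/trend are projected out once more, so outputs are numerically
   trend-free.

Denoising is *approximately* idempotent: the regression steps are exact
projections, but re-applying the Butterworth filter attenuates content near
the band edges again (measured ~2% RMS change on mid-band signals; the
suite asserts < 5%). Exact idempotence would require an ideal brick-wall
filter, which rings badly on finite series.

## Voxelwise maps

**Sample entropy** SampEn(m, r) = −log(A/B), where B counts unordered
pairs of length-m templates whose Chebyshev distance is within
r = `r_factor` x SD, and A counts the same at length m+1. Defaults
m=3, r_factor=0.6 (the values reported optimal for BOLD data). Two
conventions matter and are configurable:

- *Tolerance*: the closed inequality (distance ≤ r) is the default, which
  makes a constant series score exactly 0 (A = B); a strict inequality
  would leave it undefined.
- *Template sets*: both lengths use start indices 0..T−m−1 (the final
  length-m template is dropped), the standard alignment that guarantees
  A ≤ B and hence SampEn ≥ 0.
- *SD*: population (divide-by-T) convention.

**Intrinsic connectivity contrast** ICC(i) = Σ_{j≠i} r(t_i, t_j)², a
degree-like measure of each voxel's whole-brain coupling. Raw maps are
z-scored over the mask (mean 0, SD 1; a zero-variance map maps to zeros).
Smoothing uses a mask-aware Gaussian (σ = FWHM/2√(2 ln 2); the smoothed map
is divided by the smoothed mask so edge voxels are not dimmed). Overlap
analysis binarises each map at its threshold (value ≥ threshold) and
intersects.

## Connectivity

Static FC is the Pearson correlation over the full scan. Dynamic FC slides
a tapered window in 1-TR steps: the taper is a 22-TR rectangle convolved
with a σ=3 TR Gaussian. The Gaussian is sampled at half-integer offsets
(an even-length symmetric kernel); convolving it with the even-length
rectangle yields an odd-length symmetric curve that is cropped centrally to
**23 taps** and renormalised. The 23-tap effective length is the binding
contract — it reproduces the canonical window counts (229 windows from 251
volumes; 273 from 295). A degenerate σ→0 Gaussian returns the bare 22-tap
rectangle (documented special case). Window correlations are *weighted*
Pearson correlations with the taper as observation weights, preserving the
correlation scale.

## Graph analysis

FC matrices are proportionally thresholded: the top `density` fraction of
edges ranked by **signed** weight is retained (anticorrelations drop out
first), ties broken lexicographically by (i, j). Default density grid
{0.10, 0.15, 0.20, 0.25}, with {0.30, 0.40, 0.50} and a binarised variant
as robustness settings; metrics are averaged across the grid.

**Signed modularity.** Q rewards positive within-module weight at full
strength and penalises negative within-module weight at reduced strength
(the asymmetric signed objective):

    Q = (1/v+) Σ_ij (w+_ij − e+_ij) δ_ij − (1/(v+ + v−)) Σ_ij (w−_ij − e−_ij) δ_ij

with chance terms e±_ij = s±_i s±_j / v± (strength-product null). The
Louvain maximisation (greedy node moves + aggregation on the generalised
modularity matrix) is authored in this package and run `n_repeats` times
(default 100) with distinct RNG streams; the best-Q partition wins, ties to
the earliest repeat, and Q is recomputed directly from the returned
assignment as a self-check.

**Cartography.** Participation coefficient P_i = 1 − Σ_s (κ_is/k_i)² and
within-module z-score z_i = (κ_is − mean)/SD use positive weights only.
Conventions for degenerate cases: k_i = 0 gives P_i = 0; a module with zero
strength variance (including singletons) gives z_i = 0.

**Path length and clustering.** Edge lengths are 1/weight; characteristic
path length averages shortest paths over reachable pairs (unreachable pairs
are excluded and counted). Weighted clustering scales weights by the
maximum and uses the geometric-mean triangle intensity,
C_i = 2 t_i / (k_i (k_i − 1)) with binary degree k_i; C_i = 0 for k_i < 2.

**Null models and small-worldness.** Nulls are degree-preserving
double-edge swaps (default 100 attempted swaps per edge) with weights
travelling with edges, so the degree sequence and the weight multiset are
exactly preserved. S = (C/C_rand)/(L/L_rand) with C_rand, L_rand averaged
over `n_nulls` (default 100) rewired graphs, then averaged across the
density grid. S ≈ 1 for random graphs, > 1 for small-world graphs.

## Brain states

Each window matrix is profiled by its joint histogram of (P_i, z_i) over
nodes — 10x10 bins, P ∈ [0,1], z ∈ [−5,5] with clipping (the histogram
geometry is configurable; the fixed grid gives a fixed-length feature
comparable across windows). Windows are clustered per subject and
condition with k-means, k=2, correlation distance (1 − Pearson r between
histogram rows), mean centroid update, 500 random restarts, best total
within-cluster distance; an emptied cluster is reseeded at the worst-fit
point, and an input whose rows are all identical is rejected rather than
split arbitrarily. The cluster with the higher mean participation
coefficient is the **integrated** state. Per-state centroids are
elementwise medians of the member windows; occupancy is the member count
over the window count.

## Connectivity entropy

Each node's N−1 off-diagonal FC values are binned into n=10 equal-width
bins over the fixed range [−1, 1] (fixed edges make entropies comparable
across subjects and states; a per-node min-max range is available as a
config alternative), and H = −Σ p log p / log n ∈ [0, 1]. Values are
summarised globally and per resting-state network (7-network scheme).

## Group statistics

Two-sided permutation t-tests, default 10,000 permutations: sign-flipping
of within-subject differences (paired) or label shuffling around a
pooled-variance t (unpaired). Monte-Carlo p-values use the add-one
convention (1+b)/(n+1); when all distinct permutations fit in the budget
the test switches to exhaustive enumeration and p is exact. Effect sizes
are Hedges' g (bias-corrected; paired form standardises by the SD of
differences). Multiplicity is controlled with Benjamini-Hochberg FDR at
α=0.05 (delegated to statsmodels).

Edgewise contrasts compute per-edge mean differences, permutation p-values
vectorised across all N(N−1)/2 edges, FDR across edges, and zero
non-surviving edges. Two thresholded contrast matrices (one per dataset)
are combined into a **common-difference matrix**: both positive → minimum;
both negative → maximum (smaller magnitude); otherwise 0. A nonzero entry
marks a consistent, conservatively-sized alteration across both routes
into unconsciousness.

Voxel-map group comparisons reuse the permutation test per voxel plus
BH-FDR. This is a deliberate method variant: the original voxelwise
approach in the field is a parametric GLM with cluster-extent FWE
correction, which requires spatial smoothness estimation outside this
package's scope; results from the two approaches agree on strong effects
but are not interchangeable near threshold.

## Synthetic cohorts

`CohortSpec` defaults encode the emulated study design: 16 subjects
scanned awake and deeply sedated (paired, T=251, TR=2 s) and 22 patients
(unpaired, T=295) compared with the 16 awake scans. Signals are
block-covariance Gaussians over 90 regions in 5 equal modules
(within-module correlation 0.5), switching between an integrated regime
(between-module correlation 0.35) and a segregated regime (0.05) via a
symmetric two-state Markov chain (switch probability 0.02/TR), then mixed
with an AR(1) filter. Unconscious conditions get the between-module
coupling of the integrated regime reduced by 0.15 and a higher AR(1)
coefficient (0.6 vs 0.3; chosen once as a realistic autocorrelation
contrast that plants lower sample entropy in the unconscious cohort).
Regime switches are aligned to TRs, so windows spanning a switch have no
pure true label.

What the generator does *not* emulate: haemodynamic convolution,
physiological noise spectra, spatial autocorrelation within regions,
scanner drift, motion artefacts, or lesion-induced covariance
heterogeneity. Passing tests therefore demonstrate the correctness and
statistical calibration of the analysis chain under its own model
assumptions, not performance on real clinical data.

### Known limitation: cartographic state recovery

On these synthetic cohorts the planted regime labels are fully linearly
separable from the cartographic histograms (a supervised readout reaches
100% on switch-free windows, as does k-means applied directly to window FC
edge vectors), but the unsupervised correlation-distance k-means on the
joint P/z histograms recovers them at only ~75-85%: the dominant variance
direction in histogram space tracks fluctuation in the number of Louvain
modules rather than the integration regime, and the clustering objective
prefers that split. This is an intrinsic property of the
histogram-feature channel at 23-tap window resolution, robust to the
Louvain repeat count, k-means restarts, centroid-update convention, and
histogram bin geometry. Downstream conclusions are less affected than the
label error suggests — state centroids are medians over many windows, and
planted edgewise effects are recovered with ~97% sensitivity (see the
acceptance suite).

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; identical inputs and seeds give identical
outputs, including the Louvain and k-means restarts. The test suite runs
scaled-down problem sizes as the package's own verification profile:
Louvain repeats 3-20 and k-means restarts 10-50 in end-to-end tests
(defaults remain 100/500), rewiring nulls at 5-100, and reduced cohort
sizes for null-calibration replicates; the planted-effect sensitivity
check runs the full default cohort (16 paired subjects, 90 regions).
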