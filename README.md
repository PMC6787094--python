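# consdyn

Dynamic functional connectivity and brain-state analysis for studying loss
of consciousness in resting-state fMRI.

## What this package is for

When consciousness is lost — under deep anaesthesia or after severe brain
injury — the brain's capacity to *integrate* information across regions
and the *diversity* of its activity both change. `consdyn` implements a
complete, tested analysis chain for quantifying these changes from
regional BOLD timeseries:

- **Voxel/series metrics**: sample entropy SampEn(m, r) = −log(A/B) of
  BOLD signals (signal unpredictability) and the intrinsic connectivity
  contrast ICC(i) = Σ_{j≠i} r² (whole-brain coupling of each voxel), with
  map normalisation, smoothing and multi-map overlap.
- **Connectivity**: static Pearson FC, and dynamic FC from tapered sliding
  windows (22-TR rectangle ∗ 3-TR Gaussian, 23 effective taps, 1-TR step:
  229 windows from 251 volumes, 273 from 295).
- **Brain states**: per-window signed Louvain modularity
  (Q with the asymmetric positive/negative objective and strength-product
  chance terms), node cartography (participation coefficient P_i,
  within-module z-score z_i), joint P/z histograms, and k-means (k = 2,
  correlation distance, 500 restarts) splitting windows into an
  **integrated** and a **segregated** state with median centroid matrices
  and occupancy fractions.
- **Graph metrics**: proportional thresholding, weighted characteristic
  path length L and clustering C, degree-preserving rewiring nulls, and
  small-worldness S = (C/C_rand)/(L/L_rand) averaged over a density grid.
- **Connectivity entropy**: per-node normalised Shannon entropy
  H = −Σ p log p / log 10 of binned FC values, globally and per
  resting-state network.
- **Group statistics**: two-sided permutation t-tests (sign-flip paired /
  label-shuffle unpaired, exhaustive when feasible), Hedges' g,
  Benjamini–Hochberg FDR, edgewise contrasts, and the cross-dataset
  **common-difference matrix** (both positive → min, both negative → max,
  else 0) that isolates connectivity changes shared by different routes
  into unconsciousness.
- **Synthetic data**: regime-switching modular Gaussian cohorts with
  planted effects on integration, edge weights and entropy, so every stage
  is validated against ground truth. See `docs/methods.md` for the model
  and its limitations.

## Worked example

```python
import numpy as np
from consdyn import (CohortSpec, simulate_state_sequence, simulate_subject_timeseries,
                     dynamic_fc, static_fc, small_worldness, connectivity_entropy_nodes)
from consdyn.state_dynamics import derive_states

spec = CohortSpec(n_regions=30, n_modules=5, seed=0)
rng = np.random.default_rng(0)
seq = simulate_state_sequence(251, spec.switch_prob, rng)
ts = simulate_subject_timeseries(spec, seq, rng)

fc = static_fc(ts)
dfc = dynamic_fc(ts)                         # tapered sliding windows
states = derive_states(dfc, louvain_repeats=10, kmeans_restarts=100, seed=1)
ent = connectivity_entropy_nodes(fc)
sw = small_worldness(fc, densities=[0.10, 0.15, 0.20, 0.25],
                     n_nulls=20, swaps_per_edge=20, seed=2)

print(f"windows: {dfc.n_windows}")
print(f"fraction of time integrated: {states.fraction_integrated:.3f}")
print(f"mean connectivity entropy (static FC): {ent.global_mean:.3f}")
print(f"small-worldness S: {sw.s_value:.3f}")
```

Output:

```
windows: 229
fraction of time integrated: 0.563
mean connectivity entropy (static FC): 0.399
small-worldness S: 10.029
```

The 251-volume scan yields 229 sliding windows. This subject spends 56%
of windows in the integrated state; its between-module coupling is higher
in the integrated-state centroid than in the segregated one (0.186 vs
0.119 here), as planted by the generator. The mean connectivity entropy
of 0.40 says each region's connection profile occupies a moderate spread
of the [−1, 1] correlation range, and S ≫ 1 reflects the strong
clustering of the planted modular network relative to degree-matched
rewired nulls.

The same chain is exposed on the command line:

```bash
consdyn simulate --seed 0 --regions 30 --out cohort/
consdyn fc cohort/subA00_awake.tsv --tr 2.0 --out fc.tsv
consdyn run --seed 0 --scale 0.3 --out report/
```

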