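"""Synthetic cohorts and phantoms with planted ground truth.

The generator emulates the study design the pipeline targets: a paired
cohort of 16 subjects scanned awake and deeply sedated (T=251 retained
volumes, TR=2 s) and an unpaired cohort of 22 patients (T=295) compared
against the 16 awake scans.  Regional BOLD-like signals are drawn from a
modular block-covariance Gaussian that switches between two regimes — an
integrated regime with elevated between-module coupling and a segregated
regime where coupling is mostly within modules — and are temporally mixed
with an AR(1) filter.  Unconscious conditions get (a) a reduced
between-module coupling in the integrated regime (planting lower
integration) and (b) a higher AR(1) coefficient (planting lower sample
entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import RoiTimeseries, VolumeSeries

INTEGRATED = "integrated"
SEGREGATED = "segregated"


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the emulated study conditions."""

    n_subjects_a: int = 16
    n_subjects_b: int = 22
    n_regions: int = 90
    n_timepoints: dict = field(
        default_factory=lambda: {"awake": 251, "deep": 251, "patient": 295}
    )
    tr_seconds: float = 2.0
    n_modules: int = 5
    within_r: float = 0.5
    between_r_integrated: float = 0.35
    between_r_segregated: float = 0.05
    ar_conscious: float = 0.3
    ar_unconscious: float = 0.6
    switch_prob: float = 0.02
    effect_integration: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.switch_prob < 1:
            raise ValueError("switch_prob must be in (0, 1)")
        for name in ("within_r", "between_r_integrated", "between_r_segregated"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise ValueError(f"{name} must be a correlation in (-1, 1)")

    def module_assignment(self) -> np.ndarray:
        """Region -> module (1..n_modules), contiguous equal-size blocks."""
        return (np.arange(self.n_regions) * self.n_modules // self.n_regions) + 1


@dataclass
class GroundTruth:
    regime_labels: dict  # (cohort, subject, condition) -> list of per-TR labels
    planted_effects: dict
    module_assignment: np.ndarray


def _block_covariance(spec: CohortSpec, between_r: float) -> np.ndarray:
    modules = spec.module_assignment()
    same = modules[:, None] == modules[None, :]
    cov = np.where(same, spec.within_r, between_r)
    np.fill_diagonal(cov, 1.0)
    eig_min = np.linalg.eigvalsh(cov).min()
    if eig_min < -1e-10:
        raise ValueError(
            f"non-PSD block covariance (min eigenvalue {eig_min:.3g}) for "
            f"within_r={spec.within_r}, between_r={between_r}"
        )
    return cov


def simulate_state_sequence(t: int, switch_prob: float, seed) -> list[str]:
    """Two-state symmetric Markov chain over TRs, uniform start."""
    if not 0 < switch_prob < 1:
        raise ValueError("switch_prob must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = (INTEGRATED, SEGREGATED)
    cur = int(rng.integers(0, 2))
    out = []
    flips = rng.random(t) < switch_prob
    for i in range(t):
        if i > 0 and flips[i]:
            cur = 1 - cur
        out.append(states[cur])
    return out


def simulate_subject_timeseries(
    spec: CohortSpec,
    regime_seq: list[str],
    subject_seed,
    between_r_integrated: float | None = None,
    ar_coefficient: float | None = None,
    subject_id: str = "",
    condition: str = "",
) -> RoiTimeseries:
    """Regime-switching modular Gaussian series with AR(1) temporal mixing.

    Innovations at each TR are drawn from the active regime's block
    covariance; x_t = phi * x_{t-1} + sqrt(1 - phi^2) * z_t keeps unit
    marginal variance.  Output is standardised per region.
    """
    rng = (
        subject_seed
        if isinstance(subject_seed, np.random.Generator)
        else np.random.default_rng(subject_seed)
    )
    b_int = spec.between_r_integrated if between_r_integrated is None else between_r_integrated
    phi = spec.ar_conscious if ar_coefficient is None else ar_coefficient
    chol = {
        INTEGRATED: np.linalg.cholesky(_block_covariance(spec, b_int)),
        SEGREGATED: np.linalg.cholesky(_block_covariance(spec, spec.between_r_segregated)),
    }
    t = len(regime_seq)
    n = spec.n_regions
    z = rng.standard_normal((t, n))
    x = np.zeros((t, n))
    innov_scale = np.sqrt(1.0 - phi**2)
    for i, regime in enumerate(regime_seq):
        innov = chol[regime] @ z[i]
        x[i] = innov if i == 0 else phi * x[i - 1] + innov_scale * innov
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return RoiTimeseries(
        data=x,
        tr_seconds=spec.tr_seconds,
        region_ids=[f"roi{i:03d}" for i in range(n)],
        subject_id=subject_id,
        condition=condition,
    )


def simulate_cohorts(spec: CohortSpec):
    """Paired awake/deep cohort, patient cohort, and the planted truth.

    Returns ``(cohort_a, cohort_b, truth)`` where ``cohort_a`` maps subject
    index -> {"awake": RoiTimeseries, "deep": RoiTimeseries} and
    ``cohort_b`` maps subject index -> RoiTimeseries (patients).
    """
    rng = np.random.default_rng(spec.seed)
    b_int_low = spec.between_r_integrated - spec.effect_integration
    regime_labels = {}
    cohort_a = {}
    for s in range(spec.n_subjects_a):
        cohort_a[s] = {}
        for cond, b_int, phi in (
            ("awake", spec.between_r_integrated, spec.ar_conscious),
            ("deep", b_int_low, spec.ar_unconscious),
        ):
            seq = simulate_state_sequence(spec.n_timepoints[cond], spec.switch_prob, rng)
            cohort_a[s][cond] = simulate_subject_timeseries(
                spec, seq, rng, between_r_integrated=b_int, ar_coefficient=phi,
                subject_id=f"A{s:02d}", condition=cond,
            )
            regime_labels[("A", s, cond)] = seq
    cohort_b = {}
    for s in range(spec.n_subjects_b):
        seq = simulate_state_sequence(spec.n_timepoints["patient"], spec.switch_prob, rng)
        cohort_b[s] = simulate_subject_timeseries(
            spec, seq, rng, between_r_integrated=b_int_low,
            ar_coefficient=spec.ar_unconscious,
            subject_id=f"B{s:02d}", condition="patient",
        )
        regime_labels[("B", s, "patient")] = seq
    truth = GroundTruth(
        regime_labels=regime_labels,
        planted_effects={
            "between_module_fc_integrated": ("conscious > unconscious", spec.effect_integration),
            "sample_entropy": ("conscious > unconscious", spec.ar_unconscious - spec.ar_conscious),
        },
        module_assignment=spec.module_assignment(),
    )
    return cohort_a, cohort_b, truth


def simulate_voxel_phantom(
    grid: tuple[int, int, int],
    hub_mask: np.ndarray,
    t: int,
    hub_coupling: float,
    seed: int = 0,
    tr_seconds: float = 2.0,
) -> VolumeSeries:
    """Noise phantom with an optional strongly-coupled hub region.

    Every voxel gets i.i.d. noise plus a weak shared signal; voxels inside
    ``hub_mask`` additionally share a strong component scaled by
    ``hub_coupling``, giving them elevated whole-brain connectivity (ICC).
    """
    hub_mask = np.asarray(hub_mask, dtype=bool)
    if hub_mask.shape != tuple(grid):
        raise ValueError("hub mask shape does not match grid")
    if not hub_mask.any():
        raise ValueError("empty hub region")
    rng = np.random.default_rng(seed)
    weak = rng.standard_normal(t)
    strong = rng.standard_normal(t)
    data = rng.standard_normal((*grid, t)) + 0.2 * weak
    data[hub_mask] += hub_coupling * strong
    mask = np.ones(grid, dtype=bool)
    return VolumeSeries(data=data, mask=mask, tr_seconds=tr_seconds)
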