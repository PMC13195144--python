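"""Synthetic whole-body phantom cohorts.

Generates seeded subjects with the statistical and spatial structure the
downstream pipeline assumes: per-organ heavy-tailed SUV distributions with
inter-subject variability, spatially contiguous box organs on a shared
voxel lattice (the two heart ventricles share a face so segmentation-noise
experiments have a touching interface), and two-group cohorts where
patients differ from controls only through a declared effect.

The phantom is deliberately crude anatomy: axis-aligned boxes in a rough
body plan. It is plumbing for testing the pipeline, not an anatomical or
physical simulation, and its default distribution parameters are config
values rather than claims about real tracer uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._rng import child_rng
from .cloud import LabeledPointCloud

__all__ = [
    "OrganSpec",
    "EffectSpec",
    "CohortSpec",
    "generate_subject",
    "generate_cohort",
    "default_organ_specs",
    "default_cohort_spec",
]

_FAMILIES = ("lognormal", "gamma", "gaussian-mixture")


@dataclass(frozen=True)
class OrganSpec:
    """Axis-aligned box organ with a parametric SUV distribution.

    ``center`` and ``extent`` are in mm; ``extent`` is the full edge length
    per axis. Voxels are centers of a global lattice of ``voxel_pitch`` mm
    falling inside the half-open box, so boxes that share a face produce
    adjacent (but never duplicated) voxels.
    """

    label: str
    center: tuple[float, float, float]
    extent: tuple[float, float, float]
    voxel_pitch: float = 4.0
    suv_family: str = "lognormal"
    suv_params: Mapping[str, float] = field(default_factory=dict)
    spatial_gradient: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.suv_family not in _FAMILIES:
            raise ValueError(f"unknown suv_family {self.suv_family!r}")
        if min(self.extent) <= 0:
            raise ValueError(f"{self.label}: extent must be positive")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        e = np.asarray(self.extent, dtype=float)
        return c - e / 2.0, c + e / 2.0

    def voxel_centers(self) -> np.ndarray:
        lo, hi = self.bounds()
        p = self.voxel_pitch
        axes = []
        for a in range(3):
            k0 = int(np.ceil(lo[a] / p - 0.5))
            ks = []
            k = k0
            while p * (k + 0.5) < hi[a] - 1e-9:
                ks.append(k)
                k += 1
            axes.append(p * (np.asarray(ks, dtype=float) + 0.5))
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)


@dataclass(frozen=True)
class EffectSpec:
    """Disease effect: distributional shifts on target organs + coupling.

    ``mean_shift`` multiplies the location of each target organ's SUV
    distribution; ``variance_inflation`` multiplies its scale parameter.
    Either factor may be a single number applied to every target organ or
    a mapping from organ label to its factor. ``coupling`` lists organ
    pairs whose log-SUV fields share a latent smooth field along the
    cranio-caudal axis, inducing mutual information between their
    position-paired samples without moving marginals much.
    """

    target_labels: frozenset[str] = frozenset()
    mean_shift: float | Mapping[str, float] = 1.0
    variance_inflation: float | Mapping[str, float] = 1.0
    coupling: tuple[tuple[str, str], ...] = ()
    coupling_strength: float = 0.5

    def __post_init__(self) -> None:
        for factor in (self.mean_shift, self.variance_inflation):
            values = factor.values() if isinstance(factor, Mapping) else (factor,)
            if any(v <= 0 for v in values):
                raise ValueError("effect factors must be > 0")

    def factors_for(self, label: str) -> tuple[float, float]:
        """(mean_shift, variance_inflation) applying to one target organ."""
        if label not in self.target_labels:
            return 1.0, 1.0
        ms = self.mean_shift
        vi = self.variance_inflation
        return (
            float(ms.get(label, 1.0)) if isinstance(ms, Mapping) else float(ms),
            float(vi.get(label, 1.0)) if isinstance(vi, Mapping) else float(vi),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort layout sharing one organ plan."""

    organ_specs: tuple[OrganSpec, ...]
    n_controls: int
    n_patients: int
    subject_variability: float | Mapping[str, float] = 0.08
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be >= 0")
        labels = {s.label for s in self.organ_specs}
        extra = self.effect.target_labels - labels
        if extra:
            raise ValueError(f"effect targets not in organ plan: {sorted(extra)}")


def _check_no_overlap(specs: Sequence[OrganSpec]) -> None:
    for i in range(len(specs)):
        lo_i, hi_i = specs[i].bounds()
        for j in range(i + 1, len(specs)):
            lo_j, hi_j = specs[j].bounds()
            if np.all(np.minimum(hi_i, hi_j) - np.maximum(lo_i, lo_j) > 1e-9):
                raise ValueError(
                    f"organ boxes overlap: {specs[i].label!r} and {specs[j].label!r} "
                    "(labels must partition space)"
                )


def _jitter_scale(jitter: float | Mapping[str, float] | None, label: str) -> float:
    if jitter is None:
        return 0.0
    if isinstance(jitter, Mapping):
        return float(jitter.get(label, 0.0))
    return float(jitter)


def _sample_suv(
    spec: OrganSpec,
    n: int,
    rng: np.random.Generator,
    jit: float,
    jitter_rng: np.random.Generator,
    mean_shift: float,
    variance_inflation: float,
) -> np.ndarray:
    params = dict(spec.suv_params)
    loc_jit = jit * jitter_rng.standard_normal() if jit > 0 else 0.0
    scale_jit = float(np.exp(0.5 * jit * jitter_rng.standard_normal())) if jit > 0 else 1.0

    if spec.suv_family == "lognormal":
        mu = params.get("mu", 0.0) + loc_jit + np.log(mean_shift)
        sigma = params.get("sigma", 0.25) * scale_jit * variance_inflation
        return np.exp(mu + sigma * rng.standard_normal(n))
    if spec.suv_family == "gamma":
        shape = params.get("shape", 4.0)
        scale = params.get("scale", 0.5) * np.exp(loc_jit) * mean_shift
        return rng.gamma(shape, scale * scale_jit * variance_inflation, size=n)
    # gaussian-mixture: clipped at zero to keep SUVs nonnegative
    weights = np.asarray(params.get("weights", (1.0,)), dtype=float)
    means = np.asarray(params.get("means", (1.0,)), dtype=float)
    sigmas = np.asarray(params.get("sigmas", (0.25,)), dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(weights), size=n, p=weights)
    vals = (
        means[comp] * np.exp(loc_jit) * mean_shift
        + sigmas[comp] * scale_jit * variance_inflation * rng.standard_normal(n)
    )
    return np.clip(vals, 0.0, None)


def _axis_rank(z: np.ndarray) -> np.ndarray:
    """Normalized cranio-caudal rank in [0, 1] within one organ."""
    order = np.argsort(z, kind="stable")
    rank = np.empty(len(z), dtype=float)
    rank[order] = np.arange(len(z), dtype=float)
    return rank / max(len(z) - 1, 1)


def generate_subject(
    specs: Sequence[OrganSpec],
    jitter: float | Mapping[str, float] | None,
    seed: int,
    subject_id: str = "subject",
    effect: EffectSpec | None = None,
) -> LabeledPointCloud:
    """Generate one subject; a pure, bit-reproducible function of inputs.

    Each organ's SUVs are drawn from its (jittered, possibly effect-shifted)
    family; coupled organ pairs then share a random smooth field along the
    z axis, added on the log scale.
    """
    if not specs:
        raise ValueError("no organ specs given")
    _check_no_overlap(specs)

    positions: list[np.ndarray] = []
    suvs: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    effect = effect or EffectSpec()
    for spec in sorted(specs, key=lambda s: s.label):
        centers = spec.voxel_centers()
        n = len(centers)
        if n < 50:
            raise ValueError(f"{spec.label}: only {n} voxels (minimum 50)")
        ms, vi = effect.factors_for(spec.label)
        vals = _sample_suv(
            spec,
            n,
            child_rng(seed, "suv", spec.label),
            _jitter_scale(jitter, spec.label),
            child_rng(seed, "jitter", spec.label),
            ms,
            vi,
        )
        if spec.spatial_gradient is not None:
            drift = (centers - np.asarray(spec.center)) @ np.asarray(spec.spatial_gradient)
            vals = np.clip(vals + drift, 0.0, None)
        positions.append(centers)
        suvs.append(vals)
        labels.append(np.full(n, spec.label, dtype=object))

    cloud = LabeledPointCloud(
        np.concatenate(positions), np.concatenate(suvs), np.concatenate(labels), subject_id
    )

    for a, b in effect.coupling:
        pair_rng = child_rng(seed, "coupling", a, b)
        phase = pair_rng.uniform(0.0, 2.0 * np.pi)
        sign = 1.0 if pair_rng.random() < 0.5 else -1.0
        for lab in (a, b):
            mask = cloud.labels == lab
            t = _axis_rank(cloud.positions[mask, 2])
            f = sign * np.sin(2.0 * np.pi * t + phase)
            cloud.suv[mask] = cloud.suv[mask] * np.exp(effect.coupling_strength * f)
    return cloud


def generate_cohort(spec: CohortSpec) -> list[tuple[LabeledPointCloud, str]]:
    """Seeded two-group cohort; patients differ only through ``spec.effect``."""
    subjects: list[tuple[LabeledPointCloud, str]] = []
    for i in range(spec.n_controls):
        cloud = generate_subject(
            spec.organ_specs,
            spec.subject_variability,
            int(child_rng(spec.seed, "control", i).integers(0, 2**31 - 1)),
            subject_id=f"control_{i:03d}",
        )
        subjects.append((cloud, "control"))
    for i in range(spec.n_patients):
        cloud = generate_subject(
            spec.organ_specs,
            spec.subject_variability,
            int(child_rng(spec.seed, "patient", i).integers(0, 2**31 - 1)),
            subject_id=f"patient_{i:03d}",
            effect=spec.effect,
        )
        subjects.append((cloud, "patient"))
    return subjects


def default_organ_specs(voxel_pitch: float = 4.0) -> tuple[OrganSpec, ...]:
    """Crude 13-organ body plan, one fine organ per ROI.

    heart_ventricle_left / heart_ventricle_right share the face x = 8 mm,
    and the two fat depots share the face y = 40 mm, so boundary-noise
    experiments have touching interfaces to blur.

    Most organs form one tight similarity cluster (log-means near ln 3)
    while the brain sits far above it; the reference disease effect moves
    the right ventricle's distribution into the otherwise empty
    mid-similarity band, which is the graded, localized signal the
    classifier and saliency analyses are designed to recover.
    """

    def organ(label, center, extent, mu, sigma):
        return OrganSpec(
            label=label,
            center=center,
            extent=extent,
            voxel_pitch=voxel_pitch,
            suv_family="lognormal",
            suv_params={"mu": float(np.log(mu)), "sigma": sigma},
        )

    return (
        organ("brain", (0, 0, 400), (40, 40, 40), 6.0, 0.30),
        organ("skull", (0, 0, 360), (48, 48, 24), 3.0, 0.30),
        organ("lung_upper_lobe_left", (-40, 0, 280), (40, 40, 56), 3.05, 0.33),
        organ("heart_ventricle_left", (20, 0, 276), (24, 32, 48), 3.15, 0.32),
        organ("heart_ventricle_right", (-4, 0, 276), (24, 32, 48), 3.0, 0.30),
        organ("sternum", (0, -40, 280), (16, 16, 80), 3.1, 0.28),
        organ("liver", (32, 0, 192), (56, 48, 40), 3.05, 0.30),
        organ("spleen", (-40, 0, 196), (32, 32, 32), 2.9, 0.28),
        organ("pancreas", (0, 40, 192), (48, 24, 24), 3.0, 0.26),
        organ("kidney_left", (-44, 40, 144), (24, 24, 40), 3.1, 0.34),
        organ("torso_fat", (0, 28, 144), (48, 24, 48), 2.95, 0.32),
        organ("subcutaneous_fat", (0, 52, 144), (48, 24, 48), 2.88, 0.30),
        organ("skeletal_muscle", (0, 0, 64), (48, 48, 48), 2.95, 0.30),
        organ("femur_left", (-24, 0, -24), (24, 24, 80), 2.85, 0.28),
    )


def default_cohort_spec(
    n_controls: int = 20,
    n_patients: int = 10,
    seed: int = 0,
    mean_shift: float = 1.5,
    variance_inflation: float = 2.0,
) -> CohortSpec:
    """Reference experiment: distributional shift on the right ventricle."""
    return CohortSpec(
        organ_specs=default_organ_specs(),
        n_controls=n_controls,
        n_patients=n_patients,
        effect=EffectSpec(
            target_labels=frozenset({"heart_ventricle_right"}),
            mean_shift=mean_shift,
            variance_inflation=variance_inflation,
        ),
        seed=seed,
    )
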