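"""Synthetic two-class brain-volume cohorts with known discriminative support.

Real morphometry pipelines produce, per subject, a masked 3-D scalar volume:
smoothed modulated gray-matter density ("GM-volume" maps) or log-Jacobian
determinants of a nonlinear warp ("local deformation" maps).  This module
emulates the *statistical* structure of such maps — spatially smooth Gaussian
noise with heterogeneous per-voxel variance inside a brain-shaped mask — and
plants spherical clusters of between-group signal whose location is known
exactly, so that feature-selection and cross-validation code can be tested
against ground truth.  No imaging physics, segmentation or registration is
simulated.

Generation recipe for one subject volume:

1. white Gaussian noise, one draw per voxel of the bounding grid;
2. multiplied by a per-voxel scale field ``noise_sd * LogNormal(0, h)``
   drawn once per cohort (``h`` = ``variance_heterogeneity``);
3. Gaussian-smoothed with the requested FWHM (sigma = FWHM / 2.3548);
4. plus a constant baseline, plus — for class-D subjects only — the planted
   effect field; finally restricted to the mask.

The effect is added after smoothing, so the expected group difference at a
support voxel equals its planted effect exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import LABEL_D, LABEL_H, LabeledFeatureMatrix

# FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass(frozen=True)
class VolumeGeometry:
    """A 3-D grid, voxel size, and binary mask with a fixed feature order.

    Features are the in-mask voxels, linearized row-major (C order) over
    ``(x, y, z)`` after masking, 0-based.  This bijection is stable across
    calls: feature ``j`` always maps to the same voxel.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.dims):
            raise ValueError(f"mask shape {mask.shape} != dims {self.dims}")
        if not mask.any():
            raise ValueError("empty mask: no in-mask voxels, p = 0")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def p(self) -> int:
        """Number of features (in-mask voxels)."""
        return int(self.mask.sum())

    @property
    def feature_coords(self) -> np.ndarray:
        """(p, 3) voxel coordinates, one row per feature, in feature order."""
        return np.argwhere(self.mask)

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxels of a volume as a length-p vector."""
        volume = np.asarray(volume)
        if volume.shape != self.dims:
            raise ValueError(f"volume shape {volume.shape} != dims {self.dims}")
        return volume[self.mask].astype(np.float64)

    def unflatten(self, values: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Place a length-p feature vector back into a full 3-D volume."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.p,):
            raise ValueError(f"expected {self.p} values, got {values.shape}")
        out = np.full(self.dims, background, dtype=np.float64)
        out[self.mask] = values
        return out


def ellipsoid_mask(dims: tuple[int, int, int],
                   semi_axes: tuple[float, float, float] | None = None) -> np.ndarray:
    """Brain-shaped stand-in: an axis-aligned ellipsoid centered in the grid."""
    dims = tuple(int(d) for d in dims)
    if semi_axes is None:
        semi_axes = tuple(0.42 * d for d in dims)
    center = [(d - 1) / 2.0 for d in dims]
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def box_mask(dims: tuple[int, int, int]) -> np.ndarray:
    """All-ones mask (every voxel is a feature)."""
    return np.ones(tuple(int(d) for d in dims), dtype=bool)


def default_geometry() -> VolumeGeometry:
    """Desk-scale default: 24^3 grid, ellipsoidal mask (~4-6k features)."""
    dims = (24, 24, 24)
    return VolumeGeometry(dims=dims, voxel_size=(4.0, 4.0, 4.0),
                          mask=ellipsoid_mask(dims))


@dataclass(frozen=True)
class Cluster:
    """A spherical planted effect: all voxels within ``radius`` (in voxels,
    Euclidean) of ``center`` receive a mean shift of ``sign * delta`` in
    class D relative to class H."""

    center: tuple[int, int, int]
    radius: float
    delta: float
    sign: int = 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic cohort; identical spec => identical data.

    ``baseline`` shifts all intensities, emulating the positive baseline of
    gray-matter density maps; leave at 0 for signed log-Jacobian-like maps.
    """

    geometry: VolumeGeometry
    n_per_class: tuple[int, int] = (20, 20)  # (n_H, n_D)
    clusters: tuple[Cluster, ...] = ()
    noise_sd: float = 1.0
    smoothing_fwhm: float = 2.0  # in voxels
    variance_heterogeneity: float = 0.3
    baseline: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-feature effect (length p) and its support."""

    effect: np.ndarray  # length-p true mean difference (D minus H)

    @property
    def support(self) -> np.ndarray:
        """Feature indices carrying a nonzero planted effect."""
        return np.flatnonzero(self.effect != 0.0)


def strong_signal_spec(seed: int = 3, delta: float = 5.0) -> SyntheticSpec:
    """Canonical strong-signal fixture: the default desk-scale geometry with
    one central spherical cluster (radius 2.5 voxels, 81 support voxels)
    whose planted effect is ``delta`` times the white-noise sd."""
    geom = default_geometry()
    return SyntheticSpec(
        geometry=geom,
        clusters=(Cluster(center=(12, 12, 12), radius=2.5, delta=delta),),
        seed=seed)


def _effect_field(spec: SyntheticSpec) -> np.ndarray:
    geom = spec.geometry
    effect = np.zeros(geom.dims, dtype=np.float64)
    coords = np.indices(geom.dims)
    for i, cl in enumerate(spec.clusters):
        center = np.asarray(cl.center, dtype=float).reshape(3, 1, 1, 1)
        dist2 = ((coords - center) ** 2).sum(axis=0)
        ball = dist2 <= cl.radius ** 2
        if not ball.any():
            raise ValueError(f"cluster {i} at {cl.center} covers no voxels")
        if (ball & ~geom.mask).any():
            raise ValueError(
                f"cluster {i} at {cl.center} (radius {cl.radius}) extends "
                "outside the mask")
        effect[ball] += cl.sign * cl.delta
    return effect


def generate_cohort(spec: SyntheticSpec) -> tuple[LabeledFeatureMatrix, GroundTruth]:
    """Draw a two-class cohort from the spec; returns data and ground truth.

    Rows are ordered class H first, then class D.  Bit-identical output for
    identical spec (including seed).
    """
    geom = spec.geometry
    n_H, n_D = spec.n_per_class
    if n_H < 2 or n_D < 2:
        raise ValueError("need at least 2 subjects per class")
    effect = _effect_field(spec)

    rng = np.random.default_rng(spec.seed)
    # per-voxel noise scale, drawn once per cohort (sd 0 => constant scale,
    # same random-stream consumption either way)
    scale = spec.noise_sd * np.exp(
        rng.normal(0.0, spec.variance_heterogeneity, size=geom.dims))

    sigma = spec.smoothing_fwhm * FWHM_TO_SIGMA
    n = n_H + n_D
    X = np.empty((n, geom.p), dtype=np.float64)
    labels = np.array([LABEL_H] * n_H + [LABEL_D] * n_D, dtype=object)
    for i in range(n):
        vol = rng.normal(0.0, 1.0, size=geom.dims) * scale
        if sigma > 0:
            vol = ndimage.gaussian_filter(vol, sigma=sigma, mode="constant")
        vol = vol + spec.baseline
        if labels[i] == LABEL_D:
            vol = vol + effect
        X[i] = vol[geom.mask]

    data = LabeledFeatureMatrix(X=X, labels=np.asarray(labels, dtype=str))
    return data, GroundTruth(effect=effect[geom.mask].copy())


def generate_null_cohort(geometry: VolumeGeometry,
                         n_per_class: tuple[int, int] = (20, 20),
                         noise_sd: float = 1.0,
                         smoothing_fwhm: float = 2.0,
                         variance_heterogeneity: float = 0.3,
                         baseline: float = 0.0,
                         seed: int = 0) -> LabeledFeatureMatrix:
    """Cohort with no class signal (all planted effects zero).

    Identical to :func:`generate_cohort` with an empty cluster list; the
    class labels are pure noise labels.
    """
    spec = SyntheticSpec(geometry=geometry, n_per_class=n_per_class,
                         clusters=(), noise_sd=noise_sd,
                         smoothing_fwhm=smoothing_fwhm,
                         variance_heterogeneity=variance_heterogeneity,
                         baseline=baseline, seed=seed)
    data, _ = generate_cohort(spec)
    return data


def volumes_to_matrix(volumes: list[np.ndarray],
                      geometry: VolumeGeometry) -> np.ndarray:
    """Stack in-mask voxels of each volume into matrix rows (feature order)."""
    return np.stack([geometry.flatten(v) for v in volumes], axis=0)


def matrix_to_volumes(X: np.ndarray, geometry: VolumeGeometry,
                      background: float = 0.0) -> list[np.ndarray]:
    """Inverse of :func:`volumes_to_matrix`; out-of-mask voxels = background."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return [geometry.unflatten(row, background=background) for row in X]
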