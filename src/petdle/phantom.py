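"""Synthetic torso phantoms and projection-count simulation.

Activity distributions are built from labelled ellipsoids (body, liver,
lungs) and spherical lesions, with voxel values in SUV units.  Projection
data are Poisson counts whose expectation scales linearly with scan
duration; shorter scans are emulated by binomial thinning of the counts,
which preserves the Poisson model exactly (a Poisson(lam) count thinned at
probability p is Poisson(p*lam)).

Coordinate convention: arrays are indexed (x, y, z) with the axial
direction last; voxel indices are 0-based.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Ellipsoid",
    "Sphere",
    "PhantomSpec",
    "ActivityVolume",
    "Sinogram",
    "build_phantom",
    "organ_masks",
    "simulate_counts",
    "thin_counts",
    "default_phantom_spec",
    "rng_for",
    "child_seed",
]

ORGAN_LABELS = ("liver", "lung_left", "lung_right")


# ---------------------------------------------------------------------------
# seed management: one master seed per experiment, split deterministically
# per (operation, case, ...) tag tuple.

def child_seed(master_seed: int, *tags) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and tags."""
    key = repr(tags).encode()
    h = zlib.crc32(key, master_seed & 0xFFFFFFFF)
    return int(h & 0x7FFFFFFF)


def rng_for(master_seed: int, *tags) -> np.random.Generator:
    """Generator for one labelled random stream under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed) & 0xFFFFFFFF,
                               spawn_key=(zlib.crc32(repr(tags).encode()),))
    )


# ---------------------------------------------------------------------------
# geometry primitives

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    suv: float
    label: str = "body"

    def contains(self, x, y, z):
        """Membership test; accepts scalars or broadcastable arrays."""
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class Sphere:
    """Spherical lesion in voxel coordinates."""

    center: tuple[float, float, float]
    radius: float
    suv: float

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius ** 2


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a torso-like activity phantom.

    ``body`` is the outer soft-tissue ellipsoid; ``organs`` are labelled
    ellipsoids fully inside the body; ``lesions`` are spheres with SUV
    strictly above their enclosing compartment.  ``seed`` feeds optional
    intra-organ texture only (off by default), so phantom construction is
    deterministic given the spec.
    """

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm
    body: Ellipsoid | None
    organs: tuple[Ellipsoid, ...] = ()
    lesions: tuple[Sphere, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= 16, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive (mm)")
        structures = ([] if self.body is None else [self.body]) + list(self.organs)
        for s in structures:
            if s.suv < 0:
                raise ValueError(f"negative SUV on structure {s!r}")
        for les in self.lesions:
            if les.suv < 0:
                raise ValueError("negative lesion SUV")
        if self.body is None:
            if self.organs or self.lesions:
                raise ValueError("organs/lesions require a body ellipsoid")
            return
        x, y, z = _grid_coords(self.grid_shape)
        body_mask = self.body.contains(x, y, z)
        for org in self.organs:
            if org.label not in ORGAN_LABELS:
                raise ValueError(f"unknown organ label {org.label!r}")
            m = org.contains(x, y, z)
            if not np.all(body_mask[m]):
                raise ValueError(f"organ {org.label!r} extends outside the body")
        for i, les in enumerate(self.lesions):
            m = les.contains(x, y, z)
            if m.any() and not np.all(body_mask[m]):
                raise ValueError(f"lesion {i} extends outside the body")
            host = self._host_suv(les)
            if les.suv <= host:
                raise ValueError(
                    f"lesion {i} SUV {les.suv} must exceed its compartment SUV {host}"
                )
        for i in range(len(self.lesions)):
            for j in range(i + 1, len(self.lesions)):
                a, b = self.lesions[i], self.lesions[j]
                d = np.linalg.norm(np.subtract(a.center, b.center))
                if d < a.radius + b.radius:
                    raise ValueError(f"lesions {i} and {j} overlap")

    def _host_suv(self, lesion: Sphere) -> float:
        cx, cy, cz = lesion.center
        for org in self.organs:
            if org.contains(cx, cy, cz):
                return org.suv
        return self.body.suv if self.body is not None else 0.0


def _grid_coords(shape):
    nx, ny, nz = shape
    return np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )


# ---------------------------------------------------------------------------
# in-memory containers

@dataclass
class ActivityVolume:
    """3D tracer-uptake map in SUV units (reconstruction-free ground truth)."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = "phantom"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("ActivityVolume requires a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite activity values")
        if (self.values < 0).any():
            raise ValueError("negative activity values")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def total_activity(self) -> float:
        """Sum of SUV times voxel volume (ml)."""
        return float(self.values.sum(dtype=np.float64) * self.voxel_volume_ml)


@dataclass
class Sinogram:
    """Projection counts, shape (n_angles, radial_bins, n_slices)."""

    counts: np.ndarray
    duration_fraction: float
    scale: float  # expected counts per unit line integral at full duration
    seed: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("sinogram counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not (0.0 < self.duration_fraction <= 1.0):
            raise ValueError(f"duration_fraction must lie in (0, 1], got {self.duration_fraction}")


# ---------------------------------------------------------------------------
# operations

def build_phantom(spec: PhantomSpec, texture_sigma: float = 0.0) -> ActivityVolume:
    """Rasterise a phantom spec into an SUV volume; innermost structure wins.

    Deterministic given the spec; ``texture_sigma`` adds optional seeded
    multiplicative Gaussian texture inside the body (off by default).
    """
    spec.validate()
    values = np.zeros(spec.grid_shape, dtype=np.float64)
    if spec.body is None:
        return ActivityVolume(values, spec.voxel_size, provenance="phantom")
    x, y, z = _grid_coords(spec.grid_shape)
    body_mask = spec.body.contains(x, y, z)
    values[body_mask] = spec.body.suv
    for org in spec.organs:
        values[org.contains(x, y, z)] = org.suv
    for les in spec.lesions:
        values[les.contains(x, y, z)] = les.suv
    if texture_sigma > 0:
        rng = rng_for(spec.seed, "texture")
        noise = 1.0 + texture_sigma * rng.standard_normal(values.shape)
        values[body_mask] *= np.clip(noise[body_mask], 0.0, None)
    return ActivityVolume(values, spec.voxel_size, provenance="phantom")


def organ_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean voxel masks for the body and each labelled organ."""
    x, y, z = _grid_coords(spec.grid_shape)
    masks: dict[str, np.ndarray] = {}
    if spec.body is not None:
        masks["body"] = spec.body.contains(x, y, z)
    for org in spec.organs:
        masks[org.label] = org.contains(x, y, z)
    return masks


def simulate_counts(volume: ActivityVolume, projector_config, scale: float,
                    seed: int) -> Sinogram:
    """Draw Poisson projection counts for a full-duration acquisition.

    counts ~ Poisson(scale * forward_project(volume)); expectation scales
    linearly with ``scale`` (the counts-per-line-integral calibration at
    full duration).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    from . import recon  # local import: recon owns the projector

    lam = recon.forward_project(volume.values, projector_config) * float(scale)
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite forward projections")
    rng = rng_for(seed, "simulate_counts")
    counts = rng.poisson(lam).astype(np.int64)
    return Sinogram(counts=counts, duration_fraction=1.0, scale=float(scale),
                    seed=int(seed))


def thin_counts(sino: Sinogram, fraction: float, seed: int) -> Sinogram:
    """Binomial thinning: emulate a scan of ``fraction`` of the duration.

    Each count survives independently with probability ``fraction``, so a
    Poisson(lam) bin becomes Poisson(fraction * lam) — the same law as
    truncating the acquisition.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction == 1.0:
        return replace(sino, counts=sino.counts.copy())
    rng = rng_for(seed, "thin_counts", round(float(fraction), 12))
    counts = rng.binomial(sino.counts, fraction).astype(np.int64)
    return Sinogram(counts=counts,
                    duration_fraction=float(sino.duration_fraction * fraction),
                    scale=sino.scale, seed=int(seed))


# ---------------------------------------------------------------------------
# default desk-scale phantom family

DEFAULT_GRID = (64, 64, 24)
DEFAULT_VOXEL_MM = (4.0, 4.0, 4.0)

_BODY = Ellipsoid(center=(31.5, 31.5, 11.5), semi_axes=(29.5, 24.0, 13.0),
                  suv=1.0, label="body")
_LIVER = Ellipsoid(center=(26.0, 38.0, 12.0), semi_axes=(17.0, 12.0, 10.0),
                   suv=2.2, label="liver")
_LUNG_L = Ellipsoid(center=(20.0, 22.0, 12.0), semi_axes=(11.0, 10.0, 8.0),
                    suv=0.5, label="lung_left")
_LUNG_R = Ellipsoid(center=(44.0, 22.0, 12.0), semi_axes=(11.5, 10.0, 8.0),
                    suv=0.5, label="lung_right")


def default_phantom_spec(seed: int = 0,
                         n_lesions: int | None = None,
                         avoid_boxes: list[tuple[int, int, int]] | None = None,
                         ) -> PhantomSpec:
    """Desk-scale torso phantom: 64x64x24 voxels, 4 mm isotropic.

    Fixed body/liver/lung geometry (large enough to host five
    non-overlapping 7x7x7 VOIs per organ class) plus 3-5 seeded random
    lesions of radius 2-4 voxels and SUV 5-10.  ``avoid_boxes`` lists
    7x7x7 cube centers (e.g. organ VOIs) the lesion bounding boxes must
    not intersect.
    """
    rng = rng_for(seed, "phantom_spec")
    if n_lesions is None:
        n_lesions = int(rng.integers(3, 6))
    avoid = [np.asarray(c, dtype=float) for c in (avoid_boxes or [])]
    x, y, z = _grid_coords(DEFAULT_GRID)
    body_mask = _BODY.contains(x, y, z)
    lesions: list[Sphere] = []
    attempts = 0
    while len(lesions) < n_lesions and attempts < 4000:
        attempts += 1
        radius = float(rng.uniform(2.0, 4.0))
        suv = float(rng.uniform(5.0, 10.0))
        c = np.array([rng.uniform(6, 57), rng.uniform(10, 53), rng.uniform(5, 18)])
        # whole sphere strictly inside the body (exact voxel test), clear
        # of other lesions and of any protected VOI cube
        cand = Sphere(center=tuple(np.round(c, 2)), radius=round(radius, 2),
                      suv=round(suv, 2))
        sphere_vox = cand.contains(x, y, z)
        if not sphere_vox.any() or not body_mask[sphere_vox].all():
            continue
        if any(np.max(np.abs(c - np.asarray(l.center))) < 9.0 or
               np.linalg.norm(c - np.asarray(l.center)) < radius + l.radius + 2.0
               for l in lesions):
            continue
        if any(np.max(np.abs(c - a)) < 8.0 for a in avoid):
            continue
        lesions.append(cand)
    if len(lesions) < n_lesions:
        raise RuntimeError("could not place the requested number of lesions")
    return PhantomSpec(
        grid_shape=DEFAULT_GRID,
        voxel_size=DEFAULT_VOXEL_MM,
        body=_BODY,
        organs=(_LIVER, _LUNG_L, _LUNG_R),
        lesions=tuple(lesions),
        seed=int(seed),
    )
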