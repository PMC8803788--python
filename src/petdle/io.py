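"""File formats and experiment configuration.

Volumes are NIfTI-1 (32-bit float, voxel size in the header) with a JSON
sidecar (<name>.json next to the image) carrying provenance: method tag,
duration fraction and free-form parameters.  Sinograms are compressed
``.npz`` arrays with a JSON sidecar for duration fraction, count scale and
seed.  Phantom and experiment configurations are YAML documents versioned
with a ``schema_version`` key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import Ellipsoid, PhantomSpec, Sinogram, Sphere
from .recon import ImageVolume, ProjectorConfig, ReconParams

logger = logging.getLogger("petdle.io")

PHANTOM_SCHEMA_VERSION = 1
EXPERIMENT_SCHEMA_VERSION = 1

__all__ = [
    "VolumeReadError",
    "write_volume",
    "read_volume",
    "write_sinogram",
    "read_sinogram",
    "phantom_spec_to_dict",
    "phantom_spec_from_dict",
    "load_phantom_spec",
    "ExperimentConfig",
    "load_experiment_config",
]


class VolumeReadError(IOError):
    """Raised when a NIfTI volume cannot be parsed."""


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume, path, extra: dict | None = None) -> None:
    """Write an ImageVolume (or anything with values/voxel_size) as NIfTI-1
    float32 plus a JSON provenance sidecar."""
    path = Path(path)
    values = np.asarray(volume.values, dtype=np.float32)
    affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(values, affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))
    meta = {
        "method": getattr(volume, "method", getattr(volume, "provenance", "unknown")),
        "duration_fraction": float(getattr(volume, "duration_fraction", 1.0)),
    }
    params = getattr(volume, "params_used", None)
    if dataclasses.is_dataclass(params):
        meta["params_used"] = dataclasses.asdict(params)
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume; a missing sidecar yields provenance 'unknown'
    (warning logged); a corrupt file raises :class:`VolumeReadError`."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises several parser error types
        raise VolumeReadError(f"cannot read NIfTI volume {path}: {exc}") from exc
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        method = meta.get("method", "unknown")
        if method == "phantom":
            method = "ground_truth"
        fraction = float(meta.get("duration_fraction", 1.0))
    else:
        logger.warning("no sidecar for %s: provenance marked unknown", path)
        method, fraction = "unknown", 1.0
    return ImageVolume(values=values, voxel_size=zooms, method=method,
                       duration_fraction=fraction)


def write_sinogram(sino: Sinogram, path) -> None:
    path = Path(path)
    np.savez_compressed(path, counts=sino.counts)
    meta = {"duration_fraction": sino.duration_fraction, "scale": sino.scale,
            "seed": sino.seed}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

def read_sinogram(path) -> Sinogram:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Sinogram(counts=data["counts"],
                    duration_fraction=float(meta["duration_fraction"]),
                    scale=float(meta["scale"]), seed=int(meta["seed"]))


# ---------------------------------------------------------------------------
# phantom spec schema

def phantom_spec_to_dict(spec: PhantomSpec) -> dict:
    def ell(e):
        return {"label": e.label, "center": list(e.center),
                "semi_axes": list(e.semi_axes), "suv": e.suv}

    return {
        "schema_version": PHANTOM_SCHEMA_VERSION,
        "grid_shape": list(spec.grid_shape),
        "voxel_size": list(spec.voxel_size),
        "body": ell(spec.body) if spec.body else None,
        "organs": [ell(o) for o in spec.organs],
        "lesions": [{"center": list(l.center), "radius": l.radius, "suv": l.suv}
                    for l in spec.lesions],
        "seed": spec.seed,
    }


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    version = d.get("schema_version")
    if version != PHANTOM_SCHEMA_VERSION:
        raise ValueError(f"unsupported phantom schema_version {version!r}")

    def ell(e):
        return Ellipsoid(center=tuple(e["center"]), semi_axes=tuple(e["semi_axes"]),
                         suv=float(e["suv"]), label=e.get("label", "body"))

    spec = PhantomSpec(
        grid_shape=tuple(int(v) for v in d["grid_shape"]),
        voxel_size=tuple(float(v) for v in d["voxel_size"]),
        body=ell(d["body"]) if d.get("body") else None,
        organs=tuple(ell(o) for o in d.get("organs", ())),
        lesions=tuple(Sphere(center=tuple(l["center"]), radius=float(l["radius"]),
                             suv=float(l["suv"])) for l in d.get("lesions", ())),
        seed=int(d.get("seed", 0)),
    )
    spec.validate()
    return spec


def load_phantom_spec(path) -> PhantomSpec:
    return phantom_spec_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# experiment configuration

@dataclass(frozen=True)
class ExperimentConfig:
    """Whole-study configuration; defaults are the desk-scale study.

    ``scale`` is the count calibration (expected counts per unit line
    integral at full duration); ``bsrem_beta_grid`` and
    ``bsrem_target_noise`` drive the per-corpus regularisation
    calibration: beta is chosen so the full-duration target reconstruction
    of the first case hits the configured liver noise SD (in SUV).
    """

    n_train: int = 20
    n_validation: int = 4
    n_test: int = 4
    fractions: tuple[float, ...] = (1.0, 0.75, 0.5, 0.25)
    scale: float = 3.0
    seed: int = 0
    projector: ProjectorConfig = field(default_factory=ProjectorConfig)
    osem: ReconParams = field(default_factory=lambda: ReconParams(
        algorithm="OSEM", iterations=2, subsets=24))
    bsrem: ReconParams = field(default_factory=lambda: ReconParams(
        algorithm="BSREM", iterations=20, subsets=8, beta=1.0))
    bsrem_beta_grid: tuple[float, ...] = (8.0, 16.0, 32.0, 64.0)
    bsrem_target_noise: float = 0.16
    variants: tuple[str, ...] = ("standard",)
    net_levels: int = 3
    net_base_channels: int = 6
    max_epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 4
    patch_size: tuple[int, int, int] = (60, 48, 24)
    axial_stride: int = 24

    def validate(self) -> None:
        if self.n_train < 1 or self.n_validation < 1 or self.n_test < 1:
            raise ValueError("need at least one case per split")
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if 1.0 not in self.fractions:
            raise ValueError("the full duration (1.0) must be among fractions")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        for v in self.variants:
            if v not in ("smooth", "standard", "sharp"):
                raise ValueError(f"unknown variant {v!r}")
        self.projector.validate_for(64, 64)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = EXPERIMENT_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        version = d.pop("schema_version", EXPERIMENT_SCHEMA_VERSION)
        if version != EXPERIMENT_SCHEMA_VERSION:
            raise ValueError(f"unsupported experiment schema_version {version!r}")
        if "projector" in d and isinstance(d["projector"], dict):
            d["projector"] = ProjectorConfig(**d["projector"])
        for key in ("osem", "bsrem"):
            if key in d and isinstance(d[key], dict):
                d[key] = ReconParams(**d[key])
        for key in ("fractions", "bsrem_beta_grid", "variants", "patch_size"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_experiment_config(path) -> ExperimentConfig:
    return ExperimentConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})
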