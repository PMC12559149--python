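"""Core containers for axial lower-limb image analysis.

All volumes are indexed ``(z, y, x)`` with ``z`` running proximal→distal,
``+x`` toward the patient's left and ``+y`` posterior.  Voxel spacing is
stored as ``(dz, dy, dx)`` in millimetres; in-plane spacing may differ from
the slice spacing (anisotropic 2D acquisitions).  In-plane angles are
measured counterclockwise from ``+x`` in degrees; undirected line angles are
normalised into the half-open interval ``(-90, 90]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_FEMUR",
    "LABEL_TIBIA",
    "LABEL_FIBULA",
    "BONE_NAMES",
    "ImageStack",
    "LabelStack",
    "LimbTruth",
    "wrap_halfturn",
    "save_stack",
    "load_image_stack",
    "load_label_stack",
]

LABEL_BACKGROUND = 0
LABEL_FEMUR = 1
LABEL_TIBIA = 2
LABEL_FIBULA = 3
BONE_NAMES = {LABEL_FEMUR: "femur", LABEL_TIBIA: "tibia", LABEL_FIBULA: "fibula"}


def wrap_halfturn(angle_deg: float) -> float:
    """Normalise an undirected line angle (defined mod 180°) into (-90, 90]."""
    a = float(angle_deg) % 180.0
    if a > 90.0:
        a -= 180.0
    return a


@dataclass
class ImageStack:
    """3D axial grey-value volume with spacing and acquisition metadata."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    joint_level: str = "hip"
    side: str = "right"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("image values must be a 3D (z, y, x) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if self.joint_level not in ("hip", "knee", "ankle"):
            raise ValueError(f"unknown joint level {self.joint_level!r}")
        if self.side not in ("right", "left"):
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ImageStack":
        return ImageStack(self.values.copy(), self.spacing_mm, self.joint_level, self.side)


@dataclass
class LabelStack:
    """Integer label volume congruent with an :class:`ImageStack`.

    Codes: 0 background, 1 femur, 2 tibia, 3 fibula.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    joint_level: str = "hip"
    side: str = "right"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integer-valued")
            self.labels = lab.astype(np.int16)
        codes = np.unique(self.labels)
        if not np.isin(codes, (0, 1, 2, 3)).all():
            raise ValueError(f"unknown label codes {sorted(set(codes) - {0, 1, 2, 3})}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def copy(self) -> "LabelStack":
        return LabelStack(self.labels.copy(), self.spacing_mm, self.joint_level, self.side)


@dataclass
class LimbTruth:
    """Ground-truth geometry for one synthetic limb.

    Landmark coordinates are in millimetres, in the side-normalised frame
    (left limbs mirrored in x so that positive torsion means anteversion on
    both sides).  ``designated_slices`` lets geometry tests bypass automatic
    slice selection.
    """

    side: str
    head_center_mm: tuple[float, float]
    neck_center_mm: tuple[float, float]
    neck_axis_angle_deg: float
    condylar_angle_deg: float
    tibial_plateau_angle_deg: float
    ankle_axis_angle_deg: float
    femoral_torsion_deg: float
    tibial_torsion_deg: float
    designated_slices: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ft = wrap_halfturn(self.neck_axis_angle_deg - self.condylar_angle_deg)
        tt = wrap_halfturn(self.tibial_plateau_angle_deg - self.ankle_axis_angle_deg)
        if abs(ft - wrap_halfturn(self.femoral_torsion_deg)) > 1e-9:
            raise ValueError("femoral torsion inconsistent with reference-line angles")
        if abs(tt - wrap_halfturn(self.tibial_torsion_deg)) > 1e-9:
            raise ValueError("tibial torsion inconsistent with reference-line angles")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LimbTruth":
        d = json.loads(text)
        d["head_center_mm"] = tuple(d["head_center_mm"])
        d["neck_center_mm"] = tuple(d["neck_center_mm"])
        return cls(**d)


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """NIfTI affine for an (z, y, x)-indexed array saved in (x, y, z) order."""
    dz, dy, dx = spacing_mm
    return np.diag([dx, dy, dz, 1.0])


def save_stack(stack: ImageStack | LabelStack, path: str | Path) -> None:
    """Write a stack to NIfTI-1 (.nii or .nii.gz); spacing goes to the affine."""
    if isinstance(stack, LabelStack):
        data = stack.labels.astype(np.int16)
    else:
        data = stack.values.astype(np.float32)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(stack.spacing_mm))
    img.header.set_xyzt_units("mm")
    descrip = f"torsionlab:{stack.joint_level}:{stack.side}"
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], str, str]:
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    dx, dy, dz = img.header.get_zooms()[:3]
    joint, side = "hip", "right"
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="ignore")
    parts = descrip.split(":")
    if len(parts) == 3 and parts[0] == "torsionlab":
        joint, side = parts[1], parts[2]
    return data, (float(dz), float(dy), float(dx)), joint, side


def load_image_stack(path: str | Path) -> ImageStack:
    data, spacing, joint, side = _load(path)
    return ImageStack(data.astype(float), spacing, joint, side)


def load_label_stack(path: str | Path) -> LabelStack:
    data, spacing, joint, side = _load(path)
    return LabelStack(np.round(data).astype(np.int16), spacing, joint, side)
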