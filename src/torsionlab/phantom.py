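"""Synthetic lower-limb phantoms with analytically known torsion.

Each synthetic participant contributes three axial stacks per limb — hip,
knee, ankle — built from geometric primitives whose landmark positions are
known in closed form:

* femoral head: truncated sphere (circular cross-sections);
* femoral neck: oblique circular cylinder whose axial drift encodes the
  neck-axis angle;
* femoral/tibial condyles: two posterior circular lobes sharing a common
  posterior tangent of prescribed orientation;
* distal tibia: ellipse; distal fibula: circle, offset along the
  tibio-fibular axis.

The angle bookkeeping follows the clinical construction: femoral torsion is
the neck-axis angle minus the posterior femoral condylar angle, tibial
torsion the posterior tibial plateau angle minus the distal tibio-fibular
axis angle, both wrapped into (-90, 90].  Left limbs are rendered by
mirroring the canonical right-side geometry in x, so positive torsion means
anteversion on both sides.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .types import (
    LABEL_FEMUR,
    LABEL_FIBULA,
    LABEL_TIBIA,
    ImageStack,
    LabelStack,
    LimbTruth,
    wrap_halfturn,
)

__all__ = [
    "LimbSpec",
    "SyntheticLimb",
    "Participant",
    "generate_limb",
    "t2_intensity_model",
    "sample_limb_specs",
    "generate_cohort",
    "DEFAULT_JITTER",
]


class GeometryError(ValueError):
    """A phantom primitive does not fit inside the field of view."""


@dataclass
class LimbSpec:
    """Parameters of one synthetic limb.

    Angles in degrees, lengths in mm.  ``condylar_angle_deg`` is the
    orientation of the posterior femoral condylar tangent;
    ``tibial_plateau_angle_deg`` that of the posterior tibial tangent.
    The neck-axis and ankle-axis angles are derived, not free.
    """

    side: str = "right"
    femoral_torsion_deg: float = 15.0
    tibial_torsion_deg: float = 35.0
    condylar_angle_deg: float = 0.0
    tibial_plateau_angle_deg: float = 0.0
    head_radius_mm: float = 22.0
    neck_radius_mm: float = 12.0
    shaft_radius_mm: float = 14.0
    condyle_radius_mm: tuple[float, float] = (16.0, 14.0)  # (medial, lateral)
    tibia_radius_mm: float = 13.0
    fibula_radius_mm: float = 7.0
    stack_shape: tuple[int, int, int] = (12, 160, 160)
    spacing_mm: tuple[float, float, float] = (3.0, 0.6, 0.6)
    tissue_means: dict = field(
        default_factory=lambda: {"soft_tissue": 80.0, "marrow": 160.0, "cortical": 25.0}
    )
    texture_sd: float = 6.0
    cortical_thickness_mm: float = 0.8
    neck_offset_mm: float = 20.0
    neck_step_mm: float = 2.5
    condyle_sep_mm: float = 17.0
    plateau_sep_mm: float = 16.0
    fibula_offset_mm: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("right", "left"):
            raise ValueError(f"unknown side {self.side!r}")
        radii = (
            self.head_radius_mm,
            self.neck_radius_mm,
            self.shaft_radius_mm,
            *self.condyle_radius_mm,
            self.tibia_radius_mm,
            self.fibula_radius_mm,
        )
        if any(r <= 0 for r in radii):
            raise ValueError("all radii must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.stack_shape[0] < 5:
            raise ValueError("need at least 5 slices per stack")

    @property
    def neck_axis_angle_deg(self) -> float:
        return wrap_halfturn(self.condylar_angle_deg + self.femoral_torsion_deg)

    @property
    def ankle_axis_angle_deg(self) -> float:
        return wrap_halfturn(self.tibial_plateau_angle_deg - self.tibial_torsion_deg)


@dataclass
class SyntheticLimb:
    hip: tuple[ImageStack, LabelStack]
    knee: tuple[ImageStack, LabelStack]
    ankle: tuple[ImageStack, LabelStack]
    truth: LimbTruth
    spec: LimbSpec

    def stacks(self) -> dict[str, tuple[ImageStack, LabelStack]]:
        return {"hip": self.hip, "knee": self.knee, "ankle": self.ankle}


@dataclass
class Participant:
    participant_id: str
    limbs: dict[str, SyntheticLimb]
    severity_plan: list[str]


# ---------------------------------------------------------------------------
# rasterisation helpers (canonical right-side frame)


def _grids(spec: LimbSpec) -> tuple[np.ndarray, np.ndarray]:
    _, ny, nx = spec.stack_shape
    _, dy, dx = spec.spacing_mm
    yy = (np.arange(ny) * dy)[:, None]
    xx = (np.arange(nx) * dx)[None, :]
    return yy, xx


def _check_fov(spec: LimbSpec, name: str, cx: float, cy: float, extent: float) -> None:
    _, ny, nx = spec.stack_shape
    _, dy, dx = spec.spacing_mm
    if (
        cx - extent < 0
        or cx + extent > (nx - 1) * dx
        or cy - extent < 0
        or cy + extent > (ny - 1) * dy
    ):
        raise GeometryError(
            f"{name} (center x={cx:.1f} mm, y={cy:.1f} mm, extent {extent:.1f} mm) "
            f"exceeds the field of view"
        )


def _disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ellipse(
    yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, a: float, b: float, angle_deg: float
) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    u = (xx - cx) * np.cos(t) + (yy - cy) * np.sin(t)
    v = -(xx - cx) * np.sin(t) + (yy - cy) * np.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _tangent_lobes(
    center_xy: tuple[float, float],
    tangent_angle_deg: float,
    sep_mm: float,
    radii: tuple[float, float],
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Centers of two discs sharing a posterior common tangent.

    The tangent line has direction ``(cos a, sin a)`` and passes 8 mm
    posterior of ``center_xy``; each disc is shifted anterior of the line by
    its own radius, so the line touches both from posterior.  Returns
    (medial, lateral) centers as (x, y) mm — medial is +x in the canonical
    right-side frame.
    """
    a = np.deg2rad(tangent_angle_deg)
    ux, uy = np.cos(a), np.sin(a)
    nx_, ny_ = -np.sin(a), np.cos(a)  # posterior-pointing normal (+y at a=0)
    px = center_xy[0] + 8.0 * nx_
    py = center_xy[1] + 8.0 * ny_
    r_med, r_lat = radii
    med = (px + sep_mm * ux - r_med * nx_, py + sep_mm * uy - r_med * ny_)
    lat = (px - sep_mm * ux - r_lat * nx_, py - sep_mm * uy - r_lat * ny_)
    return med, lat


# ---------------------------------------------------------------------------
# per-joint label rendering

_HEAD_PROFILE = (0.85, 0.95, 1.0, 0.95, 0.85)  # truncated-sphere radius multipliers


def _render_hip(spec: LimbSpec) -> tuple[np.ndarray, dict]:
    nz, ny, nx = spec.stack_shape
    yy, xx = _grids(spec)
    labels = np.zeros(spec.stack_shape, dtype=np.int16)
    _, dy, dx = spec.spacing_mm
    cy = (ny - 1) * dy / 2.0
    cx = (nx - 1) * dx / 2.0

    theta = np.deg2rad(spec.neck_axis_angle_deg)
    ux, uy = np.cos(theta), np.sin(theta)

    head_band = min(len(_HEAD_PROFILE), nz - 4)
    head_slice = head_band // 2
    neck_start = head_band
    shaft_start = min(neck_start + 4, nz - 1)

    _check_fov(spec, "femoral head", cx, cy, spec.head_radius_mm)
    neck_reach = spec.neck_offset_mm + spec.neck_step_mm * max(0, shaft_start - 1 - neck_start)
    _check_fov(
        spec,
        "femoral neck",
        cx + neck_reach * ux,
        cy + neck_reach * uy,
        spec.neck_radius_mm,
    )

    for z in range(head_band):
        r = spec.head_radius_mm * _HEAD_PROFILE[z]
        labels[z][_disc(yy, xx, cy, cx, r)] = LABEL_FEMUR
    for z in range(neck_start, shaft_start):
        d = spec.neck_offset_mm + spec.neck_step_mm * (z - neck_start)
        labels[z][_disc(yy, xx, cy + d * uy, cx + d * ux, spec.neck_radius_mm)] = LABEL_FEMUR
    d_sh = spec.neck_offset_mm + spec.neck_step_mm * (shaft_start - 1 - neck_start)
    for z in range(shaft_start, nz):
        labels[z][
            _disc(yy, xx, cy + d_sh * uy, cx + d_sh * ux, spec.shaft_radius_mm)
        ] = LABEL_FEMUR

    neck_d = spec.neck_offset_mm
    meta = {
        "head": head_slice,
        "neck": neck_start,
        "head_center_mm": (cy, cx),
        "neck_center_mm": (cy + neck_d * uy, cx + neck_d * ux),
    }
    return labels, meta


def _render_knee(spec: LimbSpec) -> tuple[np.ndarray, dict]:
    nz, ny, nx = spec.stack_shape
    yy, xx = _grids(spec)
    labels = np.zeros(spec.stack_shape, dtype=np.int16)
    _, dy, dx = spec.spacing_mm
    cy = (ny - 1) * dy / 2.0
    cx = (nx - 1) * dx / 2.0

    third = nz // 4
    condyle_slices = range(third, third + 3)
    condyle_slice = third + 1
    # one empty slice between femur and tibia: the joint space, which also
    # keeps the two bones 3D-disconnected for component-based segmentation
    plateau_start = third + 4
    plateau_slices = range(plateau_start, min(plateau_start + 3, nz))
    plateau_slice = plateau_start + 1
    tibia_shaft_start = plateau_start + 3

    # distal femur: shaft then two posterior condylar lobes
    for z in range(0, third):
        labels[z][_disc(yy, xx, cy, cx, spec.shaft_radius_mm)] = LABEL_FEMUR
    med, lat = _tangent_lobes((cx, cy), spec.condylar_angle_deg, spec.condyle_sep_mm, spec.condyle_radius_mm)
    for c, r in ((med, spec.condyle_radius_mm[0]), (lat, spec.condyle_radius_mm[1])):
        _check_fov(spec, "femoral condyle", c[0], c[1], r)
    for z in condyle_slices:
        scale = 1.0 if z == condyle_slice else 0.92
        for c, r in ((med, spec.condyle_radius_mm[0]), (lat, spec.condyle_radius_mm[1])):
            labels[z][_disc(yy, xx, c[1], c[0], r * scale)] = LABEL_FEMUR

    # proximal tibia: two posterior plateau lobes, then shaft
    pl_radii = (1.05 * spec.tibia_radius_mm, 0.85 * spec.tibia_radius_mm)
    pmed, plat_ = _tangent_lobes((cx, cy), spec.tibial_plateau_angle_deg, spec.plateau_sep_mm, pl_radii)
    for c, r in ((pmed, pl_radii[0]), (plat_, pl_radii[1])):
        _check_fov(spec, "tibial plateau", c[0], c[1], r)
    for z in plateau_slices:
        scale = 1.0 if z == plateau_slice else 0.92
        for c, r in ((pmed, pl_radii[0]), (plat_, pl_radii[1])):
            labels[z][_disc(yy, xx, c[1], c[0], r * scale)] = LABEL_TIBIA
    for z in range(tibia_shaft_start, nz):
        labels[z][_disc(yy, xx, cy, cx, spec.tibia_radius_mm)] = LABEL_TIBIA

    # fibular head, posterolateral, distal slices
    fx, fy = cx - 34.0, cy + 12.0
    _check_fov(spec, "fibular head", fx, fy, spec.fibula_radius_mm)
    for z in range(tibia_shaft_start, nz):
        labels[z][_disc(yy, xx, fy, fx, spec.fibula_radius_mm)] = LABEL_FIBULA

    return labels, {"condyle": condyle_slice, "plateau": plateau_slice}


def _render_ankle(spec: LimbSpec) -> tuple[np.ndarray, dict]:
    nz, ny, nx = spec.stack_shape
    yy, xx = _grids(spec)
    labels = np.zeros(spec.stack_shape, dtype=np.int16)
    _, dy, dx = spec.spacing_mm
    cy = (ny - 1) * dy / 2.0
    cx = (nx - 1) * dx / 2.0

    psi = np.deg2rad(spec.ankle_axis_angle_deg)
    ux, uy = np.cos(psi), np.sin(psi)
    # fibula is lateral (-x for the canonical right side): step backwards
    fx = cx - spec.fibula_offset_mm * ux
    fy = cy - spec.fibula_offset_mm * uy

    a = 1.15 * spec.tibia_radius_mm
    b = 0.85 * spec.tibia_radius_mm
    _check_fov(spec, "distal tibia", cx, cy, a)
    _check_fov(spec, "distal fibula", fx, fy, spec.fibula_radius_mm)

    distal_slice = nz // 2
    for z in range(nz):
        scale = 1.0 if z == distal_slice else 0.95
        labels[z][
            _ellipse(yy, xx, cy, cx, a * scale, b * scale, spec.ankle_axis_angle_deg)
        ] = LABEL_TIBIA
        labels[z][_disc(yy, xx, fy, fx, spec.fibula_radius_mm * scale)] = LABEL_FIBULA

    return labels, {"distal": distal_slice, "tibia_center_mm": (cy, cx), "fibula_center_mm": (fy, fx)}


# ---------------------------------------------------------------------------
# intensity model


def t2_intensity_model(
    labels: LabelStack, spec: LimbSpec, rng: np.random.Generator | None = None
) -> ImageStack:
    """Render T2-like contrast from a label map.

    Bone marrow is bright, a thin cortical rim dark, surrounding soft tissue
    intermediate; seeded Gaussian texture is added and values clipped at 0.
    The rim is the in-plane boundary band of each bone mask, one erosion
    iteration per ``cortical_thickness_mm`` of in-plane spacing.
    """
    from scipy import ndimage

    lab = labels.labels
    known = {0, LABEL_FEMUR, LABEL_TIBIA, LABEL_FIBULA}
    present = set(np.unique(lab).tolist())
    if not present <= known:
        raise ValueError(f"unknown label code(s) {sorted(present - known)}")

    means = spec.tissue_means
    img = np.full(lab.shape, float(means["soft_tissue"]))
    bone = lab > 0
    if bone.any():
        _, dy, dx = spec.spacing_mm
        n_iter = int(round(spec.cortical_thickness_mm / min(dy, dx)))
        if n_iter > 0:
            structure = np.zeros((1, 3, 3), dtype=bool)
            structure[0] = ndimage.generate_binary_structure(2, 2)
            marrow = ndimage.binary_erosion(bone, structure=structure, iterations=n_iter)
        else:
            marrow = bone
        img[bone] = float(means["cortical"])
        img[marrow] = float(means["marrow"])

    if spec.texture_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.texture_sd, size=img.shape)
    return ImageStack(
        np.clip(img, 0.0, None), labels.spacing_mm, labels.joint_level, labels.side
    )


# ---------------------------------------------------------------------------
# limb and cohort generation


def generate_limb(spec: LimbSpec) -> SyntheticLimb:
    """Rasterise one limb: hip/knee/ankle image+label stacks plus ground truth.

    Deterministic given ``spec`` (including its seed).  Raises
    :class:`GeometryError` if a primitive does not fit in the field of view.
    """
    hip_lab, hip_meta = _render_hip(spec)
    knee_lab, knee_meta = _render_knee(spec)
    ankle_lab, ankle_meta = _render_ankle(spec)

    flip = spec.side == "left"
    rng = np.random.default_rng(spec.seed)

    out = {}
    for joint, lab in (("hip", hip_lab), ("knee", knee_lab), ("ankle", ankle_lab)):
        if flip:
            lab = lab[:, :, ::-1].copy()
        lstack = LabelStack(lab, spec.spacing_mm, joint, spec.side)
        istack = t2_intensity_model(lstack, spec, rng=rng)
        out[joint] = (istack, lstack)

    truth = LimbTruth(
        side=spec.side,
        head_center_mm=tuple(hip_meta["head_center_mm"]),
        neck_center_mm=tuple(hip_meta["neck_center_mm"]),
        neck_axis_angle_deg=spec.neck_axis_angle_deg,
        condylar_angle_deg=wrap_halfturn(spec.condylar_angle_deg),
        tibial_plateau_angle_deg=wrap_halfturn(spec.tibial_plateau_angle_deg),
        ankle_axis_angle_deg=spec.ankle_axis_angle_deg,
        femoral_torsion_deg=wrap_halfturn(spec.femoral_torsion_deg),
        tibial_torsion_deg=wrap_halfturn(spec.tibial_torsion_deg),
        designated_slices={
            "head": hip_meta["head"],
            "neck": hip_meta["neck"],
            "condyle": knee_meta["condyle"],
            "plateau": knee_meta["plateau"],
            "distal": ankle_meta["distal"],
        },
    )
    return SyntheticLimb(out["hip"], out["knee"], out["ankle"], truth, spec)


#: uniform jitter ranges for cohort generation (angles in degrees)
DEFAULT_JITTER: dict[str, tuple[float, float]] = {
    "femoral_torsion_deg": (0.0, 25.0),
    "tibial_torsion_deg": (20.0, 45.0),
    "condylar_angle_deg": (-5.0, 5.0),
    "tibial_plateau_angle_deg": (-5.0, 5.0),
}


def sample_limb_specs(
    n: int,
    base_spec: LimbSpec,
    jitter: dict[str, tuple[float, float]] | None = None,
    rng: np.random.Generator | int | None = None,
    side: str = "right",
) -> list[LimbSpec]:
    """Draw ``n`` limb specs with torsion parameters uniform in ``jitter`` ranges."""
    if jitter is None:
        jitter = DEFAULT_JITTER
    rng = np.random.default_rng(rng)
    specs = []
    for _ in range(n):
        draw = {k: float(rng.uniform(lo, hi)) if hi > lo else float(lo) for k, (lo, hi) in jitter.items()}
        specs.append(
            dataclasses.replace(
                base_spec,
                side=side,
                seed=int(rng.integers(0, 2**31 - 1)),
                **draw,
            )
        )
    return specs


def generate_cohort(
    n_participants: int,
    severity_plan: list[str],
    base_spec: LimbSpec | None = None,
    jitter: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    sides: tuple[str, ...] = ("right", "left"),
) -> list[Participant]:
    """Generate a cohort of synthetic participants.

    Each participant gets one clean reference limb per side; corruption per
    ``severity_plan`` condition is applied downstream.  Fully seeded: the
    same arguments reproduce the same cohort bit for bit.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if not severity_plan:
        raise ValueError("severity_plan must not be empty")
    if base_spec is None:
        base_spec = LimbSpec()
    rng = np.random.default_rng(seed)
    participants = []
    for i in range(n_participants):
        limbs = {}
        for side in sides:
            spec = sample_limb_specs(1, base_spec, jitter, rng, side=side)[0]
            limbs[side] = generate_limb(spec)
        participants.append(
            Participant(
                participant_id=f"P{i + 1:03d}",
                limbs=limbs,
                severity_plan=list(severity_plan),
            )
        )
    return participants
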