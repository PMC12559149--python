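"""Torsion quantification from axial label stacks.

Implements the clinical reference-line constructions on segmentation masks:

* femoral torsion (Lee-style): least-squares circle centers of the femoral
  head and neck define the neck axis; the posterior tangent of the two
  femoral condyles defines the distal reference; torsion is the wrapped
  angle between the two lines;
* tibial torsion (Ulm-style): posterior tangent of the tibial plateau
  proximally, the line through the centroids of distal tibia and fibula
  distally.

Angles are undirected (mod 180°), reported in (-90, 90].  Left limbs are
mirrored in x before any angle computation so positive torsion means
anteversion on both sides.  ``measure_limb`` never raises: every failure is
captured with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import LABEL_FEMUR, LABEL_FIBULA, LABEL_TIBIA, LabelStack, wrap_halfturn

__all__ = [
    "CircleFit",
    "Line2D",
    "TorsionResult",
    "fit_circle",
    "posterior_tangent",
    "centroid_line",
    "line_angle_diff",
    "mask_boundary_points",
    "femoral_torsion",
    "tibial_torsion",
    "measure_limb",
]


@dataclass
class CircleFit:
    center_mm: tuple[float, float]  # (y, x)
    radius_mm: float
    rms_residual_mm: float
    n_points: int


@dataclass
class Line2D:
    """Undirected in-plane line: angle in (-90, 90] plus an anchor point (y, x) mm."""

    angle_deg: float
    anchor_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.angle_deg = wrap_halfturn(self.angle_deg)


@dataclass
class TorsionResult:
    success: bool
    femoral_torsion_deg: float | None = None
    tibial_torsion_deg: float | None = None
    landmarks: dict = field(default_factory=dict)
    failure_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "success": bool(self.success),
            "femoral_torsion_deg": self.femoral_torsion_deg,
            "tibial_torsion_deg": self.tibial_torsion_deg,
            "failure_reason": self.failure_reason,
            "landmarks": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in self.landmarks.items()
            },
        }


class LandmarkError(ValueError):
    """A reference-line landmark could not be constructed."""


# ---------------------------------------------------------------------------
# geometric primitives


def fit_circle(points: np.ndarray) -> CircleFit:
    """Least-squares circle through ``points`` ((y, x) mm rows).

    The algebraic (Kåsa) solution of the linearised problem seeds a few
    Gauss–Newton steps on the radial residual sum((d_i - r)^2), so the
    reported circle minimises the geometric objective.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (y, x) points")
    y, x = pts[:, 0], pts[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle is undefined")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    r = float(np.sqrt(r2))

    # Gauss-Newton on (cy, cx, r); converges in a handful of steps from Kåsa
    for _ in range(20):
        dx_, dy_ = x - cx, y - cy
        d = np.hypot(dx_, dy_)
        if np.any(d < 1e-12):
            break
        res = d - r
        J = np.column_stack([-dy_ / d, -dx_ / d, -np.ones_like(d)])
        try:
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        except np.linalg.LinAlgError:
            break
        cy += step[0]
        cx += step[1]
        r += step[2]
        if np.max(np.abs(step)) < 1e-12:
            break

    d = np.hypot(x - cx, y - cy)
    rms = float(np.sqrt(np.mean((d - r) ** 2)))
    return CircleFit(
        center_mm=(float(cy), float(cx)), radius_mm=float(r), rms_residual_mm=rms, n_points=len(pts)
    )


def mask_boundary_points(mask: np.ndarray, spacing_yx: tuple[float, float]) -> np.ndarray:
    """Pixel centers of the outer contour (8-connectivity) of a 2D mask, in (y, x) mm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise LandmarkError("empty mask")
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool), border_value=0)
    boundary = mask & ~eroded
    iy, ix = np.nonzero(boundary)
    dy, dx = spacing_yx
    return np.column_stack([iy * dy, ix * dx])


def _two_largest_components(mask: np.ndarray) -> list[np.ndarray]:
    lab, n = ndimage.label(np.asarray(mask, dtype=bool), structure=np.ones((3, 3), dtype=bool))
    if n < 2:
        raise LandmarkError("condyles not separable: fewer than 2 components")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:2] + 1
    return [lab == k for k in order]


def posterior_tangent(mask_slice: np.ndarray, spacing_yx: tuple[float, float]) -> Line2D:
    """Common posterior tangent of the two largest components of a 2D mask.

    Posterior is +y.  The tangent is the posterior convex-hull edge whose
    endpoints lie in different components — the line first touched when
    advancing anteriorly from behind, equivalent to an iterative shifted-line
    search.  Contact points are stored on the returned line's anchor/meta.
    """
    comps = _two_largest_components(mask_slice)
    pts = [mask_boundary_points(c, spacing_yx) for c in comps]
    all_pts = np.vstack(pts)
    owner = np.repeat([0, 1], [len(pts[0]), len(pts[1])])

    # posterior hull: scan x, keep max-y chain (monotone-chain upper hull in y)
    order = np.lexsort((all_pts[:, 0], all_pts[:, 1]))  # by x, then y
    P = all_pts[order]
    own = owner[order]
    xs = P[:, 1]
    ys = P[:, 0]
    hull_idx: list[int] = []
    for i in range(len(P)):
        while len(hull_idx) >= 2:
            i1, i2 = hull_idx[-2], hull_idx[-1]
            cross = (xs[i2] - xs[i1]) * (ys[i] - ys[i1]) - (ys[i2] - ys[i1]) * (xs[i] - xs[i1])
            # keep only right turns so every point lies anterior (below) the chain
            if cross >= 0:
                hull_idx.pop()
            else:
                break
        hull_idx.append(i)

    for a, b in zip(hull_idx[:-1], hull_idx[1:]):
        if own[a] != own[b]:
            p1 = (float(ys[a]), float(xs[a]))
            p2 = (float(ys[b]), float(xs[b]))
            angle = np.degrees(np.arctan2(ys[b] - ys[a], xs[b] - xs[a]))
            line = Line2D(angle_deg=angle, anchor_mm=p1)
            line.contacts_mm = (p1, p2)  # type: ignore[attr-defined]
            return line
    raise LandmarkError("posterior tangent touches only one component")


def centroid_line(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing_yx: tuple[float, float],
    names: tuple[str, str] = ("tibia", "fibula"),
) -> Line2D:
    """Line through the pixel centroids of two 2D masks (mm)."""
    cents = []
    for mask, name in zip((mask_a, mask_b), names):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise LandmarkError(f"{name}: empty mask")
        iy, ix = np.nonzero(mask)
        cents.append((iy.mean() * spacing_yx[0], ix.mean() * spacing_yx[1]))
    (y1, x1), (y2, x2) = cents
    angle = np.degrees(np.arctan2(y2 - y1, x2 - x1))
    line = Line2D(angle_deg=angle, anchor_mm=(float(y1), float(x1)))
    line.centroids_mm = (tuple(map(float, cents[0])), tuple(map(float, cents[1])))  # type: ignore[attr-defined]
    return line


def line_angle_diff(proximal: Line2D, distal: Line2D) -> float:
    """Signed angle (proximal − distal) wrapped into (-90, 90] degrees."""
    return wrap_halfturn(proximal.angle_deg - distal.angle_deg)


# ---------------------------------------------------------------------------
# slice selection and limb-level measurements


def _oriented(labels: LabelStack, side: str) -> np.ndarray:
    lab = labels.labels
    return lab[:, :, ::-1] if side == "left" else lab


def _areas(lab: np.ndarray, code: int) -> np.ndarray:
    return (lab == code).sum(axis=(1, 2))


def _select_head_neck(lab: np.ndarray) -> tuple[int, int]:
    areas = _areas(lab, LABEL_FEMUR)
    if areas.max() == 0:
        raise LandmarkError("head fit: empty mask")
    head = int(np.argmax(areas))
    distal = areas[head + 1 :]
    candidates = np.nonzero(distal > 0.25 * areas[head])[0]
    if len(candidates) == 0:
        raise LandmarkError("neck fit: no usable slice distal to the head")
    neck = head + 1 + int(candidates[np.argmin(distal[candidates])])
    return head, neck


def _split_if_single(mask: np.ndarray) -> np.ndarray:
    """Split a merged condylar mass by the vertical line through its centroid."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n >= 2:
        return mask
    iy, ix = np.nonzero(mask)
    if len(ix) == 0:
        return mask
    cx = ix.mean()
    out = np.array(mask, dtype=bool)
    col = int(round(cx))
    out[:, col] = False
    return out


def femoral_torsion(
    hip: LabelStack,
    knee: LabelStack,
    side: str = "right",
    slice_hints: dict | None = None,
) -> tuple[float, dict]:
    """Femoral torsion (degrees, anteversion positive) from hip and knee labels."""
    _, dy, dx = hip.spacing_mm
    lab_hip = _oriented(hip, side)
    lab_knee = _oriented(knee, side)

    hints = slice_hints or {}
    if "head" in hints and "neck" in hints:
        head_z, neck_z = hints["head"], hints["neck"]
        if not (lab_hip[head_z] == LABEL_FEMUR).any():
            raise LandmarkError("head fit: empty mask")
    else:
        head_z, neck_z = _select_head_neck(lab_hip)

    head_fit = fit_circle(mask_boundary_points(lab_hip[head_z] == LABEL_FEMUR, (dy, dx)))
    neck_mask = lab_hip[neck_z] == LABEL_FEMUR
    if not neck_mask.any():
        raise LandmarkError("neck fit: empty mask")
    neck_fit = fit_circle(mask_boundary_points(neck_mask, (dy, dx)))

    hy, hx = head_fit.center_mm
    ny_, nx_ = neck_fit.center_mm
    if abs(ny_ - hy) < 1e-12 and abs(nx_ - hx) < 1e-12:
        raise LandmarkError("neck axis: head and neck centers coincide")
    neck_axis = Line2D(np.degrees(np.arctan2(ny_ - hy, nx_ - hx)), anchor_mm=(hy, hx))

    if "condyle" in hints:
        cond_z = hints["condyle"]
    else:
        areas = _areas(lab_knee, LABEL_FEMUR)
        if areas.max() == 0:
            raise LandmarkError("condylar tangent: empty mask")
        cond_z = int(np.argmax(areas))
    _, kdy, kdx = knee.spacing_mm
    cond_mask = _split_if_single(lab_knee[cond_z] == LABEL_FEMUR)
    tangent = posterior_tangent(cond_mask, (kdy, kdx))

    angle = line_angle_diff(neck_axis, tangent)
    landmarks = {
        "head_center_mm": head_fit.center_mm,
        "neck_center_mm": neck_fit.center_mm,
        "neck_axis_angle_deg": neck_axis.angle_deg,
        "condylar_angle_deg": tangent.angle_deg,
        "head_slice": int(head_z),
        "neck_slice": int(neck_z),
        "condyle_slice": int(cond_z),
    }
    return angle, landmarks


def tibial_torsion(
    knee: LabelStack,
    ankle: LabelStack,
    side: str = "right",
    slice_hints: dict | None = None,
) -> tuple[float, dict]:
    """Tibial torsion (degrees) from knee and ankle labels (Ulm-style)."""
    lab_knee = _oriented(knee, side)
    lab_ankle = _oriented(ankle, side)
    _, kdy, kdx = knee.spacing_mm
    _, ady, adx = ankle.spacing_mm

    hints = slice_hints or {}
    if "plateau" in hints:
        plat_z = hints["plateau"]
    else:
        areas = _areas(lab_knee, LABEL_TIBIA)
        if areas.max() == 0:
            raise LandmarkError("plateau tangent: empty mask")
        plat_z = int(np.argmax(areas))
    plat_mask = _split_if_single(lab_knee[plat_z] == LABEL_TIBIA)
    if not plat_mask.any():
        raise LandmarkError("plateau tangent: empty mask")
    proximal = posterior_tangent(plat_mask, (kdy, kdx))

    if "distal" in hints:
        dist_z = hints["distal"]
    else:
        areas = _areas(lab_ankle, LABEL_TIBIA)
        if areas.max() == 0:
            raise LandmarkError("tibia: empty mask")
        dist_z = int(np.argmax(areas))
    distal = centroid_line(
        lab_ankle[dist_z] == LABEL_TIBIA,
        lab_ankle[dist_z] == LABEL_FIBULA,
        (ady, adx),
        names=("tibia", "fibula"),
    )

    angle = line_angle_diff(proximal, distal)
    landmarks = {
        "plateau_angle_deg": proximal.angle_deg,
        "ankle_axis_angle_deg": distal.angle_deg,
        "plateau_slice": int(plat_z),
        "distal_slice": int(dist_z),
        "tibia_centroid_mm": distal.centroids_mm[0],  # type: ignore[attr-defined]
        "fibula_centroid_mm": distal.centroids_mm[1],  # type: ignore[attr-defined]
    }
    return angle, landmarks


def measure_limb(
    hip: LabelStack,
    knee: LabelStack,
    ankle: LabelStack,
    side: str = "right",
    slice_hints: dict | None = None,
) -> TorsionResult:
    """Attempt both torsion measurements; captures failures, never raises."""
    result = TorsionResult(success=False)
    reasons = []
    try:
        angle, lm = femoral_torsion(hip, knee, side, slice_hints)
        result.femoral_torsion_deg = float(angle)
        result.landmarks.update(lm)
    except (LandmarkError, ValueError) as exc:
        reasons.append(f"femoral: {exc}")
    try:
        angle, lm = tibial_torsion(knee, ankle, side, slice_hints)
        result.tibial_torsion_deg = float(angle)
        result.landmarks.update(lm)
    except (LandmarkError, ValueError) as exc:
        reasons.append(f"tibial: {exc}")
    result.success = (
        result.femoral_torsion_deg is not None and result.tibial_torsion_deg is not None
    )
    result.failure_reason = "; ".join(reasons)
    return result
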