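"""Slice-wise 2D similarity registration by mutual-information ascent.

Motion during acquisition of ankle stacks shows up as through-plane slice
misalignment; each corrupted slice is registered back to its reference
slice with a 2D similarity transform (rotation, isotropic scale,
translation).  The objective is the joint-histogram mutual information and
the optimiser is a regular-step gradient ascent: the step size is halved
whenever the gradient direction reverses, and the search stops when the
step falls below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageStack

__all__ = ["Similarity2D", "RegistrationOptions", "mutual_information", "apply_similarity", "register_slices"]


@dataclass
class Similarity2D:
    """2D similarity transform: rotation (deg), isotropic scale, translation (mm)."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation_mm: tuple[float, float] = (0.0, 0.0)  # (ty, tx)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def inverse(self) -> "Similarity2D":
        t = np.deg2rad(self.rotation_deg)
        s = self.scale
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        ty, tx = self.translation_mm
        inv_t = -(R.T / s) @ np.array([ty, tx])
        return Similarity2D(-self.rotation_deg, 1.0 / s, (float(inv_t[0]), float(inv_t[1])))


@dataclass
class RegistrationOptions:
    initial_step: float = 2.0
    min_step: float = 0.02
    max_iterations: int = 200
    bins: int = 32
    optimize_scale: bool = True
    rotation_grid_deg: tuple[float, ...] = tuple(float(r) for r in range(-12, 13, 2))
    smooth_sigma_px: float = 1.0
    # parameter units per unit step: degrees, mm, mm, scale
    param_scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.01)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> tuple[float, bool]:
    """Joint-histogram mutual information in nats; symmetric and >= 0.

    Intensities are clipped to the 1st–99th percentile before binning.
    Returns ``(mi, degenerate)`` where ``degenerate`` flags a constant image
    (MI defined as 0 there).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have congruent shapes")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if a.max() == a.min() or b.max() == b.min():
        return 0.0, True
    lo_a, hi_a = np.percentile(a, (1, 99))
    lo_b, hi_b = np.percentile(b, (1, 99))
    if hi_a <= lo_a:
        lo_a, hi_a = a.min(), a.max()
    if hi_b <= lo_b:
        lo_b, hi_b = b.min(), b.max()
    joint, _, _ = np.histogram2d(
        np.clip(a, lo_a, hi_a), np.clip(b, lo_b, hi_b), bins=bins
    )
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0), False


def apply_similarity(
    slice_2d: np.ndarray, t: Similarity2D, spacing_yx: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Resample a slice under a similarity transform about its geometric center.

    Linear interpolation; the identity transform returns the input exactly.
    """
    sl = np.asarray(slice_2d, dtype=float)
    if t.rotation_deg == 0.0 and t.scale == 1.0 and tuple(t.translation_mm) == (0.0, 0.0):
        return sl.copy()
    th = np.deg2rad(t.rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]) * t.scale
    Rinv = np.linalg.inv(R)
    center = (np.asarray(sl.shape, dtype=float) - 1.0) / 2.0
    shift_px = np.array([t.translation_mm[0] / spacing_yx[0], t.translation_mm[1] / spacing_yx[1]])
    offset = center - Rinv @ (center + shift_px)
    return ndimage.affine_transform(sl, Rinv, offset=offset, order=1, mode="constant", cval=0.0)


def _mi_of_params(
    p: np.ndarray, moving: np.ndarray, fixed: np.ndarray, spacing_yx, bins
) -> float:
    t = Similarity2D(p[0], max(p[3], 1e-3), (p[1], p[2]))
    warped = apply_similarity(moving, t, spacing_yx)
    mi, _ = mutual_information(warped, fixed, bins)
    return mi


def _register_one_slice(
    moving: np.ndarray,
    fixed: np.ndarray,
    spacing_yx: tuple[float, float],
    options: RegistrationOptions,
) -> tuple[Similarity2D, str]:
    if options.smooth_sigma_px > 0:
        moving_s = ndimage.gaussian_filter(moving, options.smooth_sigma_px)
        fixed_s = ndimage.gaussian_filter(fixed, options.smooth_sigma_px)
    else:
        moving_s, fixed_s = moving, fixed

    scales = np.asarray(options.param_scale)

    def objective(u: np.ndarray) -> float:
        return _mi_of_params(
            np.array([u[0] * scales[0], u[1] * scales[1], u[2] * scales[2], 1.0 + u[3] * scales[3]]),
            moving_s,
            fixed_s,
            spacing_yx,
            options.bins,
        )

    # initialisation: translation by phase correlation, rotation by grid
    # search (with translation re-estimated at the best rotation)
    from skimage.registration import phase_cross_correlation

    def trans_estimate(rot_deg: float) -> np.ndarray:
        rotated = apply_similarity(moving_s, Similarity2D(rot_deg, 1.0, (0.0, 0.0)), spacing_yx)
        # plain cross-correlation: the "phase" normalisation is unreliable on
        # smooth real-valued images
        shift_px, _, _ = phase_cross_correlation(
            fixed_s, rotated, upsample_factor=4, normalization=None
        )
        return np.array(
            [shift_px[0] * spacing_yx[0] / scales[1], shift_px[1] * spacing_yx[1] / scales[2]]
        )

    best_u = np.zeros(4)
    t0 = trans_estimate(0.0)
    best_u[1:3] = t0
    best_mi = objective(best_u)
    for r in options.rotation_grid_deg:
        u = np.array([r / scales[0], t0[0], t0[1], 0.0])
        mi = objective(u)
        if mi > best_mi:
            best_mi, best_u = mi, u
    if best_u[0] != 0.0:
        u = best_u.copy()
        u[1:3] = trans_estimate(best_u[0] * scales[0])
        if objective(u) > best_mi:
            best_u = u

    if options.max_iterations == 0:
        return Similarity2D(), "not converged"

    u = best_u
    step = options.initial_step
    prev_grad = None
    status = "not converged"
    n_free = 4 if options.optimize_scale else 3
    eps = 0.25
    for _ in range(options.max_iterations):
        grad = np.zeros(4)
        f0 = objective(u)
        if not np.isfinite(f0):
            return Similarity2D(), "aborted: non-finite objective"
        for i in range(n_free):
            e = np.zeros(4)
            e[i] = eps
            grad[i] = (objective(u + e) - objective(u - e)) / (2 * eps)
        norm = np.linalg.norm(grad)
        if norm == 0:
            step /= 2.0
        else:
            direction = grad / norm
            if prev_grad is not None and float(np.dot(direction, prev_grad)) < 0:
                step /= 2.0
            cand = u + step * direction
            if objective(cand) >= f0:
                u = cand
            else:
                step /= 2.0
            prev_grad = direction
        if step < options.min_step:
            status = "converged"
            break

    params = u * scales
    return Similarity2D(float(params[0]), float(1.0 + u[3] * scales[3]), (float(params[1]), float(params[2]))), status


def register_slices(
    moving: ImageStack,
    fixed: ImageStack,
    options: RegistrationOptions | None = None,
) -> tuple[list[Similarity2D], list[str], ImageStack]:
    """Register each slice of ``moving`` to ``fixed``; returns transforms,
    per-slice convergence status, and the resampled stack.

    A slice whose objective turns non-finite is left untransformed with an
    abort status; the stack as a whole never fails.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed stacks must have congruent shapes")
    if options is None:
        options = RegistrationOptions()
    _, dy, dx = moving.spacing_mm
    transforms: list[Similarity2D] = []
    statuses: list[str] = []
    out = np.empty_like(moving.values)
    for z in range(moving.shape[0]):
        t, status = _register_one_slice(moving.values[z], fixed.values[z], (dy, dx), options)
        transforms.append(t)
        statuses.append(status)
        out[z] = apply_similarity(moving.values[z], t, (dy, dx))
    return transforms, statuses, ImageStack(out, moving.spacing_mm, moving.joint_level, moving.side)
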