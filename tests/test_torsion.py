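"""Geometric core: circle fits, posterior tangents, torsion recovery."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torsionlab.artifacts import rigid_transform_slice
from torsionlab.phantom import LimbSpec, generate_limb
from torsionlab.torsion import (
    LandmarkError,
    Line2D,
    centroid_line,
    femoral_torsion,
    fit_circle,
    line_angle_diff,
    mask_boundary_points,
    measure_limb,
    posterior_tangent,
    tibial_torsion,
)
from torsionlab.types import LabelStack, wrap_halfturn

# ---------------------------------------------------------------------------
# oracles


def grid_refine_circle(points: np.ndarray, center0, span=1.0, iters=6):
    """Brute-force circle fit: nested grid search minimising sum((d_i - r)^2)."""
    best = (np.inf, center0[0], center0[1])
    cy, cx = center0
    for _ in range(iters):
        ys = np.linspace(cy - span, cy + span, 21)
        xs = np.linspace(cx - span, cx + span, 21)
        for yy in ys:
            for xx in xs:
                d = np.hypot(points[:, 1] - xx, points[:, 0] - yy)
                r = d.mean()  # optimal radius in closed form
                loss = np.sum((d - r) ** 2)
                if loss < best[0]:
                    best = (loss, yy, xx)
        _, cy, cx = best
        span /= 5.0
    return cy, cx


def rotating_line_tangent(pts_a: np.ndarray, pts_b: np.ndarray, step_deg=0.01):
    """Posterior common tangent by brute-force sweep over line angles.

    For each angle, the first-contact (most posterior) line level of each
    point set is its maximum projection on the posterior normal; the common
    tangent is the angle where both sets touch the same line.
    """
    angles = np.arange(-90.0, 90.0, step_deg)
    t = np.deg2rad(angles)
    nx, ny = -np.sin(t), np.cos(t)  # posterior normal per angle
    proj_a = np.max(np.outer(nx, pts_a[:, 1]) + np.outer(ny, pts_a[:, 0]), axis=1)
    proj_b = np.max(np.outer(nx, pts_b[:, 1]) + np.outer(ny, pts_b[:, 0]), axis=1)
    return float(angles[np.argmin(np.abs(proj_a - proj_b))])


def disc_mask(shape, cy, cx, r, spacing=1.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float) * spacing
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


# ---------------------------------------------------------------------------
# fit_circle


class TestFitCircle:
    def test_exact_four_points(self):
        fit = fit_circle([(5, 0), (0, 5), (-5, 0), (0, -5)])
        assert fit.center_mm == pytest.approx((0.0, 0.0), abs=1e-12)
        assert fit.radius_mm == pytest.approx(5.0)
        assert fit.rms_residual_mm == pytest.approx(0.0, abs=1e-12)

    def test_circumcircle_of_right_triangle(self):
        fit = fit_circle([(0, 0), (2, 0), (0, 2)])
        assert fit.center_mm == pytest.approx((1.0, 1.0))
        assert fit.radius_mm == pytest.approx(np.sqrt(2.0))

    def test_noisy_circle_matches_grid_oracle(self, rng):
        t = rng.uniform(0, 2 * np.pi, 100)
        pts = np.column_stack([-2 + 7 * np.sin(t), 3 + 7 * np.cos(t)])
        pts += rng.normal(0, 0.1, pts.shape)
        fit = fit_circle(pts)
        assert abs(fit.center_mm[0] - (-2)) < 0.05
        assert abs(fit.center_mm[1] - 3) < 0.05
        oy, ox = grid_refine_circle(pts, fit.center_mm)
        assert fit.center_mm[0] == pytest.approx(oy, abs=1e-4)
        assert fit.center_mm[1] == pytest.approx(ox, abs=1e-4)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            fit_circle([(0, 0), (1, 1)])
        with pytest.raises(ValueError, match="collinear"):
            fit_circle([(0, 0), (1, 1), (2, 2), (3, 3)])


# ---------------------------------------------------------------------------
# posterior_tangent / centroid_line / line_angle_diff


class TestPosteriorTangent:
    def test_symmetric_discs_give_zero_angle(self):
        m = disc_mask((40, 80), 20, 20, 8) | disc_mask((40, 80), 20, 60, 8)
        line = posterior_tangent(m, (1.0, 1.0))
        assert abs(line.angle_deg) < 1.0
        # tangent anchored at the posterior extreme of the discs
        assert line.anchor_mm[0] == pytest.approx(28.0, abs=1.0)

    def test_unequal_discs_match_analytic_angle(self):
        # radii 5 and 10 at center distance 30: angle = asin(5/30)
        sp = 0.2
        shape = (300, 500)
        m = disc_mask(shape, 30, 30, 5, sp) | disc_mask(shape, 30, 60, 10, sp)
        line = posterior_tangent(m, (sp, sp))
        expected = np.degrees(np.arcsin(5.0 / 30.0))
        assert line.angle_deg == pytest.approx(expected, abs=0.5)

    def test_matches_rotating_line_oracle(self, rng):
        for _ in range(20):
            r1, r2 = rng.uniform(4, 10, 2)
            sep = rng.uniform(r1 + r2 + 4, 30)
            m1 = disc_mask((120, 120), 60, 60 - sep / 2, r1)
            m2 = disc_mask((120, 120), 60, 60 + sep / 2, r2)
            line = posterior_tangent(m1 | m2, (1.0, 1.0))
            pts1 = mask_boundary_points(m1, (1.0, 1.0))
            pts2 = mask_boundary_points(m2, (1.0, 1.0))
            oracle = rotating_line_tangent(pts1, pts2, step_deg=0.05)
            assert abs(wrap_halfturn(line.angle_deg - oracle)) < 0.5

    def test_single_disc_rejected(self):
        with pytest.raises(LandmarkError, match="not separable"):
            posterior_tangent(disc_mask((40, 40), 20, 20, 8), (1.0, 1.0))


class TestCentroidLine:
    def test_cardinal_and_diagonal_angles(self):
        a = np.zeros((30, 30), bool)
        b = np.zeros((30, 30), bool)
        a[10, 10] = True
        b[10, 20] = True
        assert centroid_line(a, b, (1, 1)).angle_deg == pytest.approx(0.0)
        b[:] = False
        b[20, 20] = True
        assert centroid_line(a, b, (1, 1)).angle_deg == pytest.approx(45.0)

    def test_empty_mask_names_the_bone(self):
        a = np.ones((5, 5), bool)
        with pytest.raises(LandmarkError, match="fibula"):
            centroid_line(a, np.zeros((5, 5), bool), (1, 1))


@given(a=st.floats(-90, 90, exclude_min=True), b=st.floats(-90, 90, exclude_min=True))
@settings(max_examples=200, deadline=None)
def test_line_angle_diff_always_in_halfturn(a, b):
    d = line_angle_diff(Line2D(a), Line2D(b))
    assert -90.0 < d <= 90.0
    # consistent with direct modular arithmetic
    assert abs(wrap_halfturn(a - b) - d) < 1e-12


@pytest.mark.parametrize(
    "prox,dist,expected", [(20.0, 5.0, 15.0), (-85.0, 85.0, 10.0), (33.0, 33.0, 0.0)]
)
def test_line_angle_diff_examples(prox, dist, expected):
    assert line_angle_diff(Line2D(prox), Line2D(dist)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# limb-level measurements


class TestTorsionRecovery:
    def test_clean_phantom_within_tolerance(self, fine_limb):
        t = fine_limb.truth
        f, _ = femoral_torsion(fine_limb.hip[1], fine_limb.knee[1], t.side)
        assert f == pytest.approx(t.femoral_torsion_deg, abs=2.0)
        tt, _ = tibial_torsion(fine_limb.knee[1], fine_limb.ankle[1], t.side)
        assert tt == pytest.approx(t.tibial_torsion_deg, abs=2.0)

    def test_zero_torsion_symmetric_geometry(self):
        limb = generate_limb(
            LimbSpec(femoral_torsion_deg=0.0, condylar_angle_deg=0.0, seed=4)
        )
        f, _ = femoral_torsion(limb.hip[1], limb.knee[1])
        assert abs(f) < 0.5

    def test_plateau_equals_ankle_axis_gives_zero(self):
        limb = generate_limb(LimbSpec(tibial_torsion_deg=0.0, tibial_plateau_angle_deg=0.0, seed=4))
        t, _ = tibial_torsion(limb.knee[1], limb.ankle[1])
        assert abs(t) < 0.5

    def test_slice_hints_bypass_auto_selection(self, fine_limb):
        t = fine_limb.truth
        f, lm = femoral_torsion(
            fine_limb.hip[1], fine_limb.knee[1], t.side, slice_hints=t.designated_slices
        )
        assert lm["head_slice"] == t.designated_slices["head"]
        assert f == pytest.approx(t.femoral_torsion_deg, abs=2.0)

    def test_translation_invariance(self, fine_limb):
        t = fine_limb.truth
        shifted = {}
        for joint, (img, lab) in fine_limb.stacks().items():
            arr = np.roll(lab.labels, shift=(5, -7), axis=(1, 2))
            shifted[joint] = LabelStack(arr, lab.spacing_mm, joint, lab.side)
        f, _ = femoral_torsion(shifted["hip"], shifted["knee"], t.side)
        f0, _ = femoral_torsion(fine_limb.hip[1], fine_limb.knee[1], t.side)
        assert f == pytest.approx(f0, abs=1e-9)

    @pytest.mark.parametrize("delta", [-10.0, -5.0, 5.0, 10.0])
    def test_rotation_equivariance(self, fine_limb, delta):
        t = fine_limb.truth
        rotated = {}
        for joint, (img, lab) in fine_limb.stacks().items():
            arr = np.stack(
                [
                    rigid_transform_slice(sl.astype(float), delta, (0.0, 0.0), order=0)
                    for sl in lab.labels
                ]
            ).astype(lab.labels.dtype)
            rotated[joint] = LabelStack(arr, lab.spacing_mm, joint, lab.side)
        f, _ = femoral_torsion(rotated["hip"], rotated["knee"], t.side)
        tt, _ = tibial_torsion(rotated["knee"], rotated["ankle"], t.side)
        f0, _ = femoral_torsion(fine_limb.hip[1], fine_limb.knee[1], t.side)
        t0, _ = tibial_torsion(fine_limb.knee[1], fine_limb.ankle[1], t.side)
        assert f == pytest.approx(f0, abs=0.5)
        assert tt == pytest.approx(t0, abs=0.5)


class TestMeasureLimb:
    def test_clean_phantom_success(self, fine_limb):
        t = fine_limb.truth
        res = measure_limb(fine_limb.hip[1], fine_limb.knee[1], fine_limb.ankle[1], t.side)
        assert res.success
        assert res.femoral_torsion_deg == pytest.approx(t.femoral_torsion_deg, abs=2.0)
        assert res.tibial_torsion_deg == pytest.approx(t.tibial_torsion_deg, abs=2.0)

    def test_empty_ankle_keeps_femoral_angle(self, fine_limb):
        empty = fine_limb.ankle[1].copy()
        empty.labels[:] = 0
        res = measure_limb(fine_limb.hip[1], fine_limb.knee[1], empty, fine_limb.truth.side)
        assert not res.success
        assert res.femoral_torsion_deg is not None
        assert "tibia" in res.failure_reason

    def test_femur_missing_reports_head_fit_failure(self, fine_limb):
        empty_hip = fine_limb.hip[1].copy()
        empty_hip.labels[:] = 0
        res = measure_limb(empty_hip, fine_limb.knee[1], fine_limb.ankle[1])
        assert not res.success
        assert "head fit: empty mask" in res.failure_reason

    def test_all_empty_aggregates_reasons(self, fine_limb):
        stacks = []
        for joint, (img, lab) in fine_limb.stacks().items():
            s = lab.copy()
            s.labels[:] = 0
            stacks.append(s)
        res = measure_limb(*stacks)
        assert not res.success
        assert "femoral" in res.failure_reason and "tibial" in res.failure_reason


def test_torsion_recovery_sweep_coarse_grid():
    """Recovery within 2 deg across representative torsion values (0.6 mm)."""
    for ft, tt in [(-30.0, 0.0), (0.0, 20.0), (15.0, 35.0), (45.0, 50.0)]:
        limb = generate_limb(
            LimbSpec(femoral_torsion_deg=ft, tibial_torsion_deg=tt, seed=6)
        )
        res = measure_limb(limb.hip[1], limb.knee[1], limb.ankle[1])
        assert res.success
        assert res.femoral_torsion_deg == pytest.approx(
            limb.truth.femoral_torsion_deg, abs=2.0
        )
        assert res.tibial_torsion_deg == pytest.approx(limb.truth.tibial_torsion_deg, abs=2.0)
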