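"""k-space and intensity-domain MRI artifact operators with severity presets.

Artifacts are modelled where they physically arise:

* ghosting — periodic attenuation of every g-th phase-encode line, which
  folds displaced duplicates of the anatomy along the phase axis;
* spiking — a point of spurious energy in k-space (plus its Hermitian
  mirror, keeping the image real), giving herringbone-like stripes;
* motion — the k-space is assembled line-wise from differently
  rotated/translated copies of the anatomy, emulating movement between
  phase-encode lines;
* blur / bias field / noise — image-domain degradations.

FFT convention: DC at index 0 (numpy's unshifted layout).  The phase-encode
axis defaults to y (anterior–posterior).  All operators are the identity at
zero intensity and always return real, finite arrays.

The probabilistic sampler includes each artifact kind independently with
probability 0.5 (spikes: 0.02) and logs everything it drew in an
:class:`ArtifactRecipe`, so any corrupted stack can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageStack, LabelStack

__all__ = [
    "ArtifactRecipe",
    "SamplerConfig",
    "SEVERITIES",
    "apply_ghosting",
    "apply_spike",
    "apply_motion",
    "apply_intensity_artifacts",
    "apply_slice_misalignment",
    "severity_to_params",
    "sample_recipe",
    "apply_recipe",
    "sample_mri_specific",
]

SEVERITIES = ("none", "mild", "moderate", "severe")
PHASE_AXIS = 1  # y (anterior-posterior) for (z, y, x) volumes


@dataclass
class ArtifactRecipe:
    """Log of the sampled artifact set applied to one stack."""

    severity: str = "none"
    seed: int | None = None
    slice_wise: bool = False
    applied: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.severity == "none" and self.applied:
            raise ValueError("severity 'none' must have an empty artifact list")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SamplerConfig:
    """Per-kind inclusion probabilities and parameter ranges for the sampler."""

    probabilities: dict = field(
        default_factory=lambda: {
            "motion": 0.5,
            "ghosting": 0.5,
            "spike": 0.02,
            "blur": 0.5,
            "bias_field": 0.5,
            "noise": 0.5,
        }
    )
    ranges: dict = field(default_factory=lambda: dict(_PRESETS["moderate"]))
    slice_wise: bool = False

    def __post_init__(self) -> None:
        for kind, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {kind!r} outside [0, 1]")


# severity presets: monotone, strictly increasing parameter ranges
_PRESETS: dict[str, dict] = {
    "mild": {
        "ghost_intensity": (0.1, 0.3),
        "ghost_order": (2, 4),
        "motion_rot_deg": 2.0,
        "motion_trans_mm": 2.0,
        "motion_n_movements": 1,
        "blur_sigma_mm": 0.5,
        "bias_scale": 0.1,
        "noise_frac": 0.02,
        "spike_intensity": (0.05, 0.15),
    },
    "moderate": {
        "ghost_intensity": (0.3, 0.6),
        "ghost_order": (2, 4),
        "motion_rot_deg": 5.0,
        "motion_trans_mm": 5.0,
        "motion_n_movements": 2,
        "blur_sigma_mm": 1.0,
        "bias_scale": 0.2,
        "noise_frac": 0.05,
        "spike_intensity": (0.15, 0.3),
    },
    "severe": {
        "ghost_intensity": (0.6, 0.9),
        "ghost_order": (2, 4),
        "motion_rot_deg": 10.0,
        "motion_trans_mm": 10.0,
        "motion_n_movements": 3,
        "blur_sigma_mm": 1.5,
        "bias_scale": 0.3,
        "noise_frac": 0.08,
        "spike_intensity": (0.3, 0.6),
    },
}


def severity_to_params(severity: str) -> SamplerConfig:
    """Sampler configuration for a severity grade; 'none' samples nothing."""
    if severity not in SEVERITIES:
        raise ValueError(f"unknown severity {severity!r}; expected one of {SEVERITIES}")
    cfg = SamplerConfig()
    if severity == "none":
        cfg.probabilities = {k: 0.0 for k in cfg.probabilities}
        cfg.ranges = {}
    else:
        cfg.ranges = dict(_PRESETS[severity])
    return cfg


# ---------------------------------------------------------------------------
# k-space operators


def apply_ghosting(
    image: np.ndarray, axis: int = PHASE_AXIS, ghost_order: int = 2, intensity: float = 0.5
) -> np.ndarray:
    """Attenuate every ``ghost_order``-th phase-encode line (DC excluded) by (1-s)."""
    image = np.asarray(image, dtype=float)
    if ghost_order < 2:
        raise ValueError("ghost_order must be >= 2")
    if not -image.ndim <= axis < image.ndim:
        raise ValueError(f"axis {axis} out of range for {image.ndim}D image")
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    n = image.shape[axis]
    K = np.fft.fft(image, axis=axis)
    idx = np.arange(n)
    lines = (idx % ghost_order == 0) & (idx != 0)
    shape = [1] * image.ndim
    shape[axis] = n
    factor = np.where(lines, 1.0 - intensity, 1.0).reshape(shape)
    return np.real(np.fft.ifft(K * factor, axis=axis))


def _spike_one_slice(sl: np.ndarray, positions, intensity: float) -> np.ndarray:
    K = np.fft.fft2(sl)
    ny, nx = K.shape
    mag = intensity * np.abs(K).max()
    for u, v in positions:
        u, v = int(u) % ny, int(v) % nx
        if u == 0 and v == 0:
            raise ValueError("spike at the DC sample would only shift global brightness")
        mu, mv = (-u) % ny, (-v) % nx
        if (mu, mv) == (u, v):  # self-conjugate (Nyquist) sample: must stay real
            K[u, v] += mag
        else:
            K[u, v] += mag
            K[mu, mv] += mag  # conjugate of a real value
    return np.real(np.fft.ifft2(K))


def apply_spike(image: np.ndarray, spike_positions, intensity: float) -> np.ndarray:
    """Add spurious k-space energy of magnitude ``intensity * max|K|`` per slice.

    Each spike is mirrored Hermitially so the output stays real.  Positions
    are (row, col) indices into the unshifted 2D FFT of each axial slice.
    """
    image = np.asarray(image, dtype=float)
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if intensity == 0:
        return image.copy()
    if image.ndim == 2:
        return _spike_one_slice(image, spike_positions, intensity)
    return np.stack([_spike_one_slice(sl, spike_positions, intensity) for sl in image])


def apply_motion(
    image: np.ndarray,
    transforms: list[tuple[float, tuple[float, float]]],
    schedule: np.ndarray,
    spacing_yx: tuple[float, float] = (1.0, 1.0),
    axis: int = PHASE_AXIS,
) -> np.ndarray:
    """Assemble k-space line-wise from rigidly transformed copies of the image.

    ``transforms`` is a list of ``(rotation_deg, (ty_mm, tx_mm))`` states;
    state 0 is required to be the identity.  ``schedule`` assigns a state
    index to every phase-encode line and must cover all lines exactly once.
    Works on a 2D slice or slice-wise on a 3D volume.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        ax2d = {0: None, 1: 0, 2: 1}[axis]
        return np.stack(
            [apply_motion(sl, transforms, schedule, spacing_yx, axis=ax2d) for sl in image]
        )
    if axis not in (0, 1):
        raise ValueError("2D phase axis must be 0 or 1")
    if transforms[0][0] != 0.0 or tuple(transforms[0][1]) != (0.0, 0.0):
        raise ValueError("transform state 0 must be the identity")
    n_lines = image.shape[axis]
    schedule = np.asarray(schedule, dtype=int)
    if schedule.shape != (n_lines,):
        raise ValueError(
            f"schedule must assign exactly one state to each of {n_lines} phase lines"
        )
    if schedule.min() < 0 or schedule.max() >= len(transforms):
        raise ValueError("schedule references an unknown transform state")

    dy, dx = spacing_yx
    K_out = np.zeros(image.shape, dtype=complex)
    for state in np.unique(schedule):
        rot, (ty_mm, tx_mm) = transforms[state]
        moved = rigid_transform_slice(image, rot, (ty_mm / dy, tx_mm / dx))
        Ks = np.fft.fft2(moved)
        sel = schedule == state
        if axis == 0:
            K_out[sel, :] = Ks[sel, :]
        else:
            K_out[:, sel] = Ks[:, sel]
    return np.real(np.fft.ifft2(K_out))


def rigid_transform_slice(
    sl: np.ndarray, rot_deg: float, trans_px: tuple[float, float], order: int = 1
) -> np.ndarray:
    """Rotate a 2D slice about its center, then translate by (ty, tx) pixels."""
    sl = np.asarray(sl, dtype=float)
    if rot_deg == 0.0 and tuple(trans_px) == (0.0, 0.0):
        return sl.copy()
    t = np.deg2rad(rot_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    center = (np.asarray(sl.shape, dtype=float) - 1.0) / 2.0
    shift = np.asarray(trans_px, dtype=float)
    # output pixel x_out samples input at x_in = R^T (x_out - shift - center) + center
    offset = center - R.T @ (center + shift)
    return ndimage.affine_transform(sl, R.T, offset=offset, order=order, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# intensity-domain operators


def apply_intensity_artifacts(
    image: np.ndarray,
    spacing_mm: tuple[float, ...],
    blur_sigma_mm: float | tuple[float, ...] = 0.0,
    bias_order: int = 3,
    bias_scale: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Gaussian blur (σ in mm), multiplicative exp-polynomial bias field, noise."""
    image = np.asarray(image, dtype=float)
    if np.isscalar(blur_sigma_mm):
        blur_sigma_mm = (float(blur_sigma_mm),) * image.ndim
    if any(s < 0 for s in blur_sigma_mm) or bias_scale < 0 or noise_sd < 0 or bias_order < 0:
        raise ValueError("artifact parameters must be non-negative")
    rng = np.random.default_rng(rng)
    out = image
    sigmas_px = [s / sp for s, sp in zip(blur_sigma_mm, spacing_mm)]
    if any(s > 0 for s in sigmas_px):
        out = ndimage.gaussian_filter(out, sigma=sigmas_px, mode="reflect")
    if bias_scale > 0:
        coords = [np.linspace(-1.0, 1.0, n) for n in image.shape]
        grids = np.meshgrid(*coords, indexing="ij")
        P = np.zeros(image.shape)
        for exps in _monomials(image.ndim, bias_order):
            coef = rng.uniform(-1.0, 1.0) * bias_scale
            term = np.ones(image.shape)
            for g, e in zip(grids, exps):
                if e:
                    term = term * g**e
            P += coef * term
        out = out * np.exp(P)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=image.shape)
    return out


def _monomials(ndim: int, order: int):
    """Exponent tuples with 1 <= total degree <= order (constant excluded)."""
    from itertools import product

    for exps in product(range(order + 1), repeat=ndim):
        if 1 <= sum(exps) <= order:
            yield exps


def apply_slice_misalignment(
    image: np.ndarray,
    labels: np.ndarray | None,
    max_rot_deg: float,
    max_trans_mm: float,
    spacing_yx: tuple[float, float],
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray | None, list]:
    """Per-slice random rigid offsets (through-plane motion emulation).

    Unlike the volume-constant k-space operators this geometrically moves the
    anatomy, so the same transform is applied to the label map (nearest
    neighbour) — making registration-based recovery measurable.
    """
    rng = np.random.default_rng(rng)
    dy, dx = spacing_yx
    out_img = np.empty_like(np.asarray(image, dtype=float))
    out_lab = None if labels is None else np.zeros_like(labels)
    transforms = []
    for z in range(image.shape[0]):
        rot = float(rng.uniform(-max_rot_deg, max_rot_deg))
        ty = float(rng.uniform(-max_trans_mm, max_trans_mm))
        tx = float(rng.uniform(-max_trans_mm, max_trans_mm))
        transforms.append({"rotation_deg": rot, "ty_mm": ty, "tx_mm": tx})
        out_img[z] = rigid_transform_slice(image[z], rot, (ty / dy, tx / dx), order=1)
        if labels is not None:
            out_lab[z] = rigid_transform_slice(
                labels[z].astype(float), rot, (ty / dy, tx / dx), order=0
            ).astype(labels.dtype)
    return out_img, out_lab, transforms


# ---------------------------------------------------------------------------
# probabilistic sampler


def _draw(rng: np.random.Generator, rng_spec) -> float:
    lo, hi = rng_spec
    return float(rng.uniform(lo, hi))


def sample_recipe(
    shape: tuple[int, int, int],
    config: SamplerConfig,
    rng: np.random.Generator | int | None = None,
    severity: str = "moderate",
) -> ArtifactRecipe:
    """Draw an artifact set for a stack of the given shape.

    Each kind is included independently with its configured probability;
    parameters are drawn uniformly from the configured ranges.  The recipe is
    self-contained: :func:`apply_recipe` reproduces the corruption exactly.
    """
    rng = np.random.default_rng(rng)
    applied: list[dict] = []
    R = config.ranges
    n_lines = shape[PHASE_AXIS]

    if rng.random() < config.probabilities.get("motion", 0.0):
        n_mov = int(R["motion_n_movements"])
        transforms = [{"rotation_deg": 0.0, "ty_mm": 0.0, "tx_mm": 0.0}]
        for _ in range(n_mov):
            transforms.append(
                {
                    "rotation_deg": float(rng.uniform(-R["motion_rot_deg"], R["motion_rot_deg"])),
                    "ty_mm": float(rng.uniform(-R["motion_trans_mm"], R["motion_trans_mm"])),
                    "tx_mm": float(rng.uniform(-R["motion_trans_mm"], R["motion_trans_mm"])),
                }
            )
        cuts = np.sort(rng.choice(np.arange(1, n_lines), size=n_mov, replace=False))
        schedule = np.zeros(n_lines, dtype=int)
        for i, c in enumerate(cuts):
            schedule[c:] = i + 1
        applied.append(
            {"kind": "motion", "transforms": transforms, "schedule": schedule.tolist()}
        )
    if rng.random() < config.probabilities.get("ghosting", 0.0):
        applied.append(
            {
                "kind": "ghosting",
                "ghost_order": int(rng.integers(R["ghost_order"][0], R["ghost_order"][1] + 1)),
                "intensity": _draw(rng, R["ghost_intensity"]),
            }
        )
    if rng.random() < config.probabilities.get("spike", 0.0):
        ny, nx = shape[1], shape[2]
        u = int(rng.integers(3, max(4, ny // 3)))
        v = int(rng.integers(3, max(4, nx // 3)))
        applied.append(
            {
                "kind": "spike",
                "positions": [[u, v]],
                "intensity": _draw(rng, R["spike_intensity"]),
            }
        )
    if rng.random() < config.probabilities.get("blur", 0.0):
        applied.append({"kind": "blur", "sigma_mm": float(rng.uniform(0.0, R["blur_sigma_mm"]))})
    if rng.random() < config.probabilities.get("bias_field", 0.0):
        applied.append(
            {
                "kind": "bias_field",
                "scale": float(rng.uniform(0.0, R["bias_scale"])),
                "order": 3,
                "field_seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
    if rng.random() < config.probabilities.get("noise", 0.0):
        applied.append({"kind": "noise", "sd_frac": float(rng.uniform(0.0, R["noise_frac"])), "noise_seed": int(rng.integers(0, 2**31 - 1))})

    return ArtifactRecipe(severity=severity, slice_wise=config.slice_wise, applied=applied)


def apply_recipe(
    image: np.ndarray, spacing_mm: tuple[float, float, float], recipe: ArtifactRecipe
) -> np.ndarray:
    """Apply a sampled artifact recipe to a (z, y, x) volume, in order."""
    out = np.asarray(image, dtype=float).copy()
    dz, dy, dx = spacing_mm
    for item in recipe.applied:
        kind = item["kind"]
        if kind == "blur":
            out = apply_intensity_artifacts(
                out, spacing_mm, blur_sigma_mm=(0.0, item["sigma_mm"], item["sigma_mm"])
            )
        elif kind == "bias_field":
            out = apply_intensity_artifacts(
                out,
                spacing_mm,
                bias_order=item.get("order", 3),
                bias_scale=item["scale"],
                rng=item["field_seed"],
            )
        elif kind == "motion":
            transforms = [
                (t["rotation_deg"], (t["ty_mm"], t["tx_mm"])) for t in item["transforms"]
            ]
            out = apply_motion(
                out, transforms, np.asarray(item["schedule"]), spacing_yx=(dy, dx)
            )
        elif kind == "ghosting":
            out = apply_ghosting(
                out, axis=PHASE_AXIS, ghost_order=item["ghost_order"], intensity=item["intensity"]
            )
        elif kind == "spike":
            out = apply_spike(out, item["positions"], item["intensity"])
        elif kind == "noise":
            sd = item["sd_frac"] * float(np.abs(out).max())
            out = apply_intensity_artifacts(out, spacing_mm, noise_sd=sd, rng=item["noise_seed"])
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
    return out


def sample_mri_specific(
    image: ImageStack,
    labels: LabelStack | None,
    config: SamplerConfig,
    seed: int | None = None,
    severity: str = "moderate",
) -> tuple[ImageStack, LabelStack | None, ArtifactRecipe]:
    """Sample and apply the MRI-specific artifact set to a stack.

    Labels are returned unchanged: all sampled artifacts live in k-space or
    the intensity domain and corrupt the signal, not the nominal anatomy.
    """
    rng = np.random.default_rng(seed)
    recipe = sample_recipe(image.shape, config, rng, severity=severity)
    recipe.seed = seed
    corrupted = apply_recipe(image.values, image.spacing_mm, recipe)
    out = ImageStack(corrupted, image.spacing_mm, image.joint_level, image.side)
    return out, labels, recipe
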