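"""Deterministic preprocessing and general-purpose training augmentations.

``preprocess_stack`` mirrors the standard segmentation-pipeline recipe:
crop to the non-zero bounding box, z-score the intensities, resample image
and labels to a target voxel spacing with nearest-neighbour interpolation
(appropriate for strongly anisotropic axial stacks).

``sample_default_augmentation`` is the general-purpose sampler: rotation,
rescaling, mirroring and resolution reduction are applied identically to
image and labels (nearest neighbour for labels), while Gaussian noise,
brightness/contrast and gamma touch the image only.  Every draw is logged
and reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .artifacts import rigid_transform_slice
from .types import ImageStack, LabelStack

__all__ = ["DefaultAugConfig", "preprocess_stack", "sample_default_augmentation"]


@dataclass
class DefaultAugConfig:
    """Probabilities and ranges for the default augmentation sampler."""

    p_rotation: float = 0.5
    rotation_deg: tuple[float, float] = (-15.0, 15.0)  # in-plane
    p_rescale: float = 0.5
    rescale: tuple[float, float] = (0.85, 1.15)
    p_mirror: float = 0.5  # per permitted axis
    mirror_axes: tuple[int, ...] = (2,)  # x only: z order and A/P are anatomical
    p_noise: float = 0.25
    noise_sd_frac: tuple[float, float] = (0.0, 0.05)  # fraction of intensity SD
    p_brightness_contrast: float = 0.3
    brightness_frac: tuple[float, float] = (-0.2, 0.2)
    contrast: tuple[float, float] = (0.75, 1.25)
    p_lowres: float = 0.2
    lowres_factor: tuple[float, float] = (1.2, 2.0)
    p_gamma: float = 0.3
    gamma: tuple[float, float] = (0.7, 1.5)

    def __post_init__(self) -> None:
        for name in ("p_rotation", "p_rescale", "p_mirror", "p_noise",
                     "p_brightness_contrast", "p_lowres", "p_gamma"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.gamma[0] <= 0:
            raise ValueError("gamma must be positive")


def preprocess_stack(
    image: ImageStack,
    labels: LabelStack | None = None,
    target_spacing_mm: tuple[float, float, float] | None = None,
) -> tuple[ImageStack, LabelStack | None]:
    """Crop to the non-zero box, z-score, resample to ``target_spacing_mm``."""
    vals = image.values
    if not np.any(vals != 0):
        raise ValueError("empty image")
    nz = np.nonzero(vals != 0)
    slices = tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in nz)
    cropped = vals[slices]
    mu = cropped.mean()
    sd = cropped.std()
    if sd == 0:
        sd = 1.0
    normed = (cropped - mu) / sd

    lab = labels.labels[slices] if labels is not None else None
    spacing = image.spacing_mm
    if target_spacing_mm is not None and tuple(target_spacing_mm) != spacing:
        zoom = [s / t for s, t in zip(spacing, target_spacing_mm)]
        normed = ndimage.zoom(normed, zoom, order=0, mode="nearest")
        if lab is not None:
            lab = ndimage.zoom(lab, zoom, order=0, mode="nearest")
        spacing = tuple(float(t) for t in target_spacing_mm)

    out_img = ImageStack(normed, spacing, image.joint_level, image.side)
    out_lab = (
        LabelStack(lab, spacing, labels.joint_level, labels.side) if labels is not None else None
    )
    return out_img, out_lab


def _inplane_transform(vol: np.ndarray, rot_deg: float, scale: float, order: int) -> np.ndarray:
    """Apply in-plane rotation + isotropic rescale about each slice center."""
    t = np.deg2rad(rot_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]]) * scale
    Rinv = np.linalg.inv(R)
    center = (np.asarray(vol.shape[1:], dtype=float) - 1.0) / 2.0
    offset = center - Rinv @ center
    return np.stack(
        [
            ndimage.affine_transform(sl, Rinv, offset=offset, order=order, mode="constant", cval=0.0)
            for sl in vol
        ]
    )


def sample_default_augmentation(
    image: ImageStack,
    labels: LabelStack | None,
    config: DefaultAugConfig | None = None,
    seed: int | None = None,
) -> tuple[ImageStack, LabelStack | None, dict]:
    """Draw and apply one default-augmentation sample; returns a draw log."""
    if config is None:
        config = DefaultAugConfig()
    rng = np.random.default_rng(seed)
    img = image.values.copy()
    lab = labels.labels.copy() if labels is not None else None
    log: dict = {"seed": seed}

    # geometric: combined in-plane rotation + rescale (one resampling pass)
    rot = float(rng.uniform(*config.rotation_deg)) if rng.random() < config.p_rotation else 0.0
    scale = float(rng.uniform(*config.rescale)) if rng.random() < config.p_rescale else 1.0
    if rot != 0.0 or scale != 1.0:
        img = _inplane_transform(img, rot, scale, order=1)
        if lab is not None:
            lab = _inplane_transform(lab.astype(float), rot, scale, order=0).astype(lab.dtype)
    log["rotation_deg"] = rot
    log["rescale"] = scale

    mirrored = []
    for ax in config.mirror_axes:
        if rng.random() < config.p_mirror:
            img = np.flip(img, axis=ax)
            if lab is not None:
                lab = np.flip(lab, axis=ax)
            mirrored.append(ax)
    log["mirrored_axes"] = mirrored

    if rng.random() < config.p_lowres:
        f = float(rng.uniform(*config.lowres_factor))
        small = ndimage.zoom(img, (1.0, 1.0 / f, 1.0 / f), order=1, mode="nearest")
        up = ndimage.zoom(
            small,
            (1.0, img.shape[1] / small.shape[1], img.shape[2] / small.shape[2]),
            order=0,
            mode="nearest",
        )
        # zoom rounding can be off by one pixel: pad/crop back to input shape
        pad = [(0, max(0, t - s)) for t, s in zip(img.shape, up.shape)]
        up = np.pad(up, pad, mode="edge")
        img = up[: img.shape[0], : img.shape[1], : img.shape[2]]
        log["lowres_factor"] = f
    else:
        log["lowres_factor"] = None

    # intensity-only transforms
    if rng.random() < config.p_noise:
        sd = float(rng.uniform(*config.noise_sd_frac)) * float(img.std() or 1.0)
        img = img + rng.normal(0.0, sd, size=img.shape)
        log["noise_sd"] = sd
    else:
        log["noise_sd"] = None

    if rng.random() < config.p_brightness_contrast:
        b = float(rng.uniform(*config.brightness_frac))
        c = float(rng.uniform(*config.contrast))
        mu = img.mean()
        rng_span = img.std() or 1.0
        img = (img - mu) * c + mu + b * rng_span
        log["brightness"] = b
        log["contrast"] = c
    else:
        log["brightness"] = log["contrast"] = None

    if rng.random() < config.p_gamma:
        g = float(rng.uniform(*config.gamma))
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** g * (hi - lo) + lo
        log["gamma"] = g
    else:
        log["gamma"] = None

    out_img = ImageStack(np.ascontiguousarray(img), image.spacing_mm, image.joint_level, image.side)
    out_lab = (
        LabelStack(np.ascontiguousarray(lab), labels.spacing_mm, labels.joint_level, labels.side)
        if labels is not None
        else None
    )
    return out_img, out_lab, log
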