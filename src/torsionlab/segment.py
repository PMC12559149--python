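"""Stand-in bone segmenter and segmentation-quality metrics.

The segmenter is deliberately simple — intensity threshold (automatic Otsu
by default), morphological cleanup, connected components, rule-based bone
assignment — and serves as the integration point where a learned model
could be substituted.  What matters for the pipeline is that it is
deterministic, that it degrades gracefully with image corruption, and that
its output is a :class:`~torsionlab.types.LabelStack` the torsion module can
consume.

Bone assignment by joint level: the hip stack contains only the femur; in
the knee stack the most proximal component is the femur, the largest
remaining one the tibia, and the smallest the fibula; in the ankle stack the
larger of two components is the tibia, the smaller the fibula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import LABEL_FEMUR, LABEL_FIBULA, LABEL_TIBIA, ImageStack, LabelStack

__all__ = ["SegmentationResult", "segment_stack", "dice"]


@dataclass
class SegmentationResult:
    labels: LabelStack
    ok: bool
    message: str = ""


def _flat_disk(radius_px: int) -> np.ndarray:
    """In-plane disk structuring element embedded in a single z-slice."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= r**2)[None, :, :]


def segment_stack(
    image: ImageStack,
    threshold_quantile: float | None = None,
    min_component_voxels: int = 60,
    opening_radius_mm: float = 0.6,
    shell_mm: float = 0.8,
) -> SegmentationResult:
    """Threshold + morphology + component-labelling bone segmentation.

    ``threshold_quantile=None`` uses an automatic (Otsu) threshold, which is
    invariant to global intensity scaling; an explicit quantile is honoured.
    ``shell_mm`` re-dilates components to recover the dark cortical rim
    excluded by the bright-marrow threshold.  Never raises on unusable
    images: returns an empty label stack with ``ok=False``.
    """
    vals = image.values
    empty = LabelStack(
        np.zeros(image.shape, dtype=np.int16), image.spacing_mm, image.joint_level, image.side
    )
    if not np.any(np.isfinite(vals)) or vals.max() == vals.min():
        return SegmentationResult(empty, ok=False, message="constant or unusable image")

    if threshold_quantile is not None:
        thr = float(np.quantile(vals, threshold_quantile))
    else:
        thr = float(threshold_otsu(vals))
    cand = vals > thr

    _, dy, dx = image.spacing_mm
    # at least one pixel: isolated noise voxels must never survive (a single
    # above-threshold voxel in the joint space can 3D-bridge two bones)
    r_open = max(1, int(round(opening_radius_mm / min(dy, dx))))
    cand = ndimage.binary_opening(cand, structure=_flat_disk(r_open))

    comp_lab, n = ndimage.label(cand, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return SegmentationResult(empty, ok=False, message="no component above threshold")
    sizes = ndimage.sum_labels(np.ones_like(comp_lab), comp_lab, np.arange(1, n + 1))
    keep = np.nonzero(sizes >= min_component_voxels)[0] + 1
    if len(keep) == 0:
        return SegmentationResult(empty, ok=False, message="no component above minimum size")

    # largest components only: 1 bone expected at the hip, up to 3 elsewhere
    max_bones = {"hip": 1, "knee": 3, "ankle": 2}[image.joint_level]
    keep = keep[np.argsort(sizes[keep - 1])[::-1]][:max_bones]

    masks = [comp_lab == k for k in keep]
    r_shell = int(round(shell_mm / min(dy, dx)))
    if r_shell > 0:
        shell = _flat_disk(r_shell)
        masks = [ndimage.binary_dilation(m, structure=shell) for m in masks]

    codes = _assign_codes(masks, image.joint_level)
    out = np.zeros(image.shape, dtype=np.int16)
    for mask, code in zip(masks, codes):
        out[(out == 0) & mask] = code
    return SegmentationResult(
        LabelStack(out, image.spacing_mm, image.joint_level, image.side), ok=True
    )


def _assign_codes(masks: list[np.ndarray], joint_level: str) -> list[int]:
    sizes = [int(m.sum()) for m in masks]
    mean_z = [float(np.nonzero(m)[0].mean()) for m in masks]
    codes = [0] * len(masks)
    if joint_level == "hip":
        codes[int(np.argmax(sizes))] = LABEL_FEMUR
    elif joint_level == "ankle":
        order = np.argsort(sizes)[::-1]
        codes[order[0]] = LABEL_TIBIA
        if len(masks) > 1:
            codes[order[1]] = LABEL_FIBULA
    else:  # knee
        remaining = list(range(len(masks)))
        femur = min(remaining, key=lambda i: mean_z[i])
        codes[femur] = LABEL_FEMUR
        remaining.remove(femur)
        if remaining:
            tibia = max(remaining, key=lambda i: sizes[i])
            codes[tibia] = LABEL_TIBIA
            remaining.remove(tibia)
        if remaining:
            codes[remaining[0]] = LABEL_FIBULA
    return codes


def dice(
    a: LabelStack | np.ndarray, b: LabelStack | np.ndarray, label_code: int | None = None
) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    With ``label_code`` the stacks are compared on that bone's mask;
    otherwise the inputs are treated as boolean masks.  Two empty masks give
    1.0 (agreement on absence), empty vs non-empty 0.0.
    """
    ma = a.mask(label_code) if isinstance(a, LabelStack) else np.asarray(a, dtype=bool)
    mb = b.mask(label_code) if isinstance(b, LabelStack) else np.asarray(b, dtype=bool)
    if ma.shape != mb.shape:
        raise ValueError(f"shape mismatch: {ma.shape} vs {mb.shape}")
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom
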