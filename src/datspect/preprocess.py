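"""Extracerebral masking and striatal count normalization.

Before template building and test-retest quantification, images are (1)
masked to remove high-uptake structures outside the brain — eyes and
Harderian glands take up the tracer nonspecifically and would otherwise
dominate registration and normalization — and (2) count-normalized by the
mean of the striatal voxels within 95% of the striatal maximum, which puts
every animal's image on a common intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import NormalizationError
from .image_io import LabelVolume, VolumeImage
from .synthetic_data import Ellipsoid, _grid_coords

__all__ = [
    "MaskSpec",
    "mask_extracerebral",
    "normalize_counts",
    "provisional_striatal_region",
]

BRAIN_LABELS = ("brain", "striatum_left", "striatum_right", "cerebellum")


@dataclass
class MaskSpec:
    """How to identify the brain when removing extracerebral hot spots.

    ``brain_region_hint`` is either a boolean array (on the image grid) or
    an :class:`~datspect.synthetic_data.Ellipsoid` in mm coordinates; in
    ``"labels"`` mode a :class:`LabelVolume` supplies the truth instead.
    """

    brain_region_hint: object = None
    mode: str = "automatic"
    automatic_threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("labels", "automatic"):
            raise ValueError(f"unknown masking mode {self.mode!r}")
        if not (0.0 < self.automatic_threshold_fraction < 1.0):
            raise ValueError("threshold fraction must be in (0, 1)")


def _hint_mask(image: VolumeImage, hint) -> np.ndarray:
    if hint is None:
        raise ValueError("automatic masking needs a brain region hint")
    if isinstance(hint, Ellipsoid):
        coords = _grid_coords(image.shape, image.voxel_size_mm, image.origin_mm)
        return hint.contains(coords)
    if isinstance(hint, LabelVolume):
        return hint.mask(*BRAIN_LABELS)
    mask = np.asarray(hint)
    if mask.shape != image.shape:
        raise ValueError("brain hint mask must match the image grid")
    return mask.astype(bool)


def mask_extracerebral(
    image: VolumeImage,
    mask_spec: MaskSpec,
    labels: LabelVolume | None = None,
) -> VolumeImage:
    """Zero high-uptake voxels outside the brain; never touch voxels inside.

    In ``"automatic"`` mode, voxels outside the brain hint whose intensity
    is at least ``automatic_threshold_fraction`` of the global maximum are
    set to zero (hot-spot removal).  In ``"labels"`` mode all voxels outside
    the brain labels are zeroed.  Masking is monotone: no voxel value ever
    increases.
    """
    if mask_spec.mode == "labels":
        if labels is None:
            raise ValueError("labels mode requires a LabelVolume")
        brain = labels.mask(*BRAIN_LABELS)
        if not brain.any():
            raise ValueError("empty brain region")
        out = np.where(brain, image.data, 0.0)
        return image.with_data(out)
    brain = _hint_mask(image, mask_spec.brain_region_hint)
    if not brain.any():
        raise ValueError("empty brain region")
    threshold = mask_spec.automatic_threshold_fraction * image.data.max()
    kill = (~brain) & (image.data >= threshold)
    out = image.data.copy()
    out[kill] = 0.0
    return image.with_data(out)


def normalize_counts(
    image: VolumeImage,
    striatal_region: np.ndarray,
) -> tuple[VolumeImage, float]:
    """Normalize by the mean of striatal voxels within 95% of the striatal max.

    The normalization constant is the mean of the voxels inside
    ``striatal_region`` whose value is >= 0.95 x the maximum value within
    that region; the output image is the input divided by it.  The
    operation is idempotent (re-running on the output gives constant 1) and
    scale-invariant.
    """
    region = np.asarray(striatal_region, dtype=bool)
    if region.shape != image.shape:
        raise ValueError("striatal region must match the image grid")
    if not region.any():
        raise ValueError("striatal region is empty")
    vals = image.data[region]
    vmax = vals.max()
    if vmax <= 0:
        raise NormalizationError("striatal maximum is not positive")
    constant = float(vals[vals >= 0.95 * vmax].mean())
    return image.with_data(image.data / constant), constant


def provisional_striatal_region(
    image: VolumeImage,
    brain_hint=None,
    percentile: float = 99.0,
) -> np.ndarray:
    """Bootstrap striatal region before any template VOI exists.

    Takes the top-percentile intensity voxels (inside the brain hint when
    given) and keeps the largest connected component — in a masked brain
    image the striatum is the dominant hot blob.
    """
    if brain_hint is not None:
        inside = _hint_mask(image, brain_hint)
    else:
        inside = np.ones(image.shape, dtype=bool)
    vals = image.data[inside]
    if vals.size == 0 or vals.max() <= 0:
        raise NormalizationError("no positive intensity inside the brain hint")
    cut = np.percentile(vals[vals > 0], percentile)
    hot = inside & (image.data >= cut)
    lab, n = ndimage.label(hot)
    if n == 0:
        raise NormalizationError("no suprathreshold voxels for the provisional region")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))
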