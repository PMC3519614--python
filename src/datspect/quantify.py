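"""VOI statistics, time-activity curves, binding potential and volumetry.

The quantitative readout of the pipeline is the binding potential

    BP = (S - C) / C = S/C - 1

where S is the mean count density in the striatal volume of interest
(specific binding) and C the mean in a cerebellar reference sub-volume
(nonspecific binding).  At transient equilibrium BP is proportional to
transporter density.  Counts are decay-corrected by ``2**(t / T_half)``
before any ratio across time points is formed (BP itself is invariant to a
decay factor common to both regions).

Striatal anatomical volume is estimated by intensity thresholding: the
volume of the connected component containing the striatal seed among the
voxels above a fraction of the striatal maximum, reported as a curve over
thresholds.  Phantom resolution is scored on the Jaszczak hot-rod image by
the valley-to-peak ratio of adjacent rod pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ReferenceRegionError
from .image_io import LabelVolume, VolumeImage
from .synthetic_data import JaszczakGeometry

__all__ = [
    "VOI",
    "TimeActivityCurve",
    "BPValue",
    "ThresholdVolumeCurve",
    "decay_correct",
    "voi_mean",
    "binding_potential",
    "default_vois",
    "time_activity_curves",
    "fit_monoexponential",
    "detect_equilibrium",
    "threshold_volume_curve",
    "line_profile",
    "resolvable_rod_size",
]


@dataclass
class VOI:
    """Named volume of interest: a boolean mask with physical voxel volume."""

    name: str
    mask: np.ndarray
    voxel_volume_mm3: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"VOI {self.name!r} is empty")

    @property
    def volume_mm3(self) -> float:
        return float(np.count_nonzero(self.mask)) * self.voxel_volume_mm3


@dataclass
class TimeActivityCurve:
    region: str
    times_h: np.ndarray
    mean_counts: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        if len(self.times_h) != len(self.mean_counts):
            raise ValueError("times and counts must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class BPValue:
    striatal_mean: float
    cerebellar_mean: float

    @property
    def bp(self) -> float:
        return self.striatal_mean / self.cerebellar_mean - 1.0


@dataclass
class ThresholdVolumeCurve:
    thresholds: np.ndarray
    volumes_mm3: np.ndarray


def decay_correct(counts, t_h: float, half_life_h: float):
    """Remove physical decay: measured counts times ``2**(t / T_half)``."""
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    if t_h < 0:
        raise ValueError("time must be non-negative")
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    out = c * 2.0 ** (t_h / half_life_h)
    return float(out) if np.isscalar(counts) else out


def voi_mean(image: VolumeImage, voi: VOI) -> float:
    """Arithmetic mean intensity over the VOI voxels."""
    if voi.mask.shape != image.shape:
        raise ValueError("VOI mask does not match the image grid")
    return float(image.data[voi.mask].mean())


def binding_potential(striatal_mean: float, cerebellar_mean: float) -> BPValue:
    """Specific-to-nonspecific binding ratio minus one."""
    if cerebellar_mean <= 0:
        raise ReferenceRegionError(
            f"cerebellar reference mean must be positive, got {cerebellar_mean}")
    return BPValue(float(striatal_mean), float(cerebellar_mean))


def _eroded_core(mask: np.ndarray, target_voxels: int) -> np.ndarray:
    """The ``target_voxels`` innermost voxels of a mask (by depth from edge)."""
    if mask.sum() <= target_voxels:
        return mask
    depth = ndimage.distance_transform_edt(mask)
    flat = depth.ravel()
    order = np.argsort(flat)[::-1][:target_voxels]
    out = np.zeros(flat.shape, dtype=bool)
    out[order] = True
    return out.reshape(mask.shape)


def default_vois(labels: LabelVolume,
                 cerebellar_voi_mm3: float = 13.3,
                 striatal_core_fraction: float = 0.25) -> dict[str, VOI]:
    """Standard analysis VOIs from a label volume.

    Both VOIs are eroded cores of their anatomical labels, because the
    quantity of interest is the regional tracer *concentration*: at sub-mm
    structure sizes the edge voxels of a region are dominated by
    partial-volume spill across the point-spread function, so sampling the
    innermost voxels (where the recovery coefficient approaches one) gives
    a nearly unbiased concentration estimate while keeping enough voxels
    for stable statistics.  The cerebellar VOI is trimmed to
    ``cerebellar_voi_mm3`` (default 13.3 mm^3, deliberately only part of
    the cerebellum); the striatal VOI keeps the innermost
    ``striatal_core_fraction`` of the bilateral striatum label (default
    25%, about 5.6 mm^3 at the default anatomy).
    """
    vv = labels.voxel_volume_mm3
    striatum = labels.mask("striatum_left", "striatum_right")
    cereb = labels.mask("cerebellum")
    s_target = max(1, int(round(striatum.sum() * striatal_core_fraction)))
    c_target = max(1, int(round(cerebellar_voi_mm3 / vv)))
    return {
        "striatum": VOI("striatum", _eroded_core(striatum, s_target), vv),
        "striatum_full": VOI("striatum_full", striatum, vv),
        "cerebellum": VOI("cerebellum", _eroded_core(cereb, c_target), vv),
    }


def time_activity_curves(
    images_with_times: list[tuple[float, VolumeImage]],
    vois: dict[str, VOI],
    half_life_h: float | None = None,
) -> dict[str, TimeActivityCurve]:
    """Decay-corrected VOI mean curves, one per region.

    ``half_life_h = None`` means the frames are already decay-corrected.
    """
    if len(images_with_times) < 2:
        raise ValueError("need at least two time points")
    times = np.array([t for t, _ in images_with_times], dtype=float)
    out = {}
    for name, voi in vois.items():
        means = []
        for t, img in images_with_times:
            m = voi_mean(img, voi)
            if half_life_h is not None:
                m = decay_correct(m, t, half_life_h)
            means.append(m)
        out[name] = TimeActivityCurve(name, times, np.array(means))
    return out


def fit_monoexponential(tac: TimeActivityCurve) -> tuple[float, float]:
    """Least-squares fit of ``a * 2**(-t/h)`` in log space -> (a, h).

    A flat curve has no finite clearance time and returns ``h = inf``.
    """
    if len(tac.times_h) < 3:
        raise ValueError("need at least three points")
    if np.any(tac.mean_counts <= 0):
        raise ValueError("monoexponential fit needs positive counts")
    y = np.log(tac.mean_counts)
    slope, intercept = np.polyfit(tac.times_h, y, 1)
    amplitude = float(np.exp(intercept))
    if abs(slope) < 1e-12:
        return amplitude, float("inf")
    return amplitude, float(-np.log(2.0) / slope)


def detect_equilibrium(bp_series: np.ndarray, rel_tol: float = 0.10) -> int | None:
    """Earliest index from which all later consecutive relative changes <= tol.

    The last index alone does not count (a series that never settles
    returns None).  Intended for densely, uniformly sampled BP series;
    on sparse schedules a per-step criterion conflates step size with
    kinetic drift.
    """
    bp = np.asarray(bp_series, dtype=float)
    if len(bp) < 3:
        raise ValueError("need at least three points")
    rel = np.abs(np.diff(bp)) / np.maximum(np.abs(bp[:-1]), 1e-300)
    ok = rel <= rel_tol
    for i in range(len(bp) - 1):
        if ok[i:].all():
            return i
    return None


def threshold_volume_curve(
    image: VolumeImage,
    seed_region: np.ndarray,
    thresholds,
) -> ThresholdVolumeCurve:
    """Striatal volumetry by thresholding from the structure maximum.

    For each threshold fraction theta, voxels with intensity >=
    theta x max(intensity inside ``seed_region``) are binarized and the
    volume of the connected component(s) touching the seed region is
    reported.  Keeping only the seed-connected component prevents the
    above-60% "spreading into the rest of the brain" artifact from
    inflating the volume with disconnected tissue.  Volumes are
    non-increasing in the threshold.
    """
    thr = np.asarray(thresholds, dtype=float)
    if np.any(thr <= 0) or np.any(thr > 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    seed = np.asarray(seed_region, dtype=bool)
    if seed.shape != image.shape or not seed.any():
        raise ValueError("seed region must be a non-empty mask on the image grid")
    ref_max = image.data[seed].max()
    vox = image.voxel_volume_mm3
    vols = []
    for theta in thr:
        above = image.data >= theta * ref_max
        if not above.any():
            vols.append(0.0)
            continue
        lab, n = ndimage.label(above)
        touching = np.unique(lab[seed & above])
        touching = touching[touching > 0]
        if touching.size == 0:
            vols.append(0.0)
            continue
        vols.append(float(np.isin(lab, touching).sum()) * vox)
    return ThresholdVolumeCurve(thr, np.array(vols))


def line_profile(
    image: VolumeImage,
    start_mm,
    end_mm,
    n_samples: int = 100,
) -> np.ndarray:
    """Trilinear intensity samples along a physical segment, equally spaced."""
    start = np.asarray(start_mm, dtype=float)
    end = np.asarray(end_mm, dtype=float)
    for pt in (start, end):
        idx = image.mm_to_index(pt)
        if np.any(idx < 0) or np.any(idx > np.array(image.shape) - 1):
            raise ValueError(f"profile endpoint {pt} outside the image field")
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + ts[:, None] * (end - start)[None, :]
    coords = ((pts - image.origin_mm) / image.voxel_size_mm).T
    return ndimage.map_coordinates(image.data, coords, order=1)


def _slab_sample(image: VolumeImage, geom: JaszczakGeometry, xy_mm: np.ndarray) -> np.ndarray:
    """Sample the z-averaged rod slab at in-plane points (n, 2)."""
    z_lo, z_hi = geom.z_range_mm
    zc = image.origin_mm[2] + np.arange(image.shape[2]) * image.voxel_size_mm[2]
    margin = 0.25 * (z_hi - z_lo)
    sel = (zc >= z_lo + margin) & (zc <= z_hi - margin)
    slab = image.data[:, :, sel].mean(axis=2)
    coords = ((xy_mm - image.origin_mm[:2]) / image.voxel_size_mm[:2]).T
    return ndimage.map_coordinates(slab, coords, order=1)


def resolvable_rod_size(
    image: VolumeImage,
    geometry: JaszczakGeometry,
    ratio_threshold: float = 0.75,
    n_profile: int = 41,
) -> tuple[float | None, dict[float, float]]:
    """Smallest rod diameter whose sector is resolved, and per-sector scores.

    For every adjacent rod pair in a sector, an in-plane profile is sampled
    through the two centres on the z-averaged rod slab; the score is the
    valley minimum (middle third of the profile) over the mean of the two
    peak maxima (outer thirds).  A sector is resolved when its mean
    valley-to-peak ratio is <= ``ratio_threshold`` (a near-Rayleigh
    criterion).  Returns (smallest resolved diameter or None, the
    diameter -> mean ratio map).
    """
    scores: dict[float, float] = {}
    for sector in geometry.sectors:
        ratios = []
        for i, j in sector.adjacent_pairs:
            a, b = sector.centers_mm[i], sector.centers_mm[j]
            ts = np.linspace(0.0, 1.0, n_profile)
            pts = a[None, :] + ts[:, None] * (b - a)[None, :]
            prof = _slab_sample(image, geometry, pts)
            third = n_profile // 3
            peak = 0.5 * (prof[:third].max() + prof[-third:].max())
            valley = prof[third:-third].min()
            if peak > 0:
                ratios.append(valley / peak)
        if ratios:
            scores[sector.diameter_mm] = float(np.mean(ratios))
    resolved = [d for d, r in scores.items() if r <= ratio_threshold]
    return (min(resolved) if resolved else None), scores
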