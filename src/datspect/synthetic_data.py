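"""Digital mouse-brain and hot-rod phantoms with realistic kinetics and noise.

This module generates everything the quantification pipeline consumes, so
the full workflow is exercisable without any acquired data:

* a mouse-brain label phantom with bilateral striatal hot regions, a
  cerebellar reference region and extracerebral hot structures (Harderian
  glands, eyes) that the masking stage must remove;
* a tracer kinetic model: striatal uptake-washout as a difference of
  exponentials peaking 2-3 h post-injection, monoexponential cerebellar
  clearance with a 2.5 h half-time, and multiplicative physical decay of a
  13.22 h half-life isotope (the 123-iodine label);
* a forward acquisition model standing in for the reconstructed SPECT
  image: Gaussian point-spread blur (default 0.75 mm FWHM, the system
  resolution), a sensitivity scale, and independent Poisson counting noise;
* random per-animal pose (small rigid/affine misalignment) with the ground
  truth transform returned for registration-recovery tests;
* a Jaszczak hot-rod resolution phantom with one angular sector per rod
  diameter (0.7-1.2 mm by default) on a triangular lattice with
  centre-to-centre spacing twice the diameter;
* a seeded test-retest cohort generator with per-subject parameter jitter
  and a ground-truth record per subject.

All randomness flows from explicit integer seeds; identical seeds give
identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError, GeometryError
from .image_io import AffineTransform, LabelVolume, VolumeImage, resample, write_volume

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "KineticParams",
    "AcquisitionSpec",
    "PoseSpec",
    "LABEL_LEGEND",
    "make_brain_labels",
    "tracer_activity",
    "simulate_acquisition",
    "expected_counts",
    "apply_random_pose",
    "JaszczakGeometry",
    "make_jaszczak",
    "Subject",
    "CohortDataset",
    "simulate_cohort",
    "simulate_kinetics_series",
    "write_cohort",
    "load_cohort",
    "load_config",
]

LABEL_LEGEND = {
    "background": 0,
    "brain": 1,
    "striatum_left": 2,
    "striatum_right": 3,
    "cerebellum": 4,
    "harderian": 5,
    "eye": 6,
}

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical mm coordinates."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise GeometryError(f"ellipsoid semi-axes must be positive, got {self.semi_axes_mm}")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center_mm, tuple(s * factor for s in self.semi_axes_mm))

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean inside-test for an (..., 3) array of mm coordinates."""
        c = np.asarray(self.center_mm)
        s = np.asarray(self.semi_axes_mm)
        q = (coords - c) / s
        return np.sum(q * q, axis=-1) <= 1.0


def _grid_coords(shape, voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    vs = np.asarray(voxel_size_mm, dtype=float)
    og = np.asarray(origin_mm, dtype=float)
    return np.stack([og[a] + idx[a] * vs[a] for a in range(3)], axis=-1)


def _default_anatomy(voxel: float = 0.3, grid: tuple[int, int, int] = (64, 64, 64)):
    """Anatomy roughly at adult-mouse scale on a grid centred at half extent.

    Axes: x = left-right, y = posterior-anterior, z = ventral-dorsal.
    The striatum sits anterior-dorsal, the cerebellum posterior; Harderian
    glands and eyes are anterior, outside the brain.
    """
    cx = (np.array(grid) - 1) * voxel / 2.0
    x0, y0, z0 = cx
    brain = Ellipsoid((x0, y0, z0), (4.2, 5.8, 3.6))
    stri_l = Ellipsoid((x0 - 2.1, y0 + 2.4, z0 + 0.6), (1.05, 1.7, 1.5))
    stri_r = Ellipsoid((x0 + 2.1, y0 + 2.4, z0 + 0.6), (1.05, 1.7, 1.5))
    cereb = Ellipsoid((x0, y0 - 4.0, z0 - 0.2), (2.4, 1.6, 1.5))
    harderian = (
        Ellipsoid((x0 - 2.8, y0 + 7.0, z0 - 1.6), (0.8, 0.8, 0.8)),
        Ellipsoid((x0 + 2.8, y0 + 7.0, z0 - 1.6), (0.8, 0.8, 0.8)),
    )
    eyes = (
        Ellipsoid((x0 - 3.4, y0 + 6.2, z0 + 1.0), (0.7, 0.7, 0.7)),
        Ellipsoid((x0 + 3.4, y0 + 6.2, z0 + 1.0), (0.7, 0.7, 0.7)),
    )
    return brain, stri_l, stri_r, cereb, harderian, eyes


@dataclass
class PhantomSpec:
    """Geometry of the digital mouse-head phantom.

    ``target_striatal_volume_mm3`` is the combined (left + right) striatal
    volume; the striatal ellipsoids are rescaled at rasterization time so
    the realized voxel volume lands within 5% of it.  The 22.3 mm^3 default
    is a healthy-template striatal volume at mouse scale.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.3
    brain_ellipsoid: Ellipsoid | None = None
    striatum_left: Ellipsoid | None = None
    striatum_right: Ellipsoid | None = None
    cerebellum: Ellipsoid | None = None
    harderian_glands: tuple[Ellipsoid, ...] | None = None
    eyes: tuple[Ellipsoid, ...] | None = None
    target_striatal_volume_mm3: float = 22.3

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise GeometryError("voxel size must be positive")
        if self.target_striatal_volume_mm3 <= 0:
            raise GeometryError("target striatal volume must be positive")
        defaults = _default_anatomy(self.voxel_size_mm, tuple(self.grid_shape))
        names = ("brain_ellipsoid", "striatum_left", "striatum_right",
                 "cerebellum", "harderian_glands", "eyes")
        for name, default in zip(names, defaults):
            if getattr(self, name) is None:
                setattr(self, name, default)

    @property
    def origin_mm(self) -> np.ndarray:
        return np.zeros(3)

    def voxel_sizes(self) -> np.ndarray:
        return np.full(3, float(self.voxel_size_mm))


@dataclass
class KineticParams:
    """Regional tracer kinetics in arbitrary count units.

    Striatal activity follows an uptake-washout difference of exponentials
    ``A (exp(-k_out t) - exp(-k_in t))`` whose peak time
    ``ln(k_in/k_out)/(k_in - k_out)`` lies between 2 and 3 h for the
    defaults.  The cerebellum clears monoexponentially with a 2.5 h
    half-time; unstructured brain follows the cerebellar curve scaled by
    ``background_fraction``.  When ``striatal_amplitude`` is None it is
    calibrated so that the striatal-to-cerebellar concentration ratio at
    ``bp_reference_time_h`` equals ``target_bp + 1`` — i.e. the true binding
    potential at the reference time is exactly ``target_bp``.
    """

    striatal_amplitude: float | None = None
    k_in_per_h: float = 1.2
    k_out_per_h: float = 0.12
    cerebellum_c0: float = 100.0
    clearance_half_time_h: float = 2.5
    background_fraction: float = 0.5
    extracerebral_value: float = 300.0
    target_bp: float = 6.6
    bp_reference_time_h: float = 4.0

    def __post_init__(self) -> None:
        if not (self.k_in_per_h > self.k_out_per_h > 0):
            raise ValueError("need k_in > k_out > 0")
        if self.clearance_half_time_h <= 0:
            raise ValueError("clearance half-time must be positive")
        if self.cerebellum_c0 <= 0:
            raise ValueError("cerebellar C0 must be positive")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background fraction must be in [0, 1)")

    @property
    def peak_time_h(self) -> float:
        return float(np.log(self.k_in_per_h / self.k_out_per_h)
                     / (self.k_in_per_h - self.k_out_per_h))

    def striatal_curve(self, t_h) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        return self.amplitude * (np.exp(-self.k_out_per_h * t)
                                 - np.exp(-self.k_in_per_h * t))

    def cerebellar_curve(self, t_h) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        return self.cerebellum_c0 * np.exp2(-t / self.clearance_half_time_h)

    @property
    def amplitude(self) -> float:
        if self.striatal_amplitude is not None:
            return self.striatal_amplitude
        t = self.bp_reference_time_h
        shape = np.exp(-self.k_out_per_h * t) - np.exp(-self.k_in_per_h * t)
        target_striatal = (self.target_bp + 1.0) * float(self.cerebellar_curve(t))
        return target_striatal / shape

    def true_bp(self, t_h: float | None = None) -> float:
        """Specific-to-nonspecific concentration ratio minus one at ``t_h``."""
        t = self.bp_reference_time_h if t_h is None else t_h
        return float(self.striatal_curve(t) / self.cerebellar_curve(t)) - 1.0


_EARLY_STARTS_MIN = 20.0 + 15.0 * np.arange(9)  # nine back-to-back 15-min scans


def _default_midpoints_h() -> tuple[float, ...]:
    early = (_EARLY_STARTS_MIN + 7.5) / 60.0
    return tuple(float(t) for t in early) + (4.0, 7.0)


@dataclass
class AcquisitionSpec:
    """Scan schedule and imaging-chain parameters.

    The default schedule has 11 midpoint times: nine 15-min frames
    back-to-back from 20 min post-injection (midpoints 27.5 ... 147.5 min)
    plus two 25-min frames centred at 4 h and 7 h.  ``sensitivity`` converts
    activity units to expected counts per voxel; ``psf_fwhm_mm`` is the
    reconstructed-image resolution.
    """

    scan_midpoint_times_h: tuple[float, ...] = field(default_factory=_default_midpoints_h)
    psf_fwhm_mm: float = 0.75
    sensitivity: float = 5.0
    isotope_half_life_h: float = 13.22
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.scan_midpoint_times_h, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("scan midpoints must be a non-empty sequence")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("scan midpoints must be positive and strictly increasing")
        if self.psf_fwhm_mm <= 0 or self.sensitivity <= 0 or self.isotope_half_life_h <= 0:
            raise ValueError("psf_fwhm_mm, sensitivity and isotope half-life must be positive")


@dataclass
class PoseSpec:
    """Bounds for the random per-animal misalignment."""

    max_rotation_deg: float = 10.0
    max_translation_mm: float = 1.5
    max_scale_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_rotation_deg, self.max_translation_mm, self.max_scale_fraction) < 0:
            raise ValueError("pose bounds must be non-negative")


# ---------------------------------------------------------------------------
# Label phantom
# ---------------------------------------------------------------------------

def make_brain_labels(spec: PhantomSpec) -> LabelVolume:
    """Rasterize the phantom geometry into an integer label volume.

    The striatal ellipsoids are jointly rescaled so the realized combined
    voxel volume is within 5% of ``spec.target_striatal_volume_mm3``.
    Deterministic: two calls with the same spec give identical volumes.
    """
    shape = tuple(spec.grid_shape)
    vs = spec.voxel_sizes()
    coords = _grid_coords(shape, vs)
    brain = spec.brain_ellipsoid
    lo = np.asarray(brain.center_mm) - np.asarray(brain.semi_axes_mm)
    hi = np.asarray(brain.center_mm) + np.asarray(brain.semi_axes_mm)
    extent = (np.array(shape) - 1) * vs
    if np.any(lo < -vs / 2) or np.any(hi > extent + vs / 2):
        raise GeometryError("grid too small to contain the brain ellipsoid")

    vox_vol = float(np.prod(vs))
    target_count = spec.target_striatal_volume_mm3 / vox_vol

    def striatal_count(s: float) -> int:
        return int(spec.striatum_left.scaled(s).contains(coords).sum()
                   + spec.striatum_right.scaled(s).contains(coords).sum())

    base_vol = spec.striatum_left.volume_mm3 + spec.striatum_right.volume_mm3
    mid = (spec.target_striatal_volume_mm3 / base_vol) ** (1.0 / 3.0)
    # voxel count is monotone in the scale: bisect to the nearest count
    lo, hi = 0.7 * mid, 1.4 * mid
    best_scale, best_err = mid, abs(striatal_count(mid) - target_count)
    for _ in range(30):
        s = 0.5 * (lo + hi)
        count = striatal_count(s)
        err = abs(count - target_count)
        if err < best_err:
            best_scale, best_err = s, err
        if count < target_count:
            lo = s
        else:
            hi = s
    scale = best_scale
    left = spec.striatum_left.scaled(scale)
    right = spec.striatum_right.scaled(scale)
    count = striatal_count(scale)
    realized = count * vox_vol
    if abs(realized - spec.target_striatal_volume_mm3) / spec.target_striatal_volume_mm3 > 0.05:
        raise GeometryError(
            f"could not match target striatal volume: realized {realized:.2f} mm^3 "
            f"vs target {spec.target_striatal_volume_mm3:.2f} mm^3")

    data = np.zeros(shape, dtype=np.int16)
    data[brain.contains(coords)] = LABEL_LEGEND["brain"]
    cereb_mask = spec.cerebellum.contains(coords)
    data[cereb_mask] = LABEL_LEGEND["cerebellum"]
    lmask = left.contains(coords)
    rmask = right.contains(coords)
    if np.any(lmask & cereb_mask) or np.any(rmask & cereb_mask):
        raise GeometryError("striatal ellipsoids intersect the cerebellum")
    data[lmask] = LABEL_LEGEND["striatum_left"]
    data[rmask] = LABEL_LEGEND["striatum_right"]
    brain_mask = data > 0
    for ell, code in [(e, LABEL_LEGEND["harderian"]) for e in spec.harderian_glands] + \
                     [(e, LABEL_LEGEND["eye"]) for e in spec.eyes]:
        m = ell.contains(coords)
        if np.any(m & brain_mask):
            raise GeometryError("extracerebral structure intersects the brain")
        data[m] = code
    return LabelVolume(data, vs, np.zeros(3), dict(LABEL_LEGEND))


# ---------------------------------------------------------------------------
# Kinetics and acquisition forward model
# ---------------------------------------------------------------------------

def tracer_activity(
    labels: LabelVolume,
    kp: KineticParams,
    t_h: float,
    isotope_half_life_h: float | None = None,
) -> VolumeImage:
    """Noiseless regional activity map at post-injection time ``t_h`` (hours).

    Striatal voxels follow the uptake-washout curve, cerebellar voxels the
    monoexponential clearance, unstructured brain the cerebellar curve times
    ``background_fraction``, and extracerebral structures a fixed hot value.
    If ``isotope_half_life_h`` is given, physical decay ``2**(-t/T_half)``
    is applied multiplicatively to the whole map.
    """
    if t_h < 0:
        raise ValueError("post-injection time must be non-negative")
    s_val = float(kp.striatal_curve(t_h))
    c_val = float(kp.cerebellar_curve(t_h))
    out = np.zeros(labels.shape, dtype=np.float64)
    out[labels.mask("brain")] = kp.background_fraction * c_val
    out[labels.mask("cerebellum")] = c_val
    out[labels.mask("striatum_left", "striatum_right")] = s_val
    out[labels.mask("harderian", "eye")] = kp.extracerebral_value
    if isotope_half_life_h is not None:
        out *= 2.0 ** (-t_h / isotope_half_life_h)
    return VolumeImage(out, labels.voxel_size_mm.copy(), labels.origin_mm.copy())


def simulate_acquisition(
    activity: VolumeImage,
    acq: AcquisitionSpec,
    seed: int | np.random.Generator | None = None,
) -> VolumeImage:
    """Forward model for one reconstructed frame: PSF blur, scale, Poisson.

    The Gaussian blur with ``acq.psf_fwhm_mm`` stands in for the system
    resolution of the reconstructed image; ``acq.sensitivity`` converts the
    blurred activity to expected counts per voxel, from which one
    independent Poisson draw per voxel is taken.  Output voxel values are
    non-negative integers (stored as floats); a fixed seed reproduces the
    image exactly.
    """
    if np.any(activity.data < 0):
        raise ValueError("activity must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(acq.seed if seed is None else seed)
    sigma_vox = acq.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / activity.voxel_size_mm
    blurred = ndimage.gaussian_filter(activity.data, sigma=sigma_vox)
    expected = np.clip(acq.sensitivity * blurred, 0.0, None)
    counts = rng.poisson(expected).astype(np.float64)
    return activity.with_data(counts)


def expected_counts(activity: VolumeImage, acq: AcquisitionSpec) -> VolumeImage:
    """Noise-free expectation of :func:`simulate_acquisition`."""
    sigma_vox = acq.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / activity.voxel_size_mm
    blurred = ndimage.gaussian_filter(activity.data, sigma=sigma_vox)
    return activity.with_data(acq.sensitivity * blurred)


def apply_random_pose(
    image: VolumeImage,
    pose: PoseSpec,
    seed: int | np.random.Generator | None = None,
) -> tuple[VolumeImage, AffineTransform]:
    """Resample the image through a random small affine pose.

    Returns the misaligned image and the ground-truth transform T (mapping
    posed-space physical coordinates into the original image's space, i.e.
    ``posed = resample(image, T)``).  Rotation, translation and per-axis
    scale are drawn uniformly within the spec bounds, about the grid centre.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(pose.seed if seed is None else seed)
    rot = rng.uniform(-pose.max_rotation_deg, pose.max_rotation_deg, 3)
    trans = rng.uniform(-pose.max_translation_mm, pose.max_translation_mm, 3)
    scales = np.log(1.0 + rng.uniform(-pose.max_scale_fraction, pose.max_scale_fraction, 3))
    t = AffineTransform.from_params(rot, trans, scales, center_mm=image.center_mm)
    return resample(image, t), t


# ---------------------------------------------------------------------------
# Jaszczak hot-rod phantom
# ---------------------------------------------------------------------------

@dataclass
class SectorGeometry:
    diameter_mm: float
    centers_mm: np.ndarray            # (n, 2) in-plane rod centres
    adjacent_pairs: list[tuple[int, int]]


@dataclass
class JaszczakGeometry:
    sectors: list[SectorGeometry]
    cylinder_center_mm: np.ndarray    # in-plane (x, y)
    cylinder_radius_mm: float
    z_range_mm: tuple[float, float]
    activity_level: float


def make_jaszczak(
    rod_diameters_mm=(0.7, 0.8, 0.9, 1.0, 1.1, 1.2),
    activity_level: float = 1000.0,
    grid_shape: tuple[int, int, int] = (120, 120, 30),
    voxel_size_mm: float = 0.15,
    cylinder_radius_mm: float = 7.6,
    rod_length_mm: float = 3.0,
) -> tuple[VolumeImage, JaszczakGeometry]:
    """Hot-rod resolution phantom: one angular sector per rod diameter.

    Rods run along z on a triangular lattice with centre-to-centre spacing
    twice the rod diameter, uniform ``activity_level`` inside rods and zero
    elsewhere.  In-plane rod cross-sections are anti-aliased by 3x
    supersampling.  Sub-Nyquist sectors (diameter < 2 voxels) raise a
    warning but are still generated.
    """
    diameters = [float(d) for d in rod_diameters_mm]
    if any(d <= 0 for d in diameters):
        raise GeometryError("rod diameters must be positive")
    for d in diameters:
        if d < 2.0 * voxel_size_mm:
            warnings.warn(f"rod diameter {d} mm below twice the voxel size "
                          f"({voxel_size_mm} mm); sector is sub-Nyquist", stacklevel=2)
    nx, ny, nz = grid_shape
    center = np.array([(nx - 1) * voxel_size_mm / 2.0, (ny - 1) * voxel_size_mm / 2.0])
    if cylinder_radius_mm > min(center) - voxel_size_mm:
        raise GeometryError("cylinder does not fit in the grid")
    sector_span = 2.0 * np.pi / len(diameters)
    inner_radius = 1.5
    sectors: list[SectorGeometry] = []
    for s, d in enumerate(diameters):
        theta0 = s * sector_span
        bisector = theta0 + sector_span / 2.0
        spacing = 2.0 * d
        u = spacing * np.array([np.cos(bisector), np.sin(bisector)])
        v = spacing * np.array([np.cos(bisector + np.pi / 3), np.sin(bisector + np.pi / 3)])
        n_max = int(np.ceil(2.0 * cylinder_radius_mm / spacing)) + 2
        pts = []
        for i in range(-n_max, n_max + 1):
            for j in range(-n_max, n_max + 1):
                p = i * u + j * v
                r = np.hypot(*p)
                if not (inner_radius + d / 2.0 <= r <= cylinder_radius_mm - d / 2.0 - 0.1):
                    continue
                ang = np.arctan2(p[1], p[0]) % (2.0 * np.pi)
                # angular inset so the whole rod disc stays inside the sector
                margin = np.arcsin(min(1.0, (d / 2.0 + 0.1) / r))
                lo = (theta0 + margin) % (2.0 * np.pi)
                rel = (ang - theta0) % (2.0 * np.pi)
                if margin <= rel <= sector_span - margin:
                    pts.append(p + center)
        centers = np.array(pts) if pts else np.empty((0, 2))
        pairs = []
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if abs(np.linalg.norm(centers[i] - centers[j]) - spacing) < 0.01 * spacing:
                    pairs.append((i, j))
        sectors.append(SectorGeometry(d, centers, pairs))

    # supersampled in-plane occupancy
    ss = 3
    fine = np.zeros((nx * ss, ny * ss), dtype=bool)
    fine_step = voxel_size_mm / ss
    for sec in sectors:
        r = sec.diameter_mm / 2.0
        for cxy in sec.centers_mm:
            i0 = int(np.floor((cxy[0] - r) / fine_step + (ss - 1) / 2.0)) - 1
            j0 = int(np.floor((cxy[1] - r) / fine_step + (ss - 1) / 2.0)) - 1
            n = int(np.ceil(2 * r / fine_step)) + 3
            ii = np.arange(max(i0, 0), min(i0 + n, nx * ss))
            jj = np.arange(max(j0, 0), min(j0 + n, ny * ss))
            if len(ii) == 0 or len(jj) == 0:
                continue
            # fine-grid sample positions (voxel centres subdivided ss-fold)
            xs = (ii - (ss - 1) / 2.0) * fine_step
            ys = (jj - (ss - 1) / 2.0) * fine_step
            dist2 = (xs[:, None] - cxy[0]) ** 2 + (ys[None, :] - cxy[1]) ** 2
            patch = dist2 <= r * r
            fine[np.ix_(ii, jj)] |= patch
    occupancy = fine.reshape(nx, ss, ny, ss).mean(axis=(1, 3))

    z_extent = (nz - 1) * voxel_size_mm
    z_lo = (z_extent - rod_length_mm) / 2.0
    z_hi = z_lo + rod_length_mm
    zc = np.arange(nz) * voxel_size_mm
    z_mask = (zc >= z_lo) & (zc <= z_hi)
    data = np.zeros(grid_shape, dtype=np.float64)
    data[:, :, z_mask] = (activity_level * occupancy)[:, :, None]
    image = VolumeImage(data, np.full(3, voxel_size_mm), np.zeros(3))
    geom = JaszczakGeometry(sectors, center, cylinder_radius_mm, (z_lo, z_hi), activity_level)
    return image, geom


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    """One simulated animal with its ground truth."""

    subject_id: int
    labels: LabelVolume                  # canonical (pre-pose) anatomy
    kinetics: KineticParams
    true_bp: float
    true_striatal_volume_mm3: float
    image_test: VolumeImage
    image_retest: VolumeImage
    pose_test: AffineTransform
    pose_retest: AffineTransform
    scan_time_h: float
    seed: int


@dataclass
class CohortDataset:
    subjects: list[Subject]
    phantom_spec: PhantomSpec
    acquisition: AcquisitionSpec
    pose_spec: PoseSpec
    inter_subject_cv: float
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)


#: retest/test injected-dose ratio (0.94 vs 1.12 MBq/g body weight)
RETEST_DOSE_RATIO = 0.94 / 1.12


def simulate_cohort(
    n_subjects: int = 5,
    spec: PhantomSpec | None = None,
    kp: KineticParams | None = None,
    acq: AcquisitionSpec | None = None,
    pose: PoseSpec | None = None,
    inter_subject_cv: float = 0.10,
    seed: int = 0,
    scan_time_h: float = 4.0,
    with_pose: bool = True,
) -> CohortDataset:
    """Simulate a seeded test-retest cohort imaged at ``scan_time_h``.

    Per subject, the striatal target volume and the injected-dose scale are
    jittered with coefficient of variation ``inter_subject_cv`` (uptake
    rate constants with half that CV), the striatal amplitude is
    recalibrated so every subject's true binding potential equals the
    configured target, and test and retest frames are simulated with
    independent Poisson noise, independent poses, and the retest
    injected-dose ratio of the study design (0.94/1.12).
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    spec = spec or PhantomSpec()
    kp = kp or KineticParams()
    acq = acq or AcquisitionSpec()
    pose = pose or PoseSpec()
    rng = np.random.default_rng(seed)
    subjects = []
    for sid in range(n_subjects):
        jv, jd, jk = rng.normal(0.0, 1.0, 3)
        vol = spec.target_striatal_volume_mm3 * max(0.3, 1.0 + inter_subject_cv * jv)
        dose = max(0.3, 1.0 + inter_subject_cv * jd)
        kshift = 1.0 + 0.5 * inter_subject_cv * jk
        s_spec = replace(spec, target_striatal_volume_mm3=vol)
        s_kp = replace(kp,
                       striatal_amplitude=None,
                       cerebellum_c0=kp.cerebellum_c0 * dose,
                       k_in_per_h=kp.k_in_per_h * kshift,
                       k_out_per_h=kp.k_out_per_h * kshift,
                       extracerebral_value=kp.extracerebral_value * dose)
        labels = make_brain_labels(s_spec)
        activity = tracer_activity(labels, s_kp, scan_time_h, acq.isotope_half_life_h)
        retest_activity = activity.with_data(activity.data * RETEST_DOSE_RATIO)
        frames = []
        poses = []
        for act in (activity, retest_activity):
            frame = simulate_acquisition(act, acq, rng)
            if with_pose:
                frame, t = apply_random_pose(frame, pose, rng)
            else:
                t = AffineTransform.identity()
            frames.append(frame)
            poses.append(t)
        subjects.append(Subject(
            subject_id=sid,
            labels=labels,
            kinetics=s_kp,
            true_bp=s_kp.true_bp(scan_time_h),
            true_striatal_volume_mm3=labels.region_volume_mm3("striatum_left",
                                                              "striatum_right"),
            image_test=frames[0],
            image_retest=frames[1],
            pose_test=poses[0],
            pose_retest=poses[1],
            scan_time_h=scan_time_h,
            seed=seed,
        ))
    return CohortDataset(subjects, spec, acq, pose, inter_subject_cv, seed)


def simulate_kinetics_series(
    spec: PhantomSpec | None = None,
    kp: KineticParams | None = None,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
) -> tuple[LabelVolume, list[tuple[float, VolumeImage]]]:
    """Simulate one kinetics animal imaged at every default scan midpoint.

    Returns the (canonical, pose-free) label anatomy and the list of
    (midpoint time in h, noisy frame) pairs, physical decay included.
    """
    spec = spec or PhantomSpec()
    kp = kp or KineticParams()
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed)
    labels = make_brain_labels(spec)
    frames = []
    for t in acq.scan_midpoint_times_h:
        act = tracer_activity(labels, kp, t, acq.isotope_half_life_h)
        frames.append((float(t), simulate_acquisition(act, acq, rng)))
    return labels, frames


# ---------------------------------------------------------------------------
# On-disk cohort and configuration
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, outdir) -> Path:
    """Write NIfTI volumes plus a JSON ground-truth sidecar per subject."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        stem = out / f"subject_{sub.subject_id:02d}"
        write_volume(sub.image_test, f"{stem}_test.nii")
        write_volume(sub.image_retest, f"{stem}_retest.nii")
        write_volume(sub.labels.as_image(), f"{stem}_labels.nii")
        sidecar = {
            "subject_id": sub.subject_id,
            "true_bp": sub.true_bp,
            "true_striatal_volume_mm3": sub.true_striatal_volume_mm3,
            "scan_time_h": sub.scan_time_h,
            "isotope_half_life_h": cohort.acquisition.isotope_half_life_h,
            "seed": sub.seed,
            "pose_test": {"matrix": sub.pose_test.matrix.tolist(),
                          "translation_mm": sub.pose_test.translation_mm.tolist()},
            "pose_retest": {"matrix": sub.pose_retest.matrix.tolist(),
                            "translation_mm": sub.pose_retest.translation_mm.tolist()},
            "label_legend": sub.labels.legend,
        }
        with open(f"{stem}_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)
    return out


def load_cohort(indir) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort` back from disk."""
    from .image_io import read_volume

    indir = Path(indir)
    truth_files = sorted(indir.glob("subject_*_truth.json"))
    if not truth_files:
        raise FileNotFoundError(f"no subject sidecars found in {indir}")
    subjects = []
    half_life = 13.22
    for tf in truth_files:
        with open(tf) as fh:
            meta = json.load(fh)
        stem = str(tf)[: -len("_truth.json")]
        labels_img = read_volume(f"{stem}_labels.nii")
        labels = LabelVolume(np.rint(labels_img.data).astype(np.int16),
                             labels_img.voxel_size_mm, labels_img.origin_mm,
                             {k: int(v) for k, v in meta["label_legend"].items()})
        half_life = meta.get("isotope_half_life_h", half_life)
        subjects.append(Subject(
            subject_id=meta["subject_id"],
            labels=labels,
            kinetics=KineticParams(),
            true_bp=meta["true_bp"],
            true_striatal_volume_mm3=meta["true_striatal_volume_mm3"],
            image_test=read_volume(f"{stem}_test.nii"),
            image_retest=read_volume(f"{stem}_retest.nii"),
            pose_test=AffineTransform(np.array(meta["pose_test"]["matrix"]),
                                      np.array(meta["pose_test"]["translation_mm"])),
            pose_retest=AffineTransform(np.array(meta["pose_retest"]["matrix"]),
                                        np.array(meta["pose_retest"]["translation_mm"])),
            scan_time_h=meta["scan_time_h"],
            seed=meta["seed"],
        ))
    spec = PhantomSpec(grid_shape=subjects[0].labels.shape,
                       voxel_size_mm=float(subjects[0].labels.voxel_size_mm[0]))
    acq = AcquisitionSpec(isotope_half_life_h=half_life)
    return CohortDataset(subjects, spec, acq, PoseSpec(), 0.0,
                         subjects[0].seed)


_CONFIG_SECTIONS = {
    "phantom": PhantomSpec,
    "kinetics": KineticParams,
    "acquisition": AcquisitionSpec,
    "pose": PoseSpec,
}
_COHORT_KEYS = {"n_subjects", "inter_subject_cv", "seed", "scan_time_h"}


def load_config(path) -> dict:
    """Load a TOML run configuration.

    Sections [phantom], [kinetics], [acquisition], [pose] map onto the
    corresponding dataclasses; [cohort] holds ``n_subjects``,
    ``inter_subject_cv``, ``seed`` and ``scan_time_h``.  Unknown sections or
    keys raise :class:`ConfigError` listing the offenders.
    """
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown_sections = set(raw) - set(_CONFIG_SECTIONS) - {"cohort"}
    if unknown_sections:
        raise ConfigError(f"unknown config sections: {sorted(unknown_sections)}")
    out: dict = {}
    for name, cls in _CONFIG_SECTIONS.items():
        section = dict(raw.get(name, {}))
        allowed = set(cls.__dataclass_fields__)
        bad = set(section) - allowed
        if bad:
            raise ConfigError(f"unknown keys in [{name}]: {sorted(bad)}")
        for key in ("grid_shape", "scan_midpoint_times_h"):
            if key in section:
                section[key] = tuple(section[key])
        out[name] = cls(**section)
    cohort = dict(raw.get("cohort", {}))
    bad = set(cohort) - _COHORT_KEYS
    if bad:
        raise ConfigError(f"unknown keys in [cohort]: {sorted(bad)}")
    out["cohort"] = cohort
    return out
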