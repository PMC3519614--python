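"""Affine image registration by mutual-information maximization.

Mutual information (MI) of the joint intensity histogram is the similarity
measure; the transform class is the full 12-parameter affine (3 rotations,
3 translations, 3 log-scales, 3 shears, applied about the fixed-image
centre).  The search is multiresolution: a Gaussian pyramid is built for
both images and a derivative-free optimizer (Powell by default, Nelder-Mead
available) maximizes MI at each level, warm-starting the next; the degrees
of freedom are staged coarse-to-fine (rigid, rigid + scales, full affine)
with a final rigid polish.  MI is computed over the overlap domain
(fixed voxels whose pulled coordinate lands inside the moving image), with
a minimum-overlap fraction enforced so the optimizer cannot cheat by
shrinking the overlap.

Everything is deterministic given the settings and the initial transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image_io import AffineTransform, VolumeImage, field_of_view_mask, resample

logger = logging.getLogger(__name__)

__all__ = [
    "MISettings",
    "RegistrationResult",
    "joint_histogram",
    "mutual_information",
    "mi_from_histogram",
    "register_affine",
    "compose",
    "invert",
    "transform_discrepancy",
]


def compose(t1: AffineTransform, t2: AffineTransform) -> AffineTransform:
    """Affine composition ``t1 o t2`` (apply ``t2`` first)."""
    return t1.compose(t2)


def invert(t: AffineTransform) -> AffineTransform:
    return t.invert()


def transform_discrepancy(
    t1: AffineTransform,
    t2: AffineTransform,
    center_mm,
) -> tuple[float, float]:
    """(translation error in mm at ``center_mm``, rotation error in degrees).

    The translation error is the displacement between the two transforms'
    images of the centre point; the rotation error is the angle of the
    polar-rotation factor of ``M1 @ inv(M2)``.
    """
    c = np.asarray(center_mm, dtype=float)
    trans_err = float(np.linalg.norm(t1.apply(c) - t2.apply(c)))
    rel = AffineTransform(t1.matrix @ np.linalg.inv(t2.matrix))
    return trans_err, rel.rotation_angle_deg()


# ---------------------------------------------------------------------------
# Joint histogram and mutual information
# ---------------------------------------------------------------------------

def _edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def joint_histogram(
    a: VolumeImage | np.ndarray,
    b: VolumeImage | np.ndarray,
    n_bins: int = 32,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """2D count table of paired intensities over the (masked) common grid.

    Bin edges span each image's [min, max] over the contributing voxels with
    equal widths; the table sums to the number of contributing voxels.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 bins")
    av = a.data if isinstance(a, VolumeImage) else np.asarray(a)
    bv = b.data if isinstance(b, VolumeImage) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValueError(f"grid mismatch: {av.shape} vs {bv.shape}")
    if mask is not None:
        av, bv = av[mask], bv[mask]
    else:
        av, bv = av.ravel(), bv.ravel()
    if av.size == 0:
        raise ValueError("empty overlap: no contributing voxels")
    hist, _, _ = np.histogram2d(av, bv, bins=[_edges(av, n_bins), _edges(bv, n_bins)])
    return hist


def mi_from_histogram(hist: np.ndarray) -> float:
    """Mutual information in nats of a joint count table."""
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def mutual_information(
    a: VolumeImage | np.ndarray,
    b: VolumeImage | np.ndarray,
    n_bins: int = 32,
    mask: np.ndarray | None = None,
) -> float:
    """MI (nats) of two images on a common grid; symmetric and >= 0."""
    return mi_from_histogram(joint_histogram(a, b, n_bins, mask))


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass
class MISettings:
    """Knobs of the multiresolution MI optimizer.

    ``parameter_scales`` sets the natural step of each parameter block
    (rotation deg, translation mm, log-scale, shear) so a unit move of any
    scaled coordinate produces a comparable MI change.  ``max_evals`` and
    ``simplex_step`` may be a scalar or one value per pyramid level
    (coarsest first).
    """

    n_bins: int = 32
    pyramid_levels: int = 3
    restarts: int = 2
    optimizer: str = "powell"  # "powell" or "nelder-mead", both derivative-free
    parameter_scales: tuple[float, float, float, float] = (1.0, 0.3, 0.01, 0.01)
    convergence_tol: float = 1e-4
    max_evals: tuple[int, ...] | int = (800, 600, 500)
    simplex_step: tuple[float, ...] | float = (2.0, 0.5, 0.15)
    min_overlap_fraction: float = 0.5
    sample_stride: tuple[int, ...] | int = (1, 1, 2)  # fixed-grid subsampling per level
    degrees_of_freedom: int = 12  # 6 = rigid, 9 = rigid + scale, 12 = full affine

    def __post_init__(self) -> None:
        if self.n_bins < 4:
            raise ValueError("need at least 4 histogram bins")
        if self.pyramid_levels < 1:
            raise ValueError("need at least one pyramid level")
        if self.degrees_of_freedom not in (6, 9, 12):
            raise ValueError("degrees_of_freedom must be 6, 9 or 12")

    def _per_level(self, value, level: int):
        if np.isscalar(value):
            return value
        return value[min(level, len(value) - 1)]


@dataclass
class RegistrationResult:
    transform: AffineTransform
    final_mi: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)


def _scale_vector(settings: MISettings) -> np.ndarray:
    r, t, s, h = settings.parameter_scales
    return np.array([r] * 3 + [t] * 3 + [s] * 3 + [h] * 3)


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> AffineTransform:
    return AffineTransform.from_params(p[0:3], p[3:6], p[6:9], p[9:12], center)


def _downsample(image: VolumeImage) -> VolumeImage:
    sm = ndimage.gaussian_filter(image.data, sigma=1.0)
    return VolumeImage(sm[::2, ::2, ::2], image.voxel_size_mm * 2.0,
                       image.origin_mm.copy())


def _pyramid(image: VolumeImage, levels: int) -> list[VolumeImage]:
    pyr = [image]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 8:
            break
        pyr.append(_downsample(pyr[-1]))
    return pyr[::-1]  # coarsest first


def _overlap_mi(moving: VolumeImage, fixed: VolumeImage, t: AffineTransform,
                n_bins: int, min_overlap: float) -> float:
    """MI over the overlap domain; -inf-like penalty when overlap too small."""
    warped = resample(moving, t, fixed, "trilinear")
    mask = field_of_view_mask(moving, t, fixed)
    frac = mask.mean()
    if frac < min_overlap:
        return -1.0 + frac  # steers the optimizer back toward overlap
    return mi_from_histogram(joint_histogram(fixed.data, warped.data, n_bins, mask))


class _LevelSampler:
    """Fast MI evaluation on a (possibly subsampled) fixed-voxel lattice.

    Precomputes the fixed-grid sample indices and intensities once per
    pyramid level; each candidate transform then costs one coordinate
    matmul, one trilinear interpolation of the moving image at the in-field
    samples, and one bincount joint histogram.
    """

    def __init__(self, moving: VolumeImage, fixed: VolumeImage,
                 n_bins: int, stride: int, min_overlap: float) -> None:
        self.moving = moving
        self.n_bins = n_bins
        self.min_overlap = min_overlap
        sl = (slice(None, None, stride),) * 3
        idx = np.indices(fixed.shape, dtype=np.float64)[(slice(None),) + sl]
        self.idx = idx.reshape(3, -1)
        self.fixed_vals = fixed.data[sl].ravel()
        self.fixed_voxel = fixed.voxel_size_mm
        self.fixed_origin = fixed.origin_mm
        self.bounds = np.array(moving.shape, dtype=float) - 1.0

    def mi(self, t: AffineTransform) -> float:
        mat = (t.matrix * self.fixed_voxel[None, :]) / self.moving.voxel_size_mm[:, None]
        off = (t.matrix @ self.fixed_origin + t.translation_mm
               - self.moving.origin_mm) / self.moving.voxel_size_mm
        pulled = mat @ self.idx + off[:, None]
        inside = ((pulled >= 0.0) & (pulled <= self.bounds[:, None])).all(axis=0)
        frac = inside.mean()
        if frac < self.min_overlap:
            return -1.0 + frac
        vals = ndimage.map_coordinates(self.moving.data, pulled[:, inside], order=1)
        a = self.fixed_vals[inside]
        nb = self.n_bins
        joint = np.bincount(_bin_index(a, nb) * nb + _bin_index(vals, nb),
                            minlength=nb * nb).reshape(nb, nb)
        return mi_from_histogram(joint)


def _bin_index(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo = values.min()
    hi = values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.intp)
    ix = ((values - lo) * (n_bins / (hi - lo))).astype(np.intp)
    return np.minimum(ix, n_bins - 1)


def _active_mask(dof: int) -> np.ndarray:
    active = np.zeros(12, dtype=bool)
    active[:6] = True
    if dof >= 9:
        active[6:9] = True
    if dof == 12:
        active[9:12] = True
    return active


def register_affine(
    moving: VolumeImage,
    fixed: VolumeImage,
    settings: MISettings | None = None,
    init: AffineTransform | None = None,
) -> RegistrationResult:
    """Find the affine transform maximizing MI between ``fixed`` and ``moving``.

    The returned transform maps fixed-space physical coordinates into the
    moving image (use it directly with :func:`~datspect.image_io.resample`
    to bring ``moving`` onto the fixed grid).

    The degrees of freedom are staged over the pyramid — rigid at the
    coarsest level, rigid + scales next, the full requested model at the
    finest — and a final rigid-only polish runs at full resolution; staging
    keeps the coarse search low-dimensional and the subtle rotation /
    translation refinement well-conditioned.  The final MI is never worse
    than the MI at the initial transform: if the search ends below it, the
    initial transform is returned with a warning.  Candidate optima within
    ``convergence_tol`` of each other are tie-broken toward the smaller
    translation norm, making the result deterministic.
    """
    settings = settings or MISettings()
    init = init or AffineTransform.identity()
    if moving.data.max() <= 0 or fixed.data.max() <= 0:
        raise ValueError("both images need positive intensity for registration")
    center = fixed.center_mm
    scales = _scale_vector(settings)

    mov_pyr = _pyramid(moving, settings.pyramid_levels)
    fix_pyr = _pyramid(fixed, settings.pyramid_levels)
    levels = min(len(mov_pyr), len(fix_pyr))
    mov_pyr, fix_pyr = mov_pyr[-levels:], fix_pyr[-levels:]
    dof_schedule = [min(settings.degrees_of_freedom, (6, 9, 12)[min(lv, 2)])
                    for lv in range(levels)]

    p = np.zeros(12)
    total_evals = 0
    trace = []
    converged = True

    def optimize_stage(sampler, active, max_evals, xtol):
        nonlocal total_evals, converged
        def fun(z_active):
            q = p.copy()
            q[active] = z_active * scales[active]
            t = compose(init, _params_to_transform(q, center))
            return -sampler.mi(t)

        best_z = (p[active] / scales[active]).copy()
        best_f = fun(best_z)
        stage_settled = False
        for _ in range(max(1, settings.restarts)):
            if settings.optimizer == "powell":
                res = optimize.minimize(
                    fun, best_z, method="Powell",
                    options={"maxfev": max_evals, "xtol": xtol,
                             "ftol": settings.convergence_tol / 10.0})
            else:
                n = best_z.size
                simplex = np.tile(best_z, (n + 1, 1))
                simplex[1:] += np.eye(n) * float(
                    settings._per_level(settings.simplex_step, 0))
                res = optimize.minimize(
                    fun, best_z, method="Nelder-Mead",
                    options={"maxfev": max_evals,
                             "fatol": settings.convergence_tol,
                             "xatol": xtol, "initial_simplex": simplex,
                             "adaptive": True})
            total_evals += res.nfev
            cand_z, cand_f = res.x, res.fun
            if cand_f < best_f - settings.convergence_tol:
                best_z, best_f = cand_z, cand_f
            elif abs(cand_f - best_f) <= settings.convergence_tol:
                # tie-break toward the smaller translation norm
                q_c, q_b = p.copy(), p.copy()
                q_c[active] = cand_z * scales[active]
                q_b[active] = best_z * scales[active]
                if np.linalg.norm(q_c[3:6]) < np.linalg.norm(q_b[3:6]):
                    best_z, best_f = cand_z, cand_f
            # settled: the optimizer either finished within budget or a
            # further run no longer improves the objective meaningfully
            stage_settled = bool(res.success) or \
                cand_f >= best_f - settings.convergence_tol
        if not stage_settled:
            converged = False
        p[active] = best_z * scales[active]
        return -best_f

    for level, (mov_l, fix_l) in enumerate(zip(mov_pyr, fix_pyr)):
        stride = int(settings._per_level(settings.sample_stride, level))
        sampler = _LevelSampler(mov_l, fix_l, settings.n_bins, stride,
                                settings.min_overlap_fraction)
        max_evals = int(settings._per_level(settings.max_evals, level))
        mi_level = optimize_stage(sampler, _active_mask(dof_schedule[level]),
                                  max_evals, xtol=1e-3)
        trace.append({"level": level, "shape": fix_l.shape,
                      "dof": dof_schedule[level], "mi": mi_level,
                      "evals": total_evals})

    # rigid polish at full resolution
    stride = int(settings._per_level(settings.sample_stride, levels - 1))
    sampler = _LevelSampler(mov_pyr[-1], fix_pyr[-1], settings.n_bins, stride,
                            settings.min_overlap_fraction)
    mi_polish = optimize_stage(sampler, _active_mask(6), 400, xtol=5e-4)
    trace.append({"level": "polish", "shape": fix_pyr[-1].shape, "dof": 6,
                  "mi": mi_polish, "evals": total_evals})

    final = compose(init, _params_to_transform(p, center))
    final_mi = _overlap_mi(moving, fixed, final, settings.n_bins,
                           settings.min_overlap_fraction)
    init_mi = _overlap_mi(moving, fixed, init, settings.n_bins,
                          settings.min_overlap_fraction)
    if final_mi < init_mi:
        warnings.warn("registration ended below the initial MI; "
                      "returning the initial transform", stacklevel=2)
        return RegistrationResult(init, init_mi, total_evals, False, trace)
    return RegistrationResult(final, final_mi, total_evals, converged, trace)
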