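"""Volumetric image container, file I/O, resampling and principal-axes pre-alignment.

The pipeline's universal currency is :class:`VolumeImage`: a 3D intensity
grid with axis-aligned physical geometry (voxel size and origin in mm).
Physical coordinates follow the centre-of-voxel convention

    x_mm = origin_mm + index * voxel_size_mm

with array axes (i, j, k) mapped to physical axes (x, y, z).  Spatial maps
are 12-parameter affine transforms acting on physical coordinates; by
convention a transform used for resampling maps *fixed*-space (output)
coordinates to *moving*-space (input) coordinates, i.e. resampling is a
pull operation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import FormatError, GeometryError, HeaderError, TransformError

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "resample",
    "field_of_view_mask",
    "straighten",
]


@dataclass
class VolumeImage:
    """A 3D image with isotropic or anisotropic voxels on an axis-aligned grid.

    Parameters
    ----------
    data
        3D array of finite intensities.
    voxel_size_mm
        Per-axis voxel edge length in mm (all > 0).
    origin_mm
        Physical coordinate of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise GeometryError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        if np.any(self.voxel_size_mm <= 0):
            raise GeometryError(f"voxel size must be positive, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def center_mm(self) -> np.ndarray:
        """Physical coordinate of the grid centre."""
        return self.origin_mm + (np.array(self.shape) - 1) / 2.0 * self.voxel_size_mm

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm matrix (diagonal by construction)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(idx, dtype=float) * self.voxel_size_mm

    def mm_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin_mm) / self.voxel_size_mm

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """New image with the same geometry and different voxel values."""
        return VolumeImage(np.asarray(data), self.voxel_size_mm.copy(), self.origin_mm.copy())

    def copy(self) -> "VolumeImage":
        return self.with_data(self.data.copy())


@dataclass
class LabelVolume:
    """Integer region map sharing the grid conventions of :class:`VolumeImage`.

    ``legend`` maps region names (e.g. ``"striatum_left"``) to integer codes;
    0 is reserved for background.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    origin_mm: np.ndarray
    legend: dict[str, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=np.float64).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named regions."""
        codes = [self.legend[n] for n in names]
        return np.isin(self.data, codes)

    def region_volume_mm3(self, *names: str) -> float:
        return float(np.count_nonzero(self.mask(*names))) * self.voxel_volume_mm3

    def as_image(self) -> VolumeImage:
        return VolumeImage(self.data.astype(np.float64), self.voxel_size_mm.copy(),
                           self.origin_mm.copy())


@dataclass
class AffineTransform:
    """Affine map ``x -> matrix @ x + translation`` on physical coordinates (mm).

    Used for resampling with the pull convention: the transform maps
    fixed-space output coordinates into the moving image's space.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(3, 3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise TransformError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_params(
        cls,
        rotations_deg: np.ndarray = (0.0, 0.0, 0.0),
        translation_mm: np.ndarray = (0.0, 0.0, 0.0),
        log_scales: np.ndarray = (0.0, 0.0, 0.0),
        shears: np.ndarray = (0.0, 0.0, 0.0),
        center_mm: np.ndarray = (0.0, 0.0, 0.0),
    ) -> "AffineTransform":
        """Build a transform from 12 interpretable parameters.

        The linear part is R @ S @ H (rotations about x, y, z applied in that
        order, diagonal scales ``exp(log_scales)``, unit upper-triangular
        shears); the map rotates about ``center_mm`` and then translates.
        """
        rx, ry, rz = np.deg2rad(np.asarray(rotations_deg, dtype=float))
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        S = np.diag(np.exp(np.asarray(log_scales, dtype=float)))
        h1, h2, h3 = np.asarray(shears, dtype=float)
        H = np.array([[1.0, h1, h2], [0.0, 1.0, h3], [0.0, 0.0, 1.0]])
        M = Rz @ Ry @ Rx @ S @ H
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(translation_mm, dtype=float) + c - M @ c
        return cls(M, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map physical points; accepts shape (3,) or (n, 3)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation_mm

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.translation_mm + self.translation_mm)

    def invert(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation_mm)

    def rotation_angle_deg(self) -> float:
        """Rotation angle of the polar-decomposition rotation factor."""
        u, _, vt = np.linalg.svd(self.matrix)
        r = u @ vt
        if np.linalg.det(r) < 0:  # reflection: report as a large angle
            return 180.0
        tr = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(tr)))

    def is_identity(self, tol: float = 1e-10) -> bool:
        return (np.allclose(self.matrix, np.eye(3), atol=tol)
                and np.allclose(self.translation_mm, 0.0, atol=tol))


# ---------------------------------------------------------------------------
# File I/O (NIfTI-1 and Analyze 7.5 via nibabel)
# ---------------------------------------------------------------------------

def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.hdr/.img) volume.

    Analyze 7.5 carries no formal orientation; such files are read assuming
    the package's native axis order, with a logged warning.  Orientation
    information beyond axis-aligned scaling in a NIfTI affine is dropped
    (with a warning): downstream registration operates on physical
    coordinates and recovers residual rotation.
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise FormatError(f"cannot read {path!r} as NIfTI-1/Analyze 7.5: {exc}") from exc
    try:
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise HeaderError(f"truncated or inconsistent image data in {path!r}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    aff = img.affine
    if aff is None or isinstance(img, nib.AnalyzeImage) and not isinstance(img, nib.Nifti1Image):
        logger.warning("Analyze 7.5 file %s has no orientation; assuming native axis order", path)
    if aff is None:
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        return VolumeImage(np.asarray(data, dtype=np.float64), zooms, np.zeros(3))
    linear = aff[:3, :3]
    voxel = np.linalg.norm(linear, axis=0)
    if np.any(voxel <= 0):
        raise HeaderError(f"non-positive voxel size in header of {path!r}")
    off_diag = linear - np.diag(np.diag(linear))
    if np.any(np.abs(off_diag) > 1e-6 * voxel.max()):
        logger.warning("non-axis-aligned affine in %s; keeping voxel sizes only", path)
    origin = aff[:3, 3]
    return VolumeImage(np.asarray(data, dtype=np.float64), voxel, origin)


def write_volume(image: VolumeImage, path, dtype=np.float32) -> None:
    """Write NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.img/.hdr)."""
    p = str(path)
    arr = image.data.astype(dtype)
    if p.endswith((".nii", ".nii.gz")):
        out = nib.Nifti1Image(arr, image.affine)
    elif p.endswith((".img", ".hdr")):
        out = nib.AnalyzeImage(arr, image.affine)
    else:
        raise FormatError(f"unknown image extension on {path!r} (use .nii, .nii.gz, .img)")
    nib.save(out, p)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _voxel_space_affine(moving: VolumeImage, transform: AffineTransform,
                        out_voxel, out_origin):
    """Compose physical transform with both grids' index<->mm maps."""
    vs_m = moving.voxel_size_mm
    mat = (transform.matrix * np.asarray(out_voxel)[None, :]) / vs_m[:, None]
    off = (transform.matrix @ np.asarray(out_origin) + transform.translation_mm
           - moving.origin_mm) / vs_m
    return mat, off


def resample(
    image: VolumeImage,
    transform: AffineTransform,
    out_grid: VolumeImage | LabelVolume | None = None,
    interpolation: str = "trilinear",
) -> VolumeImage:
    """Pull-resample ``image`` through ``transform`` onto ``out_grid``.

    The output voxel at physical coordinate x takes the value of ``image``
    at ``transform(x)``; coordinates falling outside the input field give 0.
    """
    if out_grid is None:
        out_grid = image
    order = {"nearest": 0, "trilinear": 1}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise TransformError("cannot resample through a singular transform")
    mat, off = _voxel_space_affine(image, transform, out_grid.voxel_size_mm,
                                   out_grid.origin_mm)
    out = ndimage.affine_transform(image.data, mat, offset=off,
                                   output_shape=out_grid.shape, order=order,
                                   mode="constant", cval=0.0)
    return VolumeImage(out, np.asarray(out_grid.voxel_size_mm).copy(),
                       np.asarray(out_grid.origin_mm).copy())


def field_of_view_mask(
    image: VolumeImage,
    transform: AffineTransform,
    out_grid: VolumeImage | None = None,
) -> np.ndarray:
    """Boolean mask of output voxels whose pulled coordinate is inside ``image``."""
    if out_grid is None:
        out_grid = image
    ones = np.ones(image.shape)
    mat, off = _voxel_space_affine(image, transform, out_grid.voxel_size_mm,
                                   out_grid.origin_mm)
    w = ndimage.affine_transform(ones, mat, offset=off, output_shape=out_grid.shape,
                                 order=1, mode="constant", cval=0.0)
    return w > 0.999


# ---------------------------------------------------------------------------
# Principal-axes pre-alignment ("straightening")
# ---------------------------------------------------------------------------

def straighten(image: VolumeImage) -> AffineTransform:
    """Rigid pre-alignment from the intensity distribution's principal axes.

    Returns a transform T such that ``resample(image, T)`` centres the
    intensity centroid on the grid centre and aligns the principal axes of
    the intensity distribution with the grid axes, the largest-variance axis
    going to the anterior-posterior (y) axis.  Axis signs are fixed
    deterministically: each principal direction is oriented so the third
    central moment (skewness) of the intensity along it is positive; for
    nearly symmetric directions the dominant component is made positive, and
    a right-handed frame is enforced by flipping the most symmetric axis.

    For a point-symmetric image (e.g. a sphere) the rotation is
    unconstrained and resolved by these tie-breaks; the translation still
    centres the centroid.
    """
    w = np.clip(image.data, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot straighten an image with no positive intensity")
    idx = np.indices(image.shape, dtype=float)
    coords = np.stack([image.origin_mm[a] + idx[a] * image.voxel_size_mm[a]
                       for a in range(3)], axis=-1)
    flat = coords.reshape(-1, 3)
    wf = w.ravel() / total
    centroid = wf @ flat
    d = flat - centroid
    cov = (d * wf[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    # eigenvalue rank -> physical axis: largest to y (anterior-posterior),
    # second to x (left-right), third to z (dorsal-ventral)
    axis_for_rank = (1, 0, 2)
    R = np.zeros((3, 3))
    skews = np.zeros(3)
    scale = np.sqrt(np.maximum(evals[order], 1e-30))
    for rank, col in enumerate(axis_for_rank):
        u = evecs[:, order[rank]]
        proj = d @ u
        skew = float(wf @ proj**3) / max(scale[rank] ** 3, 1e-30)
        if abs(skew) < 1e-3:
            dom = int(np.argmax(np.abs(u)))
            if u[dom] < 0:
                u = -u
        elif skew < 0:
            u, skew = -u, -skew
        R[:, col] = u
        skews[col] = skew
    if np.linalg.det(R) < 0:
        flip = int(np.argmin(np.abs(skews)))
        R[:, flip] = -R[:, flip]
    g = image.center_mm
    return AffineTransform(R, centroid - R @ g)
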