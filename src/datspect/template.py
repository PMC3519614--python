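"""Population mean/SD templates and voxel-wise group comparison.

A template is the voxel-wise mean (with a companion sample-SD image) of
spatially and count-normalized subject images.  Each input is straightened
(principal-axes pre-alignment), masked of extracerebral hot spots,
count-normalized to the striatal 95%-of-maximum mean, and MI-registered
into a common space.  The reference is the first image on the first pass;
a second pass re-registers every image to the provisional mean, which
bounds the dependence on the arbitrary reference choice.

Two templates (e.g. test vs retest) are compared by a voxel-by-voxel
two-sample t test on the registered, normalized subject images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image_io import AffineTransform, VolumeImage, resample, straighten
from .preprocess import MaskSpec, mask_extracerebral, normalize_counts, \
    provisional_striatal_region
from .registration import MISettings, register_affine
from .synthetic_data import Ellipsoid

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSettings",
    "TemplateResult",
    "TemplateComparison",
    "build_template",
    "compare_templates",
]


def _default_brain_hint(image: VolumeImage) -> Ellipsoid:
    """Generous central ellipsoid assumed to contain the (straightened) brain."""
    extent = (np.array(image.shape) - 1) * image.voxel_size_mm
    semi = extent * np.array([0.24, 0.31, 0.24])
    return Ellipsoid(tuple(image.center_mm), tuple(semi))


@dataclass
class TemplateSettings:
    mask_spec: MaskSpec | None = None
    mi_settings: MISettings = field(default_factory=MISettings)
    refinement_passes: int = 1
    brain_hint: Ellipsoid | None = None


@dataclass
class TemplateResult:
    mean_image: VolumeImage
    sd_image: VolumeImage
    n_subjects: int
    per_subject_transforms: list[AffineTransform]
    registered_images: list[VolumeImage]
    reference_choice: str
    flagged_subjects: list[int]


@dataclass
class TemplateComparison:
    t_map: VolumeImage
    p_map: VolumeImage
    n1: int
    n2: int
    fraction_significant: float
    fraction_significant_bonferroni: float
    multiple_testing_mode: str = "uncorrected+bonferroni"


def _prepare(image: VolumeImage, settings: TemplateSettings) -> VolumeImage:
    """Straighten, mask, count-normalize one subject image."""
    t = straighten(image)
    st = resample(image, t)
    hint = settings.brain_hint or _default_brain_hint(st)
    mask_spec = settings.mask_spec or MaskSpec(brain_region_hint=hint)
    if mask_spec.brain_region_hint is None:
        mask_spec = MaskSpec(hint, mask_spec.mode, mask_spec.automatic_threshold_fraction)
    masked = mask_extracerebral(st, mask_spec)
    region = provisional_striatal_region(masked, hint)
    normalized, _ = normalize_counts(masked, region)
    return normalized


def build_template(images: list[VolumeImage], settings: TemplateSettings | None = None
                   ) -> TemplateResult:
    """Build the voxel-wise mean and sample-SD template from subject images.

    Pipeline per image: straighten -> mask -> normalize -> register.  The
    first image serves as the pass-1 reference; one refinement pass (by
    default) re-registers every normalized image to the provisional mean.
    A registration that fails to converge flags the subject but the
    template is still built.
    """
    settings = settings or TemplateSettings()
    if len(images) < 2:
        raise ValueError("need at least two images to build a template")
    prepared = [_prepare(img, settings) for img in images]

    flagged: set[int] = set()

    def register_all(reference: VolumeImage):
        transforms, warped = [], []
        for i, prep in enumerate(prepared):
            if prep is reference:
                transforms.append(AffineTransform.identity())
                warped.append(prep)
                continue
            res = register_affine(prep, reference, settings.mi_settings)
            if not res.converged:
                flagged.add(i)
                logger.warning("subject %d registration flagged as non-converged", i)
            transforms.append(res.transform)
            warped.append(resample(prep, res.transform, reference))
        return transforms, warped

    _, warped = register_all(prepared[0])
    reference_choice = "first image"
    for _ in range(max(0, settings.refinement_passes)):
        provisional = VolumeImage(np.mean([w.data for w in warped], axis=0),
                                  prepared[0].voxel_size_mm.copy(),
                                  prepared[0].origin_mm.copy())
        transforms, warped = register_all(provisional)
        reference_choice = "first image, refined to provisional mean"

    stack = np.stack([w.data for w in warped])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    grid = warped[0]
    return TemplateResult(
        mean_image=grid.with_data(mean),
        sd_image=grid.with_data(sd),
        n_subjects=len(images),
        per_subject_transforms=transforms,
        registered_images=warped,
        reference_choice=reference_choice,
        flagged_subjects=sorted(flagged),
    )


def compare_templates(
    group1: list[VolumeImage],
    group2: list[VolumeImage],
    alpha: float = 0.05,
    welch: bool = False,
) -> TemplateComparison:
    """Voxel-by-voxel two-sample t test between two registered groups.

    The pooled-variance (equal-variance) t is the default, matching the
    repeated-measures design where both groups are the same animals; Welch
    is available behind ``welch=True``.  Voxels where both groups are
    identically zero-variance and equal get p = 1; the significant fraction
    is reported uncorrected and Bonferroni-corrected over the defined
    voxels.
    """
    n1, n2 = len(group1), len(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two images")
    shapes = {tuple(img.shape) for img in group1 + group2}
    if len(shapes) != 1:
        raise ValueError("all images must share a common grid")
    g1 = np.stack([img.data for img in group1])
    g2 = np.stack([img.data for img in group2])
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1, v2 = g1.var(axis=0, ddof=1), g2.var(axis=0, ddof=1)

    defined = ((v1 > 0) | (m1 != 0)) & ((v2 > 0) | (m2 != 0))
    t_map = np.zeros(m1.shape)
    p_map = np.ones(m1.shape)
    if welch:
        denom = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, 1.0)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full(m1.shape, n1 + n2 - 2, dtype=float)

    diff = m1 - m2
    usable = defined & (denom > 0)
    t_map[usable] = diff[usable] / denom[usable]
    p_map[usable] = 2.0 * stats.t.sf(np.abs(t_map[usable]), df[usable])
    # zero pooled variance but different means: infinitely significant
    degenerate = defined & (denom == 0) & (diff != 0)
    t_map[degenerate] = np.sign(diff[degenerate]) * np.inf
    p_map[degenerate] = 0.0

    n_defined = int(defined.sum())
    frac = float((p_map[defined] < alpha).mean()) if n_defined else 0.0
    frac_bonf = (float((p_map[defined] < alpha / n_defined).mean())
                 if n_defined else 0.0)
    grid = group1[0]
    return TemplateComparison(
        t_map=grid.with_data(t_map),
        p_map=grid.with_data(p_map),
        n1=n1, n2=n2,
        fraction_significant=frac,
        fraction_significant_bonferroni=frac_bonf,
    )
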