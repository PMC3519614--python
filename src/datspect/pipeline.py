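"""End-to-end analysis workflows combining the pipeline stages.

These functions are the glue the command-line interface and the
reproduction script run: quantify a single frame against a canonical
reference, analyze a kinetics series, score a test-retest cohort, and
measure striatal volumes by thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import LabelVolume, VolumeImage, resample
from .quantify import (VOI, TimeActivityCurve, binding_potential, decay_correct,
                       default_vois, detect_equilibrium, fit_monoexponential,
                       threshold_volume_curve, time_activity_curves, voi_mean)
from .registration import MISettings, register_affine
from .reliability import TestRetestResult, testretest_summary
from .synthetic_data import (AcquisitionSpec, CohortDataset, KineticParams,
                             PhantomSpec, expected_counts, make_brain_labels,
                             tracer_activity)

__all__ = [
    "canonical_reference",
    "quantify_frame",
    "striatal_seed_mask",
    "measure_striatal_volume",
    "analyze_testretest_cohort",
    "analyze_kinetics_series",
]


def canonical_reference(
    spec: PhantomSpec | None = None,
    kp: KineticParams | None = None,
    acq: AcquisitionSpec | None = None,
    t_h: float = 4.0,
) -> tuple[VolumeImage, LabelVolume]:
    """Noise-free canonical-space target image and its labels.

    The reference is the expected (blurred, decayed, unposed) count image
    of the default phantom at the scan time; individual frames are
    MI-registered to it so canonical-space VOIs apply.
    """
    spec = spec or PhantomSpec()
    kp = kp or KineticParams()
    acq = acq or AcquisitionSpec()
    labels = make_brain_labels(spec)
    act = tracer_activity(labels, kp, t_h, acq.isotope_half_life_h)
    return expected_counts(act, acq), labels


def prealign_transform(moving: VolumeImage, fixed: VolumeImage):
    """Principal-axes initialization for MI refinement.

    Straightens both images (after automatic extracerebral masking) into the
    same deterministic canonical orientation and composes the two rigid
    transforms into an initial fixed-to-moving map.  Useful when the moving
    image's orientation may sit outside the MI capture range (e.g. a
    template built in its own straightened space).
    """
    from .image_io import straighten
    from .preprocess import MaskSpec, mask_extracerebral
    from .template import _default_brain_hint

    def _mask(img):
        return mask_extracerebral(img, MaskSpec(_default_brain_hint(img)))

    t_mov = straighten(_mask(moving))
    t_fix = straighten(_mask(fixed))
    return t_mov.compose(t_fix.invert())


def quantify_frame(
    image: VolumeImage,
    reference: VolumeImage,
    labels: LabelVolume,
    t_h: float,
    half_life_h: float,
    mi_settings: MISettings | None = None,
    prealign: bool = False,
) -> dict:
    """Register one frame to the reference and report decay-corrected BP.

    The frame is MI-registered to the canonical reference, resampled into
    canonical space, and the striatal / cerebellar VOI means (from the
    label anatomy) are decay-corrected; BP = S/C - 1.  ``prealign`` seeds
    the registration from the principal-axes alignment instead of the
    identity (needed when the frame orientation is far from canonical).
    """
    init = prealign_transform(image, reference) if prealign else None
    res = register_affine(image, reference, mi_settings, init=init)
    vois = default_vois(labels)
    # pull the canonical-space VOIs into the native frame instead of warping
    # the image: image voxels stay untouched by interpolation
    to_canonical = res.transform.invert()
    native = {}
    for name in ("striatum", "cerebellum"):
        voi = vois[name]
        mask_img = VolumeImage(voi.mask.astype(np.float64), labels.voxel_size_mm,
                               labels.origin_mm)
        pulled = resample(mask_img, to_canonical, image, "nearest")
        native[name] = VOI(name, pulled.data > 0.5, image.voxel_volume_mm3)
    s = decay_correct(voi_mean(image, native["striatum"]), t_h, half_life_h)
    c = decay_correct(voi_mean(image, native["cerebellum"]), t_h, half_life_h)
    bp = binding_potential(s, c)
    return {
        "striatal_mean": s,
        "cerebellar_mean": c,
        "bp": bp.bp,
        "final_mi": res.final_mi,
        "registration_converged": res.converged,
        "transform": res.transform,
    }


def striatal_seed_mask(image: VolumeImage, fraction: float = 0.9,
                       inside: np.ndarray | None = None) -> np.ndarray:
    """Voxels within ``fraction`` of the maximum — the striatal hot cores.

    Both striatal sides qualify (their intensities are equal up to noise),
    so the seed feeds the connected-component volumetry with every striatal
    component.
    """
    data = image.data if inside is None else np.where(inside, image.data, 0.0)
    return data >= fraction * data.max()


def measure_striatal_volume(
    image: VolumeImage,
    threshold: float = 0.5,
    seed_fraction: float = 0.9,
    inside: np.ndarray | None = None,
) -> float:
    """Striatal volume at one threshold of the structure maximum (mm^3)."""
    seed = striatal_seed_mask(image, seed_fraction, inside)
    curve = threshold_volume_curve(image, seed, [threshold])
    return float(curve.volumes_mm3[0])


def analyze_testretest_cohort(
    cohort: CohortDataset,
    mi_settings: MISettings | None = None,
) -> tuple[TestRetestResult, list[dict]]:
    """Quantify every test and retest frame of a cohort and summarize.

    Each frame is registered to a canonical reference rendered at the
    cohort's scan time; VOIs come from each subject's own (canonical-space)
    label anatomy.  Returns the group summary and per-subject detail
    records including the ground-truth BP.
    """
    t_h = cohort.subjects[0].scan_time_h
    reference, _ = canonical_reference(cohort.phantom_spec, None,
                                       cohort.acquisition, t_h)
    half_life = cohort.acquisition.isotope_half_life_h
    details = []
    for sub in cohort.subjects:
        rec = {"subject_id": sub.subject_id, "true_bp": sub.true_bp}
        for tag, img in (("test", sub.image_test), ("retest", sub.image_retest)):
            q = quantify_frame(img, reference, sub.labels, t_h, half_life,
                               mi_settings)
            rec[f"bp_{tag}"] = q["bp"]
            rec[f"registration_converged_{tag}"] = q["registration_converged"]
        details.append(rec)
    summary = testretest_summary([d["bp_test"] for d in details],
                                 [d["bp_retest"] for d in details],
                                 [d["subject_id"] for d in details])
    return summary, details


def analyze_kinetics_series(
    labels: LabelVolume,
    frames: list[tuple[float, VolumeImage]],
    half_life_h: float = 13.22,
    equilibrium_tol: float = 0.10,
) -> dict:
    """TACs, cerebellar clearance fit, BP series and equilibrium detection."""
    vois = default_vois(labels)
    tacs = time_activity_curves(frames, vois, half_life_h)
    stri, cereb = tacs["striatum"], tacs["cerebellum"]
    _, half_time = fit_monoexponential(cereb)
    bp_series = stri.mean_counts / cereb.mean_counts - 1.0
    eq_index = detect_equilibrium(bp_series, equilibrium_tol)
    return {
        "tacs": tacs,
        "cerebellar_half_time_h": half_time,
        "bp_series": bp_series,
        "times_h": stri.times_h,
        "equilibrium_index": eq_index,
        "equilibrium_time_h": (None if eq_index is None
                               else float(stri.times_h[eq_index])),
    }
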