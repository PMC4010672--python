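"""Cohort-level orchestration: per-subject fits and the standard analyses.

Ties the pieces together the way the study design runs them: every subject
gets a single-tensor fit (uncorrected metrics) and a regularised free-water
fit (corrected metrics + f); tract analyses track on the subject's own
uncorrected tensor field and sample both map sets along the same
streamlines; skeleton and histogram analyses consume the same per-subject
maps.  Everything here is deterministic given the cohort seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .freewater import FweConfig, corrected_metrics, fit_bitensor_field
from .phantom import Subject
from .tensor import default_mask, fit_single_tensor, tensor_metrics
from .tracking import RoiPlan, TrackingConfig, apply_roi_plan, track, tract_mean

logger = logging.getLogger("fwelim")


@dataclass
class SubjectFits:
    subject_id: str
    group: str
    uncorrected: dict      # metric -> ScalarMap (FA, MD, AD, RD)
    corrected: dict        # metric -> ScalarMap (FA, MD, AD, RD, f)
    mask: np.ndarray
    affine: np.ndarray
    tensor_field: object   # uncorrected TensorField (direction source)


def fit_subject(subject: Subject, fwe_config: FweConfig | None = None,
                mask: np.ndarray | None = None) -> SubjectFits:
    """Uncorrected single-tensor and corrected free-water fits for a subject.

    The fit mask defaults to the phantom's ground-truth non-CSF voxels (the
    stand-in for the T1-based brain-tissue mask a real pipeline would use):
    pure CSF carries no tissue signal, so including it would only couple
    noise into the regularised tensor field.  Corrected maps are missing in
    CSF by construction.
    """
    dwi = subject.dwi
    if mask is None:
        mask = subject.labels != -1
    tfield = fit_single_tensor(dwi, mask)
    unc = tensor_metrics(tfield, correction="uncorrected")
    bifit = fit_bitensor_field(dwi, mask, fwe_config or FweConfig(),
                               smoothing_classes=subject.labels,
                               data_weights=csf_distance_weights(subject.labels))
    cor = corrected_metrics(bifit)
    return SubjectFits(subject_id=subject.subject_id, group=subject.group,
                       uncorrected=unc, corrected=cor, mask=mask,
                       affine=dwi.affine, tensor_field=tfield)


def fit_cohort(subjects: list, fwe_config: FweConfig | None = None) -> list:
    return [fit_subject(s, fwe_config) for s in subjects]


def tract_analysis(fits: list, subjects: list, structure_label: int,
                   metrics: tuple = ("FA", "MD"),
                   tracking: TrackingConfig | None = None) -> pd.DataFrame:
    """Per-subject tract means of uncorrected and corrected metrics.

    Streamlines are seeded in (and constrained by an AND waypoint on) the
    ground-truth voxels of the requested structure, tracked on the subject's
    uncorrected tensor field — contamination therefore affects the geometry
    exactly as it would in practice.  Returns one row per subject with
    ``<metric>_u`` / ``<metric>_c`` columns (NaN when the bundle is empty).
    """
    tracking = tracking or TrackingConfig()
    rows = []
    for fit, subj in zip(fits, subjects):
        seed_roi = subj.labels == structure_label
        streamlines = track(fit.tensor_field, fit.mask, tracking, seeds=seed_roi)
        bundle = apply_roi_plan(streamlines, RoiPlan(and_rois=[seed_roi]),
                                fit.affine, tracking)
        row = {"subject": fit.subject_id, "group": fit.group,
               "n_streamlines": len(bundle)}
        for m in metrics:
            row[f"{m}_u"] = tract_mean(bundle, fit.uncorrected[m])
            row[f"{m}_c"] = tract_mean(bundle, fit.corrected[m])
        rows.append(row)
    return pd.DataFrame(rows)


def csf_distance_weights(labels: np.ndarray, rim: float = 2.0,
                         ramp: float = 1.0) -> np.ndarray:
    """Reliability weights for the tensor data term, from CSF proximity.

    Voxels near CSF are partial-volumed: after the free-water subtraction
    their log tissue attenuation is noise-dominated, so the field fit should
    let the smoothness term interpolate the tensor there rather than trust
    the local data.  Weights rise quadratically with the segmentation's
    distance-to-CSF and saturate at ``saturation`` voxels.  Shared by all
    subjects of a cohort (the segmentation geometry is common), which keeps
    the factorised fit system cacheable.
    """
    from scipy.ndimage import distance_transform_edt

    csf = labels == -1
    if not csf.any():
        return np.ones(labels.shape)
    d = distance_transform_edt(~csf)
    return np.clip((d - rim) / ramp, 0.0, 1.0) ** 2


def wm_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """White-matter analysis mask from ground-truth labels (bundles only)."""
    return labels > 0
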