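"""Reference group summaries from a published MCI case-control study.

These are the printed tract-mean and whole-white-matter histogram summary
tables (group mean and SD per metric, before and after free-water
correction) of a diffusion MRI comparison of 25 patients with mild
cognitive impairment against 20 matched healthy controls.  They serve as
the canonical worked input for the attribution arithmetic: the study's
reported percentages of apparent group difference attributable to (or
unmasked by) CSF contamination are all recomputable from these numbers.

Tract means cover the fornix, uncinate fasciculus (UNC) and
parahippocampal cingulum (PHC); the left and right PHC were each
unreconstructable in two patients, hence n=23 there.  Diffusivities are in
10^-3 mm^2/s.
"""

from __future__ import annotations

import pandas as pd

_TRACT_ROWS = [
    # tract, metric, correction, group, n, mean, sd
    ("fornix", "FA", "uncorrected", "patient", 25, 0.201, 0.027),
    ("fornix", "FA", "uncorrected", "control", 20, 0.224, 0.023),
    ("fornix", "FA", "fwe_corrected", "patient", 25, 0.237, 0.045),
    ("fornix", "FA", "fwe_corrected", "control", 20, 0.272, 0.037),
    ("fornix", "MD", "uncorrected", "patient", 25, 1.876, 0.238),
    ("fornix", "MD", "uncorrected", "control", 20, 1.660, 0.205),
    ("fornix", "MD", "fwe_corrected", "patient", 25, 1.020, 0.125),
    ("fornix", "MD", "fwe_corrected", "control", 20, 1.065, 0.069),
    ("unc_left", "FA", "uncorrected", "patient", 25, 0.401, 0.025),
    ("unc_left", "FA", "uncorrected", "control", 20, 0.377, 0.030),
    ("unc_left", "FA", "fwe_corrected", "patient", 25, 0.429, 0.053),
    ("unc_left", "FA", "fwe_corrected", "control", 20, 0.418, 0.029),
    ("unc_left", "MD", "uncorrected", "patient", 25, 0.880, 0.048),
    ("unc_left", "MD", "uncorrected", "control", 20, 0.861, 0.043),
    ("unc_left", "MD", "fwe_corrected", "patient", 25, 0.802, 0.040),
    ("unc_left", "MD", "fwe_corrected", "control", 20, 0.781, 0.027),
    ("unc_right", "FA", "uncorrected", "patient", 25, 0.395, 0.027),
    ("unc_right", "FA", "uncorrected", "control", 20, 0.380, 0.023),
    ("unc_right", "FA", "fwe_corrected", "patient", 25, 0.427, 0.056),
    ("unc_right", "FA", "fwe_corrected", "control", 20, 0.420, 0.025),
    ("unc_right", "MD", "uncorrected", "patient", 25, 0.892, 0.036),
    ("unc_right", "MD", "uncorrected", "control", 20, 0.872, 0.035),
    ("unc_right", "MD", "fwe_corrected", "patient", 25, 0.816, 0.047),
    ("unc_right", "MD", "fwe_corrected", "control", 20, 0.790, 0.023),
    ("phc_left", "FA", "uncorrected", "patient", 23, 0.342, 0.033),
    ("phc_left", "FA", "uncorrected", "control", 20, 0.311, 0.023),
    ("phc_left", "FA", "fwe_corrected", "patient", 23, 0.386, 0.032),
    ("phc_left", "FA", "fwe_corrected", "control", 20, 0.356, 0.023),
    ("phc_left", "MD", "uncorrected", "patient", 23, 0.845, 0.054),
    ("phc_left", "MD", "uncorrected", "control", 20, 0.846, 0.042),
    ("phc_left", "MD", "fwe_corrected", "patient", 23, 0.786, 0.040),
    ("phc_left", "MD", "fwe_corrected", "control", 20, 0.785, 0.028),
    ("phc_right", "FA", "uncorrected", "patient", 23, 0.364, 0.037),
    ("phc_right", "FA", "uncorrected", "control", 20, 0.331, 0.026),
    ("phc_right", "FA", "fwe_corrected", "patient", 23, 0.409, 0.033),
    ("phc_right", "FA", "fwe_corrected", "control", 20, 0.379, 0.026),
    ("phc_right", "MD", "uncorrected", "patient", 23, 0.827, 0.067),
    ("phc_right", "MD", "uncorrected", "control", 20, 0.829, 0.048),
    ("phc_right", "MD", "fwe_corrected", "patient", 23, 0.767, 0.042),
    ("phc_right", "MD", "fwe_corrected", "control", 20, 0.772, 0.031),
]

_HISTOGRAM_ROWS = [
    # metric, statistic, correction, group, n, mean, sd
    ("FA", "mean", "uncorrected", "patient", 25, 0.323, 0.029),
    ("FA", "mean", "uncorrected", "control", 20, 0.345, 0.017),
    ("FA", "mean", "fwe_corrected", "patient", 25, 0.353, 0.028),
    ("FA", "mean", "fwe_corrected", "control", 20, 0.373, 0.015),
    ("FA", "mode", "uncorrected", "patient", 25, 0.262, 0.039),
    ("FA", "mode", "uncorrected", "control", 20, 0.300, 0.034),
    ("FA", "mode", "fwe_corrected", "patient", 25, 0.284, 0.062),
    ("FA", "mode", "fwe_corrected", "control", 20, 0.336, 0.038),
    ("FA", "peak_height", "uncorrected", "patient", 25, 0.0145, 0.0015),
    ("FA", "peak_height", "uncorrected", "control", 20, 0.0139, 0.0009),
    ("FA", "peak_height", "fwe_corrected", "patient", 25, 0.0130, 0.0020),
    ("FA", "peak_height", "fwe_corrected", "control", 20, 0.0127, 0.0008),
    ("MD", "mean", "uncorrected", "patient", 25, 0.871, 0.066),
    ("MD", "mean", "uncorrected", "control", 20, 0.833, 0.033),
    ("MD", "mean", "fwe_corrected", "patient", 25, 0.780, 0.039),
    ("MD", "mean", "fwe_corrected", "control", 20, 0.757, 0.021),
    ("MD", "mode", "uncorrected", "patient", 25, 0.803, 0.040),
    ("MD", "mode", "uncorrected", "control", 20, 0.784, 0.030),
    ("MD", "mode", "fwe_corrected", "patient", 25, 0.753, 0.029),
    ("MD", "mode", "fwe_corrected", "control", 20, 0.737, 0.020),
    ("MD", "peak_height", "uncorrected", "patient", 25, 0.0340, 0.0070),
    ("MD", "peak_height", "uncorrected", "control", 20, 0.0411, 0.0053),
    ("MD", "peak_height", "fwe_corrected", "patient", 25, 0.0529, 0.0107),
    ("MD", "peak_height", "fwe_corrected", "control", 20, 0.0634, 0.0079),
    ("AD", "mean", "uncorrected", "patient", 25, 1.166, 0.055),
    ("AD", "mean", "uncorrected", "control", 20, 1.143, 0.031),
    ("AD", "mean", "fwe_corrected", "patient", 25, 1.071, 0.029),
    ("AD", "mean", "fwe_corrected", "control", 20, 1.064, 0.018),
    ("AD", "mode", "uncorrected", "patient", 25, 1.068, 0.042),
    ("AD", "mode", "uncorrected", "control", 20, 1.059, 0.029),
    ("AD", "mode", "fwe_corrected", "patient", 25, 0.997, 0.031),
    ("AD", "mode", "fwe_corrected", "control", 20, 0.983, 0.019),
    ("AD", "peak_height", "uncorrected", "patient", 25, 0.0196, 0.0044),
    ("AD", "peak_height", "uncorrected", "control", 20, 0.0223, 0.0014),
    ("AD", "peak_height", "fwe_corrected", "patient", 25, 0.0249, 0.0022),
    ("AD", "peak_height", "fwe_corrected", "control", 20, 0.0262, 0.0013),
    ("RD", "mean", "uncorrected", "patient", 25, 0.723, 0.073),
    ("RD", "mean", "uncorrected", "control", 20, 0.677, 0.035),
    ("RD", "mean", "fwe_corrected", "patient", 25, 0.634, 0.046),
    ("RD", "mean", "fwe_corrected", "control", 20, 0.604, 0.024),
    ("RD", "mode", "uncorrected", "patient", 25, 0.661, 0.045),
    ("RD", "mode", "uncorrected", "control", 20, 0.637, 0.033),
    ("RD", "mode", "fwe_corrected", "patient", 25, 0.618, 0.033),
    ("RD", "mode", "fwe_corrected", "control", 20, 0.601, 0.025),
    ("RD", "peak_height", "uncorrected", "patient", 25, 0.0285, 0.0048),
    ("RD", "peak_height", "uncorrected", "control", 20, 0.0326, 0.0027),
    ("RD", "peak_height", "fwe_corrected", "patient", 25, 0.0370, 0.0048),
    ("RD", "peak_height", "fwe_corrected", "control", 20, 0.0410, 0.0028),
]


def mci_tract_summaries() -> pd.DataFrame:
    """Published tract-mean summaries (mean/SD/n per tract, metric, group,
    correction status). Diffusivities in 10^-3 mm^2/s."""
    return pd.DataFrame(_TRACT_ROWS, columns=[
        "tract", "metric", "correction", "group", "n", "mean", "sd"])


def mci_histogram_summaries() -> pd.DataFrame:
    """Published whole-white-matter histogram summaries (mean, mode location
    and peak height per metric, group and correction status)."""
    return pd.DataFrame(_HISTOGRAM_ROWS, columns=[
        "metric", "statistic", "correction", "group", "n", "mean", "sd"])


def published_attribution_inputs() -> dict:
    """The six comparisons for which the study reports an attribution (or
    unmasking) percentage, as (patient_u, control_u, patient_c, control_c)
    group means keyed by a descriptive name."""
    hist = mci_histogram_summaries()
    tract = mci_tract_summaries()

    def h(metric):
        rows = hist[(hist.metric == metric) & (hist.statistic == "mean")]
        return tuple(rows[(rows.correction == c) & (rows.group == g)]["mean"].item()
                     for c in ("uncorrected", "fwe_corrected")
                     for g in ("patient", "control"))

    def t(name, metric="FA"):
        rows = tract[(tract.tract == name) & (tract.metric == metric)]
        return tuple(rows[(rows.correction == c) & (rows.group == g)]["mean"].item()
                     for c in ("uncorrected", "fwe_corrected")
                     for g in ("patient", "control"))

    return {
        "histogram_mean_FA": h("FA"),
        "histogram_mean_MD": h("MD"),
        "histogram_mean_AD": h("AD"),
        "fornix_FA": t("fornix"),
        "phc_left_FA": t("phc_left"),
        "phc_right_FA": t("phc_right"),
    }
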