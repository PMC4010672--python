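"""Whole-white-matter histograms of diffusion metrics.

Binning is fixed per metric: FA over [0, 1] in steps of 0.005 (200 bins);
MD, AD and RD over [0.10, 3.00] in steps of 0.01, in units of
10^-3 mm^2/s (290 bins).  Bins are left-closed/right-open with the final
bin closed.  Heights are normalised by the number of in-mask voxels whose
value falls inside the histogram range ("voxels contributing"), so
out-of-range voxels are excluded from both the counts and the denominator.
The three summary statistics per histogram are the mean (of the raw
in-range voxel values, not of bin centres), the peak (mode) location — the
centre of the tallest bin, ties resolved toward the lower bin — and the
peak height (the tallest normalised frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ParameterError
from .tensor import ScalarMap

#: map values are in mm^2/s; histograms use the conventional 1e-3 mm^2/s units
DIFFUSIVITY_SCALE = 1e3

HISTOGRAM_SPECS = {
    "FA": {"range": (0.0, 1.0), "width": 0.005, "scale": 1.0},
    "MD": {"range": (0.10, 3.00), "width": 0.01, "scale": DIFFUSIVITY_SCALE},
    "AD": {"range": (0.10, 3.00), "width": 0.01, "scale": DIFFUSIVITY_SCALE},
    "RD": {"range": (0.10, 3.00), "width": 0.01, "scale": DIFFUSIVITY_SCALE},
}


@dataclass
class HistogramResult:
    edges: np.ndarray        # bin boundaries, metric units
    heights: np.ndarray      # normalised frequencies, sum to 1
    mean_value: float        # mean of raw in-range values
    mode_location: float     # centre of the tallest bin
    peak_height: float       # tallest normalised frequency
    n_contributing: int


def metric_edges(metric: str) -> np.ndarray:
    spec = HISTOGRAM_SPECS[metric]
    lo, hi = spec["range"]
    n_bins = round((hi - lo) / spec["width"])
    return np.linspace(lo, hi, n_bins + 1)


def wm_histogram(scalar_map: ScalarMap, wm_mask: np.ndarray,
                 metric: str | None = None) -> HistogramResult:
    """Histogram of one metric over a white-matter mask."""
    metric = metric or scalar_map.metric
    if metric not in HISTOGRAM_SPECS:
        raise ParameterError(f"no histogram convention for metric '{metric}'")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ParameterError("white-matter mask is empty")
    spec = HISTOGRAM_SPECS[metric]
    vals = scalar_map.values[wm_mask & scalar_map.mask] * spec["scale"]
    edges = metric_edges(metric)
    in_range = (vals >= edges[0]) & (vals <= edges[-1])
    vals = vals[in_range]
    if len(vals) == 0:
        raise ParameterError("no in-range values in the white-matter mask")
    counts, _ = np.histogram(vals, bins=edges)
    heights = counts / counts.sum()
    peak_bin = int(np.argmax(heights))        # ties -> lower bin
    centres = 0.5 * (edges[:-1] + edges[1:])
    return HistogramResult(edges=edges, heights=heights,
                           mean_value=float(vals.mean()),
                           mode_location=float(centres[peak_bin]),
                           peak_height=float(heights[peak_bin]),
                           n_contributing=int(len(vals)))


def cohort_histograms(subject_maps: list, wm_masks: list, groups: list,
                      subject_ids: list | None = None,
                      metric: str | None = None) -> pd.DataFrame:
    """Per-subject histogram summaries for downstream group statistics.

    One row per subject with mean, mode location and peak height; subjects
    whose map is missing (None) are skipped with a warning.
    """
    import warnings

    rows = []
    ids = subject_ids or [f"s{i:02d}" for i in range(len(subject_maps))]
    for sid, smap, mask, group in zip(ids, subject_maps, wm_masks, groups):
        if smap is None:
            warnings.warn(f"subject {sid}: missing map, row skipped", stacklevel=2)
            continue
        h = wm_histogram(smap, mask, metric=metric)
        rows.append({"subject": sid, "group": group,
                     "metric": metric or smap.metric,
                     "correction": smap.correction,
                     "mean": h.mean_value, "mode": h.mode_location,
                     "peak_height": h.peak_height,
                     "n_voxels": h.n_contributing})
    return pd.DataFrame(rows)
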