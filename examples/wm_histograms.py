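"""Whole-white-matter histograms before and after free-water correction.

On a contaminated phantom the uncorrected MD histogram grows a heavy right
tail (CSF-contaminated voxels); correction narrows the distribution, which
raises the peak height — the signature seen in whole-brain histogram
analyses of atrophic cohorts.
"""

import numpy as np

import fwelim as fw
from fwelim.freewater import FweConfig, corrected_metrics, fit_bitensor_field
from fwelim.histogram import wm_histogram
from fwelim.phantom import build_phantom, default_phantom_spec, simulate_signal
from fwelim.pipeline import csf_distance_weights
from fwelim.tensor import fit_single_tensor, tensor_metrics

scheme = fw.make_gradient_scheme(30, 1200.0, 3, seed=42)
spec = default_phantom_spec()
tensors, f_true, labels = build_phantom(spec, atrophy_shift={"fornix": 0.8})
dwi = simulate_signal(tensors, f_true, scheme, s0=spec.s0,
                      noise_sigma=spec.noise_sigma, seed=2)
mask = labels != -1
wm = labels > 0

unc = tensor_metrics(fit_single_tensor(dwi, mask))
cor = corrected_metrics(fit_bitensor_field(
    dwi, mask, FweConfig(), smoothing_classes=labels,
    data_weights=csf_distance_weights(labels)))
hu = wm_histogram(unc["MD"], wm, metric="MD")
hc = wm_histogram(cor["MD"], wm & cor["MD"].mask, metric="MD")
centres = 0.5 * (hu.edges[:-1] + hu.edges[1:])
tail = centres > 1.5
print("MD histogram (units 1e-3 mm^2/s):")
print(f"  uncorrected  mean {hu.mean_value:.3f}  mode {hu.mode_location:.3f}"
      f"  peak height {hu.peak_height:.3f}  tail mass(>1.5) "
      f"{hu.heights[tail].sum():.3f}")
print(f"  corrected    mean {hc.mean_value:.3f}  mode {hc.mode_location:.3f}"
      f"  peak height {hc.peak_height:.3f}  tail mass(>1.5) "
      f"{hc.heights[tail].sum():.3f}")
print("\nCorrection trims the contaminated right tail and sharpens the peak.")
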