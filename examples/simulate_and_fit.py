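"""Simulate one contaminated phantom head and fit both models.

Builds the default geometry (a thin bundle abutting a ventricle-like CSF
space plus a deep control bundle), generates the two-compartment signal at
SNR 25, then fits the single diffusion tensor (uncorrected metrics) and the
regularised free-water model (corrected metrics + tissue fraction f).
"""

import numpy as np

import fwelim as fw
from fwelim.freewater import FweConfig, corrected_metrics, fit_bitensor_field
from fwelim.phantom import build_phantom, default_phantom_spec, simulate_signal
from fwelim.tensor import fit_single_tensor, tensor_metrics

scheme = fw.make_gradient_scheme(30, 1200.0, 3, seed=42)
spec = default_phantom_spec()
tensors, f_true, labels = build_phantom(spec)
dwi = simulate_signal(tensors, f_true, scheme, s0=spec.s0,
                      noise_sigma=spec.noise_sigma, seed=7)

mask = labels != -1
unc = tensor_metrics(fit_single_tensor(dwi, mask))
fit = fit_bitensor_field(dwi, mask, FweConfig(), smoothing_classes=labels)
cor = corrected_metrics(fit)

for name, region in (("fornix-analogue", labels == 1),
                     ("deep bundle", labels == 2)):
    sel = region & cor["MD"].mask
    print(f"{name:16s} true f {f_true[region].mean():.2f}   "
          f"MD_u {unc['MD'].values[sel].mean()*1e3:.3f}  "
          f"MD_c {cor['MD'].values[sel].mean()*1e3:.3f}  "
          f"FA_u {unc['FA'].values[sel].mean():.3f}  "
          f"FA_c {cor['FA'].values[sel].mean():.3f}   (1e-3 mm^2/s)")

print("\nGround truth: tissue MD 0.767e-3 mm^2/s, FA 0.80.  Near CSF the")
print("uncorrected MD is inflated and FA depressed; the corrected values")
print("recover the tissue tensor, and pure-CSF voxels are flagged missing.")
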