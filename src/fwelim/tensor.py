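"""Single diffusion tensor fitting and the scalar microstructure metrics.

The single-tensor model describes the diffusion-weighted signal as
``S(g, b) = S0 * exp(-b g^T D g)`` with a symmetric positive 3x3 tensor D
per voxel.  Fitting is weighted log-linear least squares, which is exact on
noise-free single-compartment data.  From the eigenvalues (sorted
``l1 >= l2 >= l3``) the four standard metrics follow:

- MD = (l1 + l2 + l3) / 3
- AD = l1
- RD = (l2 + l3) / 2
- FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, GradientScheme, ParameterError

logger = logging.getLogger("fwelim")

#: floor applied to signals before taking logs, as a fraction of S0
LOG_CLAMP_FRACTION = 1e-6

METRICS = ("FA", "MD", "AD", "RD")


@dataclass
class ScalarMap:
    """One scalar metric per voxel, tagged by metric name and correction.

    ``mask`` marks voxels with a valid value; everything outside is treated
    as missing by downstream statistics (never zero-filled).
    """

    values: np.ndarray
    metric: str                       # FA | MD | AD | RD | f
    correction: str = "uncorrected"   # uncorrected | fwe_corrected
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")

    def masked(self) -> np.ndarray:
        """Values with missing voxels set to NaN."""
        return np.where(self.mask, self.values, np.nan)


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors with baseline signal map."""

    tensors: np.ndarray   # (X, Y, Z, 3, 3) mm^2/s
    s0_map: np.ndarray    # (X, Y, Z)
    mask: np.ndarray      # (X, Y, Z) bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    clamped_voxels: int = 0   # diagnostics: voxels where the log floor fired


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows mapping [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0] to log-signal."""
    b, g = scheme.bvals, scheme.bvecs
    return np.column_stack([
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1], -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ])


def vec6_to_tensor(v: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric."""
    out = np.empty(v.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = v[..., 0]
    out[..., 1, 1] = v[..., 1]
    out[..., 2, 2] = v[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = v[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = v[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = v[..., 5]
    return out


def tensor_to_vec6(d: np.ndarray) -> np.ndarray:
    return np.stack([d[..., 0, 0], d[..., 1, 1], d[..., 2, 2],
                     d[..., 0, 1], d[..., 0, 2], d[..., 1, 2]], axis=-1)


def default_mask(dwi: DWIVolume, s0_fraction: float = 0.1) -> np.ndarray:
    """Voxels whose mean b=0 signal exceeds ``s0_fraction`` of the volume max."""
    b0 = dwi.b0_mean()
    return b0 > s0_fraction * b0.max()


def fit_single_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Weighted log-linear least-squares single-tensor fit, voxelwise.

    Weights are the squared (clamped) signals, the standard first-order
    variance propagation for log-transformed Rician-corrupted magnitudes.
    Non-positive signals are clamped to ``LOG_CLAMP_FRACTION * S0`` before
    the log; affected voxels are counted in the diagnostics.
    """
    scheme = dwi.scheme
    if scheme.n_b0 == 0 or not scheme.dw_mask.any():
        raise ParameterError("scheme needs at least one b=0 and six weighted volumes")
    if mask is None:
        mask = default_mask(dwi)
    mask = np.asarray(mask, dtype=bool)
    X = design_matrix(scheme)                        # (G, 7)
    sig = dwi.signal[mask]                           # (N, G)
    s0 = dwi.signal[mask][:, scheme.b0_mask].mean(axis=1)
    floor = LOG_CLAMP_FRACTION * np.maximum(s0, np.finfo(float).tiny)
    clamped = sig < floor[:, None]
    sigc = np.maximum(sig, floor[:, None])
    y = np.log(sigc)                                 # (N, G)
    w = sigc ** 2
    # batched weighted normal equations: (X^T W X) beta = X^T W y
    xtwx = np.einsum("gi,ng,gj->nij", X, w, X)
    xtwy = np.einsum("gi,ng,ng->ni", X, w, y)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]   # (N, 7)
    tensors = np.zeros(mask.shape + (3, 3))
    tensors[mask] = vec6_to_tensor(beta[:, :6])
    s0_map = np.zeros(mask.shape)
    s0_map[mask] = np.exp(beta[:, 6])
    n_clamped = int(clamped.any(axis=1).sum())
    if n_clamped:
        logger.debug("fit_single_tensor: log floor applied in %d voxels", n_clamped)
    return TensorField(tensors=tensors, s0_map=s0_map, mask=mask,
                       affine=dwi.affine, clamped_voxels=n_clamped)


def eigenvalues_descending(tensors: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric (..., 3, 3) tensors, sorted l1 >= l2 >= l3."""
    return np.linalg.eigvalsh(tensors)[..., ::-1]


def metrics_from_eigenvalues(evals: np.ndarray) -> dict:
    """FA/MD/AD/RD from descending eigenvalues; negatives clipped to 0.

    An all-zero tensor gets FA = 0 by convention rather than NaN.
    """
    ev = np.clip(evals, 0.0, None)
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = ev[..., 1:].mean(axis=-1)
    num = ((ev - md[..., None]) ** 2).sum(axis=-1)
    den = (ev ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den > 0, fa, 0.0)
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd}


def tensor_metrics(tfield: TensorField, correction: str = "uncorrected") -> dict:
    """Compute the four ScalarMaps (FA, MD, AD, RD) from a tensor field."""
    evals = eigenvalues_descending(tfield.tensors)
    n_neg = int(((evals < 0) & tfield.mask[..., None]).any(axis=-1).sum())
    if n_neg:
        logger.debug("tensor_metrics: clipped negative eigenvalues in %d voxels", n_neg)
    vals = metrics_from_eigenvalues(evals)
    return {
        name: ScalarMap(values=v, metric=name, correction=correction,
                        mask=tfield.mask.copy(), affine=tfield.affine)
        for name, v in vals.items()
    }
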