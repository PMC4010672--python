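"""Reading and writing of diffusion MRI artifacts.

Volumes travel as NIfTI-1 (via nibabel), gradient tables as FSL-dialect
``bvals``/``bvecs`` whitespace-separated text (bvecs = 3 rows x G columns),
and streamlines as TCK.  The :class:`GradientScheme` and :class:`DWIVolume`
containers validate their invariants on construction so that downstream fits
can assume a clean acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("fwelim")

#: b-values below this (s/mm^2) are treated as b=0, tolerating scanners that
#: report small non-zero values for the unweighted volumes.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """Malformed on-disk input (shape mismatch, non-finite voxels, ...)."""


class ParameterError(ValueError):
    """Invalid parameter value for an operation."""


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: b-values (s/mm^2) and unit direction vectors.

    Directions with b < :data:`B0_THRESHOLD` count as unweighted (b=0); all
    other directions must be unit vectors.  At least six non-collinear
    weighted directions are required for tensor fitting.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (len(bvals), 3):
            raise FormatError(
                f"bvecs shape {bvecs.shape} does not match {len(bvals)} b-values"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        dw = self.dw_mask
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise FormatError("non-b0 direction with non-unit norm (zero vector at non-zero b?)")
        if self._n_independent_directions() < 6:
            raise ParameterError("need at least 6 non-collinear non-zero-b directions")

    def _n_independent_directions(self) -> int:
        g = self.bvecs[self.dw_mask]
        if len(g) == 0:
            return 0
        # rank of the design {g_x^2, g_y^2, g_z^2, g_x g_y, g_x g_z, g_y g_z}
        q = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2],
        ])
        return int(np.linalg.matrix_rank(q))

    @property
    def dw_mask(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) entries."""
        return self.bvals >= B0_THRESHOLD

    @property
    def b0_mask(self) -> np.ndarray:
        return ~self.dw_mask

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal lattice plus its gradient scheme."""

    signal: np.ndarray          # (X, Y, Z, G), arbitrary units, finite, >= 0
    scheme: GradientScheme
    voxel_size: np.ndarray      # (3,) mm
    affine: np.ndarray          # 4x4 voxel-to-world

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[-1] != len(self.scheme):
            raise FormatError(
                f"signal has {self.signal.shape[-1]} volumes but scheme has "
                f"{len(self.scheme)} entries"
            )
        bad = ~np.isfinite(self.signal)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise FormatError(f"non-finite signal value at voxel index {idx}")
        if (self.signal < 0).any():
            raise FormatError("negative signal values")
        if (self.voxel_size <= 0).any() or self.voxel_size.shape != (3,):
            raise FormatError("voxel_size must be 3 strictly positive values")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.signal.shape[:3]

    def b0_mean(self) -> np.ndarray:
        """Mean signal over the unweighted volumes, one value per voxel."""
        return self.signal[..., self.scheme.b0_mask].mean(axis=-1)


def read_gradient_table(bval_path, bvec_path) -> GradientScheme:
    """Read FSL-dialect bvals/bvecs text files into a validated scheme."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"bvec columns ({bvecs.shape[0]}) do not match bvals ({bvals.size})"
        )
    # renormalise weighted directions to unit length; zero vectors stay zero
    # and are caught by GradientScheme validation when paired with b > 0
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs[nz] = bvecs[nz] / norms[nz, None]
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4-D NIfTI plus its FSL gradient table into a :class:`DWIVolume`."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    scheme = read_gradient_table(bval_path, bvec_path)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    vol = DWIVolume(signal=data, scheme=scheme, voxel_size=voxel_size,
                    affine=np.asarray(img.affine))
    logger.info("read_dwi: %s shape=%s G=%d n_b0=%d", image_path,
                vol.shape, len(scheme), scheme.n_b0)
    return vol


def write_dwi(vol: DWIVolume, image_path, bval_path=None, bvec_path=None) -> Path:
    """Write a DWIVolume as NIfTI (+ optional bvals/bvecs text files)."""
    img = nib.Nifti1Image(vol.signal, vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        np.savetxt(bval_path, vol.scheme.bvals[None, :], fmt="%.1f")
    if bvec_path is not None:
        np.savetxt(bvec_path, vol.scheme.bvecs.T, fmt="%.8f")
    return Path(image_path)


def write_scalar_map(scalar_map, path) -> Path:
    """Write a ScalarMap to NIfTI; voxels outside the mask are written as 0.

    Raises :class:`FormatError` on non-finite values inside the mask.
    """
    values = np.asarray(scalar_map.values, dtype=float)
    mask = np.asarray(scalar_map.mask, dtype=bool)
    if not np.all(np.isfinite(values[mask])):
        raise FormatError(f"non-finite {scalar_map.metric} value inside the mask")
    out = np.where(mask, values, 0.0)
    nib.save(nib.Nifti1Image(out, np.asarray(scalar_map.affine, dtype=float)), str(path))
    logger.info("write_scalar_map: %s (%s/%s) -> %s", scalar_map.metric,
                scalar_map.correction, out.shape, path)
    return Path(path)


def read_scalar_map(path, metric: str = "FA", correction: str = "uncorrected"):
    """Read a NIfTI into a ScalarMap; zero voxels become the mask complement."""
    from .tensor import ScalarMap

    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    return ScalarMap(values=values, metric=metric, correction=correction,
                     mask=values != 0, affine=np.asarray(img.affine))


def make_gradient_scheme(n_dirs: int, b: float, n_b0: int, seed: int = 0,
                         n_iter: int = 300) -> GradientScheme:
    """Generate ``n_dirs`` approximately uniform half-sphere directions.

    Directions are spread by iterative electrostatic repulsion with antipodal
    symmetry (each point repels both the others and their mirror images),
    which is how optimised diffusion gradient tables are constructed.
    Deterministic for a given seed.
    """
    if n_dirs < 6:
        raise ParameterError("at least 6 diffusion directions are required")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_dirs, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.08
    for it in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]          # repulsion from points
        anti = v[:, None, :] + v[None, :, :]          # ... and their antipodes
        d2 = (diff ** 2).sum(-1) + np.eye(n_dirs)
        a2 = (anti ** 2).sum(-1)
        force = (diff / d2[..., None] ** 1.5).sum(1) + (anti / a2[..., None] ** 1.5).sum(1)
        np.fill_diagonal(d2, np.inf)
        v = v + step * force / n_dirs
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.985
    # canonical hemisphere (z >= 0) for reproducible sign convention
    flip = v[:, 2] < 0
    v[flip] = -v[flip]
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), v])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def min_pairwise_angle_deg(scheme: GradientScheme) -> float:
    """Smallest pairwise angle (degrees, antipodally symmetric) among the
    diffusion-weighted directions — a spread audit for generated schemes."""
    g = scheme.bvecs[scheme.dw_mask]
    dots = np.abs(g @ g.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1, 1))))
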