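"""Synthetic two-group diffusion MRI cohorts with known ground truth.

The phantom emulates the situation the free-water analysis is built for: a
thin white-matter bundle running alongside a CSF-filled space (a fornix
analogue), a deep bundle far from CSF (a parahippocampal-cingulum analogue),
and isotropic background tissue.  Near CSF the tissue volume fraction ``f``
declines smoothly, so boundary voxels contain a mixture of tissue and free
water.  The forward signal model is the non-exchanging two-compartment
bi-exponential

    S(g, b) = S0 * [ f * exp(-b g^T D_t g) + (1 - f) * exp(-b * d_w) ]

with ``D_t`` the tissue tensor and ``d_w`` the free-water diffusivity.
Magnitude-MRI noise is Rician.  A cohort applies group effects of two kinds:
*intrinsic* change (scaled tissue eigenvalues) and *atrophy* (the f profile
pulled toward CSF), which is exactly the confound the analysis quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.special import expit

from .io import DWIVolume, GradientScheme, ParameterError

#: free-water diffusivity at body temperature, mm^2/s
FREE_WATER_DIFFUSIVITY = 3.0e-3

#: canonical healthy white-matter bundle eigenvalues, mm^2/s
BUNDLE_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)

#: isotropic background (grey-matter-like) diffusivity, mm^2/s
BACKGROUND_DIFFUSIVITY = 0.7e-3


class SpecificationError(ValueError):
    """Inconsistent phantom specification (e.g. overlapping structures)."""


# ---------------------------------------------------------------------------
# geometry primitives (voxel coordinates, half-open bounds)

@dataclass(frozen=True)
class Box:
    """Axis-aligned box with a constant fibre direction."""

    lo: tuple
    hi: tuple
    axis: tuple = (0.0, 1.0, 0.0)

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((ijk >= lo) & (ijk < hi), axis=-1)

    def direction(self, ijk: np.ndarray) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        return np.broadcast_to(a, ijk.shape[:-1] + (3,)).copy()


@dataclass(frozen=True)
class Cylinder:
    """Circular-cross-section tube along a coordinate axis."""

    center: tuple          # 3-vector; the component along `axis_dim` is ignored
    radius: float
    axis_dim: int = 1      # 0=x, 1=y, 2=z
    lo: float = -np.inf    # extent along the axis
    hi: float = np.inf

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        perp = [d for d in range(3) if d != self.axis_dim]
        r2 = sum((ijk[..., d] - c[d]) ** 2 for d in perp)
        along = ijk[..., self.axis_dim]
        return (r2 <= self.radius ** 2) & (along >= self.lo) & (along < self.hi)

    def direction(self, ijk: np.ndarray) -> np.ndarray:
        a = np.zeros(3)
        a[self.axis_dim] = 1.0
        return np.broadcast_to(a, ijk.shape[:-1] + (3,)).copy()


@dataclass(frozen=True)
class Arc:
    """Curved tube: a circular arc of radius ``radius`` in the plane spanned
    by axes ``plane`` around ``center``, with tube radius ``tube_radius``.
    Fibre direction is the local tangent.  Angles in radians, measured from
    the first plane axis."""

    center: tuple
    radius: float
    tube_radius: float
    plane: tuple = (0, 1)
    angle_range: tuple = (0.0, np.pi / 2)

    def _polar(self, ijk: np.ndarray):
        c = np.asarray(self.center, dtype=float)
        u = ijk[..., self.plane[0]] - c[self.plane[0]]
        v = ijk[..., self.plane[1]] - c[self.plane[1]]
        return u, v, np.hypot(u, v), np.arctan2(v, u)

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        u, v, r, theta = self._polar(ijk)
        off_dim = [d for d in range(3) if d not in self.plane][0]
        w = ijk[..., off_dim] - c[off_dim]
        in_ring = (np.abs(r - self.radius) <= self.tube_radius) & \
                  (np.abs(w) <= self.tube_radius)
        lo, hi = self.angle_range
        return in_ring & (theta >= lo) & (theta <= hi)

    def direction(self, ijk: np.ndarray) -> np.ndarray:
        u, v, r, theta = self._polar(ijk)
        out = np.zeros(ijk.shape[:-1] + (3,))
        out[..., self.plane[0]] = -np.sin(theta)
        out[..., self.plane[1]] = np.cos(theta)
        return out


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class Structure:
    name: str
    geometry: object
    eigenvalues: tuple = BUNDLE_EIGENVALUES


def logistic_f_profile(distance, width: float = 2.0, steepness: float = 4.0):
    """Logistic decline of tissue fraction from 1 to 0 over ``width`` voxels
    of distance to CSF, rescaled to hit exactly 0 at distance 0 and exactly 1
    at ``width``."""
    d = np.asarray(distance, dtype=float)
    t = np.clip(d / width, 0.0, 1.0)
    lo, hi = expit(-steepness / 2), expit(steepness / 2)
    return (expit(steepness * (t - 0.5)) - lo) / (hi - lo)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal parameters of one synthetic head."""

    grid_shape: tuple = (16, 14, 8)
    voxel_size: tuple = (2.4, 2.4, 2.4)           # mm, emulating the acquisition
    structures: tuple = ()
    csf_regions: tuple = ()
    f_profile: object = logistic_f_profile
    s0: float = 1000.0
    noise_sigma: float = 40.0                      # s0 / 25 default SNR
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    """Two-group design: group A ("patient") receives the effects."""

    n_group_a: int = 25
    n_group_b: int = 20
    intrinsic_effect: dict = dc_field(default_factory=dict)   # name -> (3,) fractional eigenvalue change
    atrophy_effect: dict = dc_field(default_factory=dict)     # name -> f-profile shift toward CSF (voxels)
    between_subject_sd: float = 0.12   # fractional jitter of eigenvalues/atrophy
    seed: int = 0

    def __post_init__(self):
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise SpecificationError("need at least 2 subjects per group")


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Fornix-analogue (thin, abutting CSF) + deep-bundle (PHC-analogue) head.

    A ventricle-like CSF slab sits at x in [9, 13); the fornix analogue is a
    three-voxel-wide bundle directly against it, so its boundary column is
    partial-volumed; the deep bundle sits more than four voxels away and is
    uncontaminated.
    """
    structures = (
        Structure("fornix", Box(lo=(6, 2, 3), hi=(9, 12, 5))),
        Structure("deep_bundle", Box(lo=(2, 2, 3), hi=(4, 12, 5))),
    )
    csf = (Box(lo=(9, 2, 2), hi=(13, 12, 7)),)
    return replace(PhantomSpec(structures=structures, csf_regions=csf), **overrides)


def default_cohort_spec(**overrides) -> CohortSpec:
    """Atrophy-only two-group design at the study's group sizes (25 vs 20).

    The patient group's tissue-fraction profile is pulled half a voxel toward
    the CSF border of the fornix analogue; tissue tensors are identical in
    both groups, so any apparent group difference in uncorrected diffusivity
    there is pure CSF contamination.  Between-subject jitter of 12% matches
    the coefficient of variation typical of tract-mean diffusivity in
    elderly cohorts.
    """
    return replace(CohortSpec(atrophy_effect={"fornix": 0.5}), **overrides)


# ---------------------------------------------------------------------------
# phantom construction

def build_phantom(spec: PhantomSpec, atrophy_shift: dict | None = None):
    """Materialise (tensor field, f field, label volume) from a spec.

    ``atrophy_shift`` maps structure names to a reduction (in voxels) of the
    distance argument of the f profile, emulating atrophy-driven loss of
    tissue fraction near CSF.  Labels: 0 background tissue, 1.. structures in
    order, -1 CSF.
    """
    shape = tuple(spec.grid_shape)
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                   axis=-1).astype(float) + 0.5     # voxel centres
    labels = np.zeros(shape, dtype=int)
    tensors = np.empty(shape + (3, 3))
    tensors[:] = np.eye(3) * BACKGROUND_DIFFUSIVITY

    for k, st in enumerate(spec.structures, start=1):
        inside = st.geometry.contains(ijk)
        clash = inside & (labels > 0)
        if clash.any():
            raise SpecificationError(
                f"structure '{st.name}' overlaps another structure")
        labels[inside] = k
        dirs = st.geometry.direction(ijk)[inside]
        ev = np.asarray(st.eigenvalues, dtype=float)
        if (ev <= 0).any() or (ev > FREE_WATER_DIFFUSIVITY).any():
            raise SpecificationError(
                f"structure '{st.name}': eigenvalues must be in (0, d_w]")
        tensors[inside] = _axial_tensors(dirs, ev)

    csf = np.zeros(shape, dtype=bool)
    for region in spec.csf_regions:
        csf |= region.geometry.contains(ijk) if isinstance(region, Structure) \
            else region.contains(ijk)
    labels[csf] = -1
    tensors[csf] = np.eye(3) * FREE_WATER_DIFFUSIVITY

    if csf.any():
        dist = distance_transform_edt(~csf)
        if atrophy_shift:
            name_to_label = {st.name: k for k, st in enumerate(spec.structures, 1)}
            for name, shift in atrophy_shift.items():
                sel = labels == name_to_label[name]
                dist = np.where(sel, np.maximum(dist - float(shift), 0.0), dist)
        f = np.asarray(spec.f_profile(dist), dtype=float)
        f[csf] = 0.0
    else:
        f = np.ones(shape)

    if ((f < 0) | (f > 1)).any():
        raise SpecificationError("f profile produced values outside [0, 1]")
    return tensors, f, labels


def _axial_tensors(dirs: np.ndarray, eigenvalues: np.ndarray) -> np.ndarray:
    """Axially symmetric tensors with principal axis ``dirs`` (N, 3)."""
    l1, l2, l3 = eigenvalues
    lperp = 0.5 * (l2 + l3)
    outer = dirs[..., :, None] * dirs[..., None, :]
    return lperp * np.eye(3) + (l1 - lperp) * outer


# ---------------------------------------------------------------------------
# forward signal model

def simulate_signal(tensors: np.ndarray, f: np.ndarray, scheme: GradientScheme,
                    s0: float = 1000.0, noise_sigma: float = 0.0,
                    seed: int = 0, d_w: float = FREE_WATER_DIFFUSIVITY,
                    voxel_size=(2.4, 2.4, 2.4), affine=None) -> DWIVolume:
    """Evaluate the two-compartment bi-exponential and add Rician noise.

    With ``noise_sigma == 0`` the model is exact; otherwise the signal is
    the magnitude of a complex Gaussian perturbation (Rician), deterministic
    for a given seed.
    """
    f = np.asarray(f, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ParameterError("tissue fraction f must lie in [0, 1]")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    shape = f.shape
    b, g = scheme.bvals, scheme.bvecs
    q = np.einsum("...ij,gi,gj->...g", tensors, g, g)      # g^T D g
    tissue = np.exp(-b * q)
    water = np.exp(-b * d_w)
    signal = s0 * (f[..., None] * tissue + (1 - f[..., None]) * water)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        re = signal + noise_sigma * rng.standard_normal(signal.shape)
        im = noise_sigma * rng.standard_normal(signal.shape)
        signal = np.hypot(re, im)
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    return DWIVolume(signal=signal, scheme=scheme,
                     voxel_size=np.asarray(voxel_size, dtype=float), affine=affine)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class Subject:
    subject_id: str
    group: str                 # "patient" | "control"
    dwi: DWIVolume
    true_tensors: np.ndarray
    true_f: np.ndarray
    labels: np.ndarray


def simulate_cohort(phantom: PhantomSpec, cohort: CohortSpec,
                    scheme: GradientScheme) -> list:
    """Simulate the full two-group cohort with stored ground truth.

    Group A ("patient") receives the intrinsic and atrophy effects; every
    subject gets an independent multiplicative eigenvalue jitter (shared
    across structures) and an independent noise realisation.  Fully
    reproducible from ``cohort.seed``.
    """
    rng = np.random.default_rng(cohort.seed)
    subjects = []
    name_list = [st.name for st in phantom.structures]
    # Biological variability: independent axial/radial eigenvalue jitter per
    # subject (varies MD *and* FA).  The jitter table is shared between the
    # groups (common random numbers): subject i of either group carries the
    # same draw, so the only *systematic* group difference is the modelled
    # effect — an atrophy-only cohort then has identical group tissue-tensor
    # samples by construction, not merely in expectation.
    n_max = max(cohort.n_group_a, cohort.n_group_b)
    jit_table = 1.0 + cohort.between_subject_sd * rng.standard_normal((n_max, 2))
    jit_table = np.maximum(jit_table, 0.2)
    for group, n in (("patient", cohort.n_group_a), ("control", cohort.n_group_b)):
        for i in range(n):
            jit_ax, jit_rad = jit_table[i]
            jit = np.array([jit_ax, jit_rad, jit_rad])
            structures = []
            for st in phantom.structures:
                ev = np.asarray(st.eigenvalues, dtype=float)
                if group == "patient" and st.name in cohort.intrinsic_effect:
                    ev = ev * (1.0 + np.asarray(cohort.intrinsic_effect[st.name]))
                if (ev <= 0).any():
                    raise SpecificationError("intrinsic effect made an eigenvalue non-positive")
                structures.append(replace(st, eigenvalues=tuple(ev * jit)))
            spec_i = replace(phantom, structures=tuple(structures))
            shift = None
            if group == "patient" and cohort.atrophy_effect:
                sjit = 1.0 + cohort.between_subject_sd * rng.standard_normal()
                shift = {k: v * max(sjit, 0.0) for k, v in cohort.atrophy_effect.items()}
            tensors, f, labels = build_phantom(spec_i, atrophy_shift=shift)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            dwi = simulate_signal(tensors, f, scheme, s0=phantom.s0,
                                  noise_sigma=phantom.noise_sigma,
                                  seed=noise_seed, voxel_size=phantom.voxel_size)
            subjects.append(Subject(
                subject_id=f"{group[:3]}{i:02d}", group=group, dwi=dwi,
                true_tensors=tensors, true_f=f, labels=labels))
    assert name_list == [st.name for st in phantom.structures]
    return subjects


def write_cohort(subjects: list, out_dir) -> "pandas.DataFrame":
    """Write per-subject DWIs, gradient tables and ground truth plus a
    manifest TSV (subject, group, paths) into ``out_dir``."""
    import pandas as pd
    from pathlib import Path

    import nibabel as nib

    from .io import write_dwi

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        base = out / s.subject_id
        write_dwi(s.dwi, f"{base}_dwi.nii.gz", f"{base}.bval", f"{base}.bvec")
        nib.save(nib.Nifti1Image(s.true_f, s.dwi.affine), f"{base}_truef.nii.gz")
        nib.save(nib.Nifti1Image(s.labels.astype(np.int16), s.dwi.affine),
                 f"{base}_labels.nii.gz")
        rows.append({"subject": s.subject_id, "group": s.group,
                     "dwi": f"{base}_dwi.nii.gz", "bval": f"{base}.bval",
                     "bvec": f"{base}.bvec", "true_f": f"{base}_truef.nii.gz",
                     "labels": f"{base}_labels.nii.gz"})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
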