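"""Group-level statistics and the CSF-contamination attribution arithmetic.

Covers the comparisons a case-control diffusion study runs on tract and
histogram summaries: pooled-variance unpaired t-tests, Cohen's d, the
2 (group) x 2 (uncorrected vs corrected, repeated) mixed-design ANOVA, and
the headline attribution computation: expressing each group difference
relative to the control mean before and after free-water correction, the
share of the apparent difference attributable to CSF contamination is

    pct_attributed = 100 * (rel_u - rel_c) / rel_u        (rel_u > rel_c)

while a correction that *enlarges* the relative difference unmasks intrinsic
change hidden by contamination:

    pct_unmasked  = 100 * (rel_c - rel_u) / rel_u         (rel_c > rel_u)

with rel = |group difference| / control mean.  Exactly one of the two is
reported per comparison, by the sign of (rel_u - rel_c).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ParameterError


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table style summary of one group: n, mean, sd."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("group needs n >= 2")
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")


@dataclass
class AnovaResult:
    F_within: float
    p_within: float
    F_interaction: float
    p_interaction: float
    F_between: float
    p_between: float
    df_within: tuple
    df_between: tuple
    n_dropped: int = 0


@dataclass
class AttributionResult:
    rel_diff_uncorrected: float
    rel_diff_corrected: float
    pct_attributed_to_csfc: float | None   # correction shrank the difference
    pct_unmasked: float | None             # correction enlarged it

    def rounded(self) -> int:
        """Reported integer percentage (half away from zero)."""
        pct = self.pct_attributed_to_csfc if self.pct_attributed_to_csfc is not None \
            else self.pct_unmasked
        return int(math.floor(abs(pct) + 0.5)) * (1 if pct >= 0 else -1)


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[np.isfinite(x)]


def two_sample_t(a, b):
    """Pooled-variance two-tailed unpaired t-test; returns (t, df, p)."""
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 finite values")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ParameterError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def two_sample_t_from_summary(a: GroupSummary, b: GroupSummary):
    """Summary-statistics pooled t-test (for printed Mean/SD/n tables)."""
    t, p = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                    equal_var=True)
    return float(t), a.n + b.n - 2, float(p)


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    df = a.n + b.n - 2
    return math.sqrt(((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df)


def cohens_d(a, b) -> float:
    """Cohen's d with (n-1)-weighted pooled SD, absolute-value convention
    (invariant to exchanging the groups)."""
    if isinstance(a, GroupSummary) and isinstance(b, GroupSummary):
        sp = _pooled_sd(a, b)
        if sp == 0:
            raise ParameterError("zero pooled SD")
        return abs(a.mean - b.mean) / sp
    a, b = _clean(a), _clean(b)
    sa = GroupSummary("a", len(a), float(a.mean()), float(a.std(ddof=1)))
    sb = GroupSummary("b", len(b), float(b.mean()), float(b.std(ddof=1)))
    return cohens_d(sa, sb)


def mixed_anova(uncorrected, corrected, groups) -> AnovaResult:
    """2 (between: group) x 2 (within: correction) mixed-design ANOVA.

    Classical sums-of-squares decomposition on the subject x condition table;
    subjects with a missing member of the pair are dropped with a warning
    (per-comparison exclusion, not listwise).
    """
    u = np.asarray(uncorrected, dtype=float)
    c = np.asarray(corrected, dtype=float)
    g = np.asarray(groups)
    ok = np.isfinite(u) & np.isfinite(c)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"mixed_anova: dropped {n_dropped} subjects with "
                      "missing pair members", stacklevel=2)
    u, c, g = u[ok], c[ok], g[ok]
    levels = np.unique(g)
    if len(levels) != 2:
        raise ParameterError("exactly two groups are required")
    y = np.stack([u, c], axis=1)              # (N, 2)
    n = len(y)
    k = 2
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)

    is_a = g == levels[0]
    ng = {0: int(is_a.sum()), 1: int((~is_a).sum())}
    grp_means = {0: subj_means[is_a].mean(), 1: subj_means[~is_a].mean()}
    cell_means = {(0, j): y[is_a, j].mean() for j in range(k)}
    cell_means.update({(1, j): y[~is_a, j].mean() for j in range(k)})

    ss_between = k * sum(ng[i] * (grp_means[i] - grand) ** 2 for i in range(2))
    ss_subj_tot = k * ((subj_means - grand) ** 2).sum()
    ss_err_between = ss_subj_tot - ss_between

    ss_within_tot = ((y - subj_means[:, None]) ** 2).sum()
    # cell-level within-subject SS split into condition main effect and interaction
    ss_cells_ws = sum(ng[i] * (cell_means[i, j] - grp_means[i]) ** 2
                      for i in range(2) for j in range(k))
    w_cond = np.array([sum(ng[i] * (cell_means[i, j] - grp_means[i]) for i in range(2))
                       for j in range(k)]) / n
    ss_cond = n * (w_cond ** 2).sum()
    ss_inter = ss_cells_ws - ss_cond
    ss_err_within = ss_within_tot - ss_cells_ws

    df_b, df_eb = 1, n - 2
    df_w, df_i, df_ew = k - 1, k - 1, (n - 2) * (k - 1)

    scale = max(float(((y - grand) ** 2).sum()), np.finfo(float).tiny)

    def f_and_p(ss, df, ss_err, df_err):
        # degenerate designs: an effect (or error) SS at float-noise level
        # relative to the total SS counts as zero
        tol = 1e-12 * scale
        if ss_err <= tol:
            return (0.0, 1.0) if ss <= tol else (np.inf, 0.0)
        F = (ss / df) / (ss_err / df_err)
        return float(F), float(sps.f.sf(F, df, df_err))

    F_b, p_b = f_and_p(ss_between, df_b, ss_err_between, df_eb)
    F_w, p_w = f_and_p(ss_cond, df_w, ss_err_within, df_ew)
    F_i, p_i = f_and_p(ss_inter, df_i, ss_err_within, df_ew)
    return AnovaResult(F_within=F_w, p_within=p_w, F_interaction=F_i,
                       p_interaction=p_i, F_between=F_b, p_between=p_b,
                       df_within=(df_w, df_ew), df_between=(df_b, df_eb),
                       n_dropped=n_dropped)


def csfc_attribution(patient_u: float, control_u: float,
                     patient_c: float, control_c: float) -> AttributionResult:
    """Share of an apparent group difference attributable to CSF contamination.

    Arguments are the four group means (patient/control, uncorrected/
    corrected).  Relative differences use the control mean as denominator.
    """
    if control_u == 0 or control_c == 0:
        raise ParameterError("control means must be non-zero")
    rel_u = abs(patient_u - control_u) / abs(control_u)
    rel_c = abs(patient_c - control_c) / abs(control_c)
    if rel_u == 0:
        if rel_c == 0:
            return AttributionResult(0.0, 0.0, 0.0, None)
        raise ParameterError("uncorrected relative difference is zero; "
                             "attribution undefined")
    if rel_u >= rel_c:
        return AttributionResult(rel_u, rel_c,
                                 100.0 * (rel_u - rel_c) / rel_u, None)
    return AttributionResult(rel_u, rel_c, None,
                             100.0 * (rel_c - rel_u) / rel_u)
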