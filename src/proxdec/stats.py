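"""Group-level inference for sub-ROI robustness curves and voxel maps.

Implements the summary statistics used downstream of decoding: averaging
classifier-information curves over voxel counts and hemispheres, one-sample
and paired t tests with Cohen's d and 95% CIs, the 2x2 within-subject
interaction F, one-dimensional threshold-free cluster enhancement (TFCE)
with a sign-flip permutation null, within-ROI univariate means, whole-brain
cluster-extent contrasts, and the inattentive-participant exclusion rule
(first quartile minus two interquartile ranges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "TestResult",
    "TFCEResult",
    "summarize_curve",
    "one_sample_t",
    "paired_t",
    "interaction_anova_2x2",
    "tfce_1d",
    "tfce_signflip_test",
    "exclude_inattentive",
    "univariate_roi",
    "whole_brain_contrast",
]


@dataclass
class TestResult:
    statistic: float
    dof: float
    p: float
    cohens_d: float
    ci_low: float
    ci_high: float
    sided: str = "two"
    zero_variance: bool = False

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic, "dof": self.dof, "p": self.p,
            "cohens_d": self.cohens_d, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "sided": self.sided,
        }


@dataclass
class TFCEResult:
    observed_t: np.ndarray
    observed_tfce: np.ndarray
    z: np.ndarray
    p_fwe: np.ndarray
    n_permutations: int
    seed: int
    null_mode: str = "max"


def summarize_curve(
    curve: pd.DataFrame,
    value_col: str = "value",
    over=("n_voxels", "hemisphere"),
    by=("condition",),
) -> pd.DataFrame:
    """Per-condition scalar summary: mean over voxel counts and hemispheres.

    Requires a complete grid (every ``by`` level present for every ``over``
    cell).
    """
    by = list(by)
    over = [c for c in over if c in curve.columns]
    sizes = curve.groupby(by, sort=True).size()
    if sizes.nunique() > 1:
        raise ValueError(f"incomplete curve: cell sizes {dict(sizes)}")
    out = curve.groupby(by, sort=True, as_index=False)[value_col].mean()
    return out


def _t_result(mean, sd, n, sided) -> TestResult:
    se = sd / np.sqrt(n)
    dof = n - 1
    if sd == 0:
        t = 0.0 if mean == 0 else np.inf * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        d = 0.0 if mean == 0 else np.inf * np.sign(mean)
        return TestResult(t, dof, p, d, mean, mean, sided, zero_variance=True)
    t = mean / se
    if sided == "two":
        p = 2 * sps.t.sf(abs(t), dof)
        tcrit = sps.t.ppf(0.975, dof)
    else:
        p = sps.t.sf(t, dof)
        tcrit = sps.t.ppf(0.975, dof)
    return TestResult(
        statistic=float(t), dof=float(dof), p=float(p), cohens_d=float(mean / sd),
        ci_low=float(mean - tcrit * se), ci_high=float(mean + tcrit * se),
        sided=sided,
    )


def one_sample_t(values, popmean: float = 0.0, sided: str = "two") -> TestResult:
    """One-sample t test against ``popmean`` with Cohen's d = mean/SD."""
    x = np.asarray(values, dtype=float) - popmean
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return _t_result(x.mean(), x.std(ddof=1), x.size, sided)


def paired_t(a, b, sided: str = "two") -> TestResult:
    """Paired t test on ``a - b``; d = mean difference / SD of differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, sided=sided)


def interaction_anova_2x2(table: np.ndarray):
    """Repeated-measures interaction F for a subjects x 2 x 2 table.

    ``table[s, i, j]`` holds subject ``s`` in level ``i`` of factor A
    (e.g. congruency) and level ``j`` of factor B (e.g. ROI).  Returns
    ``(F, p, partial_eta_squared)`` with (1, n-1) degrees of freedom.
    Algebraically, F equals the squared paired t of the per-subject
    difference of differences.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise ValueError("table must be subjects x 2 x 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cell in the within-subject table")
    n = x.shape[0]
    grand = x.mean()
    cell = x.mean(axis=0)              # 2 x 2 cell means
    a_m = x.mean(axis=(0, 2))          # factor A marginal means
    b_m = x.mean(axis=(0, 1))
    s_m = x.mean(axis=(1, 2))          # subject means
    as_m = x.mean(axis=2)              # subject x A
    bs_m = x.mean(axis=1)              # subject x B
    ss_ab = n * np.sum((cell - a_m[:, None] - b_m[None, :] + grand) ** 2)
    resid = (
        x
        - as_m[:, :, None]
        - bs_m[:, None, :]
        + s_m[:, None, None]
        - cell[None, :, :]
        + a_m[None, :, None]
        + b_m[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)
    dof_err = n - 1
    if ss_abs == 0:
        F = 0.0 if ss_ab == 0 else np.inf
        p = 1.0 if ss_ab == 0 else 0.0
        pes = 0.0 if ss_ab == 0 else 1.0
        return F, p, pes
    F = float(ss_ab / (ss_abs / dof_err))
    p = float(sps.f.sf(F, 1, dof_err))
    pes = float(ss_ab / (ss_ab + ss_abs))
    return F, p, pes


@njit(cache=True)
def _tfce_one_sign(t, E, H, dh):  # pragma: no cover - exercised via tfce_1d
    """TFCE for the nonnegative part of a 1D statistic curve."""
    P = t.shape[0]
    out = np.zeros(P)
    tmax = 0.0
    for i in range(P):
        if t[i] > tmax:
            tmax = t[i]
    if tmax <= 0 or dh <= 0:
        return out
    n_steps = int(np.floor(tmax / dh + 1e-12))
    for k in range(1, n_steps + 1):
        h = k * dh
        hh = h**H * dh
        i = 0
        while i < P:
            if t[i] >= h:
                j = i
                while j + 1 < P and t[j + 1] >= h:
                    j += 1
                add = (j - i + 1) ** E * hh
                for s in range(i, j + 1):
                    out[s] += add
                i = j + 1
            else:
                i += 1
    return out


def tfce_1d(
    tcurve: np.ndarray, E: float = 0.5, H: float = 2.0, dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 1D statistic curve.

    Each point accumulates ``extent(h)**E * h**H * dh`` over thresholds
    ``h = dh, 2dh, ... <= t``, where extent is the length of the contiguous
    suprathreshold run containing the point.  Negative statistics are
    enhanced on the mirrored curve with the sign restored.  When ``dh`` is
    not given it is set to ``max |t| / n_steps``.
    """
    t = np.asarray(tcurve, dtype=float)
    if dh is None:
        tmax = np.max(np.abs(t), initial=0.0)
        if tmax == 0:
            return np.zeros_like(t)
        dh = tmax / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _tfce_one_sign(np.where(t > 0, t, 0.0), E, H, dh)
    neg = _tfce_one_sign(np.where(t < 0, -t, 0.0), E, H, dh)
    return pos - neg


def _t_curves(curves: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t curves for sign-flipped cohorts.

    ``signs`` is permutations x subjects; flipping leaves per-subject squares
    unchanged, so the flipped SD follows from the fixed second moment.
    """
    n = curves.shape[0]
    sumsq = np.sum(curves**2, axis=0)
    m = signs @ curves / n
    var = (sumsq - n * m**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def tfce_signflip_test(
    subject_curves: np.ndarray,
    n_permutations: int = 10_000,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    seed: int = 0,
    null_mode: str = "max",
    sided: str = "two",
) -> TFCEResult:
    """Sign-flip permutation test on TFCE-enhanced one-sample t curves.

    The observed per-point t curve is TFCE-enhanced; the null flips each
    subject's entire curve with probability 1/2 and records, per
    permutation, the maximum enhanced statistic over points
    (``null_mode='max'``, family-wise control) or the per-point values
    (``null_mode='pointwise'``).  ``p_fwe`` uses the add-one permutation
    estimator and ``z`` is the corresponding normal quantile.  ``dh`` is
    fixed from the observed curve (max |t| / 100) and reused for the null.
    """
    X = np.asarray(subject_curves, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a subjects x points matrix with >= 2 subjects")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: unstable tail estimates")
    n, P = X.shape
    t_obs = _t_curves(X, np.ones((1, n)))[0]
    if dh is None:
        tmax = np.max(np.abs(t_obs), initial=0.0)
        dh = tmax / 100 if tmax > 0 else 1.0
    tfce_obs = tfce_1d(t_obs, E=E, H=H, dh=dh)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 707]))
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    t_null = _t_curves(X, signs)
    stat_obs = np.abs(tfce_obs) if sided == "two" else tfce_obs
    if null_mode == "max":
        null_max = np.empty(n_permutations)
        for k in range(n_permutations):
            e = tfce_1d(t_null[k], E=E, H=H, dh=dh)
            null_max[k] = np.max(np.abs(e)) if sided == "two" else np.max(e)
        p = (1 + np.sum(null_max[:, None] >= stat_obs[None, :], axis=0)) / (
            n_permutations + 1
        )
    elif null_mode == "pointwise":
        null_pt = np.empty((n_permutations, P))
        for k in range(n_permutations):
            e = tfce_1d(t_null[k], E=E, H=H, dh=dh)
            null_pt[k] = np.abs(e) if sided == "two" else e
        p = (1 + np.sum(null_pt >= stat_obs[None, :], axis=0)) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")
    z = sps.norm.isf(p)
    return TFCEResult(
        observed_t=t_obs, observed_tfce=tfce_obs, z=z, p_fwe=p,
        n_permutations=n_permutations, seed=seed, null_mode=null_mode,
    )


def exclude_inattentive(per_subject_correlations) -> np.ndarray:
    """Keep-mask: subject excluded iff r < Q1 - 2*IQR (linear-interpolated
    quartiles)."""
    r = np.asarray(per_subject_correlations, dtype=float)
    if r.size < 4:
        raise ValueError("need at least 4 subjects for quartile-based exclusion")
    q1, q3 = np.percentile(r, [25, 75])
    return r >= q1 - 2 * (q3 - q1)


def univariate_roi(
    maintask_betas: list,
    subrois: dict,
    conditions=("congruent", "incongruent"),
) -> pd.DataFrame:
    """Mean beta over voxels within each sub-ROI, then over sub-ROIs.

    ``maintask_betas`` are the congruency-GLM estimates (one beta per
    condition per run).  Returns one row per ROI x condition with the
    subject-level mean activation (runs, sub-ROIs and hemispheres averaged).
    """
    from .decoding import stack_betas

    est, lab = stack_betas(maintask_betas)
    congr = lab["congruency"].to_numpy()
    rows = []
    by_roi = {}
    for (roi, hemi), sub in sorted(subrois.items()):
        for cond in conditions:
            mask = congr == cond
            if not mask.any():
                raise ValueError(f"no betas for condition {cond}")
            cond_mean = est[mask].mean(axis=0)  # over runs
            sub_means = [cond_mean[sub.members(n)].mean() for n in sub.voxel_counts]
            by_roi.setdefault((roi, cond), []).append(float(np.mean(sub_means)))
    for (roi, cond), vals in sorted(by_roi.items()):
        rows.append({"roi": roi, "condition": cond, "mean_beta": float(np.mean(vals))})
    return pd.DataFrame(rows)


def whole_brain_contrast(
    difference_maps: np.ndarray,
    coords: np.ndarray,
    alpha: float = 0.001,
    cluster_min: int = 10,
    sided: str = "two",
):
    """Second-level cluster-extent contrast on a common voxel grid.

    Per-voxel one-sample t across subjects; voxels with p < ``alpha``
    (uncorrected, two-sided or one-sided-greater) are grouped into
    face-adjacent (6-connected) 3D clusters and clusters smaller than
    ``cluster_min`` voxels are removed.

    Returns ``(cluster_table, tmap)``; the table has one row per surviving
    cluster with size, peak coordinates and peak t.
    """
    X = np.asarray(difference_maps, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 subjects of voxel maps")
    coords = np.asarray(coords, dtype=int)
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.nan_to_num(t, nan=0.0)
    if sided == "two":
        p = 2 * sps.t.sf(np.abs(t), n - 1)
    elif sided == "greater":
        p = sps.t.sf(t, n - 1)
    else:
        raise ValueError(f"unknown sided {sided!r}")
    sig = p < alpha

    # embed into a 3D grid for connectivity
    dims = coords.max(axis=0) + 1
    grid = np.zeros(dims, dtype=bool)
    grid[tuple(coords[sig].T)] = True
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n_clusters = ndimage.label(grid, structure=structure)
    voxel_label = labels[tuple(coords.T)]

    rows = []
    for c in range(1, n_clusters + 1):
        members = np.flatnonzero(voxel_label == c)
        if members.size < cluster_min:
            continue
        peak = members[np.argmax(np.abs(t[members]))]
        rows.append({
            "cluster": len(rows) + 1,
            "size": int(members.size),
            "peak_x": int(coords[peak, 0]),
            "peak_y": int(coords[peak, 1]),
            "peak_z": int(coords[peak, 2]),
            "peak_t": float(t[peak]),
        })
    table = pd.DataFrame(
        rows, columns=["cluster", "size", "peak_x", "peak_y", "peak_z", "peak_t"]
    )
    return table, t
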