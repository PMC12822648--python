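"""Information-activation coupling analysis.

For each voxel of the (simulated) brain, the 10-bin FIR activation time
course after stimulus onset is correlated, per condition, with the seed
region's time-resolved classifier-information curve.  Subjects' congruent
and incongruent correlation maps are then contrasted at the group level
with a one-sided cluster-extent test, revealing voxels whose activation
covaries with decodable shape information specifically on congruent trials.

The seed decoding is repeated over several voxel-inclusion settings (by
default the top 500..1000 localizer-ranked voxels pooled across both
hemispheres) and the per-setting correlation maps are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .decoding import stack_betas, time_resolved_decode
from .stats import whole_brain_contrast

__all__ = [
    "CouplingMaps",
    "voxel_timecourses",
    "coupling_maps",
    "coupling_pipeline",
    "coupling_contrast",
    "DEFAULT_SEED_SIZES",
]

DEFAULT_SEED_SIZES = (500, 600, 700, 800, 900, 1000)


@dataclass
class CouplingMaps:
    """Per-voxel seed-coupling correlations for one subject."""

    r: dict                         # condition -> voxel-length correlations
    subject: str = ""
    voxel_count_settings: tuple = DEFAULT_SEED_SIZES
    degenerate: dict = field(default_factory=dict)   # condition -> bool flags


def voxel_timecourses(fir_betas: list, conditions=("congruent", "incongruent")):
    """Per-voxel, per-condition FIR activation curves, averaged across runs
    (and across the proximal-shape regressors within each condition).

    Returns ``{condition: bins x voxels array}``.
    """
    if not fir_betas:
        raise ValueError("no FIR estimates given")
    est, lab = stack_betas(fir_betas)
    n_runs = len({b.run for b in fir_betas})
    if lab.groupby(["congruency", "bin"]).size().nunique() > 1:
        raise ValueError("missing run or condition in FIR estimates")
    out = {}
    congr = lab["congruency"].to_numpy()
    bins = lab["bin"].to_numpy()
    n_bins = bins.max() + 1
    for cond in conditions:
        curves = np.empty((n_bins, est.shape[1]))
        for b in range(n_bins):
            mask = (congr == cond) & (bins == b)
            if not mask.any():
                raise ValueError(f"missing FIR cell: {cond}, bin {b}")
            curves[b] = est[mask].mean(axis=0)
        out[cond] = curves
    return out


def coupling_maps(seed_info_curves: dict, voxel_curves: dict, subject: str = "") -> CouplingMaps:
    """Pearson correlation of each voxel's activation curve with the seed
    information curve, per condition.

    Zero-variance voxels (or a zero-variance seed) contribute r = 0 with a
    flag, keeping map geometry fixed across subjects.
    """
    r, flags = {}, {}
    for cond, seed in seed_info_curves.items():
        seed = np.asarray(seed, dtype=float)
        if seed.size < 3:
            raise ValueError("need at least 3 time bins to correlate")
        V = voxel_curves[cond]
        if V.shape[0] != seed.size:
            raise ValueError("bin count mismatch between seed and voxel curves")
        s = seed - seed.mean()
        s_sd = s.std()
        Vc = V - V.mean(axis=0)
        v_sd = Vc.std(axis=0)
        bad = (v_sd == 0) | (s_sd == 0)
        denom = np.where(bad, 1.0, v_sd * s_sd) * seed.size
        rr = (s @ Vc) / denom
        rr[bad] = 0.0
        r[cond] = rr
        flags[cond] = bad
    return CouplingMaps(r=r, subject=subject, degenerate=flags)


def coupling_pipeline(
    training_betas: list,
    fir_betas: list,
    localizer_t: np.ndarray,
    voxel_meta: pd.DataFrame,
    seed_roi: str = "EVC",
    voxel_count_settings=DEFAULT_SEED_SIZES,
    n_bins: int = 10,
    C: float = 1.0,
    subject: str = "",
) -> CouplingMaps:
    """Full per-subject coupling analysis, averaged over seed sizes.

    For each voxel-count setting the top-N seed voxels (localizer ranking
    pooled across both hemispheres of ``seed_roi``) feed the time-resolved
    decoder; the resulting 10-bin information curves are correlated with
    every voxel's FIR activation curve and the maps are averaged over
    settings.
    """
    in_seed = np.flatnonzero((voxel_meta["roi"] == seed_roi).to_numpy())
    if in_seed.size == 0:
        raise ValueError(f"no voxels in seed ROI {seed_roi!r}")
    order = in_seed[np.lexsort((in_seed, -localizer_t[in_seed]))]
    vox_curves = voxel_timecourses(fir_betas)
    acc = None
    settings = tuple(int(n) for n in voxel_count_settings)
    for n in settings:
        if n > order.size:
            warnings.warn(
                f"seed size {n} exceeds {seed_roi} voxel count {order.size}; truncating"
            )
        seed_idx = order[: min(n, order.size)]
        info = time_resolved_decode(training_betas, fir_betas, seed_idx,
                                    n_bins=n_bins, C=C)
        seed_curves = {
            cond: grp.sort_values("bin")["value"].to_numpy()
            for cond, grp in info.groupby("condition")
        }
        maps = coupling_maps(seed_curves, vox_curves, subject=subject)
        if acc is None:
            acc = {c: v.copy() for c, v in maps.r.items()}
        else:
            for c in acc:
                acc[c] += maps.r[c]
    r = {c: v / len(settings) for c, v in acc.items()}
    return CouplingMaps(r=r, subject=subject, voxel_count_settings=settings)


def coupling_contrast(
    cohort_maps: list,
    coords: np.ndarray,
    alpha: float = 0.001,
    cluster_min: int = 10,
    fisher: bool = False,
):
    """Group cluster contrast of congruent vs. incongruent coupling.

    Per-voxel paired t (congruent - incongruent) across subjects, one-sided
    (greater), thresholded and clustered exactly like the univariate
    whole-brain contrast.  ``fisher=True`` applies the Fisher z transform
    to the correlations first.

    Returns ``(cluster_table, tmap)``.
    """
    if len(cohort_maps) < 3:
        raise ValueError("need at least 3 subjects")
    diffs = []
    for m in cohort_maps:
        a, b = m.r["congruent"], m.r["incongruent"]
        if fisher:
            a, b = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12)), np.arctanh(
                np.clip(b, -1 + 1e-12, 1 - 1e-12)
            )
        diffs.append(a - b)
    return whole_brain_contrast(
        np.vstack(diffs), coords, alpha=alpha, cluster_min=cluster_min,
        sided="greater",
    )
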