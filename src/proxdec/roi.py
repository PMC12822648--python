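"""Localizer-based voxel ranking and nested sub-ROI construction.

Voxels are ranked within each ROI x hemisphere mask by a one-sample t
statistic of the localizer stimuli-vs-baseline contrast across localizer
runs, and the top-N sets for an increasing ladder of N values form nested
sub-ROIs (the protocol ladder is N = 100..6000 in steps of 100, i.e. 60
sub-ROIs per ROI and hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .glm import BetaMaps

__all__ = ["SubROISet", "localizer_tmap", "make_subrois", "default_counts"]

STIMULUS_CATEGORIES = ("objects", "scrambled")


def default_counts(max_n: int = 6000, step: int = 100) -> np.ndarray:
    return np.arange(step, max_n + 1, step)


@dataclass
class SubROISet:
    """Nested top-N voxel subsets for one ROI x hemisphere."""

    roi: str
    hemisphere: str
    voxel_counts: np.ndarray
    order: np.ndarray              # ROI voxels sorted by descending rank statistic

    def members(self, n: int) -> np.ndarray:
        """Voxel indices of the top-``min(n, available)`` set."""
        return self.order[: min(int(n), len(self.order))]

    def to_frame(self) -> pd.DataFrame:
        """Membership table (voxel_index, roi, hemisphere, rank), rank 1 =
        most responsive; exportable as TSV."""
        return pd.DataFrame({
            "voxel_index": self.order,
            "roi": self.roi,
            "hemisphere": self.hemisphere,
            "rank": np.arange(1, len(self.order) + 1),
        })


def localizer_tmap(localizer_betas: list[BetaMaps], stimuli=STIMULUS_CATEGORIES):
    """Per-voxel one-sample t of the stimuli-vs-baseline contrast across runs.

    The contrast is the mean of the stimulus-category betas (objects and
    scrambled objects) in each run; with the fixation baseline absorbed by
    the run intercept, the null value is zero.  Voxels with zero variance
    across runs get ``t = +/-inf`` (sign of the mean; 0 where the mean is
    also 0) and are flagged.

    Returns ``(t, flags)`` arrays of length n_voxels.
    """
    if len(localizer_betas) < 2:
        raise ValueError("need at least 2 localizer runs for a t statistic")
    contrasts = []
    for bm in localizer_betas:
        mask = bm.labels["trial_type"].isin(stimuli).to_numpy()
        if not mask.any():
            raise ValueError(f"no stimulus regressors {stimuli} in localizer betas")
        contrasts.append(bm.estimates[mask].mean(axis=0))
    C = np.vstack(contrasts)
    n = C.shape[0]
    mean = C.mean(axis=0)
    sd = C.std(axis=0, ddof=1)
    flags = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[flags & (mean > 0)] = np.inf
    t[flags & (mean < 0)] = -np.inf
    t[flags & (mean == 0)] = 0.0
    return t, flags


def make_subrois(
    tmap: np.ndarray,
    voxel_meta: pd.DataFrame,
    counts: np.ndarray | None = None,
    rois=("EVC", "LVC"),
) -> dict:
    """Nested sub-ROIs per ROI x hemisphere, ranked by descending ``tmap``.

    Ties are broken by ascending voxel index, making selection deterministic.
    Requested counts exceeding the mask size are truncated with a warning.
    Returns ``{(roi, hemisphere): SubROISet}``.
    """
    counts = default_counts() if counts is None else np.asarray(counts, dtype=int)
    if len(counts) == 0 or np.any(counts <= 0) or np.any(np.diff(counts) <= 0):
        raise ValueError("counts must be positive and strictly increasing")
    out = {}
    roi_arr = voxel_meta["roi"].to_numpy()
    hemi_arr = voxel_meta["hemisphere"].to_numpy()
    for roi in rois:
        for hemi in pd.unique(hemi_arr):
            mask = np.flatnonzero((roi_arr == roi) & (hemi_arr == hemi))
            if mask.size == 0:
                continue
            if counts[-1] > mask.size:
                warnings.warn(
                    f"{roi}/{hemi}: requested N up to {counts[-1]} exceeds mask size "
                    f"{mask.size}; truncating"
                )
            t_roi = tmap[mask]
            # descending t, ties by ascending voxel index
            order = mask[np.lexsort((mask, -t_roi))]
            out[(roi, hemi)] = SubROISet(
                roi=roi, hemisphere=hemi, voxel_counts=counts.copy(), order=order
            )
    return out
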