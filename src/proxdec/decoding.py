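"""Cross-decoding of proximal object shape and the classifier-information
statistic.

Linear SVMs are trained on benchmark patterns from the classifier-training
runs and tested on main-task patterns (and vice versa; results are averaged
across directions).  Decoding performance is summarized as *classifier
information*

    CI = (1/n) * sum_i d_i * l_i

where ``d_i`` are the z-scored (across test samples) signed distances from
the decision boundary, ``l_i`` the true labels (+/-1), and ``n`` the number
of test samples.  CI is 0 at chance by construction and invariant to
positive rescaling of the raw distances.

Experiment 1 uses background-matched decoding: separate classifiers
discriminate the A vs. B object orientations against the 30- and 90-degree
scene backgrounds (conditions A30 vs. B30 and A90 vs. B90), so that shape
information cannot be driven by the background orientation confound.
Classifier information is averaged across backgrounds, across the three
congruent-trial splits (congruent condition only), and across decoding
directions.  Incongruent test labels are the orientation actually shown on
screen.  Experiment 2 trains a single wide-vs-narrow classifier (wide
groups A30 with B90, narrow groups B30 with A90) and tests on the occluded
final-period patterns, catch trials excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glm import BetaMaps
from .svm import LinearModel, train_svm

__all__ = [
    "zscore_features",
    "train_linear_classifier",
    "classifier_information",
    "stack_betas",
    "cross_decode_exp1",
    "cross_decode_exp2",
    "time_resolved_decode",
]


def zscore_features(X: np.ndarray, return_flags: bool = False):
    """Standardize each column to mean 0, population SD 1.

    Zero-variance columns map to all-zero columns (flagged).  Requires at
    least 2 samples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 samples to standardize")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    flags = sd == 0
    sd_safe = np.where(flags, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, flags] = 0.0
    return (Z, flags) if return_flags else Z


def train_linear_classifier(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, meta: dict | None = None
) -> LinearModel:
    """Maximum-margin linear classifier on standardized features.

    ``y`` holds labels +/-1 with the positive class fixed by the caller
    (+1 = "wide", or orientation A in background-matched decoding).
    """
    return train_svm(X, y, C=C, meta=meta)


def classifier_information(
    distances: np.ndarray, labels: np.ndarray, return_flag: bool = False
):
    """Mean of z-scored decision distances times true labels.

    Distances are z-scored with the population SD across test samples;
    zero-variance distances yield 0 (flagged).  Chance level is 0.
    """
    d = np.asarray(distances, dtype=float).ravel()
    l = np.asarray(labels, dtype=float).ravel()
    if d.shape != l.shape:
        raise ValueError(f"{d.size} distances vs {l.size} labels")
    if d.size < 2:
        raise ValueError("need at least 2 test samples")
    if not set(np.unique(l)) <= {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1")
    sd = d.std()
    if sd == 0:
        return (0.0, True) if return_flag else 0.0
    z = (d - d.mean()) / sd
    value = float(np.mean(z * l))
    return (value, False) if return_flag else value


def _accuracy(distances, labels):
    s = np.sign(distances)
    return float(np.mean(np.where(s == 0, 0.5, s == labels)))


def stack_betas(betas: list[BetaMaps]):
    """Stack per-run BetaMaps into one estimate matrix + label table."""
    est = np.vstack([b.estimates for b in betas])
    labs = []
    for b in betas:
        lab = b.labels.copy()
        lab["run"] = b.run
        labs.append(lab)
    return est, pd.concat(labs, ignore_index=True)


def _score_distances(d, y, runs, pooling, accuracy):
    """Classifier information (or accuracy) from raw decision distances."""
    if pooling == "within_run":
        zd = d.copy()
        for r in np.unique(runs):
            m = runs == r
            sd = zd[m].std()
            zd[m] = 0.0 if sd == 0 else (zd[m] - zd[m].mean()) / sd
    elif pooling == "pooled":
        sd = d.std()
        zd = np.zeros_like(d) if sd == 0 else (d - d.mean()) / sd
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")
    if accuracy:
        return _accuracy(d, y)
    return float(np.mean(zd * y))


class _Cell:
    """A z-scored sample set (features standardized across its samples).

    Because standardization is per-voxel, slicing columns after z-scoring
    equals z-scoring the slice, so one pass serves every sub-ROI size.
    """

    __slots__ = ("Z", "y", "runs")

    def __init__(self, est, labels_df, mask, y):
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            raise ValueError("empty decoding cell")
        self.Z = zscore_features(est[rows])
        self.y = y[rows]
        self.runs = labels_df["run"].to_numpy()[rows]


def _require(mask, what):
    if not np.any(mask):
        raise ValueError(f"missing decoding cell: {what}")


def cross_decode_exp1(
    training_betas: list[BetaMaps],
    maintask_betas: list[BetaMaps],
    subrois: dict,
    counts: np.ndarray | None = None,
    C: float = 1.0,
    pooling: str = "pooled",
    accuracy: bool = False,
    n_splits: int = 3,
) -> pd.DataFrame:
    """Background-matched bidirectional cross-decoding (Experiment 1).

    Returns a tidy frame with columns roi, hemisphere, n_voxels, condition
    (congruent / incongruent), direction (forward = train on training runs,
    reverse, mean) and value (classifier information, or accuracy when
    ``accuracy=True``).
    """
    tr_est, tr_lab = stack_betas(training_betas)
    mt_est, mt_lab = stack_betas(maintask_betas)
    tr_bg = tr_lab["background"].to_numpy()
    tr_y = np.where(tr_lab["trial_type"].str.startswith("A"), 1.0, -1.0)
    mt_bg = mt_lab["background"].to_numpy()
    mt_congr = mt_lab["congruency"].to_numpy()
    mt_split = mt_lab["split_id"].to_numpy()
    mt_y = np.where(mt_lab["trial_type"].str.startswith("A"), 1.0, -1.0)

    # z-score once over all voxels; column slices remain valid per sub-ROI
    train_cells, test_cells = {}, {}
    for bg in (30, 90):
        tmask = tr_bg == bg
        _require(tmask, f"training background {bg}")
        train_cells[bg] = _Cell(tr_est, tr_lab, tmask, tr_y)
        for congr, splits in [
            ("congruent", range(1, n_splits + 1)),
            ("incongruent", [None]),
        ]:
            for s in splits:
                cmask = (mt_congr == congr) & (mt_bg == bg)
                if s is not None:
                    cmask = cmask & (mt_split == s)
                _require(cmask, f"{congr} split {s}, background {bg}")
                test_cells[(congr, bg, s)] = _Cell(mt_est, mt_lab, cmask, mt_y)

    rows = []
    for (roi, hemi), sub in sorted(subrois.items()):
        use_counts = sub.voxel_counts if counts is None else counts
        # permute columns to ranked order once: top-N sets become prefix views
        tr_perm = {bg: c.Z[:, sub.order] for bg, c in train_cells.items()}
        te_perm = {k: c.Z[:, sub.order] for k, c in test_cells.items()}
        for n in use_counts:
            m = min(int(n), sub.order.size)
            fwd = {"congruent": [], "incongruent": []}
            rev = {"congruent": [], "incongruent": []}
            for bg in (30, 90):
                tc = train_cells[bg]
                Ztr = tr_perm[bg][:, :m]
                model = train_linear_classifier(
                    Ztr, tc.y, C=C, meta={"background": bg, "classes": ("B", "A")}
                )
                for (congr, cbg, s), cell in test_cells.items():
                    if cbg != bg:
                        continue
                    Zte = te_perm[(congr, cbg, s)][:, :m]
                    d = model.decision(Zte)
                    fwd[congr].append(
                        _score_distances(d, cell.y, cell.runs, pooling, accuracy)
                    )
                    # reverse direction: train on this main-task cell, test
                    # on training mini-blocks of the matching background
                    rmodel = train_linear_classifier(
                        Zte, cell.y, C=C,
                        meta={"background": bg, "classes": ("B", "A")},
                    )
                    dr = rmodel.decision(Ztr)
                    rev[congr].append(
                        _score_distances(dr, tc.y, tc.runs, pooling, accuracy)
                    )
            for cond in ("congruent", "incongruent"):
                f, r = float(np.mean(fwd[cond])), float(np.mean(rev[cond]))
                for direction, value in [
                    ("forward", f), ("reverse", r), ("mean", 0.5 * (f + r))
                ]:
                    rows.append({
                        "roi": roi, "hemisphere": hemi, "n_voxels": int(n),
                        "condition": cond, "direction": direction,
                        "value": value,
                    })
    return pd.DataFrame(rows)


def cross_decode_exp2(
    training_betas: list[BetaMaps],
    maintask_betas: list[BetaMaps],
    subrois: dict,
    counts: np.ndarray | None = None,
    C: float = 1.0,
    pooling: str = "pooled",
    accuracy: bool = False,
) -> pd.DataFrame:
    """Wide-vs-narrow cross-decoding of the occluded period (Experiment 2).

    Catch trials must already be excluded from (or labeled 'catch' in) the
    main-task betas; they are dropped here.  Condition is reported as
    'occluded'.
    """
    tr_est, tr_lab = stack_betas(training_betas)
    mt_est, mt_lab = stack_betas(maintask_betas)
    tr_keep = tr_lab["trial_type"].isin(["wide", "narrow"]).to_numpy()
    mt_keep = mt_lab["trial_type"].isin(["wide", "narrow"]).to_numpy()
    _require(tr_keep, "training wide/narrow betas")
    _require(mt_keep, "occluded wide/narrow betas")
    tr_y = np.where(tr_lab["trial_type"] == "wide", 1.0, -1.0)
    mt_y = np.where(mt_lab["trial_type"] == "wide", 1.0, -1.0)
    tr_cell = _Cell(tr_est, tr_lab, tr_keep, tr_y)
    mt_cell = _Cell(mt_est, mt_lab, mt_keep, mt_y)

    rows = []
    for (roi, hemi), sub in sorted(subrois.items()):
        use_counts = sub.voxel_counts if counts is None else counts
        for n in use_counts:
            cols = sub.members(n)
            meta = {"background": "none", "classes": ("narrow", "wide")}
            model = train_linear_classifier(tr_cell.Z[:, cols], tr_cell.y, C=C, meta=meta)
            f = _score_distances(
                model.decision(mt_cell.Z[:, cols]), mt_cell.y, mt_cell.runs,
                pooling, accuracy,
            )
            rmodel = train_linear_classifier(mt_cell.Z[:, cols], mt_cell.y, C=C, meta=meta)
            r = _score_distances(
                rmodel.decision(tr_cell.Z[:, cols]), tr_cell.y, tr_cell.runs,
                pooling, accuracy,
            )
            for direction, value in [
                ("forward", f), ("reverse", r), ("mean", 0.5 * (f + r))
            ]:
                rows.append({
                    "roi": roi, "hemisphere": hemi, "n_voxels": int(n),
                    "condition": "occluded", "direction": direction,
                    "value": value,
                })
    return pd.DataFrame(rows)


def time_resolved_decode(
    training_betas: list[BetaMaps],
    fir_betas: list[BetaMaps],
    voxel_idx: np.ndarray,
    n_bins: int = 10,
    C: float = 1.0,
    conditions=("congruent", "incongruent"),
) -> pd.DataFrame:
    """Classifier information per post-onset time bin and condition.

    One wide-vs-narrow classifier is trained on the training-run mini-block
    betas (backgrounds pooled); each FIR bin's patterns are then scored.
    Returns a frame with columns condition, bin, value.
    """
    tr_est, tr_lab = stack_betas(training_betas)
    fir_est, fir_lab = stack_betas(fir_betas)
    bins = fir_lab["bin"].to_numpy()
    if bins.max() + 1 != n_bins:
        raise ValueError(
            f"FIR betas have {bins.max() + 1} bins, expected {n_bins}"
        )
    tr_y = np.where(tr_lab["shape"] == "wide", 1.0, -1.0)
    model = train_linear_classifier(
        zscore_features(tr_est[:, voxel_idx]), tr_y, C=C,
        meta={"background": "pooled", "classes": ("narrow", "wide")},
    )
    fir_y = np.where(fir_lab["shape"] == "wide", 1.0, -1.0)
    congr = fir_lab["congruency"].to_numpy()
    rows = []
    for cond in conditions:
        for b in range(n_bins):
            mask = (congr == cond) & (bins == b)
            _require(mask, f"FIR bin {b}, {cond}")
            cell = _Cell(fir_est[:, voxel_idx], fir_lab, mask, fir_y)
            value = _score_distances(
                model.decision(cell.Z), cell.y, cell.runs, "pooled", False
            )
            rows.append({"condition": cond, "bin": b, "value": value})
    return pd.DataFrame(rows)
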