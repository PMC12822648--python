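"""General linear model estimation of voxelwise response amplitudes.

Event regressors are built on a 10x oversampled time grid, convolved with a
canonical double-gamma hemodynamic response function (or expanded into a
finite-impulse-response basis), and sampled at volume acquisition times.
Estimation is ordinary least squares via the pseudoinverse (minimum-norm
solution), without prewhitening: downstream decoding consumes relative
pattern geometry, not single-voxel significance.

Conventions
-----------
* Impulse events (duration 0) contribute an exact copy of the HRF kernel, so
  a unit-amplitude impulse yields a regressor with peak 1.
* Boxcar events integrate the kernel over the event (regressor value
  approximates ``int h(t - s) ds``), so a unit-amplitude boxcar regressor
  scales with event duration.
* The run intercept is always included as the run-based nuisance regressor;
  motion or button-press columns are appended unconvolved when supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import gammaln

__all__ = [
    "canonical_hrf",
    "hrf_double_gamma",
    "build_design_matrix",
    "fit_glm",
    "fit_fir",
    "DesignMatrix",
    "BetaMaps",
]

OVERSAMPLE = 10

# Conventional double-gamma parameterization: response gamma with delay 6 s,
# undershoot gamma with delay 16 s, unit dispersions, undershoot ratio 1/6.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0


def hrf_double_gamma(t: np.ndarray) -> np.ndarray:
    """Unnormalized double-gamma HRF evaluated at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)

    def gpdf(x, shape, scale):
        x = np.where(x <= 0, np.nan, x)
        logp = (
            (shape - 1) * np.log(x)
            - x / scale
            - shape * np.log(scale)
            - gammaln(shape)
        )
        return np.where(np.isnan(logp), 0.0, np.exp(logp))

    peak = gpdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, HRF_PEAK_DISP)
    under = gpdf(t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, HRF_UNDERSHOOT_DISP)
    return peak - HRF_RATIO * under


def canonical_hrf(tr_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Canonical HRF sampled every ``tr_seconds``, scaled to unit peak.

    The kernel covers ``[0, duration_seconds)`` and has a negative
    post-peak undershoot.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0.0, duration_seconds, tr_seconds)
    h = hrf_double_gamma(t)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return h / peak


@dataclass
class DesignMatrix:
    """Time x regressor design with per-column labels.

    ``labels`` has one row per column with at least ``name`` and ``kind``
    (``task`` or ``nuisance``); task rows carry the event grouping columns.
    """

    matrix: np.ndarray
    labels: pd.DataFrame
    basis: str = "canonical"
    n_fir_bins: int = 0
    tr_seconds: float = 1.0

    @property
    def task_columns(self) -> np.ndarray:
        return np.flatnonzero(self.labels["kind"].to_numpy() == "task")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels["name"].tolist())

    def to_csv(self, path) -> None:
        """Write the design matrix (named columns) for inspection."""
        self.to_frame().to_csv(path, index=False)


@dataclass
class BetaMaps:
    """Per-condition voxel-pattern estimates from one GLM fit."""

    estimates: np.ndarray          # task regressor x voxel
    labels: pd.DataFrame           # aligned to rows of ``estimates``
    run: int = -1
    subject: str = ""
    zero_columns: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    full_estimates: np.ndarray | None = None   # including nuisance rows
    full_labels: pd.DataFrame | None = None

    def save(self, prefix) -> None:
        """Write ``<prefix>_labels.csv`` and ``<prefix>_estimates.npy``."""
        self.labels.to_csv(f"{prefix}_labels.csv", index=False)
        np.save(f"{prefix}_estimates.npy", self.estimates)

    @classmethod
    def load(cls, prefix) -> "BetaMaps":
        return cls(
            estimates=np.load(f"{prefix}_estimates.npy"),
            labels=pd.read_csv(f"{prefix}_labels.csv"),
        )


def _hires_regressor(events: pd.DataFrame, n_volumes: int, tr: float) -> np.ndarray:
    """Neural input function per event on the oversampled grid."""
    dt = tr / OVERSAMPLE
    n_hi = n_volumes * OVERSAMPLE
    u = np.zeros((n_hi, len(events)))
    for col, (onset, dur) in enumerate(zip(events["onset"], events["duration"])):
        i0 = int(round(onset / dt))
        if i0 >= n_hi:
            raise ValueError(f"event onset {onset} s falls outside the run")
        if dur <= 0:
            u[i0, col] = 1.0
        else:
            i1 = min(n_hi, int(round((onset + dur) / dt)))
            u[i0:i1, col] = dt
    return u


def _convolve_events(events: pd.DataFrame, n_volumes: int, tr: float) -> np.ndarray:
    """One convolved column per event row, sampled at volume times."""
    u = _hires_regressor(events, n_volumes, tr)
    dt = tr / OVERSAMPLE
    kernel = hrf_double_gamma(np.arange(0.0, 32.0, dt))
    kernel = kernel / kernel.max()
    n_hi = u.shape[0]
    conv = fftconvolve(u, kernel[:, None], axes=0)[:n_hi]
    return np.ascontiguousarray(conv[::OVERSAMPLE])


def event_regressors(
    events: pd.DataFrame, n_volumes: int, tr_seconds: float = 1.0
) -> np.ndarray:
    """One HRF-convolved regressor per event row (volumes x events).

    Lean label-free path shared by the forward simulator; identical to the
    task columns of ``build_design_matrix(..., per_event=True)``.
    """
    if len(events) and events["onset"].max() > n_volumes * tr_seconds:
        raise ValueError("events extend past the end of the run")
    return _convolve_events(events, n_volumes, tr_seconds)


DEFAULT_GROUPBY = ("trial_type", "congruency", "split_id")


def _group_key(events: pd.DataFrame, groupby) -> pd.Series:
    cols = [c for c in groupby if c in events.columns]
    parts = []
    for c in cols:
        vals = events[c].astype(str)
        nuniq = vals.nunique()
        if nuniq > 1 or c == "trial_type":
            parts.append(vals)
    if not parts:
        parts = [events["trial_type"].astype(str)]
    key = parts[0]
    for p in parts[1:]:
        key = key + "/" + p
    # collapse degenerate tags such as "A30/congruent/-1"
    return key.str.replace("/n/a", "", regex=False).str.replace("/-1", "", regex=False)


def build_design_matrix(
    events: pd.DataFrame,
    basis: str = "canonical",
    n_volumes: int = 0,
    tr_seconds: float = 1.0,
    nuisance_columns: np.ndarray | None = None,
    groupby=DEFAULT_GROUPBY,
    per_event: bool = False,
    n_fir_bins: int = 10,
    fir_bin_seconds: float = 1.0,
    expect_boxcar: bool = False,
) -> DesignMatrix:
    """Build a run design matrix from an event table.

    ``groupby`` defines one task regressor per unique combination of the named
    columns (constant columns are dropped from the key); ``per_event=True``
    instead yields one regressor per event row, as used for mini-block-wise
    training-run estimates.  The FIR basis produces ``n_fir_bins`` stick
    columns per condition, bin 0 aligned to the onset volume.  Nuisance
    columns are appended unconvolved and a run intercept is always included.
    """
    if n_volumes <= 0:
        raise ValueError("n_volumes must be given")
    if nuisance_columns is not None and len(nuisance_columns) != n_volumes:
        raise ValueError("nuisance columns must have n_volumes rows")
    if len(events) and events["onset"].max() > n_volumes * tr_seconds:
        raise ValueError("events extend past the end of the run")
    if expect_boxcar and len(events) and (events["duration"] <= 0).any():
        warnings.warn(
            "zero-duration event(s) in a boxcar design; treated as impulses"
        )

    cols, labels = [], []
    if len(events):
        if per_event:
            keys = _group_key(events, groupby) + "#" + events.index.astype(str)
        else:
            keys = _group_key(events, groupby)
        uniq = list(dict.fromkeys(keys))
        if basis == "canonical":
            conv = _convolve_events(events, n_volumes, tr_seconds)
            for key in uniq:
                members = np.flatnonzero((keys == key).to_numpy())
                cols.append(conv[:, members].sum(axis=1))
                row = events.iloc[members[0]]
                labels.append(_task_label(key, row, bin_index=-1))
        elif basis == "fir":
            if n_fir_bins <= 0:
                raise ValueError("n_fir_bins must be positive for the FIR basis")
            bin_vol = fir_bin_seconds / tr_seconds
            if abs(bin_vol - round(bin_vol)) > 1e-9:
                raise ValueError("fir_bin_seconds must be an integer number of volumes")
            bin_vol = int(round(bin_vol))
            for key in uniq:
                members = np.flatnonzero((keys == key).to_numpy())
                onset_vols = np.round(
                    events["onset"].to_numpy()[members] / tr_seconds
                ).astype(int)
                row = events.iloc[members[0]]
                for b in range(n_fir_bins):
                    stick = np.zeros(n_volumes)
                    idx = onset_vols + b * bin_vol
                    idx = idx[idx < n_volumes]
                    for v0 in idx:
                        stick[v0 : v0 + bin_vol] = 1.0
                    cols.append(stick)
                    labels.append(_task_label(f"{key}@bin{b}", row, bin_index=b))
        else:
            raise ValueError(f"unknown basis {basis!r}")

    matrix = [np.column_stack(cols)] if cols else []
    label_rows = list(labels)
    # run intercept (the run-based nuisance regressor)
    matrix.append(np.ones((n_volumes, 1)))
    label_rows.append(_nuisance_label("intercept"))
    if nuisance_columns is not None:
        nuis = np.atleast_2d(np.asarray(nuisance_columns, dtype=float))
        if nuis.shape[0] != n_volumes:
            nuis = nuis.T
        matrix.append(nuis)
        label_rows += [_nuisance_label(f"nuisance_{i}") for i in range(nuis.shape[1])]
    X = np.column_stack(matrix) if len(matrix) > 1 else matrix[0]
    label_df = pd.DataFrame(label_rows)
    if label_df["name"].duplicated().any():
        raise ValueError("duplicate design-matrix column labels")
    return DesignMatrix(
        matrix=X,
        labels=label_df,
        basis=basis,
        n_fir_bins=n_fir_bins if basis == "fir" else 0,
        tr_seconds=tr_seconds,
    )


def _task_label(name: str, row: pd.Series, bin_index: int) -> dict:
    return {
        "name": name,
        "kind": "task",
        "trial_type": row.get("trial_type", ""),
        "congruency": row.get("congruency", "n/a"),
        "split_id": row.get("split_id", -1),
        "shape": row.get("shape", "n/a"),
        "background": row.get("background", -1),
        "catch": bool(row.get("catch", False)),
        "bin": bin_index,
    }


def _nuisance_label(name: str) -> dict:
    return {
        "name": name,
        "kind": "nuisance",
        "trial_type": "",
        "congruency": "n/a",
        "split_id": -1,
        "shape": "n/a",
        "background": -1,
        "catch": False,
        "bin": -1,
    }


def fit_glm(data: np.ndarray, X: DesignMatrix, run: int = -1, subject: str = "") -> BetaMaps:
    """Minimum-norm least-squares fit of a run design to a time x voxel matrix.

    All-zero design columns are flagged and their estimates set to zero.
    Nuisance estimates are retained on the result (``full_estimates``) but the
    returned ``estimates`` contain task rows only.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.matrix.shape[0]:
        raise ValueError(
            f"data has {Y.shape[0] if Y.ndim == 2 else '?'} rows, design has "
            f"{X.matrix.shape[0]}"
        )
    M = X.matrix
    zero_cols = np.flatnonzero(~np.any(M != 0, axis=0))
    if zero_cols.size:
        warnings.warn(f"{zero_cols.size} all-zero design column(s); estimates set to 0")
        keep = np.setdiff1d(np.arange(M.shape[1]), zero_cols)
        beta_keep = np.linalg.pinv(M[:, keep]) @ Y
        beta = np.zeros((M.shape[1], Y.shape[1]))
        beta[keep] = beta_keep
    else:
        beta = np.linalg.pinv(M) @ Y
    task = X.task_columns
    return BetaMaps(
        estimates=beta[task],
        labels=X.labels.iloc[task].reset_index(drop=True),
        run=run,
        subject=subject,
        zero_columns=zero_cols,
        full_estimates=beta,
        full_labels=X.labels,
    )


def fit_fir(
    data: np.ndarray,
    events: pd.DataFrame,
    tr_seconds: float = 1.0,
    n_bins: int = 10,
    fir_bin_seconds: float = 1.0,
    groupby=("congruency", "shape"),
    run: int = -1,
    subject: str = "",
) -> BetaMaps:
    """Deconvolve per-condition response curves with an FIR basis.

    Returns one estimate row per condition x post-onset bin; equivalent to
    ``fit_glm`` on the FIR design built by :func:`build_design_matrix`.
    """
    n_volumes = data.shape[0]
    if n_bins * fir_bin_seconds > n_volumes * tr_seconds:
        raise ValueError("FIR window does not fit in the run")
    ev = events.copy()
    ev["trial_type"] = _group_key(events, groupby)
    X = build_design_matrix(
        ev,
        basis="fir",
        n_volumes=n_volumes,
        tr_seconds=tr_seconds,
        groupby=("trial_type",),
        n_fir_bins=n_bins,
        fir_bin_seconds=fir_bin_seconds,
    )
    return fit_glm(data, X, run=run, subject=subject)
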