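"""Forward simulation of BOLD runs with known ground truth.

Each simulated subject owns fixed voxel patterns for the two proximal
shapes (wide/narrow), background-orientation confound patterns (30/90
degrees), a nonnegative visual-responsiveness gain per voxel, congruency
gains on the shape-pattern amplitude, a spatially uniform "surprise"
amplitude added on incongruent reappearances, and a top-down gain carried
by the occluded period in Experiment 2.  Per-voxel signal amplitude is
responsiveness times the pattern entry, so ranking voxels by a localizer
responsiveness statistic preferentially selects informative voxels.

The forward model is the exact inverse of the GLM in :mod:`proxdec.glm`:
per-event amplitudes are convolved with the same canonical HRF at the same
resolution, so a noiseless simulated run is recovered to machine precision
by ``fit_glm``.  Noise is AR(1) Gaussian per voxel (white noise is the
``ar1_rho = 0`` special case), stationary with marginal SD ``noise_sigma``.

All randomness flows from a single integer seed through a documented
hierarchical split (cohort -> subject -> run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .design import ConfigurationError, DesignParams, ExperimentDesign, make_design
from .glm import event_regressors

__all__ = [
    "TruthParams",
    "SubjectGroundTruth",
    "SubjectData",
    "VoxelTimeSeries",
    "make_voxel_meta",
    "make_subject",
    "simulate_run",
    "simulate_subject",
    "simulate_cohort",
    "simulate_reports",
    "coupling_target_indices",
]

ROIS = ("EVC", "LVC")
HEMISPHERES = ("L", "R")

# localizer drive per stimulus category, relative to responsiveness
LOCALIZER_DRIVE = {"objects": 1.0, "scrambled": 1.0, "faces": 0.5, "scenes": 0.5}

GRID_SIDE = 10          # cross-section of each region's voxel slab
GRID_SPACING = 3        # empty planes between region slabs


@dataclass(frozen=True)
class TruthParams:
    """Population-level generative parameters (per-subject values are drawn
    around these).  Amplitudes are in units of the noise SD of a single
    volume (``noise_sigma = 1``).  Defaults reproduce the order of the
    group effects reported for the two experiments; see docs/methods.md.
    """

    amp_shape: float = 0.009            # shape-pattern amplitude, EVC
    roi_scale: dict = field(default_factory=lambda: {"EVC": 1.0, "LVC": 0.6})
    amp_background: float = 0.0045      # background-confound amplitude
    gain_congruent: dict | float = field(
        default_factory=lambda: {"EVC": 1.07, "LVC": 1.0}
    )
    gain_incongruent: dict | float = field(
        default_factory=lambda: {"EVC": 0.93, "LVC": 1.0}
    )
    surprise_amplitude: float = 0.018   # uniform additive drive, incongruent only
    occluded_signal_gain: dict | float = field(
        default_factory=lambda: {"EVC": 0.08, "LVC": 0.19}
    )  # top-down shape signal during occlusion, relative to visible patterns
    amp_localizer: float = 1.0
    responsiveness_shape: float = 2.0   # gamma shape of per-voxel responsiveness
    localizer_t_noise: float = 0.5
    noise_sigma: float = 1.0
    ar1_rho: float = 0.3
    between_subject_sd: float = 0.08    # lognormal spread of per-subject amplitudes
    coupling_gain_congruent: float = 0.0   # univariate drive of coupled voxels
    coupling_gain_incongruent: float = 0.0
    n_coupled_voxels: int = 0
    attention_noise: float = 0.5        # SD of reappearance-report errors (counts)


def _strict_truth(overrides: dict) -> TruthParams:
    """Build TruthParams from a dict, rejecting unknown keys."""
    import dataclasses

    allowed = {f.name for f in dataclasses.fields(TruthParams)}
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"unknown truth parameter(s): {sorted(unknown)}")
    return TruthParams(**overrides)


@dataclass
class SubjectGroundTruth:
    """One subject's generative state, retained for recovery scoring."""

    pattern_wide: np.ndarray
    pattern_narrow: np.ndarray
    pattern_bg30: np.ndarray
    pattern_bg90: np.ndarray
    responsiveness: np.ndarray
    gain_congruent: np.ndarray      # per voxel
    gain_incongruent: np.ndarray
    surprise_amplitude: float
    occluded_signal_gain: np.ndarray   # per voxel
    noise_sigma: float
    ar1_rho: float
    localizer_amp: np.ndarray
    coupled_voxels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    coupling_gain_congruent: float = 0.0
    coupling_gain_incongruent: float = 0.0
    attention_noise: float = 0.5

    def shape_pattern(self, shape: str) -> np.ndarray:
        return self.pattern_wide if shape == "wide" else self.pattern_narrow

    def background_pattern(self, background: int) -> np.ndarray:
        if background == 30:
            return self.pattern_bg30
        if background == 90:
            return self.pattern_bg90
        return np.zeros_like(self.pattern_bg30)


@dataclass
class VoxelTimeSeries:
    """One run's time x voxel data plus voxel metadata."""

    data: np.ndarray
    tr_seconds: float
    voxel_meta: pd.DataFrame

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")


@dataclass
class SubjectData:
    """All simulated runs and the ground truth for one subject."""

    subject: str
    design: ExperimentDesign
    voxel_meta: pd.DataFrame
    truth: SubjectGroundTruth
    main_runs: list
    training_runs: list
    localizer_runs: list


def make_voxel_meta(
    voxels_per_roi: int | dict, n_other: int = 0, hemispheres=HEMISPHERES
) -> pd.DataFrame:
    """Voxel metadata table with ROI / hemisphere labels and 3D coordinates.

    ``voxels_per_roi`` is either one count per ROI x hemisphere or a mapping
    ``{roi: count_per_hemisphere}``.  Each region occupies its own slab of a
    common integer grid (cross-section ``GRID_SIDE**2``), so any contiguous
    index prefix within a region is face-connected in 3D.
    """
    if isinstance(voxels_per_roi, int):
        voxels_per_roi = {roi: voxels_per_roi for roi in ROIS}
    groups = [(roi, hemi, int(voxels_per_roi.get(roi, 0))) for roi in voxels_per_roi
              for hemi in hemispheres]
    if n_other:
        groups.append(("other", "L", int(n_other)))
    rows = []
    x_offset = 0
    for roi, hemi, count in groups:
        if count <= 0:
            continue
        idx = np.arange(count)
        z, x, y = np.unravel_index(idx, ( -(-count // (GRID_SIDE**2)), GRID_SIDE, GRID_SIDE))
        rows.append(pd.DataFrame({
            "roi": roi, "hemisphere": hemi,
            "x": x + x_offset, "y": y, "z": z,
        }))
        x_offset += GRID_SIDE + GRID_SPACING
    meta = pd.concat(rows, ignore_index=True)
    meta["localizer_t"] = np.nan
    return meta


def coupling_target_indices(voxel_meta: pd.DataFrame, n: int) -> np.ndarray:
    """The first ``n`` voxels of the 'other' region (a face-connected block)."""
    idx = np.flatnonzero((voxel_meta["roi"] == "other").to_numpy())
    if len(idx) < n:
        raise ConfigurationError(f"need {n} 'other' voxels, have {len(idx)}")
    return idx[:n]


def _per_roi(value: dict | float, meta: pd.DataFrame, default: float = 1.0) -> np.ndarray:
    if np.isscalar(value):
        return np.full(len(meta), float(value))
    return meta["roi"].map(lambda r: float(value.get(r, default))).to_numpy()


def make_subject(
    params: DesignParams,
    truth_params: TruthParams,
    seed: int,
    voxel_meta: pd.DataFrame,
    max_subroi: int | None = None,
) -> SubjectGroundTruth:
    """Draw one subject's fixed patterns and gains.

    Pattern vectors are Gaussian per voxel, scaled elementwise by the voxel's
    responsiveness (gamma-distributed, mean 1) and the ROI signal scale, so
    responsiveness and shape-signal magnitude are positively coupled.
    Per-subject overall amplitude varies lognormally around the population
    value with SD ``between_subject_sd``.
    """
    tp = truth_params
    if max_subroi is not None:
        counts = voxel_meta.groupby(["roi", "hemisphere"]).size()
        for (roi, hemi), c in counts.items():
            if roi != "other" and c < max_subroi:
                raise ConfigurationError(
                    f"{roi}/{hemi} has {c} voxels < requested sub-ROI maximum {max_subroi}"
                )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    V = len(voxel_meta)
    resp = rng.gamma(tp.responsiveness_shape, 1.0 / tp.responsiveness_shape, size=V)
    roi_scale = _per_roi(tp.roi_scale, voxel_meta, default=0.0)
    subj_amp = float(np.exp(rng.normal(0.0, tp.between_subject_sd)))
    shape_amp = tp.amp_shape * subj_amp * roi_scale * resp
    bg_amp = tp.amp_background * subj_amp * roi_scale * resp
    in_roi = (voxel_meta["roi"] != "other").to_numpy()
    truth = SubjectGroundTruth(
        pattern_wide=shape_amp * rng.standard_normal(V),
        pattern_narrow=shape_amp * rng.standard_normal(V),
        pattern_bg30=bg_amp * rng.standard_normal(V),
        pattern_bg90=bg_amp * rng.standard_normal(V),
        responsiveness=resp,
        gain_congruent=_per_roi(tp.gain_congruent, voxel_meta),
        gain_incongruent=_per_roi(tp.gain_incongruent, voxel_meta),
        surprise_amplitude=tp.surprise_amplitude,
        occluded_signal_gain=_per_roi(tp.occluded_signal_gain, voxel_meta),
        noise_sigma=tp.noise_sigma,
        ar1_rho=tp.ar1_rho,
        localizer_amp=tp.amp_localizer * subj_amp * resp * in_roi,
        coupling_gain_congruent=tp.coupling_gain_congruent,
        coupling_gain_incongruent=tp.coupling_gain_incongruent,
        attention_noise=tp.attention_noise,
    )
    if tp.n_coupled_voxels:
        truth.coupled_voxels = coupling_target_indices(voxel_meta, tp.n_coupled_voxels)
    return truth


def _event_amplitudes(
    events: pd.DataFrame, truth: SubjectGroundTruth, run_kind: str, experiment: int
) -> np.ndarray:
    """Per-event, per-voxel neural amplitude matrix (events x voxels)."""
    V = len(truth.responsiveness)
    A = np.zeros((len(events), V))
    for e, row in enumerate(events.itertuples(index=False)):
        if run_kind == "localizer":
            A[e] = LOCALIZER_DRIVE[row.trial_type] * truth.localizer_amp
            continue
        shape_pat = truth.shape_pattern(row.shape)
        if run_kind == "training":
            amp = shape_pat.copy()
            if experiment == 1:
                amp = amp + truth.background_pattern(row.background)
            A[e] = amp
            continue
        # main-task runs
        if experiment == 1:
            gain = (
                truth.gain_congruent
                if row.congruency == "congruent"
                else truth.gain_incongruent
            )
            amp = gain * shape_pat + truth.background_pattern(row.background)
            if row.congruency == "incongruent":
                amp = amp + truth.surprise_amplitude
            cg = (
                truth.coupling_gain_congruent
                if row.congruency == "congruent"
                else truth.coupling_gain_incongruent
            )
            if cg and len(truth.coupled_voxels):
                amp = amp.copy()
                amp[truth.coupled_voxels] += cg
        else:
            if row.trial_type == "catch_reappearance":
                amp = shape_pat + truth.background_pattern(row.background)
            else:
                # occluded final period: scaled top-down copy of the
                # expected shape pattern
                amp = truth.occluded_signal_gain * shape_pat
        A[e] = amp
    return A


@njit(cache=True)
def _ar1_recurse(z, rho):  # pragma: no cover - exercised via _ar1_noise
    V, T = z.shape
    for v in range(V):
        for t in range(1, T):
            z[v, t] += rho * z[v, t - 1]


def _ar1_noise(shape, sigma, rho, rng) -> np.ndarray:
    if sigma == 0:
        return np.zeros(shape)
    # generate as voxel x time so the recursion runs along the fast axis
    z = rng.standard_normal(shape[::-1])
    if rho == 0:
        return sigma * z.T
    _ar1_recurse(z, rho)
    # stationary marginal SD sigma (up to the short initial transient)
    z *= sigma * np.sqrt(1.0 - rho**2)
    return z.T


def simulate_run(
    events: pd.DataFrame,
    truth: SubjectGroundTruth,
    seed: int,
    n_volumes: int,
    tr_seconds: float = 1.0,
    run_kind: str = "main",
    experiment: int = 1,
    voxel_meta: pd.DataFrame | None = None,
    regressors: np.ndarray | None = None,
) -> VoxelTimeSeries:
    """Simulate one run: HRF-convolved event responses plus AR(1) noise.

    ``regressors`` may carry precomputed per-event regressors (from
    :func:`proxdec.glm.event_regressors`) when many subjects share a design.
    """
    if len(events) and events["onset"].max() > n_volumes * tr_seconds:
        raise ValueError("events do not fit within the run duration")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    R = regressors if regressors is not None else event_regressors(
        events, n_volumes=n_volumes, tr_seconds=tr_seconds)
    A = _event_amplitudes(events, truth, run_kind, experiment)
    signal = R @ A
    noise = _ar1_noise(signal.shape, truth.noise_sigma, truth.ar1_rho, rng)
    meta = voxel_meta if voxel_meta is not None else pd.DataFrame(
        {"roi": "EVC", "hemisphere": "L"}, index=range(signal.shape[1])
    )
    return VoxelTimeSeries(data=signal + noise, tr_seconds=tr_seconds, voxel_meta=meta)


def simulate_subject(
    params: DesignParams,
    truth_params: TruthParams,
    voxel_meta: pd.DataFrame,
    seed: int,
    subject: str = "sub-00",
) -> SubjectData:
    """Simulate a full session (design, all runs) for one subject."""
    ss = np.random.SeedSequence([int(seed), 404])
    child = ss.generate_state(2 + params.n_runs_main
                              + params.n_runs_training + params.n_runs_localizer,
                              dtype=np.uint32)
    design = make_design(params, int(child[0]))
    truth = make_subject(params, truth_params, int(child[1]), voxel_meta)
    k = 2
    runs = {}
    for kind, run_list in [
        ("main", design.main_runs),
        ("training", design.training_runs),
        ("localizer", design.localizer_runs),
    ]:
        n_vol = {
            "main": params.run_length_volumes,
            "training": params.training_run_volumes,
            "localizer": params.localizer_run_volumes,
        }[kind]
        runs[kind] = []
        for ev in run_list:
            runs[kind].append(
                simulate_run(
                    ev, truth, int(child[k]), n_vol, params.tr_seconds,
                    run_kind=kind, experiment=params.experiment,
                    voxel_meta=voxel_meta,
                )
            )
            k += 1
    return SubjectData(
        subject=subject,
        design=design,
        voxel_meta=voxel_meta,
        truth=truth,
        main_runs=runs["main"],
        training_runs=runs["training"],
        localizer_runs=runs["localizer"],
    )


def subject_seeds(seed: int, n_subjects: int) -> np.ndarray:
    """Per-subject seeds derived from one cohort seed (all < 2**31)."""
    return np.random.SeedSequence([int(seed), 505]).generate_state(
        n_subjects, dtype=np.uint32
    ) >> 1


def simulate_cohort(
    params: DesignParams,
    truth_params: TruthParams,
    n_subjects: int,
    seed: int,
    voxel_meta: pd.DataFrame | None = None,
) -> list:
    """Simulate ``n_subjects`` independent subjects (ground truth retained).

    Materializes every subject's runs; for large cohorts prefer iterating
    over :func:`simulate_subject` with :func:`subject_seeds` to bound memory.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if voxel_meta is None:
        voxel_meta = make_voxel_meta(300)
    seeds = subject_seeds(seed, n_subjects)
    return [
        simulate_subject(params, truth_params, voxel_meta, int(s), subject=f"sub-{i:02d}")
        for i, s in enumerate(seeds)
    ]


def simulate_reports(
    design: ExperimentDesign, attention: float, seed: int
) -> pd.DataFrame:
    """Per-run true vs. reported object-reappearance counts (Experiment 2).

    ``attention`` scales integer Gaussian report noise; 0 means perfect
    reports.  Reported counts are clipped at zero.
    """
    if design.params.experiment != 1 and design.params.catch_fraction > 0:
        pass
    else:
        raise ValueError("reappearance reports require an Experiment 2 design with catch trials")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    rows = []
    for r, ev in enumerate(design.main_runs):
        true = int(((ev["catch"]) & (ev["duration"] > 0)).sum())
        err = int(np.round(attention * rng.standard_normal()))
        rows.append({"run": r, "true_count": true, "reported_count": max(0, true + err)})
    return pd.DataFrame(rows)
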