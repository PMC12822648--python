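"""Trial and mini-block event tables for the two experiments.

Both experiments share the same trial skeleton: a static initial view of a
room containing a central object, a stepwise rotation of the whole scene
during which the object becomes occluded, and a final viewpoint.  In
Experiment 1 the object reappears at the end of every trial, rotated either
congruently or incongruently with the scene; in Experiment 2 it stays
occluded except on rare catch trials.  Separate classifier-training runs
show the final object views in mini-blocks (with the scene background in
Experiment 1, without it in Experiment 2), and two functional-localizer
runs show category mini-blocks used to rank voxels by visual responsiveness.

Event tables are plain :class:`pandas.DataFrame` objects in BIDS style
(``onset``, ``duration``, ``trial_type`` plus analysis columns), one per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "DesignParams",
    "ExperimentDesign",
    "exp1_params",
    "exp2_params",
    "exp1_scaled_params",
    "exp2_scaled_params",
    "make_design",
]

#: the four initial-orientation x scene-rotation combinations
CONDITIONS = ("A30", "A90", "B30", "B90")

#: mapping from combination to the proximal (2D-projected) shape it produces
SHAPE_OF = {"A30": "wide", "B90": "wide", "B30": "narrow", "A90": "narrow"}

#: final scene (background) orientation in degrees
BACKGROUND_OF = {"A30": 30, "B30": 30, "A90": 90, "B90": 90}

LOCALIZER_CATEGORIES = ("objects", "scrambled", "faces", "scenes")

# fixed timing constants (seconds)
FIXATION_SECONDS = 15.0          # fixation at the start and end of every run
TRIAL_FINAL_ONSET = 4.0          # final-view onset relative to trial start
FINAL_JITTER = (1.5, 2.0)        # occluded final period duration (uniform)
MINIBLOCK_GAP = 6.75             # blank between mini-block series
LOCALIZER_BLOCK_SECONDS = 15.0
EXP1_MINIBLOCK_SECONDS = 13.5
EXP2_MINIBLOCK_SECONDS = 6.75
EXP1_SERIES = 4                  # mini-blocks between blanks, Exp1 training
EXP2_SERIES = 8
HRF_TAIL = 15.0                  # margin after the last event


class ConfigurationError(ValueError):
    """An experiment design that cannot be packed or balanced."""


@dataclass(frozen=True)
class DesignParams:
    """Design constants for one experiment.

    Defaults are set by :func:`exp1_params` / :func:`exp2_params` (the scanner
    protocols) and :func:`exp1_scaled_params` / :func:`exp2_scaled_params`
    (shorter versions of the same structure for simulation studies).
    """

    experiment: int
    n_runs_main: int
    trials_per_run: int
    p_congruent: float
    n_runs_training: int
    miniblocks_per_training_run: int
    n_runs_localizer: int = 2
    localizer_miniblocks_per_run: int = 16
    catch_fraction: float = 0.0
    tr_seconds: float = 1.0
    run_length_volumes: int = 404
    training_run_volumes: int = 333
    localizer_run_volumes: int = 318
    n_splits: int = 3
    conditions: tuple = CONDITIONS

    def __post_init__(self):
        if self.experiment not in (1, 2):
            raise ConfigurationError("experiment must be 1 or 2")
        if not 0.0 <= self.p_congruent <= 1.0:
            raise ConfigurationError("p_congruent must lie in [0, 1]")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        n_cong = round(self.trials_per_run * self.p_congruent)
        n_inc = self.trials_per_run - n_cong
        k = len(self.conditions)
        if self.experiment == 1:
            if n_cong % (k * self.n_splits):
                raise ConfigurationError(
                    f"congruent trials per run ({n_cong}) must divide evenly over "
                    f"{k} conditions x {self.n_splits} splits"
                )
            if n_inc % k:
                raise ConfigurationError(
                    f"incongruent trials per run ({n_inc}) must divide evenly over "
                    f"{k} conditions"
                )
        else:
            if self.trials_per_run % k:
                raise ConfigurationError(
                    f"trials per run ({self.trials_per_run}) must divide evenly "
                    f"over {k} conditions"
                )
        if self.main_soa < TRIAL_FINAL_ONSET + FINAL_JITTER[1] + 1.0:
            raise ConfigurationError(
                "run_length_volumes too small: trial onset asynchrony "
                f"{self.main_soa:.2f} s cannot contain one trial"
            )
        for label, volumes, seconds in [
            ("training", self.training_run_volumes, self._training_span()),
            ("localizer", self.localizer_run_volumes, self._localizer_span()),
        ]:
            if volumes * self.tr_seconds < seconds:
                raise ConfigurationError(
                    f"{label} run of {volumes} volumes is shorter than its "
                    f"event span of {seconds:.2f} s"
                )

    @property
    def n_congruent_per_run(self) -> int:
        return round(self.trials_per_run * self.p_congruent)

    @property
    def n_incongruent_per_run(self) -> int:
        return self.trials_per_run - self.n_congruent_per_run

    @property
    def main_soa(self) -> float:
        """Trial onset asynchrony in the main task (constant-duration runs)."""
        return (
            self.run_length_volumes * self.tr_seconds - 2 * FIXATION_SECONDS
        ) / self.trials_per_run

    def _training_span(self) -> float:
        mb = EXP1_MINIBLOCK_SECONDS if self.experiment == 1 else EXP2_MINIBLOCK_SECONDS
        series = EXP1_SERIES if self.experiment == 1 else EXP2_SERIES
        n = self.miniblocks_per_training_run
        n_gaps = max(0, int(np.ceil(n / series)) - 1)
        return 2 * FIXATION_SECONDS + n * mb + n_gaps * MINIBLOCK_GAP

    def _localizer_span(self) -> float:
        n = self.localizer_miniblocks_per_run
        n_gaps = max(0, int(np.ceil(n / len(LOCALIZER_CATEGORIES))) - 1)
        return 2 * FIXATION_SECONDS + n * LOCALIZER_BLOCK_SECONDS + n_gaps * MINIBLOCK_GAP


def exp1_params(**overrides) -> DesignParams:
    """Experiment 1 protocol: 7 main runs x 48 trials (75% congruent),
    3 training runs of 20 mini-blocks, 2 localizer runs."""
    base = dict(
        experiment=1,
        n_runs_main=7,
        trials_per_run=48,
        p_congruent=0.75,
        n_runs_training=3,
        miniblocks_per_training_run=20,
        run_length_volumes=404,
        training_run_volumes=333,
        localizer_run_volumes=318,
    )
    base.update(overrides)
    return DesignParams(**base)


def exp2_params(**overrides) -> DesignParams:
    """Experiment 2 protocol: 8 main runs x 40 trials, 12.5% catch trials,
    3 training runs of 40 shape mini-blocks, 2 localizer runs."""
    base = dict(
        experiment=2,
        n_runs_main=8,
        trials_per_run=40,
        p_congruent=1.0,
        catch_fraction=0.125,
        n_runs_training=3,
        miniblocks_per_training_run=40,
        run_length_volumes=315,
        training_run_volumes=333,
        localizer_run_volumes=318,
    )
    base.update(overrides)
    return DesignParams(**base)


def _volumes_for(seconds: float, tr: float) -> int:
    return int(np.ceil(seconds / tr)) + 2


def exp1_scaled_params(
    n_runs_main: int = 2,
    trials_per_run: int = 32,
    n_runs_training: int = 2,
    miniblocks_per_training_run: int = 12,
    localizer_miniblocks_per_run: int = 8,
    **overrides,
) -> DesignParams:
    """A shorter Experiment 1 design with the same structure and timing
    constants, used for simulation studies (see docs/methods.md)."""
    tr = overrides.get("tr_seconds", 1.0)
    soa = (404 - 2 * FIXATION_SECONDS) / 48  # protocol trial asynchrony
    probe = DesignParams(
        experiment=1,
        n_runs_main=n_runs_main,
        trials_per_run=trials_per_run,
        p_congruent=overrides.pop("p_congruent", 0.75),
        n_runs_training=n_runs_training,
        miniblocks_per_training_run=miniblocks_per_training_run,
        localizer_miniblocks_per_run=localizer_miniblocks_per_run,
        run_length_volumes=_volumes_for(2 * FIXATION_SECONDS + trials_per_run * soa, tr),
        training_run_volumes=10_000,
        localizer_run_volumes=10_000,
        **overrides,
    )
    return replace(
        probe,
        training_run_volumes=_volumes_for(probe._training_span(), tr),
        localizer_run_volumes=_volumes_for(probe._localizer_span(), tr),
    )


def exp2_scaled_params(
    n_runs_main: int = 3,
    trials_per_run: int = 24,
    n_runs_training: int = 2,
    miniblocks_per_training_run: int = 16,
    localizer_miniblocks_per_run: int = 8,
    **overrides,
) -> DesignParams:
    """A shorter Experiment 2 design (12.5% catch trials preserved)."""
    tr = overrides.get("tr_seconds", 1.0)
    soa = (315 - 2 * FIXATION_SECONDS) / 40
    probe = DesignParams(
        experiment=2,
        n_runs_main=n_runs_main,
        trials_per_run=trials_per_run,
        p_congruent=1.0,
        catch_fraction=overrides.pop("catch_fraction", 0.125),
        n_runs_training=n_runs_training,
        miniblocks_per_training_run=miniblocks_per_training_run,
        localizer_miniblocks_per_run=localizer_miniblocks_per_run,
        run_length_volumes=_volumes_for(2 * FIXATION_SECONDS + trials_per_run * soa, tr),
        training_run_volumes=10_000,
        localizer_run_volumes=10_000,
        **overrides,
    )
    return replace(
        probe,
        training_run_volumes=_volumes_for(probe._training_span(), tr),
        localizer_run_volumes=_volumes_for(probe._localizer_span(), tr),
    )


@dataclass
class ExperimentDesign:
    """Event tables for every run of one simulated session."""

    params: DesignParams
    main_runs: list = field(default_factory=list)
    training_runs: list = field(default_factory=list)
    localizer_runs: list = field(default_factory=list)

    def all_runs(self):
        for kind, runs in [
            ("main", self.main_runs),
            ("training", self.training_runs),
            ("localizer", self.localizer_runs),
        ]:
            for i, ev in enumerate(runs):
                yield kind, i, ev


def _event_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=[
            "onset",
            "duration",
            "trial_type",
            "congruency",
            "split_id",
            "shape",
            "background",
            "catch",
            "run",
        ],
    )
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    return df


def _exp1_main_run(params: DesignParams, run: int, rng: np.random.Generator) -> pd.DataFrame:
    k = len(params.conditions)
    per_cond_cong = params.n_congruent_per_run // k
    per_cond_inc = params.n_incongruent_per_run // k
    trials = []
    for cond in params.conditions:
        split_ids = np.repeat(np.arange(1, params.n_splits + 1), per_cond_cong // params.n_splits)
        split_ids = rng.permutation(split_ids)
        trials += [(cond, "congruent", int(s)) for s in split_ids]
        trials += [(cond, "incongruent", -1)] * per_cond_inc
    order = rng.permutation(len(trials))
    rows = []
    for i, j in enumerate(order):
        cond, congr, split = trials[j]
        onset = (
            FIXATION_SECONDS
            + i * params.main_soa
            + TRIAL_FINAL_ONSET
            + rng.uniform(*FINAL_JITTER)
        )
        rows.append(
            (onset, 0.0, cond, congr, split, SHAPE_OF[cond], BACKGROUND_OF[cond], False, run)
        )
    return _event_frame(rows)


def _exp2_main_run(
    params: DesignParams, run: int, n_catch: int, rng: np.random.Generator
) -> pd.DataFrame:
    k = len(params.conditions)
    conds = np.repeat(params.conditions, params.trials_per_run // k)
    conds = rng.permutation(conds)
    catch_idx = set(rng.choice(params.trials_per_run, size=n_catch, replace=False).tolist())
    rows = []
    for i, cond in enumerate(conds):
        start = FIXATION_SECONDS + i * params.main_soa
        onset = start + TRIAL_FINAL_ONSET
        dur = rng.uniform(*FINAL_JITTER)
        is_catch = i in catch_idx
        trial_type = "catch" if is_catch else SHAPE_OF[cond]
        rows.append(
            (onset, dur, trial_type, "n/a", -1, SHAPE_OF[cond], BACKGROUND_OF[cond], is_catch, run)
        )
        if is_catch:
            # the object reappears briefly at the end of the occluded period
            rows.append(
                (onset + dur, 0.0, "catch_reappearance", "n/a", -1,
                 SHAPE_OF[cond], BACKGROUND_OF[cond], True, run)
            )
    return _event_frame(rows)


def _catch_counts(params: DesignParams, rng: np.random.Generator) -> np.ndarray:
    """Per-run catch-trial counts: random but near-uniform, exact total."""
    total = round(params.catch_fraction * params.n_runs_main * params.trials_per_run)
    n_runs = params.n_runs_main
    mean = total / n_runs
    lo = max(1 if total >= n_runs else 0, int(np.floor(mean / 2)))
    hi = min(params.trials_per_run, int(np.ceil(mean * 2)))
    for _ in range(1000):
        counts = rng.multinomial(total, np.full(n_runs, 1.0 / n_runs))
        if counts.min() >= lo and counts.max() <= hi:
            return counts
    raise ConfigurationError(
        f"cannot distribute {total} catch trials over {n_runs} runs within [{lo}, {hi}]"
    )


def _training_run(params: DesignParams, run: int, rng: np.random.Generator) -> pd.DataFrame:
    if params.experiment == 1:
        labels = list(params.conditions)
        mb_dur, series = EXP1_MINIBLOCK_SECONDS, EXP1_SERIES
    else:
        labels = ["wide", "narrow"]
        mb_dur, series = EXP2_MINIBLOCK_SECONDS, EXP2_SERIES
    n = params.miniblocks_per_training_run
    if n % len(labels):
        raise ConfigurationError(
            f"training mini-blocks per run ({n}) must divide evenly over {len(labels)} labels"
        )
    seq = rng.permutation(np.repeat(labels, n // len(labels)))
    rows = []
    t = FIXATION_SECONDS
    for i, lab in enumerate(seq):
        if i and i % series == 0:
            t += MINIBLOCK_GAP
        if params.experiment == 1:
            shape, bg = SHAPE_OF[lab], BACKGROUND_OF[lab]
        else:
            shape, bg = lab, -1
        rows.append((t, mb_dur, lab, "n/a", -1, shape, bg, False, run))
        t += mb_dur
    return _event_frame(rows)


def _localizer_run(params: DesignParams, run: int, rng: np.random.Generator) -> pd.DataFrame:
    k = len(LOCALIZER_CATEGORIES)
    n = params.localizer_miniblocks_per_run
    if n % k:
        raise ConfigurationError(
            f"localizer mini-blocks per run ({n}) must divide evenly over {k} categories"
        )
    rows = []
    t = FIXATION_SECONDS
    for block in range(n // k):
        if block:
            t += MINIBLOCK_GAP
        for cat in rng.permutation(LOCALIZER_CATEGORIES):
            rows.append((t, LOCALIZER_BLOCK_SECONDS, cat, "n/a", -1, "n/a", -1, False, run))
            t += LOCALIZER_BLOCK_SECONDS
    return _event_frame(rows)


def make_design(params: DesignParams, seed: int) -> ExperimentDesign:
    """Generate all event tables for one session.

    Condition counts are exact for every seed; only trial order, congruent-split
    membership, catch-trial placement, and within-trial jitter are randomized.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    design = ExperimentDesign(params=params)
    if params.experiment == 1:
        design.main_runs = [
            _exp1_main_run(params, r, rng) for r in range(params.n_runs_main)
        ]
    else:
        counts = _catch_counts(params, rng)
        design.main_runs = [
            _exp2_main_run(params, r, int(counts[r]), rng)
            for r in range(params.n_runs_main)
        ]
    design.training_runs = [
        _training_run(params, r, rng) for r in range(params.n_runs_training)
    ]
    design.localizer_runs = [
        _localizer_run(params, r, rng) for r in range(params.n_runs_localizer)
    ]
    return design
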