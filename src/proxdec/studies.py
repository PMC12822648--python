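"""Predefined simulation-study configurations.

These are the package's own calibration and recovery studies: scaled-down
versions of the two experimental designs (same structure, fewer/shorter
runs) with generator settings chosen so each study probes one property of
the pipeline -- type-I error of the congruency TFCE test on null cohorts,
power to recover a congruency effect of the size reported for the EVC,
recovery of above-chance occluded-shape decoding, and recovery of
condition-specific information-activation coupling.  Problem sizes are
documented in docs/methods.md.

Cohorts in these studies share one trial sequence (``share_design=True``);
subjects keep independent patterns, gains and noise.  This leaves the
sign-flip and label symmetries intact while making replicate cohorts cheap.
"""

from __future__ import annotations

from .config import PipelineConfig, make_config

__all__ = [
    "type1_exp1_config",
    "recovery_exp1_config",
    "recovery_exp2_config",
    "coupling_config",
]

# Short Experiment 1 design for null calibration: 2 main runs x 16 trials,
# 2 training runs x 8 mini-blocks, 2 localizer runs x 8 mini-blocks.
_EXP1_NULL_DESIGN = dict(
    n_runs_main=2, trials_per_run=16,
    n_runs_training=2, miniblocks_per_training_run=4,
    localizer_miniblocks_per_run=4,
)

# Recovery-scale Experiment 1 design: 3 main runs x 48 trials.
_EXP1_EFFECT_DESIGN = dict(
    n_runs_main=3, trials_per_run=48,
    n_runs_training=2, miniblocks_per_training_run=12,
    localizer_miniblocks_per_run=8,
)

# Recovery-scale Experiment 2 design: 3 main runs x 24 trials (12.5% catch).
_EXP2_DESIGN = dict(
    n_runs_main=3, trials_per_run=24,
    n_runs_training=2, miniblocks_per_training_run=16,
    localizer_miniblocks_per_run=8,
)

# Generator amplitude for the scaled studies: larger than the paper-scale
# default so that per-subject measurement noise at the reduced trial counts
# leaves the group effect detectable (see docs/methods.md).
_SCALED_AMP = dict(amp_shape=0.04, amp_background=0.02)


def type1_exp1_config(seed: int = 0, n_permutations: int = 500) -> PipelineConfig:
    """Null cohorts (equal congruency gains) for type-I calibration of the
    congruency TFCE test: 34 subjects, 600 voxels per ROI, sub-ROIs
    100..600."""
    return make_config(dict(
        experiment=1, n_subjects=34, seed=seed, scale="scaled",
        design=dict(_EXP1_NULL_DESIGN),
        voxels_per_roi=600, subroi_step=100, subroi_max=600,
        rois=("EVC",), hemispheres=("L",),
        truth=dict(_SCALED_AMP, gain_congruent=1.0, gain_incongruent=1.0,
                   surprise_amplitude=0.0),
        stats={"n_permutations": n_permutations},
        run_univariate=False, share_design=True, write_outputs=False,
    ))


def recovery_exp1_config(seed: int = 0, effect: bool = True,
                         n_permutations: int = 500) -> PipelineConfig:
    """Effect cohorts for congruency-effect recovery: EVC gains chosen so
    the expected per-subject congruent-incongruent information difference
    is ~0.05-0.06; LVC gains equal (the no-effect control ROI)."""
    gains = ({"EVC": 1.11, "LVC": 1.0}, {"EVC": 0.89, "LVC": 1.0}) if effect \
        else (1.0, 1.0)
    return make_config(dict(
        experiment=1, n_subjects=24, seed=seed, scale="scaled",
        design=dict(_EXP1_EFFECT_DESIGN),
        voxels_per_roi=300, subroi_step=100, subroi_max=300,
        truth=dict(_SCALED_AMP, gain_congruent=gains[0],
                   gain_incongruent=gains[1], surprise_amplitude=0.08),
        stats={"n_permutations": n_permutations},
        run_univariate=False, share_design=True, write_outputs=False,
    ))


def recovery_exp2_config(seed: int = 0, occluded_gain: float = 0.2,
                         n_permutations: int = 500) -> PipelineConfig:
    """Occluded-decoding recovery cohorts (Experiment 2); the
    ``occluded_gain = 0`` variant is the null."""
    return make_config(dict(
        experiment=2, n_subjects=16, seed=seed, scale="scaled",
        design=dict(_EXP2_DESIGN),
        voxels_per_roi=300, subroi_step=100, subroi_max=300,
        truth=dict(_SCALED_AMP, gain_congruent=1.0, gain_incongruent=1.0,
                   surprise_amplitude=0.0, occluded_signal_gain=occluded_gain,
                   attention_noise=0.5),
        stats={"n_permutations": n_permutations},
        run_univariate=False, share_design=True, write_outputs=False,
    ))


#: voxels carrying condition-specific coupling in the coupling study
COUPLING_BLOCK_SIZE = 15

def coupling_config(seed: int = 0, effect: bool = True) -> PipelineConfig:
    """Coupling-recovery cohorts: a 15-voxel block outside the visual ROIs
    responds on congruent trials only, so its activation tracks the seed
    region's congruent information time course."""
    return make_config(dict(
        experiment=1, n_subjects=16, seed=seed, scale="scaled",
        design=dict(n_runs_main=3, trials_per_run=32,
                    n_runs_training=2, miniblocks_per_training_run=8,
                    localizer_miniblocks_per_run=8),
        voxels_per_roi=300, n_other_voxels=300,
        subroi_step=100, subroi_max=300,
        truth=dict(amp_shape=0.03, amp_background=0.015,
                   gain_congruent=1.0, gain_incongruent=1.0,
                   surprise_amplitude=0.0,
                   n_coupled_voxels=COUPLING_BLOCK_SIZE,
                   coupling_gain_congruent=2.0 if effect else 0.0,
                   coupling_gain_incongruent=0.0),
        coupling_seed_sizes=(100, 150, 200, 250, 300, 350),
        stats={"n_permutations": 100},
        run_univariate=False, run_coupling=True, share_design=True,
        write_outputs=False,
    ))
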