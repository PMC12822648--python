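"""End-to-end orchestration of the two experiments and calibration studies.

``run_experiment1`` simulates (or accepts) a cohort, estimates per-run GLMs,
ranks voxels by the localizer contrast, runs background-matched
cross-decoding over nested sub-ROIs, and performs the group analyses:
condition summaries and paired t tests, the congruency x ROI interaction,
TFCE sign-flip inference on the congruent-incongruent curves, within-ROI
univariate means with a whole-brain cluster contrast, and (optionally) the
information-activation coupling contrast.  ``run_experiment2`` is the
analogous occluded-shape analysis with catch-trial exclusion and the
reappearance-report participant exclusion rule.  ``run_calibration``
replicates null or effect cohorts and tabulates detection rates.

Every results bundle embeds the resolved configuration, its hash, the seed
and package versions, making identical configurations byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash
from .coupling import coupling_contrast, coupling_pipeline
from .decoding import cross_decode_exp1, cross_decode_exp2
from .design import exp1_params, exp1_scaled_params, exp2_params, exp2_scaled_params
from .glm import build_design_matrix, fit_fir
from .roi import localizer_tmap, make_subrois
from .simulate import (
    SubjectData,
    TruthParams,
    _strict_truth,
    make_voxel_meta,
    simulate_reports,
    simulate_run,
    simulate_subject,
    subject_seeds,
)
from .stats import (
    exclude_inattentive,
    interaction_anova_2x2,
    one_sample_t,
    paired_t,
    summarize_curve,
    tfce_signflip_test,
    univariate_roi,
    whole_brain_contrast,
)

log = logging.getLogger("proxdec")

__all__ = ["run_experiment1", "run_experiment2", "run_calibration", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(f"stage '{name}' failed: {e}") from e
        return wrapped
    return deco


def _design_params(cfg: PipelineConfig):
    if cfg.experiment == 1:
        maker = exp1_params if cfg.scale == "paper" else exp1_scaled_params
    else:
        maker = exp2_params if cfg.scale == "paper" else exp2_scaled_params
    return maker(**cfg.design)


def _truth_params(cfg: PipelineConfig) -> TruthParams:
    return _strict_truth(cfg.truth)


def _subroi_counts(cfg: PipelineConfig) -> np.ndarray:
    return np.arange(cfg.subroi_step, cfg.subroi_max + 1, cfg.subroi_step)


class SubjectAnalyzer:
    """Per-subject GLM + ROI + decoding, with design matrices (and their
    pseudoinverses) cached so they can be shared across a cohort."""

    def __init__(self, cfg: PipelineConfig, params, voxel_meta):
        self.cfg = cfg
        self.params = params
        self.voxel_meta = voxel_meta
        self.counts = _subroi_counts(cfg)
        self._cache = {}

    def _design(self, key, events, n_volumes, **kw):
        if key not in self._cache:
            X = build_design_matrix(
                events, n_volumes=n_volumes, tr_seconds=self.params.tr_seconds, **kw
            )
            self._cache[key] = (X, np.linalg.pinv(X.matrix))
        return self._cache[key]

    def _fit(self, key, events, n_volumes, data, run, **kw):
        X, pinv = self._design(key, events, n_volumes, **kw)
        beta = pinv @ data
        task = X.task_columns
        from .glm import BetaMaps

        return BetaMaps(
            estimates=beta[task],
            labels=X.labels.iloc[task].reset_index(drop=True),
            run=run,
            full_estimates=beta,
            full_labels=X.labels,
        )

    @_stage("glm")
    def betas(self, sd: SubjectData):
        p = self.params
        shared = self.cfg.share_design
        tag = "cohort" if shared else sd.subject
        loc = [
            self._fit((tag, "loc", i), ev, p.localizer_run_volumes, r.data, i)
            for i, (ev, r) in enumerate(zip(sd.design.localizer_runs, sd.localizer_runs))
        ]
        train = [
            self._fit((tag, "train", i), ev, p.training_run_volumes, r.data, i,
                      per_event=True)
            for i, (ev, r) in enumerate(zip(sd.design.training_runs, sd.training_runs))
        ]
        main = [
            self._fit((tag, "main", i), ev, p.run_length_volumes, r.data, i)
            for i, (ev, r) in enumerate(zip(sd.design.main_runs, sd.main_runs))
        ]
        return loc, train, main

    @_stage("roi")
    def rank_voxels(self, loc_betas):
        tmap, _ = localizer_tmap(loc_betas)
        subrois = make_subrois(tmap, self.voxel_meta, counts=self.counts,
                               rois=self.cfg.rois)
        return tmap, subrois

    @_stage("decode")
    def decode(self, train_betas, main_betas, subrois):
        dec = self.cfg.decoding
        fn = cross_decode_exp1 if self.params.experiment == 1 else cross_decode_exp2
        return fn(
            train_betas, main_betas, subrois,
            C=dec.C, pooling=dec.pooling, accuracy=dec.accuracy,
        )

    @_stage("univariate")
    def univariate(self, sd: SubjectData, subrois):
        p = self.params
        tag = "cohort" if self.cfg.share_design else sd.subject
        betas = [
            self._fit((tag, "univar", i), ev, p.run_length_volumes, r.data, i,
                      groupby=("congruency",))
            for i, (ev, r) in enumerate(zip(sd.design.main_runs, sd.main_runs))
        ]
        table = univariate_roi(betas, subrois)
        # whole-brain per-voxel difference map (incongruent - congruent)
        from .decoding import stack_betas

        est, lab = stack_betas(betas)
        tt = lab["congruency"].to_numpy()
        diff = est[tt == "incongruent"].mean(axis=0) - est[tt == "congruent"].mean(axis=0)
        return table, diff

    @_stage("coupling")
    def coupling(self, sd: SubjectData, train_betas, localizer_t):
        p = self.params
        fir = [
            fit_fir(
                r.data,
                ev[ev["congruency"].isin(["congruent", "incongruent"])],
                tr_seconds=p.tr_seconds,
                n_bins=self.cfg.n_fir_bins,
                run=i,
            )
            for i, (ev, r) in enumerate(zip(sd.design.main_runs, sd.main_runs))
        ]
        return coupling_pipeline(
            train_betas, fir, localizer_t, self.voxel_meta,
            voxel_count_settings=self.cfg.coupling_seed_sizes,
            n_bins=self.cfg.n_fir_bins, C=self.cfg.decoding.C,
            subject=sd.subject,
        )


def _simulate_cohort_stream(cfg: PipelineConfig, params, voxel_meta):
    seeds = subject_seeds(cfg.seed, cfg.n_subjects)
    shared_design = None
    regressor_cache = None
    for i, s in enumerate(seeds):
        if cfg.share_design:
            if shared_design is None:
                sd = simulate_subject(params, _truth_params(cfg), voxel_meta,
                                      int(seeds[0]), subject="sub-00")
                shared_design = sd.design
                regressor_cache = _cache_regressors(params, shared_design)
            else:
                sd = _simulate_with_design(cfg, params, voxel_meta, shared_design,
                                           int(s), f"sub-{i:02d}",
                                           regressor_cache)
        else:
            sd = simulate_subject(params, _truth_params(cfg), voxel_meta, int(s),
                                  subject=f"sub-{i:02d}")
        yield sd


def _run_kinds(params, design):
    return [
        ("main", design.main_runs, params.run_length_volumes),
        ("training", design.training_runs, params.training_run_volumes),
        ("localizer", design.localizer_runs, params.localizer_run_volumes),
    ]


def _cache_regressors(params, design):
    from .glm import event_regressors

    return {
        (kind, i): event_regressors(ev, n_volumes=n_vol,
                                    tr_seconds=params.tr_seconds)
        for kind, evs, n_vol in _run_kinds(params, design)
        for i, ev in enumerate(evs)
    }


def _simulate_with_design(cfg, params, voxel_meta, design, seed, subject,
                          regressor_cache=None):
    from .simulate import make_subject

    ss = np.random.SeedSequence([int(seed), 404])
    n_runs = params.n_runs_main + params.n_runs_training + params.n_runs_localizer
    child = ss.generate_state(2 + n_runs, dtype=np.uint32)
    truth = make_subject(params, _truth_params(cfg), int(child[1]), voxel_meta)
    k = 2
    runs = {"main": [], "training": [], "localizer": []}
    for kind, evs, n_vol in _run_kinds(params, design):
        for i, ev in enumerate(evs):
            R = regressor_cache.get((kind, i)) if regressor_cache else None
            runs[kind].append(
                simulate_run(ev, truth, int(child[k]), n_vol, params.tr_seconds,
                             run_kind=kind, experiment=params.experiment,
                             voxel_meta=voxel_meta, regressors=R)
            )
            k += 1
    return SubjectData(
        subject=subject, design=design, voxel_meta=voxel_meta, truth=truth,
        main_runs=runs["main"], training_runs=runs["training"],
        localizer_runs=runs["localizer"],
    )


def _group_curves(curve_frames) -> pd.DataFrame:
    return pd.concat(curve_frames, ignore_index=True)


def _summaries(curves: pd.DataFrame) -> pd.DataFrame:
    """Per subject x ROI x condition scalar (mean over N and hemispheres)."""
    rows = []
    for (subj, roi), grp in curves.groupby(["subject", "roi"], sort=True):
        s = summarize_curve(grp[grp["direction"] == "mean"])
        for _, r in s.iterrows():
            rows.append({"subject": subj, "roi": roi, "condition": r["condition"],
                         "value": r["value"]})
    return pd.DataFrame(rows)


def _difference_curves(curves: pd.DataFrame, roi: str) -> np.ndarray:
    """Subjects x N matrix of congruent-incongruent classifier information,
    averaged over hemispheres."""
    sel = curves[(curves["roi"] == roi) & (curves["direction"] == "mean")]
    piv = sel.pivot_table(index="subject", columns=["condition", "n_voxels"],
                          values="value", aggfunc="mean", sort=True)
    cong = piv["congruent"].to_numpy()
    inc = piv["incongruent"].to_numpy()
    return cong - inc


def _info_curves(curves: pd.DataFrame, roi: str, condition: str) -> np.ndarray:
    sel = curves[
        (curves["roi"] == roi)
        & (curves["direction"] == "mean")
        & (curves["condition"] == condition)
    ]
    piv = sel.pivot_table(index="subject", columns="n_voxels", values="value",
                          aggfunc="mean", sort=True)
    return piv.to_numpy()


def _test_row(name, res) -> dict:
    return {"test": name, **res.as_dict()}


def _write_outputs(cfg, out: dict):
    if not cfg.write_outputs:
        return
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in out.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.csv", index=False)
    manifest = {
        "package": "proxdec",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "config": cfg.to_dict(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("results written to %s (config %s)", out_dir, manifest["config_hash"])


def _log_decisions(cfg: PipelineConfig):
    s, d = cfg.stats, cfg.decoding
    log.info(
        "active analysis choices: pooling=%s C=%s TFCE E=%s H=%s dh=%s null=%s "
        "connectivity=6 quantiles=linear alpha=%s cluster_min=%s",
        d.pooling, d.C, s.E, s.H, s.dh if s.dh else "max|t|/100", s.tfce_null,
        s.alpha, s.cluster_min,
    )


def run_experiment1(cfg: PipelineConfig, cohort=None) -> dict:
    """Full Experiment 1 analysis; returns the results bundle as a dict."""
    if cfg.experiment != 1:
        raise ValueError("config is not for experiment 1")
    _log_decisions(cfg)
    params = _design_params(cfg)
    voxel_meta = make_voxel_meta(cfg.voxels_per_roi, cfg.n_other_voxels,
                                 hemispheres=cfg.hemispheres)
    analyzer = SubjectAnalyzer(cfg, params, voxel_meta)
    subjects = cohort if cohort is not None else _simulate_cohort_stream(
        cfg, params, voxel_meta
    )

    curve_frames, uni_rows, diff_maps, coupling_maps_list = [], [], [], []
    for sd in subjects:
        loc, train, main = analyzer.betas(sd)
        tmap, subrois = analyzer.rank_voxels(loc)
        cdf = analyzer.decode(train, main, subrois)
        cdf.insert(0, "subject", sd.subject)
        curve_frames.append(cdf)
        if cfg.run_univariate:
            table, diff = analyzer.univariate(sd, subrois)
            table.insert(0, "subject", sd.subject)
            uni_rows.append(table)
            diff_maps.append(diff)
        if cfg.run_coupling:
            coupling_maps_list.append(analyzer.coupling(sd, train, tmap))

    curves = _group_curves(curve_frames)
    summaries = _summaries(curves)
    tests, tfce_rows = [], []
    piv = summaries.pivot_table(index="subject", columns=["roi", "condition"],
                                values="value", sort=True)
    for roi in cfg.rois:
        cong = piv[(roi, "congruent")].to_numpy()
        inc = piv[(roi, "incongruent")].to_numpy()
        tests.append(_test_row(f"{roi}_overall_vs_0", one_sample_t((cong + inc) / 2)))
        tests.append(_test_row(f"{roi}_congruent_vs_incongruent", paired_t(cong, inc)))
        X = _difference_curves(curves, roi)
        res = tfce_signflip_test(
            X, n_permutations=cfg.stats.n_permutations, E=cfg.stats.E,
            H=cfg.stats.H, dh=cfg.stats.dh, seed=cfg.seed,
            null_mode=cfg.stats.tfce_null,
        )
        counts = np.sort(curves["n_voxels"].unique())
        for k, n in enumerate(counts):
            tfce_rows.append({
                "roi": roi, "n_voxels": int(n), "t": res.observed_t[k],
                "tfce": res.observed_tfce[k], "z": res.z[k],
                "p_fwe": res.p_fwe[k],
                "significant": bool(res.p_fwe[k] < cfg.stats.fwe_alpha),
            })
    if len(cfg.rois) == 2:
        r1, r2 = cfg.rois
        table = np.stack([
            np.stack([piv[(r, c)].to_numpy() for r in (r1, r2)], axis=-1)
            for c in ("congruent", "incongruent")
        ], axis=1)
        F, p, pes = interaction_anova_2x2(table)
        tests.append({
            "test": "interaction_congruency_x_roi", "statistic": F,
            "dof": f"(1, {table.shape[0] - 1})", "p": p, "cohens_d": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "sided": "two",
            "partial_eta_squared": pes,
        })

    out = {
        "curves": curves,
        "summaries": summaries,
        "group_tests": pd.DataFrame(tests),
        "tfce": pd.DataFrame(tfce_rows),
    }
    if cfg.run_univariate:
        uni = pd.concat(uni_rows, ignore_index=True)
        out["univariate"] = uni
        upiv = uni.pivot_table(index="subject", columns=["roi", "condition"],
                               values="mean_beta", sort=True)
        for roi in cfg.rois:
            res = paired_t(upiv[(roi, "congruent")].to_numpy(),
                           upiv[(roi, "incongruent")].to_numpy())
            tests.append(_test_row(f"{roi}_univariate_congruent_vs_incongruent", res))
        out["group_tests"] = pd.DataFrame(tests)
        coords = voxel_meta[["x", "y", "z"]].to_numpy()
        clusters, _ = whole_brain_contrast(
            np.vstack(diff_maps), coords, alpha=cfg.stats.alpha,
            cluster_min=cfg.stats.cluster_min, sided="two",
        )
        out["univariate_clusters"] = clusters
    if cfg.run_coupling:
        coords = voxel_meta[["x", "y", "z"]].to_numpy()
        cl, _ = coupling_contrast(
            coupling_maps_list, coords, alpha=cfg.stats.alpha,
            cluster_min=cfg.stats.cluster_min, fisher=cfg.stats.fisher,
        )
        out["coupling_clusters"] = cl
        out["_coupling_maps"] = coupling_maps_list
    _write_outputs(cfg, out)
    return out


def run_experiment2(cfg: PipelineConfig, cohort=None) -> dict:
    """Full Experiment 2 analysis with participant exclusion."""
    if cfg.experiment != 2:
        raise ValueError("config is not for experiment 2")
    _log_decisions(cfg)
    params = _design_params(cfg)
    voxel_meta = make_voxel_meta(cfg.voxels_per_roi, cfg.n_other_voxels,
                                 hemispheres=cfg.hemispheres)
    analyzer = SubjectAnalyzer(cfg, params, voxel_meta)
    subjects = cohort if cohort is not None else _simulate_cohort_stream(
        cfg, params, voxel_meta
    )

    curve_frames, report_rows = [], []
    for sd in subjects:
        reports = simulate_reports(
            sd.design, sd.truth.attention_noise,
            seed=int(np.random.SeedSequence(
                [cfg.seed, int(sd.subject.split("-")[-1]), 808]
            ).generate_state(1)[0] >> 1),
        )
        r = _report_correlation(reports)
        report_rows.append({"subject": sd.subject, "report_correlation": r})
        loc, train, main = analyzer.betas(sd)
        _, subrois = analyzer.rank_voxels(loc)
        cdf = analyzer.decode(train, main, subrois)
        cdf.insert(0, "subject", sd.subject)
        curve_frames.append(cdf)

    reports_df = pd.DataFrame(report_rows)
    keep = exclude_inattentive(reports_df["report_correlation"].to_numpy())
    reports_df["excluded"] = ~keep
    kept = set(reports_df.loc[keep, "subject"])
    curves = _group_curves([c for c in curve_frames if c["subject"].iloc[0] in kept])

    summaries = _summaries(curves)
    tests, tfce_rows = [], []
    piv = summaries.pivot_table(index="subject", columns=["roi", "condition"],
                                values="value", sort=True)
    for roi in cfg.rois:
        vals = piv[(roi, "occluded")].to_numpy()
        tests.append(_test_row(f"{roi}_occluded_vs_0", one_sample_t(vals)))
        X = _info_curves(curves, roi, "occluded")
        res = tfce_signflip_test(
            X, n_permutations=cfg.stats.n_permutations, E=cfg.stats.E,
            H=cfg.stats.H, dh=cfg.stats.dh, seed=cfg.seed,
            null_mode=cfg.stats.tfce_null,
        )
        counts = np.sort(curves["n_voxels"].unique())
        for k, n in enumerate(counts):
            tfce_rows.append({
                "roi": roi, "n_voxels": int(n), "t": res.observed_t[k],
                "tfce": res.observed_tfce[k], "z": res.z[k],
                "p_fwe": res.p_fwe[k],
                "significant": bool(res.p_fwe[k] < cfg.stats.fwe_alpha),
            })
    if len(cfg.rois) == 2:
        r1, r2 = cfg.rois
        tests.append(_test_row(
            f"{r1}_vs_{r2}_occluded",
            paired_t(piv[(r1, "occluded")].to_numpy(), piv[(r2, "occluded")].to_numpy()),
        ))
    out = {
        "curves": curves,
        "summaries": summaries,
        "group_tests": pd.DataFrame(tests),
        "tfce": pd.DataFrame(tfce_rows),
        "reports": reports_df,
    }
    _write_outputs(cfg, out)
    return out


def run_coupling_study(cfg: PipelineConfig) -> dict:
    """Coupling-only analysis of one simulated cohort.

    Runs GLM + localizer ranking + the per-subject coupling pipeline
    (skipping sub-ROI decoding, which the coupling contrast does not use)
    and returns the group cluster table plus the per-subject maps.
    """
    params = _design_params(cfg)
    voxel_meta = make_voxel_meta(cfg.voxels_per_roi, cfg.n_other_voxels,
                                 hemispheres=cfg.hemispheres)
    analyzer = SubjectAnalyzer(cfg, params, voxel_meta)
    maps = []
    for sd in _simulate_cohort_stream(cfg, params, voxel_meta):
        loc, train, _main = analyzer.betas(sd)
        tmap, _ = analyzer.rank_voxels(loc)
        maps.append(analyzer.coupling(sd, train, tmap))
    coords = voxel_meta[["x", "y", "z"]].to_numpy()
    clusters, t = coupling_contrast(
        maps, coords, alpha=cfg.stats.alpha, cluster_min=cfg.stats.cluster_min,
        fisher=cfg.stats.fisher,
    )
    return {"clusters": clusters, "tmap": t, "maps": maps,
            "voxel_meta": voxel_meta}


def _report_correlation(reports: pd.DataFrame) -> float:
    t = reports["true_count"].to_numpy(dtype=float)
    r = reports["reported_count"].to_numpy(dtype=float)
    if t.std() == 0 or r.std() == 0:
        return 1.0 if np.array_equal(t, r) else 0.0
    return float(np.corrcoef(t, r)[0, 1])


def run_calibration(cfg: PipelineConfig, n_replicates: int) -> pd.DataFrame:
    """Replicate cohorts and tabulate per-replicate detection outcomes.

    For Experiment 1 the detection target is the congruency effect
    (paired t and TFCE on congruent-incongruent curves, per ROI); for
    Experiment 2 it is above-chance occluded decoding.  Returns one row per
    replicate x ROI with p-values and significance flags; rates are simple
    column means.  Univariate/coupling stages are skipped.
    """
    rows = []
    base = cfg.to_dict()
    base.update({"run_univariate": False, "run_coupling": False,
                 "write_outputs": False})
    from .config import make_config

    for rep in range(n_replicates):
        rcfg = make_config(dict(base, seed=int(
            np.random.SeedSequence([cfg.seed, 909, rep]).generate_state(1)[0] >> 1
        )))
        res = (run_experiment1 if cfg.experiment == 1 else run_experiment2)(rcfg)
        tests = res["group_tests"].set_index("test")
        tfce = res["tfce"]
        for roi in cfg.rois:
            if cfg.experiment == 1:
                t_row = tests.loc[f"{roi}_congruent_vs_incongruent"]
            else:
                t_row = tests.loc[f"{roi}_occluded_vs_0"]
            roi_tfce = tfce[tfce["roi"] == roi]
            rows.append({
                "replicate": rep,
                "roi": roi,
                "cohens_d": float(t_row["cohens_d"]),
                "statistic": float(t_row["statistic"]),
                "p": float(t_row["p"]),
                "significant_t": bool(
                    t_row["p"] < 0.05 and t_row["statistic"] > 0
                ),
                "significant_t_twosided": bool(t_row["p"] < 0.05),
                "min_p_fwe": float(roi_tfce["p_fwe"].min()),
                "significant_tfce": bool(roi_tfce["significant"].any()),
            })
    return pd.DataFrame(rows)
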