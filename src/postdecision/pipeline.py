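"""End-to-end replay of the post-decision accumulation analysis on a
synthetic cohort: simulate behavior, render epochs, estimate theta
power, extract single-trial metrics, run the ROC / regression /
mediation statistics and fit the one-choice diffusion model per subject.

The whole run is a deterministic function of (config, seed): every
random stage derives its stream from ``config.cohort.seed``, and the
summary JSON is written with sorted keys so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cohort as coh
from . import ddm, mediation, metrics, regression, roc, spectral
from .io import (write_epochs_h5, write_fit_json, write_mediation_json,
                 write_trials_csv)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StatsConfig", "DdmFitConfig", "run_pipeline"]


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm_roc: int = 1000
    n_boot_mediation: int = 10_000
    mediation_bin_size: int = 12
    min_trials_regression: int = 20
    roc_span: tuple[float, float] = (-0.4, 0.6)
    roc_width: float = 0.020
    cpp_lowpass_hz: float = 6.0
    baseline_window: tuple[float, float] = (-0.3, 0.0)  # re stimulus


@dataclass
class DdmFitConfig:
    enabled: bool = True
    n_sim: int = 15_000
    n_particles: int = 30
    n_iter: int = 100
    min_detected: int = 10
    max_subjects: int | None = None
    traj_rt_bins: int = 3
    traj_n_sim: int = 2000


@dataclass
class PipelineConfig:
    cohort: coh.CohortConfig = field(default_factory=coh.CohortConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    ddm_fit: DdmFitConfig = field(default_factory=DdmFitConfig)
    output_dir: str = "postdecision_out"
    save_epochs: bool = False


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the summary dictionary.

    On a stage failure the partial summary written so far is preserved in
    ``summary.json`` and the error is re-raised with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.cohort.seed
    config_echo = dataclasses.asdict(config)
    config_echo.pop("output_dir", None)  # filesystem detail, not analysis state
    summary: dict = {
        "config": _jsonable(config_echo),
        "stages": [],
    }

    def checkpoint():
        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True))

    state: dict = {}

    def stage(name):
        def wrap(fn):
            summary["stages"].append(name)
            try:
                fn()
            except Exception as err:
                checkpoint()
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            checkpoint()
        return wrap

    @stage("simulate")
    def _simulate():
        trials = coh.generate_behavior(config.cohort)
        state["trials"] = trials
        write_trials_csv(trials, out / "trials.csv")
        summary["behavior"] = coh.behavioral_summary(trials)

    @stage("epochs")
    def _epochs():
        trials = state["trials"]
        detected = trials[trials.detected.astype(bool)]
        errors = trials[trials.is_error]
        state["epochs_err_resp"] = coh.render_epochs(errors, config.cohort,
                                                     "response")
        state["epochs_det_resp"] = coh.render_epochs(detected, config.cohort,
                                                     "response")
        state["epochs_det_rep"] = coh.render_epochs(detected, config.cohort,
                                                    "report")
        state["epochs_det_stim"] = coh.render_epochs(detected, config.cohort,
                                                     "stimulus")
        if config.save_epochs:
            write_epochs_h5(state["epochs_err_resp"], out / "epochs_error_response.h5")
            write_epochs_h5(state["epochs_det_rep"], out / "epochs_detected_report.h5")

    @stage("power")
    def _power():
        st = config.stats
        resp = state["epochs_err_resp"]
        power = spectral.hilbert_band_power(resp, "FCtheta")
        # condition-specific trial-averaged pre-stimulus baseline
        stim = coh.render_epochs(state["trials"][state["trials"].is_error],
                                 config.cohort, "stimulus")
        base_power = spectral.hilbert_band_power(stim, "FCtheta")
        labels = state["trials"].loc[resp.trial_index, "detected"].astype(bool)
        power_db = spectral.db_normalize(power, st.baseline_window,
                                         groups=labels.to_numpy(),
                                         baseline_from=base_power)
        state["theta_power_err"] = power_db
        det_mask = labels.to_numpy()
        state["theta_power_det"] = spectral.TFPower(
            power=power_db.power[det_mask], times=power_db.times,
            normalization="dB")
        state["det_in_err"] = det_mask

    @stage("metrics")
    def _metrics():
        st = config.stats
        trials = state["trials"]
        cpp_resp = spectral.lowpass_epochs(state["epochs_det_resp"],
                                           st.cpp_lowpass_hz, ("CPP",))
        cpp_rep = spectral.lowpass_epochs(state["epochs_det_rep"],
                                          st.cpp_lowpass_hz, ("CPP",))
        table = metrics.build_single_trial_metrics(
            trials, state["theta_power_det"], cpp_resp, cpp_rep)
        state["metrics"] = table
        table.to_csv(out / "metrics.csv", index=False)
        _, n_excluded = metrics.go_rt_exclusion(trials)
        summary["go_rt_exclusions"] = n_excluded

    @stage("roc")
    def _roc():
        st = config.stats
        resp = state["epochs_err_resp"]
        labels = state["det_in_err"]
        subjects = state["trials"].loc[resp.trial_index, "subject"].to_numpy()
        res = {}
        for name, data in (("CPP", resp.channel("CPP")),
                           ("FCtheta", state["theta_power_err"].power)):
            series = roc.permutation_null(
                data, resp.times, labels, subjects, n=st.n_perm_roc,
                seed=seed + 11, width=st.roc_width, step=st.roc_width,
                span=st.roc_span)
            series.to_frame().to_csv(out / f"roc_{name}.csv", index=False)
            above = series.auc > series.threshold_hi
            res[name] = {
                "n_windows": int(series.auc.size),
                "n_above": int(above.sum()),
                "max_auc": float(series.auc.max()),
                "first_sig_time": (float(series.window_centers[above][0])
                                   if above.any() else None),
            }
        summary["roc"] = res

    @stage("regression")
    def _regression():
        st = config.stats
        table = state["metrics"]
        res = {}
        for model in ("amplitude", "buildup"):
            effects = regression.within_subject_model(
                table, model, st.min_trials_regression)
            effects.to_csv(out / f"effects_{model}.csv", index=False)
            res[model] = regression.group_level_tests(effects)
            res[model]["max_vif"] = float(effects["vif"].max())
        summary["regression"] = res

    @stage("mediation")
    def _mediation():
        st = config.stats
        table = state["metrics"].dropna(
            subset=["fctheta_amp", "cpp_buildup_mediation", "rt_d"])
        result = mediation.mediation_analysis(
            table["fctheta_amp"].to_numpy(),
            table["cpp_buildup_mediation"].to_numpy(),
            table["rt_d"].to_numpy(),
            table["subject"].to_numpy(),
            bin_size=st.mediation_bin_size,
            n_boot=st.n_boot_mediation, seed=seed + 23)
        write_mediation_json(result, out / "mediation.json")
        summary["mediation"] = result.to_dict()
        summary["mediation"].pop("ci", None)

    @stage("ddm_fits")
    def _ddm_fits():
        fc = config.ddm_fit
        if not fc.enabled:
            summary["ddm"] = None
            return
        trials = state["trials"]
        fits = []
        subjects = sorted(trials["subject"].unique())
        if fc.max_subjects is not None:
            subjects = subjects[: fc.max_subjects]
        for subj in subjects:
            sub = trials[(trials.subject == subj) & trials.is_error]
            rts = sub.loc[sub.detected.astype(bool), "rt_d"].to_numpy()
            if rts.size < fc.min_detected:
                logger.info("subject %s skipped: %d detected trials", subj, rts.size)
                continue
            deadline = ddm.estimate_deadline(rts)
            q, O = ddm.defective_quantile_bins(rts, len(sub))
            fit = ddm.fit_pso(O, q, len(sub), deadline, ddm.FitConfig(
                n_sim=fc.n_sim, n_particles=fc.n_particles,
                n_iter=fc.n_iter, seed=seed + 100 + subj))
            write_fit_json(fit, out / f"fit_subject{subj}.json")
            fits.append((subj, fit))
        if fits:
            arr = np.array([[f.params.a, f.params.t_nd, f.params.v,
                             f.params.eta, f.chi2] for _, f in fits])
            summary["ddm"] = {
                "n_fitted": len(fits),
                "mean": dict(zip(("a", "t_nd", "v", "eta", "chi2"),
                                 arr.mean(axis=0))),
                "sd": dict(zip(("a", "t_nd", "v", "eta", "chi2"),
                               arr.std(axis=0, ddof=1) if len(fits) > 1
                               else np.zeros(5))),
                "df": fits[0][1].df,
            }
            subj0, fit0 = fits[0]
            traj = ddm.simulate_decision_variable(
                fit0.params, rt_bins=fc.traj_rt_bins,
                n_sim=fc.traj_n_sim, seed=seed + 51)
            summary["ddm"]["trajectory_peak_times"] = [
                float(traj.times[np.argmax(tr)]) for tr in traj.detected]
        else:
            summary["ddm"] = {"n_fitted": 0}

    checkpoint()
    return json.loads((out / "summary.json").read_text())
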