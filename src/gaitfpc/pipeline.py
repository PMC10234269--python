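"""End-to-end orchestration: events -> stride matrices -> foot-placement
fit -> push-off correlations -> group inference.

The unit of analysis is one trial per participant per condition. Within a
trial, placements are analyzed per foot (placements of the left and of the
right foot are separate regressions); per-foot correlation curves are
averaged in Fisher-z space within a participant before group statistics, so
participants remain the independent unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import fpm, inference, pushoff
from .io import PipelineConfig, Trial, read_trial, write_manifest
from .synthetic import COMBINED_GRF, KINETIC_SIGNALS, TRAILING_GRF, TRAILING_MOMENT

logger = logging.getLogger("gaitfpc")

SIDES = ("left", "right")


@dataclass
class TrialResult:
    participant: str
    condition: str
    events: ev.GaitEventTable
    stride: ev.StrideMatrix
    fits: dict                     # placing foot -> FootPlacementFit
    errors: dict                   # placing foot -> per-step error vector (m)
    errors_by_step: np.ndarray     # (n_steps,) errors aligned to stride rows, NaN elsewhere
    corr: dict                     # signal -> placing foot -> CorrelationField
    contrasts: dict                # signal -> placing foot -> ExtremeContrast


def kinetic_rows(stride: ev.StrideMatrix, signal: str) -> np.ndarray:
    """Step-indexed rows of one of the three analysis kinetic signals."""
    if signal == COMBINED_GRF:
        return (stride.channels["grf_ap_left_N"] + stride.channels["grf_ap_right_N"])
    if signal == TRAILING_GRF:
        return pushoff.trailing_channel(stride, "grf_ap")
    if signal == TRAILING_MOMENT:
        return pushoff.trailing_channel(stride, "ankle_moment")
    raise ValueError(f"unknown kinetic signal {signal!r}")


def kinetic_rows_pre(stride: ev.StrideMatrix, signal: str) -> np.ndarray:
    """Pre-heel-strike rows for the full-stride view: the leg that pushes
    off in the next step's double stance, followed through this step (where
    it is the stance/leading leg)."""
    if signal == COMBINED_GRF:
        return kinetic_rows(stride, signal)
    base = "grf_ap" if signal == TRAILING_GRF else "ankle_moment"
    return pushoff.leading_channel(stride, base)


def analyze_trial(trial: Trial, config: PipelineConfig,
                  signals: tuple = KINETIC_SIGNALS,
                  contrasts: bool = True) -> TrialResult:
    """Run the single-trial analysis chain."""
    df = trial.signals
    if config.use_truth_events and hasattr(trial, "truth"):
        table = trial.truth.events
    else:
        table = ev.detect_events_from_cop(
            df["cop_ap_m"].to_numpy(), df["cop_ml_m"].to_numpy(), trial.fs,
            min_step_time=config.min_step_time, smooth_window=config.smooth_window,
        )
    windows = ev.segment_steps(table, n_samples=len(df))
    stride = ev.time_normalize(df, windows, j_ds=config.j_ds, j_ss=config.j_ss,
                               fs=trial.fs, method=config.interp_method)

    sides = np.array(stride.sides_leading())
    fits, errors = {}, {}
    errors_by_step = np.full(stride.n_steps, np.nan)
    for foot in SIDES:
        # the foot *placed* at the step's closing heel strike is the
        # contralateral of the step's leading side
        subset = sides == ev.other_side(foot)
        if subset.sum() < 3:
            logger.warning("%s: fewer than 3 %s-foot placements; skipped",
                           trial.participant, foot)
            continue
        fit = fpm.fit_fpm_from_stride(stride, step_subset=subset)
        fits[foot] = fit
        errors[foot] = fpm.foot_placement_errors(fit)
        errors_by_step[subset] = errors[foot]

    corr: dict = {}
    contr: dict = {}
    for signal in signals:
        rows = kinetic_rows(stride, signal)
        rows_pre = kinetic_rows_pre(stride, signal)
        corr[signal] = {}
        contr[signal] = {}
        for foot in fits:
            e = np.where(sides == ev.other_side(foot), errors_by_step, np.nan)
            corr[signal][foot] = pushoff.correlate_errors_kinetics(
                e, rows, lag="full_stride", signal_id=signal,
                j_ds=config.j_ds, j_ss=config.j_ss, kinetics_pre=rows_pre,
            )
            if contrasts:
                contr[signal][foot] = pushoff.extreme_error_contrast(
                    e, rows, k=config.k_extreme, lag="full_stride",
                    j_ds=config.j_ds, j_ss=config.j_ss, kinetics_pre=rows_pre,
                )
    return TrialResult(participant=trial.participant, condition=trial.condition,
                       events=table, stride=stride, fits=fits, errors=errors,
                       errors_by_step=errors_by_step, corr=corr, contrasts=contr)


def participant_z_curve(result: TrialResult, signal: str) -> np.ndarray:
    """Per-participant Fisher-z curve: per-foot curves averaged in z-space."""
    zs = [f.fisher_z() for f in result.corr[signal].values()]
    Z = np.stack(zs)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(Z, axis=0)


@dataclass
class GroupResults:
    condition: str
    fields: dict               # signal -> inference.GroupField
    trial_results: list


def group_analysis(results: list[TrialResult], config: PipelineConfig,
                   signals: tuple = KINETIC_SIGNALS) -> dict[str, GroupResults]:
    """Group per-condition inference across participants."""
    out: dict[str, GroupResults] = {}
    rng = np.random.default_rng(config.seed)
    for condition in sorted({r.condition for r in results}):
        sub = [r for r in results if r.condition == condition]
        fields = {}
        for signal in signals:
            Z = np.stack([participant_z_curve(r, signal) for r in sub])
            fields[signal] = inference.group_correlation_field(
                signal, Z, alpha=config.alpha,
                n_permutations=config.n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
        out[condition] = GroupResults(condition=condition, fields=fields,
                                      trial_results=sub)
    return out


# ---------------------------------------------------------------------------
# Null calibration of the cluster test
# ---------------------------------------------------------------------------

def null_generator_config(**overrides) -> "synthetic.GeneratorConfig":
    """Generator configuration with all feedback gains zero: errors and
    kinetics are independent by construction."""
    from . import synthetic

    defaults = dict(gain_trailing_grf=0.0, gain_ankle_moment=0.0,
                    gain_leading_grf=0.0)
    defaults.update(overrides)
    return synthetic.GeneratorConfig(**defaults)


def null_fwer_rate(
    n_replicates: int = 200,
    n_participants: int = 20,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    signal: str = TRAILING_GRF,
    gen_config=None,
) -> float:
    """Family-wise false-positive rate of the permutation cluster test on
    replicate null experiments.

    Each replicate simulates ``n_participants`` trials with zero feedback
    gain, runs the full pipeline (CoP event detection, normalization,
    foot-placement fit, error-kinetics correlation, per-participant z
    averaging over feet) and one permutation cluster test of the group
    field; returns the fraction of replicates with any significant cluster.
    """
    base = gen_config if gen_config is not None else null_generator_config()
    pcfg = PipelineConfig(alpha=alpha, n_permutations=n_permutations)
    root = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in root.spawn(n_replicates):
        children = rep_ss.spawn(n_participants + 1)
        Z = []
        for i in range(n_participants):
            s = int(children[i].generate_state(1)[0] % (2**31 - 1))
            from . import synthetic
            trial = synthetic.simulate_trial(base, seed=s)
            res = analyze_trial(trial, pcfg, signals=(signal,), contrasts=False)
            Z.append(participant_z_curve(res, signal))
        Z = np.stack(Z)
        perm_seed = int(children[-1].generate_state(1)[0] % (2**31 - 1))
        mask = np.any(np.isnan(Z), axis=0)
        result = inference.permutation_cluster_inference(
            Z, alpha=alpha, n_permutations=n_permutations, seed=perm_seed, mask=mask
        )
        hits += int(result.any_significant)
    return hits / n_replicates


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, trial_paths: list) -> dict[str, GroupResults]:
    """Read trials, run per-trial and group analyses, write the result bundle.

    Outputs per trial: events JSON, foot-placement fit CSV, correlation-field
    CSVs; per condition and signal: group field CSV and a cluster report;
    plus a machine-readable run manifest. Any stage failure aborts with the
    stage and offending trial named.
    """
    if not trial_paths:
        raise ValueError("need at least one trial")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    dropped: list[str] = []

    results = []
    for path in trial_paths:
        try:
            trial = read_trial(path)
        except Exception as exc:
            raise RuntimeError(f"stage=read trial={path}: {exc}") from exc
        try:
            res = analyze_trial(trial, config)
        except Exception as exc:
            raise RuntimeError(f"stage=analyze trial={path}: {exc}") from exc
        results.append(res)
        stem = f"{res.participant}_{res.condition}"
        res.events.to_json(out_dir / f"{stem}_events.json")
        outputs.append(f"{stem}_events.json")
        fit_rows = []
        for foot, fit in res.fits.items():
            for j in range(fit.phase.size):
                fit_rows.append({
                    "foot": foot, "phase_pct": fit.phase[j],
                    "beta_pos": fit.beta_pos[j], "beta_vel": fit.beta_vel[j],
                    "r_squared": fit.r_squared[j], "p_value": fit.p_values[j],
                })
        pd.DataFrame(fit_rows).to_csv(out_dir / f"{stem}_fpm.csv", index=False)
        outputs.append(f"{stem}_fpm.csv")
        for signal, per_foot in res.corr.items():
            rows = []
            for foot, cf in per_foot.items():
                for j in range(cf.r.size):
                    rows.append({
                        "foot": foot, "j": j, "phase_label": cf.phase_labels[j],
                        "r": cf.r[j], "slope": cf.slope[j],
                        "n_pairs": cf.n_pairs, "masked": bool(cf.mask[j]),
                    })
            pd.DataFrame(rows).to_csv(out_dir / f"{stem}_corr_{signal}.csv", index=False)
            outputs.append(f"{stem}_corr_{signal}.csv")

    try:
        groups = group_analysis(results, config)
    except Exception as exc:
        raise RuntimeError(f"stage=group_inference: {exc}") from exc
    for condition, g in groups.items():
        for signal, gf in g.fields.items():
            df = pd.DataFrame({"j": np.arange(gf.mean_r.size),
                               "mean_r": gf.mean_r, "masked": gf.mask})
            name = f"group_{condition}_{signal}.csv"
            df.to_csv(out_dir / name, index=False)
            outputs.append(name)
            rep = f"group_{condition}_{signal}_clusters.txt"
            with open(out_dir / rep, "w") as fh:
                if gf.cluster_result is not None:
                    fh.write(gf.cluster_result.report() + "\n")
                else:
                    fh.write("no testable phases\n")
            outputs.append(rep)

    write_manifest(out_dir / "manifest.json", config,
                   inputs=[str(p) for p in trial_paths], outputs=outputs,
                   dropped=dropped)
    return groups
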