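"""End-to-end pipeline: simulate → preprocess → score → TFR → RSA → stats.

:func:`run_pipeline` strings every stage together for a simulated cohort
and returns (and optionally writes) a machine-readable summary: fixed-effect
tables for each measure, interaction contrasts, the rating ANOVA,
magnitude-effect correlations, RSA cluster tables, split-half reliabilities
and the artifact-retention rate.  Reruns with the same configuration and
seed are bit-identical at the table level.

Stage order: mastoid re-reference → artifact screen → band-pass filter →
(ERP view) baseline subtraction and single-trial scoring / (TF view) Morlet
transform on the ROI channels, welding-baseline normalization and band
scoring.  The artifact screen runs before filtering so threshold violations
are judged on unsmoothed voltages.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp, rsa, stats, synth, tfr
from .epochs import (EpochSet, baseline_subtract, filter_bandpass,
                     reject_artifacts, rereference_mastoids)

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """Configuration of one full simulated-cohort analysis run."""

    seed: int = 0
    design: synth.DesignSpec = field(default_factory=synth.DesignSpec)
    effects: synth.EffectSpec = field(default_factory=synth.default_effects)
    noise: synth.NoiseSpec = field(default_factory=synth.NoiseSpec)
    band: tuple[float, float] = (0.1, 35.0)
    baseline: tuple[float, float] = (-200.0, 0.0)
    erp_measures: tuple[erp.MeasureSpec, ...] = (erp.REWP, erp.P3)
    tf_measures: tuple = (tfr.THETA_MEASURE, tfr.DELTA_MEASURE)
    tf_baseline: tuple[float, float] = (-500.0, -300.0)
    rsa_window: tuple[float, float] = (-200.0, 1000.0)
    n_perm: int = 1000
    run_tf: bool = True
    run_rsa: bool = True
    n_reliability_splits: int = 20
    make_plots: bool = False        # best-effort figures, not deterministic


def _preprocess(e: EpochSet, cfg: PipelineConfig) -> tuple[EpochSet, float]:
    e = rereference_mastoids(e)
    e, rep = reject_artifacts(e)
    e = filter_bandpass(e, cfg.band[0], cfg.band[1])
    return e, rep.retained_fraction


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on a freshly simulated cohort; return the summary.

    Participants are simulated and processed one at a time (the same child
    seeds :func:`prosorew.synth.simulate_cohort` would use), so memory stays
    at single-participant scale regardless of cohort size.
    """
    seeds = synth.participant_seeds(cfg.seed, cfg.design.n_participants)

    retained = []
    erp_scores: dict[str, list[erp.SingleTrialScores]] = {
        m.name: [] for m in cfg.erp_measures}
    tf_scores: dict[str, list[erp.SingleTrialScores]] = {
        m[0]: [] for m in cfg.tf_measures} if cfg.run_tf else {}
    rating_frames: list[pd.DataFrame] = []

    tf_channels = sorted({ch for m in cfg.tf_measures for ch in m[3]})

    full_models = rsa.model_rdms()
    full_coefs: dict[str, list[np.ndarray]] = {f: [] for f in full_models}
    split_coefs: dict[str, dict[str, list[np.ndarray]]] = {}
    rsa_times: np.ndarray | None = None

    for i, s in enumerate(seeds):
        b = synth.simulate_participant(cfg.design, cfg.effects, cfg.noise,
                                       int(s), f"p{i:02d}")
        rating_frames.append(b.ratings)
        clean, frac = _preprocess(b.epochs, cfg)
        del b
        retained.append(frac)

        if cfg.run_tf:
            t_raw = tfr.morlet_transform(clean, channels=tf_channels)
            t_z = tfr.weld_baseline(t_raw, cfg.tf_baseline)
            for name, band, window, roi in cfg.tf_measures:
                tf_scores[name].append(
                    tfr.score_band_power(t_z, band, window, roi, name=name))
            del t_raw, t_z

        based = baseline_subtract(clean, cfg.baseline)
        for m in cfg.erp_measures:
            erp_scores[m.name].append(erp.score_single_trial(based, m))

        if cfg.run_rsa:
            keep = based.time_mask(cfg.rsa_window)
            cropped = EpochSet(
                data=based.data[:, :, keep], times=based.times[keep],
                channels=based.channels, positions=based.positions,
                conditions=based.conditions,
                participant_id=based.participant_id,
                baseline_window=based.baseline_window)
            rsa_times = cropped.times
            n = rsa.neural_rdm(cropped)
            c = rsa.rdm_regression(n, full_models,
                                   participant_id=cropped.participant_id)
            for k, name in enumerate(c.predictors):
                full_coefs[name].append(c.coef[k])
            sp = rsa.rsa_by_time_condition([cropped])
            for lvl, preds in sp.items():
                dest = split_coefs.setdefault(lvl, {f: [] for f in preds})
                for name, arr in preds.items():
                    dest[name].append(arr[0])
            del cropped
        del clean, based

    ratings = pd.concat(rating_frames, ignore_index=True)

    from .io import FORMAT_VERSION as EPOCH_FORMAT_VERSION

    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "epoch_format_version": EPOCH_FORMAT_VERSION,
        "seed": cfg.seed,
        "n_participants": cfg.design.n_participants,
        "n_trials": cfg.design.n_trials,
        "sampling_rate": cfg.design.sampling_rate,
        "retained_fraction": float(np.mean(retained)),
        "measures": {},
    }

    all_scores = {**erp_scores, **tf_scores}
    score_frames: dict[str, pd.DataFrame] = {}
    for name, per_part in all_scores.items():
        frame = erp.concat_scores(per_part)
        score_frames[name] = frame
        fit = stats.fit_mixed(frame, measure=name)
        contrasts = stats.emm_contrasts(fit, "simple_magnitude")
        rel = erp.split_half_reliability(
            {s.table["participant"].iloc[0]: s for s in per_part},
            n_splits=cfg.n_reliability_splits, seed=cfg.seed)
        summary["measures"][name] = {
            "fixed_effects": fit.table.to_dict(orient="records"),
            "simplification_trail": fit.trail,
            "simple_magnitude_contrasts": contrasts.to_dict(orient="records"),
            "split_half_reliability": rel,
        }

    anova = stats.rm_anova(ratings)
    summary["rating_anova"] = anova.table.to_dict(orient="records")

    corr_measures = {n: f for n, f in score_frames.items()}
    comparisons = stats.magnitude_effect_correlations(corr_measures)
    summary["magnitude_effect_correlations"] = [asdict(c) for c in comparisons]

    if cfg.run_rsa:
        rsa_summary = {}
        for k, name in enumerate(sorted(full_coefs)):
            res = rsa.cluster_permutation(np.vstack(full_coefs[name]),
                                          rsa_times, n_perm=cfg.n_perm,
                                          seed=cfg.seed + 1 + k)
            rsa_summary[name] = _cluster_records(res)
        split_summary = {}
        for lvl, preds in split_coefs.items():
            split_summary[lvl] = {}
            for k, name in enumerate(sorted(preds)):
                res = rsa.cluster_permutation(
                    np.vstack(preds[name]), rsa_times, n_perm=cfg.n_perm,
                    seed=cfg.seed + 100 + k)
                split_summary[lvl][name] = _cluster_records(res)
        summary["rsa"] = {"full_design": rsa_summary,
                          "by_time": split_summary}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in score_frames.items():
            frame.to_csv(out / f"scores_{name}.csv", index=False)
        ratings.to_csv(out / "ratings.csv", index=False)
        if cfg.run_rsa:
            rows = []
            for pred, cl in summary["rsa"]["full_design"].items():
                for i, c in enumerate(cl):
                    rows.append({"level": "all", "predictor": pred,
                                 "cluster_id": i, **c})
            for lvl, preds in summary["rsa"]["by_time"].items():
                for pred, cl in preds.items():
                    for i, c in enumerate(cl):
                        rows.append({"level": lvl, "predictor": pred,
                                     "cluster_id": i, **c})
            pd.DataFrame(rows, columns=["level", "predictor", "cluster_id",
                                        "start_ms", "end_ms", "mass", "p"]
                         ).to_csv(out / "clusters.csv", index=False)
        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, default=_jsonable)
        if cfg.make_plots and cfg.run_rsa:
            _plot_coding_series(full_coefs, rsa_times,
                                out / "coding_series.png")
    return summary


def _plot_coding_series(full_coefs: dict, times: np.ndarray,
                        out_path: Path) -> None:
    """Best-effort figure of the mean RSA coding time series."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name in sorted(full_coefs):
        arr = np.vstack(full_coefs[name])
        m = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        ax.plot(times, m, label=name, lw=1.2)
        ax.fill_between(times, m - sem, m + sem, alpha=0.25)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("coding coefficient (z units)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)


def _cluster_records(res: rsa.ClusterResult) -> list[dict]:
    return [
        {"start_ms": c.start_ms, "end_ms": c.end_ms, "mass": c.mass, "p": c.p}
        for c in res.clusters
    ]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def plot_grand_average(epoch_sets, channel: str, out_path: str | Path) -> None:
    """Best-effort grand-average waveform figure for one channel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .design import cell_table

    grand, sem, times = erp.grand_average(epoch_sets)
    ci = epoch_sets[0].channels.index(channel)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i, row in cell_table().iterrows():
        label = f"{row['beneficiary']}/{row['magnitude']}/{row['time']}"
        ax.plot(times, grand[i, ci], label=label, lw=1)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (μV)")
    ax.set_title(f"grand average at {channel}")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
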