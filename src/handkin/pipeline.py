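"""End-to-end orchestration: simulate -> sync -> kinematics -> agreement.

This module contains the library-level plumbing behind the command-line
interface: running a simulated study, writing/reading trial bundles as CSV,
analysing bundles into per-trial measures, ROM tables, segment-length
summaries and Bland-Altman results, and rendering a human-readable report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import agreement as agr
from . import kinematics as kin
from . import simulate as sim
from . import sync
from .config import PipelineConfig
from .exceptions import ValidationError
from .recording import Recording

logger = logging.getLogger(__name__)


def sensors_from_config(config: PipelineConfig) -> Tuple[sim.SensorModel, sim.SensorModel]:
    reference = sim.SensorModel(
        nominal_rate=config.reference_rate_hz,
        positional_noise_sd=config.reference_noise_mm,
    )
    bias = config.test_angular_bias_deg
    test = sim.SensorModel(
        nominal_rate=config.test_rate_hz,
        interval_jitter_cv=config.test_jitter_cv,
        positional_noise_sd=config.test_noise_mm,
        angular_bias=dict(sim.DEFAULT_TEST_ANGULAR_BIAS if bias is None else bias),
        dropout_prob=config.test_dropout_prob,
        trial_bias_sd=config.test_trial_bias_sd_deg,
    )
    return reference, test


def simulate_study(config: PipelineConfig,
                   profiles: Optional[Sequence[sim.TaskProfile]] = None,
                   ) -> List[sim.TrialBundle]:
    reference, test = sensors_from_config(config)
    return sim.generate_study(
        n_subjects=config.n_subjects,
        trials_per_subject=config.trials_per_subject,
        profiles=profiles,
        reference_sensor=reference,
        test_sensor=test,
        base_seed=config.seed,
        static_trials_per_subject=config.static_trials_per_subject,
    )


# --------------------------------------------------------------------------
# bundle persistence
# --------------------------------------------------------------------------

def bundle_prefix(bundle: sim.TrialBundle) -> str:
    return f"s{bundle.subject:02d}_{bundle.task}_t{bundle.trial:02d}"


def write_bundles(bundles: Sequence[sim.TrialBundle], out_dir,
                  config: PipelineConfig) -> dict:
    """Write each bundle's recordings, truth and metadata; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for bundle in bundles:
        prefix = bundle_prefix(bundle)
        bundle.reference_recording.to_csv(out / f"{prefix}_reference.csv")
        bundle.test_recording.to_csv(out / f"{prefix}_test.csv")
        if bundle.truth is not None:
            bundle.truth.to_long_frame().to_csv(out / f"{prefix}_truth.csv", index=False)
        meta = {**bundle.metadata, "seed": bundle.seed,
                "reference_nominal_rate": bundle.reference_recording.nominal_rate,
                "test_nominal_rate": bundle.test_recording.nominal_rate}
        with open(out / f"{prefix}_meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        entries.append({"prefix": prefix, "subject": bundle.subject,
                        "task": bundle.task, "trial": bundle.trial,
                        "static": bundle.is_static})
    manifest = {**config.provenance(),
                "n_dynamic": sum(1 for e in entries if not e["static"]),
                "n_static": sum(1 for e in entries if e["static"]),
                "bundles": entries}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@dataclass
class LoadedTrial:
    """A trial pair read back from disk (truth not required for analysis)."""

    reference_recording: Optional[Recording]
    test_recording: Optional[Recording]
    metadata: Dict

    @property
    def subject(self):
        return self.metadata.get("subject")

    @property
    def task(self):
        return self.metadata.get("task")

    @property
    def trial(self):
        return self.metadata.get("trial")

    @property
    def is_static(self):
        return self.metadata.get("task") == "static"


def load_bundles(in_dir) -> List[LoadedTrial]:
    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json in {in_dir}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    trials = []
    for entry in manifest["bundles"]:
        prefix = entry["prefix"]
        with open(in_dir / f"{prefix}_meta.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)

        def read(which, rate_key):
            path = in_dir / f"{prefix}_{which}.csv"
            if not path.exists():
                return None
            return Recording.from_csv(path, nominal_rate=meta.get(rate_key))

        trials.append(LoadedTrial(
            reference_recording=read("reference", "reference_nominal_rate"),
            test_recording=read("test", "test_nominal_rate"),
            metadata=meta,
        ))
    return trials


# --------------------------------------------------------------------------
# analysis
# --------------------------------------------------------------------------

def paired_trial_measure(ref_traj: kin.AngleTrajectory, test_traj: kin.AngleTrajectory,
                         measure: str, rate: float) -> Tuple[float, float]:
    """Per-trial (reference, test) summary values for one joint.

    ``"rom"`` uses each trajectory's own full span.  ``"mean"``/``"max"``
    evaluate both trajectories on their overlapping uniform grid so that a
    slight span mismatch between streams cannot masquerade as bias.
    """
    if measure == "rom":
        return (kin.rom(ref_traj).rom, kin.rom(test_traj).rom)
    t_end = min(float(ref_traj.times[-1]), float(test_traj.times[-1]))
    grid = np.arange(0.0, t_end + 1e-9, 1.0 / rate)
    rv = np.interp(grid, ref_traj.times, ref_traj.angles)
    tv = np.interp(grid, test_traj.times, test_traj.angles)
    if measure == "mean":
        return float(np.mean(rv)), float(np.mean(tv))
    if measure == "max":
        return float(np.max(rv)), float(np.max(tv))
    raise ValidationError(f"unknown measure {measure!r}")


def analyze_trial(trial, config: PipelineConfig) -> Tuple[List[dict], dict]:
    """Measures for one dynamic trial: one row per joint per system."""
    joints = trial.metadata.get("target_joints") or list(kin.hand.FLEXION_JOINTS)
    timeline = sync.build_time_vector(trial.test_recording)
    resampled = sync.resample_uniform(trial.test_recording, timeline,
                                      target_rate=config.target_rate_hz)
    ref_trajs = kin.angle_trajectories(trial.reference_recording, joints=joints)
    test_trajs = kin.angle_trajectories(resampled, joints=joints)
    rows = []
    curves = []
    for joint in joints:
        # trials of different speeds are compared on a 0-100% duration grid
        for system, traj in (("reference", ref_trajs[joint]),
                             ("test", test_trajs[joint])):
            norm = sync.time_normalize(traj, n_points=config.n_normalization_points)
            curves.append({"task": trial.task, "joint": joint, "system": system,
                           "angles": norm.angles, "percent": norm.times})
    for joint in joints:
        ref_rom = kin.rom(ref_trajs[joint])
        test_rom = kin.rom(test_trajs[joint])
        ref_val, test_val = paired_trial_measure(ref_trajs[joint], test_trajs[joint],
                                                 config.measure, config.target_rate_hz)
        base = {"subject": trial.subject, "task": trial.task,
                "trial": trial.trial, "joint": joint}
        rows.append({**base, "system": "reference", "rom": ref_rom.rom,
                     "angle_max": ref_rom.angle_max, "angle_min": ref_rom.angle_min,
                     "measure_value": ref_val})
        rows.append({**base, "system": "test", "rom": test_rom.rom,
                     "angle_max": test_rom.angle_max, "angle_min": test_rom.angle_min,
                     "measure_value": test_val})
    stats = {"subject": trial.subject, "task": trial.task, "trial": trial.trial,
             "source_rate_mean": timeline.mean_rate, "source_rate_cv": timeline.rate_cv,
             "n_frames_test": trial.test_recording.n_frames,
             "n_frames_reference": trial.reference_recording.n_frames}
    return rows, stats, curves


def analyze_static_trial(trial) -> List[dict]:
    rows = []
    for system, rec, rule in (("reference", trial.reference_recording, "thumb_only"),
                              ("test", trial.test_recording, "all")):
        for record in kin.segment_lengths(rec, metacarpals=rule):
            rows.append({"subject": trial.subject, "system": system,
                         "finger": record.finger, "segment": record.segment,
                         "mean_mm": record.mean, "sd_mm": record.sd})
    return rows


def analyze_bundles(trials: Sequence, config: PipelineConfig) -> Dict:
    """Analyse a set of trials into study-level tables.

    Returns a dict with ``trial_measures``, ``agreement``, ``rom_table``,
    ``segment_subject_means``, ``segment_summary`` DataFrames, per-trial
    ``resampling_stats``, the list of per-comparison ``ba_results`` and a
    ``failures`` accounting of skipped trials.
    """
    measure_rows: List[dict] = []
    segment_rows: List[dict] = []
    stats_rows: List[dict] = []
    curve_rows: List[dict] = []
    n_failed = 0
    failures = []
    for trial in trials:
        if trial.reference_recording is None or trial.test_recording is None:
            n_failed += 1
            failures.append({"subject": trial.subject, "task": trial.task,
                             "trial": trial.trial, "reason": "missing recording"})
            logger.warning("skipping trial %s/%s/%s: missing recording",
                           trial.subject, trial.task, trial.trial)
            continue
        try:
            if trial.is_static:
                segment_rows.extend(analyze_static_trial(trial))
            else:
                rows, stats, curves = analyze_trial(trial, config)
                measure_rows.extend(rows)
                stats_rows.append(stats)
                curve_rows.extend(curves)
        except Exception as exc:
            n_failed += 1
            failures.append({"subject": trial.subject, "task": trial.task,
                             "trial": trial.trial, "reason": str(exc)})
            logger.warning("skipping trial %s/%s/%s: %s",
                           trial.subject, trial.task, trial.trial, exc)

    normalized = pd.DataFrame()
    if curve_rows:
        # across-trial mean flexion curve per task/joint/system on the 0-100% grid
        agg: Dict[Tuple[str, str, str], List[np.ndarray]] = {}
        percent = curve_rows[0]["percent"]
        for row in curve_rows:
            agg.setdefault((row["task"], row["joint"], row["system"]), []).append(
                row["angles"])
        norm_rows = []
        for (task, joint, system), stack in agg.items():
            mean_curve = np.mean(np.vstack(stack), axis=0)
            for pct, ang in zip(percent, mean_curve):
                norm_rows.append({"task": task, "joint": joint, "system": system,
                                  "percent": pct, "angle_deg": ang,
                                  "n_trials": len(stack)})
        normalized = pd.DataFrame(norm_rows)

    trial_measures = pd.DataFrame(measure_rows)
    results = {"trial_measures": trial_measures,
               "normalized_curves": normalized,
               "resampling_stats": pd.DataFrame(stats_rows),
               "failures": {"n_success": len(stats_rows), "n_failed": n_failed,
                            "details": failures}}

    if len(trial_measures):
        results["rom_table"] = agr.rom_table(
            trial_measures.rename(columns={"rom": "rom"})[
                ["task", "joint", "system", "rom"]],
            pooling=config.rom_pooling)
        ba_results = []
        for (task, joint), group in trial_measures.groupby(["task", "joint"], sort=False):
            wide = group.pivot_table(index=["subject", "trial"], columns="system",
                                     values="measure_value").dropna()
            if len(wide) < 2:
                continue
            model = agr.BlandAltman(
                agr.PairedMeasurements(wide["reference"].to_numpy(),
                                       wide["test"].to_numpy()),
                sign=config.ba_sign, label=f"{task}/{joint}")
            result = model.fit()
            ba_results.append(((task, joint), result))
        results["ba_results"] = ba_results
        results["agreement"] = pd.DataFrame(
            [{"task": task, "joint": joint, **res.to_dict()}
             for (task, joint), res in ba_results]
        ).drop(columns=["label"])
    else:
        results["rom_table"] = pd.DataFrame()
        results["ba_results"] = []
        results["agreement"] = pd.DataFrame()

    if segment_rows:
        per_subject = pd.DataFrame(segment_rows)
        results["segment_subject_means"] = per_subject
        results["segment_summary"] = agr.summarize_segment_lengths(per_subject)
    else:
        results["segment_subject_means"] = pd.DataFrame()
        results["segment_summary"] = pd.DataFrame()
    return results


def write_analysis(results: Dict, out_dir, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("trial_measures", "agreement", "rom_table",
                 "segment_subject_means", "segment_summary", "resampling_stats",
                 "normalized_curves"):
        results[name].to_csv(out / f"{name}.csv", index=False)
    ba_dir = out / "ba_points"
    ba_dir.mkdir(exist_ok=True)
    for (task, joint), res in results["ba_results"]:
        res.plot_data().to_csv(ba_dir / f"{task}__{joint}.csv", index=False)
    manifest = {**config.provenance(), "failures": results["failures"]}
    with open(out / "analysis_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def render_report(analysis_dir, out_path) -> str:
    """One human-readable summary (segment table, ROM table, BA block per
    joint/task) regenerated byte-identically from the analysis outputs."""
    analysis_dir = Path(analysis_dir)
    manifest_path = analysis_dir / "analysis_manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no analysis_manifest.json in {analysis_dir}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)

    def table(name):
        path = analysis_dir / f"{name}.csv"
        return pd.read_csv(path) if path.exists() and path.stat().st_size > 1 else pd.DataFrame()

    lines = ["# Hand-tracking agreement report", "",
             f"Config hash: {manifest['config_hash']}  |  "
             f"package version: {manifest['package_version']}", "",
             f"Trials analysed: {manifest['failures']['n_success']} succeeded, "
             f"{manifest['failures']['n_failed']} failed/skipped", ""]

    seg = table("segment_summary")
    if len(seg):
        lines += ["## Segment lengths (mean +/- sd across subjects, mm)", "",
                  seg.round(2).to_string(index=False), ""]
    romt = table("rom_table")
    if len(romt):
        lines += ["## Range of motion per joint (pooled across trials, deg)", "",
                  romt.round(2).to_string(index=False), ""]
    ba = table("agreement")
    if len(ba):
        lines += ["## Bland-Altman agreement per joint and movement", ""]
        for _, row in ba.iterrows():
            trend = ("r undefined" if not row["r_defined"]
                     else f"r = {row['r']:.4f}, P = {row['p']:.4f}")
            lines += [f"### {row['task']} / {row['joint']}",
                      f"- n = {int(row['n'])} pairs",
                      f"- bias = {row['bias']:.2f} deg "
                      f"(95% CI [{row['ci95_low']:.2f}, {row['ci95_high']:.2f}])",
                      f"- limits of agreement [{row['loa_low']:.2f}, {row['loa_high']:.2f}] deg",
                      f"- trend: {trend}", ""]
    text = "\n".join(lines)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def plot_bland_altman(result, ax=None):
    """Render one BA plot (points, bias line, LoA lines) with matplotlib."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias {result.bias:.2f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of systems (deg)")
    ax.set_ylabel(f"difference (deg, {result.sign})")
    if result.label:
        ax.set_title(result.label)
    ax.legend(frameon=False)
    return ax
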