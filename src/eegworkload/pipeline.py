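"""Cohort-level orchestration: session scoring and tidy result tables."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import spectral
from .behavior import summarize_behavior
from .eegio import read_recording
from .synth import trial_results_from_frame
from .tasks import CONDITIONS, Task

__all__ = ["score_session", "cohort_workload", "cohort_behavior", "load_manifest"]


def load_manifest(cohort_dir: str | Path) -> dict:
    path = Path(cohort_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"cohort manifest not found: {path}")
    return json.loads(path.read_text())


def _session_files(cohort_dir: Path, rel: str) -> tuple[Path, Path]:
    sess = cohort_dir / rel
    trials_csv = sess / "trials.csv"
    eeg_dat = sess / "eeg.dat"
    missing = [str(p) for p in (trials_csv, eeg_dat) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"incomplete session {rel}: missing {missing}")
    return trials_csv, eeg_dat


def score_session(
    trials_csv: str | Path,
    eeg_path: str | Path,
    band: tuple[float, float] = (0.1, 30.0),
    window: tuple[float, float] = spectral.DEFAULT_WINDOW,
    artifact_threshold: float = spectral.DEFAULT_ARTIFACT_THRESHOLD,
    tar_method: str = "ratio_of_means",
) -> spectral.WorkloadScore:
    """Full single-session pipeline: filter, epoch, spectra, TAR."""
    trials = trial_results_from_frame(pd.read_csv(trials_csv))
    rec = read_recording(eeg_path)
    rec = spectral.bandpass_filter(rec, *band)
    epochs = spectral.extract_epochs(
        rec, trials, window=window, artifact_threshold=artifact_threshold
    )
    return spectral.compute_tar(epochs, method=tar_method)


def cohort_workload(cohort_dir: str | Path, **kwargs) -> pd.DataFrame:
    """Workload table: one row per subject x phase x task."""
    cohort_dir = Path(cohort_dir)
    manifest = load_manifest(cohort_dir)
    rows = []
    for subj in manifest["subjects"]:
        for sess in subj["sessions"]:
            trials_csv, eeg_dat = _session_files(cohort_dir, sess["path"])
            score = score_session(trials_csv, eeg_dat, **kwargs)
            rows.append(
                (
                    subj["subject"],
                    subj["group"],
                    sess["phase"],
                    sess["task"],
                    score.theta_fz,
                    score.alpha_pz,
                    score.tar,
                    score.n_epochs,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "phase", "task",
                 "theta_fz", "alpha_pz", "tar", "n_epochs"],
    )


def cohort_behavior(cohort_dir: str | Path) -> pd.DataFrame:
    """Behavior table: one row per subject x phase x task."""
    cohort_dir = Path(cohort_dir)
    manifest = load_manifest(cohort_dir)
    rows = []
    for subj in manifest["subjects"]:
        for sess in subj["sessions"]:
            trials_csv, _ = _session_files(cohort_dir, sess["path"])
            trials = trial_results_from_frame(pd.read_csv(trials_csv))
            summary = summarize_behavior(trials)
            task = Task(sess["task"])
            inhib_cond, neutral_cond = CONDITIONS[task]
            rows.append(
                (
                    subj["subject"],
                    subj["group"],
                    sess["phase"],
                    sess["task"],
                    round(summary.mean_rt[neutral_cond], 3),
                    round(summary.mean_rt[inhib_cond], 3),
                    summary.error_count[neutral_cond],
                    summary.error_count[inhib_cond],
                    round(summary.inhibition_score, 3),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "phase", "task",
                 "rt_neutral", "rt_inhibition", "errors_neutral",
                 "errors_inhibition", "inhibition_score"],
    )


def workload_to_scores(workload: pd.DataFrame, behavior: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot per-session tables into the per-subject x task scores frame."""
    wide = workload.pivot_table(
        index=["subject", "group", "task"], columns="phase", values="tar"
    ).reset_index()
    wide = wide.rename(columns={"pre": "tar_pre", "post": "tar_post"})
    if behavior is not None:
        beh = behavior.pivot_table(
            index=["subject", "group", "task"], columns="phase",
            values="inhibition_score",
        ).reset_index()
        beh = beh.rename(columns={"pre": "inhib_pre", "post": "inhib_post"})
        wide = wide.merge(beh, on=["subject", "group", "task"], how="left")
    return wide
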