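"""Synthetic behavior and EEG for three-group pre/post cohorts.

Generates trial-level responses (truncated lognormal RTs, configurable
error/omission rates) and continuous multi-channel EEG whose frontal
theta and parietal alpha amplitudes encode a latent theta/alpha-ratio
(TAR) target per session, superposed on 1/f background noise with
optional high-amplitude artifact transients.

A full cohort draws each subject's (pre, post) latent TAR from a
bivariate normal with group-specific means/SDs and pre-post correlation
``r``; oscillation amplitudes are set so the analysis pipeline's
expected TAR equals the latent target (band power of an A-amplitude
sinusoid is A²/2, so amplitudes scale with the square root of the
target ratio).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import tasks
from .eegio import EEGRecording, Event, write_recording
from .tasks import Task, TaskDesign, build_design, design_to_frame

__all__ = [
    "TrialResult",
    "RTParams",
    "BehaviorModel",
    "EEGGenParams",
    "StudyConfig",
    "GROUPS",
    "DEFAULT_TAR_PARAMS",
    "DEFAULT_RT_CELLS",
    "simulate_behavior",
    "simulate_eeg",
    "simulate_session",
    "simulate_study",
    "simulate_cohort_scores",
    "trial_results_to_frame",
    "trial_results_from_frame",
    "standard_montage",
    "compact_montage",
]

GROUPS = ("A", "B", "C")  # simulator / attention / control

#: response alternatives per task
RESPONSE_SETS = {
    Task.STROOP: ("red", "green", "yellow", "blue"),
    Task.NEGATIVE_PRIMING: ("vowel", "consonant"),
    Task.FLANKER: ("left", "right"),
}


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated/observed trial."""

    trial_id: int
    task: Task
    block_index: int
    trial_index: int
    condition: str
    onset: float  # stimulus onset, seconds from recording start
    response: str | None  # None = omission
    rt: float  # seconds; NaN for omissions
    correct: bool


@dataclass(frozen=True)
class RTParams:
    """Lognormal RT distribution (moment-matched to mean/sd, seconds)."""

    mean: float
    sd: float
    error_prob: float = 0.03
    omission_prob: float = 0.005

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("RT mean and sd must be positive")
        for p in (self.error_prob, self.omission_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def lognormal_params(self) -> tuple[float, float]:
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


class BehaviorConfigError(KeyError):
    """A (task, condition) cell is missing from the behavior model."""


# per-(task, condition) T1 RT means (s); SDs from the descriptive table
_DEFAULT_CELLS = {
    (Task.STROOP, "congruent"): RTParams(0.905, 0.130),
    (Task.STROOP, "incongruent"): RTParams(1.078, 0.200),
    (Task.NEGATIVE_PRIMING, "control"): RTParams(0.671, 0.080),
    (Task.NEGATIVE_PRIMING, "np"): RTParams(0.688, 0.080),
    (Task.FLANKER, "compatible"): RTParams(0.622, 0.100),
    (Task.FLANKER, "incompatible"): RTParams(0.835, 0.250),
}


@dataclass(frozen=True)
class BehaviorModel:
    """Per-(task, condition) response model."""

    cells: dict = field(default_factory=lambda: dict(_DEFAULT_CELLS))

    def params(self, task: Task, condition: str) -> RTParams:
        try:
            return self.cells[(task, condition)]
        except KeyError:
            raise BehaviorConfigError(
                f"no RT/error parameters configured for task={task.value!r}, "
                f"condition={condition!r}"
            ) from None


def simulate_behavior(
    design: TaskDesign, model: BehaviorModel, seed: int
) -> list[TrialResult]:
    """One :class:`TrialResult` per trial of ``design``.

    RTs are lognormal truncated at the trial's response deadline (by
    resampling); errors press a wrong button, omissions give no response
    and count as errors.  Onsets accumulate fixation + stimulus
    intervals, so trials are strictly ordered in time.
    """
    rng = np.random.default_rng(seed)
    # validate coverage up front so failures name the condition
    for block in design.blocks:
        for t in block.trials:
            model.params(design.task, t.condition)

    responses = RESPONSE_SETS[design.task]
    results = []
    clock = 2.0  # lead-in so the pre-stimulus epoch window fits
    trial_id = 0
    for block in design.blocks:
        for t in block.trials:
            p = model.params(design.task, t.condition)
            mu, sigma = p.lognormal_params()
            rt = float(rng.lognormal(mu, sigma))
            while rt >= t.max_presentation:
                rt = float(rng.lognormal(mu, sigma))
            clock += t.fixation_duration
            onset = clock
            omitted = rng.random() < p.omission_prob
            if omitted:
                response, rt, correct = None, float("nan"), False
            elif rng.random() < p.error_prob:
                wrong = [r for r in responses if r != t.correct_response]
                response = wrong[rng.integers(len(wrong))]
                correct = False
            else:
                response, correct = t.correct_response, True
            if design.task is Task.NEGATIVE_PRIMING:
                # fixed presentation: 0.5 s stimulus + post-stimulus blank
                clock = onset + t.max_presentation
            else:
                clock = onset + (t.max_presentation if omitted else rt)
            results.append(
                TrialResult(
                    trial_id=trial_id,
                    task=design.task,
                    block_index=t.block_index,
                    trial_index=t.trial_index,
                    condition=t.condition,
                    onset=onset,
                    response=response,
                    rt=rt,
                    correct=correct,
                )
            )
            trial_id += 1
    return results


# --- EEG generation --------------------------------------------------------


def standard_montage() -> list[str]:
    """64 EEG labels (10-20/10-10 names, incl. Fz and Pz) + 2 eye channels."""
    eeg = [
        "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8", "F7", "F5", "F3", "F1",
        "Fz", "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCz",
        "FC2", "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "Cz", "C2",
        "C4", "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4",
        "CP6", "TP8", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
        "P8", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "P9",
        "P10", "TP9", "TP10", "Iz",
    ]
    return eeg + ["HEOG", "VEOG"]


def compact_montage() -> list[str]:
    """Reduced montage for fast simulation; keeps the analysis channels."""
    return ["Fz", "Cz", "Pz", "Oz", "HEOG", "VEOG"]


EYE_CHANNELS = ("HEOG", "VEOG")


@dataclass(frozen=True)
class EEGGenParams:
    """Generator settings for one recording session."""

    sampling_rate: float = 500.0
    channel_labels: tuple[str, ...] = tuple(standard_montage())
    noise_amplitude: float = 3.0  # µV RMS of the 1/f background
    noise_exponent: float = 1.0
    theta_freq: float = 6.0
    alpha_freq: float = 10.0
    theta_amp_fz: float = 10.0  # µV
    alpha_amp_pz: float = 10.0  # µV
    artifact_prob: float = 0.05
    artifact_amplitude: float = 300.0  # µV
    artifact_duration: float = 0.5  # s

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 30.0:
            raise ValueError("sampling_rate must exceed twice the analysis band")
        for label in ("Fz", "Pz"):
            if label not in self.channel_labels:
                raise ValueError(f"montage must include {label}")
        if min(self.theta_amp_fz, self.alpha_amp_pz, self.noise_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.artifact_prob <= 1:
            raise ValueError("artifact_prob must lie in [0, 1]")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_eeg(
    trials: list[TrialResult], params: EEGGenParams, seed: int
) -> EEGRecording:
    """Continuous recording spanning all trials, with stimulus markers.

    Fz carries a theta oscillation and Pz an alpha oscillation at the
    configured amplitudes for the whole session; every channel gets 1/f
    noise (eye channels noise only).  With probability
    ``artifact_prob`` a trial receives a high-amplitude transient inside
    its analysis window on all EEG channels.
    """
    if params.sampling_rate < 64:
        raise ValueError("sampling rate below 64 Hz cannot represent the alpha band")
    if not trials:
        raise ValueError("no trials to simulate")
    onsets = [t.onset for t in trials]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("trials must be strictly ordered in time")

    rate = params.sampling_rate
    duration = onsets[-1] + 4.0  # post-stimulus window + padding
    n = int(np.ceil(duration * rate))
    labels = list(params.channel_labels)
    rng = np.random.default_rng(seed)

    data = np.empty((len(labels), n))
    for i in range(len(labels)):
        data[i] = (
            params.noise_amplitude * _pink_noise(rng, n, params.noise_exponent)
            if params.noise_amplitude > 0
            else 0.0
        )

    t = np.arange(n) / rate
    fz = labels.index("Fz")
    pz = labels.index("Pz")
    data[fz] += params.theta_amp_fz * np.sin(
        2 * np.pi * params.theta_freq * t + rng.uniform(0, 2 * np.pi)
    )
    data[pz] += params.alpha_amp_pz * np.sin(
        2 * np.pi * params.alpha_freq * t + rng.uniform(0, 2 * np.pi)
    )

    eeg_rows = [i for i, lab in enumerate(labels) if lab not in EYE_CHANNELS]
    n_art = int(round(params.artifact_duration * rate))
    bump = np.hanning(max(n_art, 2))
    events = []
    for trial in trials:
        sample = int(round(trial.onset * rate))
        events.append(Event(sample=sample, trial_id=trial.trial_id, code=1))
        if params.artifact_prob > 0 and rng.random() < params.artifact_prob:
            # place the transient inside the [-0.5, +1.5] s analysis window
            offset = rng.uniform(-0.3, 1.5 - params.artifact_duration)
            start = sample + int(round(offset * rate))
            stop = min(start + n_art, n)
            if stop > start:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                data[np.ix_(eeg_rows, range(start, stop))] += (
                    sign * params.artifact_amplitude * bump[: stop - start]
                )
    return EEGRecording(labels, rate, data, events)


# --- study-level simulation ------------------------------------------------

# group x task x phase TAR population (mean, sd) of the descriptive table
DEFAULT_TAR_PARAMS = {
    "A": {
        Task.STROOP: {"pre": (2.06, 1.41), "post": (1.34, 0.67)},
        Task.NEGATIVE_PRIMING: {"pre": (2.01, 1.23), "post": (1.27, 0.57)},
        Task.FLANKER: {"pre": (1.96, 1.03), "post": (1.14, 0.80)},
    },
    "B": {
        Task.STROOP: {"pre": (2.03, 1.65), "post": (2.06, 1.52)},
        Task.NEGATIVE_PRIMING: {"pre": (1.61, 1.28), "post": (1.44, 0.70)},
        Task.FLANKER: {"pre": (1.36, 0.84), "post": (1.31, 0.86)},
    },
    "C": {
        Task.STROOP: {"pre": (1.41, 0.73), "post": (1.40, 0.98)},
        Task.NEGATIVE_PRIMING: {"pre": (1.57, 1.71), "post": (1.58, 1.00)},
        Task.FLANKER: {"pre": (1.43, 1.28), "post": (1.43, 1.00)},
    },
}

# group x task x condition x phase RT cell means/SDs (s) of the same table
DEFAULT_RT_CELLS = {
    "A": {
        (Task.STROOP, "congruent"): {"pre": (0.899, 0.130), "post": (0.853, 0.147)},
        (Task.STROOP, "incongruent"): {"pre": (1.060, 0.193), "post": (0.969, 0.184)},
        (Task.NEGATIVE_PRIMING, "control"): {"pre": (0.660, 0.077), "post": (0.648, 0.094)},
        (Task.NEGATIVE_PRIMING, "np"): {"pre": (0.675, 0.080), "post": (0.668, 0.089)},
        (Task.FLANKER, "compatible"): {"pre": (0.626, 0.130), "post": (0.586, 0.112)},
        (Task.FLANKER, "incompatible"): {"pre": (0.825, 0.280), "post": (0.722, 0.190)},
    },
    "B": {
        (Task.STROOP, "congruent"): {"pre": (0.926, 0.124), "post": (0.850, 0.131)},
        (Task.STROOP, "incongruent"): {"pre": (1.101, 0.199), "post": (0.995, 0.179)},
        (Task.NEGATIVE_PRIMING, "control"): {"pre": (0.664, 0.052), "post": (0.651, 0.076)},
        (Task.NEGATIVE_PRIMING, "np"): {"pre": (0.683, 0.055), "post": (0.668, 0.079)},
        (Task.FLANKER, "compatible"): {"pre": (0.612, 0.090), "post": (0.593, 0.104)},
        (Task.FLANKER, "incompatible"): {"pre": (0.834, 0.264), "post": (0.751, 0.230)},
    },
    "C": {
        (Task.STROOP, "congruent"): {"pre": (0.893, 0.130), "post": (0.864, 0.118)},
        (Task.STROOP, "incongruent"): {"pre": (1.079, 0.203), "post": (1.028, 0.172)},
        (Task.NEGATIVE_PRIMING, "control"): {"pre": (0.696, 0.106), "post": (0.681, 0.089)},
        (Task.NEGATIVE_PRIMING, "np"): {"pre": (0.710, 0.090), "post": (0.698, 0.083)},
        (Task.FLANKER, "compatible"): {"pre": (0.623, 0.067), "post": (0.591, 0.066)},
        (Task.FLANKER, "incompatible"): {"pre": (0.849, 0.222), "post": (0.737, 0.106)},
    },
}


@dataclass(frozen=True)
class StudyConfig:
    """Three-group pre/post study generator settings."""

    group_sizes: dict = field(default_factory=lambda: {"A": 30, "B": 23, "C": 23})
    tasks: tuple[Task, ...] = (Task.STROOP, Task.NEGATIVE_PRIMING, Task.FLANKER)
    tar_params: dict = field(default_factory=lambda: DEFAULT_TAR_PARAMS)
    rt_cells: dict = field(default_factory=lambda: DEFAULT_RT_CELLS)
    pre_post_r: float = 0.7
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    eeg: EEGGenParams = field(default_factory=EEGGenParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for g, size in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if size < 2:
                raise ValueError(f"group {g} needs at least 2 subjects")
        if not -1 < self.pre_post_r < 1:
            raise ValueError("pre_post_r must lie in (-1, 1)")
        for g in self.group_sizes:
            for task in self.tasks:
                for phase in ("pre", "post"):
                    mean, sd = self.tar_params[g][task][phase]
                    if sd <= 0:
                        raise ValueError(f"TAR SD must be positive ({g}/{task.value}/{phase})")


def _subject_seed(master_seed: int, subject: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, subject])


def _draw_latent_pair(
    rng: np.random.Generator,
    pre: tuple[float, float],
    post: tuple[float, float],
    r: float,
    floor: float = 0.05,
) -> tuple[float, float]:
    """Bivariate-normal (pre, post) draw, resampled until both positive."""
    m = np.array([pre[0], post[0]])
    cov = np.array(
        [
            [pre[1] ** 2, r * pre[1] * post[1]],
            [r * pre[1] * post[1], post[1] ** 2],
        ]
    )
    for _ in range(1000):
        x = rng.multivariate_normal(m, cov)
        if x.min() > floor:
            return float(x[0]), float(x[1])
    raise RuntimeError("could not draw a positive latent TAR pair")


def amplitudes_for_target(
    tar_target: float, base_alpha_amp: float
) -> tuple[float, float]:
    """(theta_amp_fz, alpha_amp_pz) whose expected pipeline TAR is the target."""
    if tar_target <= 0:
        raise ValueError(f"infeasible TAR target {tar_target}: must be positive")
    return base_alpha_amp * float(np.sqrt(tar_target)), base_alpha_amp


def simulate_session(
    task: Task,
    phase: str,
    tar_target: float,
    config: StudyConfig,
    seed: np.random.SeedSequence | int,
    behavior: BehaviorModel | None = None,
) -> tuple[list[TrialResult], EEGRecording]:
    """One subject x phase x task session: trial results + EEG recording."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_design, s_behav, s_eeg = ss.spawn(3)
    start_pre, start_post = tasks.START_BLOCKS[task]
    start = start_pre if phase == "pre" else start_post
    design = build_design(task, int(s_design.generate_state(1)[0]), start)
    trials = simulate_behavior(
        design, behavior or config.behavior, int(s_behav.generate_state(1)[0])
    )
    theta_amp, alpha_amp = amplitudes_for_target(tar_target, config.eeg.alpha_amp_pz)
    params = replace(config.eeg, theta_amp_fz=theta_amp, alpha_amp_pz=alpha_amp)
    rec = simulate_eeg(trials, params, int(s_eeg.generate_state(1)[0]))
    return trials, rec


def _behavior_model_for(config: StudyConfig, group: str, phase: str) -> BehaviorModel:
    cells = {}
    for (task, cond), phases in config.rt_cells[group].items():
        mean, sd = phases[phase]
        base = config.behavior.cells.get((task, cond))
        cells[(task, cond)] = RTParams(
            mean,
            sd,
            error_prob=base.error_prob if base else 0.03,
            omission_prob=base.omission_prob if base else 0.005,
        )
    return BehaviorModel(cells)


def _subject_table(config: StudyConfig) -> list[tuple[int, str]]:
    table = []
    sid = 1
    for g in GROUPS:
        for _ in range(config.group_sizes.get(g, 0)):
            table.append((sid, g))
            sid += 1
    return table


def simulate_cohort_scores(config: StudyConfig, seed: int | None = None) -> pd.DataFrame:
    """Fast latent-score cohort: per subject x task TAR and inhibition scores.

    Draws the same latent (pre, post) TAR pairs the full EEG pipeline
    encodes, plus per-condition RT means from the configured cells, and
    returns a tidy frame with columns ``subject, group, task, tar_pre,
    tar_post, inhib_pre, inhib_post``.  Used for statistics-scale
    simulation where synthesizing continuous EEG would be prohibitive;
    the EEG route is validated separately by latent-target recovery.
    """
    master = config.master_seed if seed is None else seed
    rows = []
    for sid, group in _subject_table(config):
        rng = np.random.default_rng(_subject_seed(master, sid))
        for task in config.tasks:
            p = config.tar_params[group][task]
            tar_pre, tar_post = _draw_latent_pair(
                rng, p["pre"], p["post"], config.pre_post_r
            )
            inhib_cond, neutral_cond = tasks.CONDITIONS[task]
            inhib = {}
            for phase in ("pre", "post"):
                vals = {}
                for cond in (inhib_cond, neutral_cond):
                    mean, sd = config.rt_cells[group][(task, cond)][phase]
                    vals[cond] = mean
                inhib[phase] = vals
            # subject-level deviations shared pre/post with correlation r
            z_pre = rng.standard_normal()
            z_post = config.pre_post_r * z_pre + np.sqrt(
                1 - config.pre_post_r**2
            ) * rng.standard_normal()
            sd_pre = config.rt_cells[group][(task, inhib_cond)]["pre"][1] * 0.5
            sd_post = config.rt_cells[group][(task, inhib_cond)]["post"][1] * 0.5
            inhib_pre = (
                inhib["pre"][inhib_cond] - inhib["pre"][neutral_cond] + sd_pre * z_pre
            )
            inhib_post = (
                inhib["post"][inhib_cond]
                - inhib["post"][neutral_cond]
                + sd_post * z_post
            )
            rows.append(
                (sid, group, task.value, tar_pre, tar_post, inhib_pre, inhib_post)
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "task", "tar_pre", "tar_post", "inhib_pre", "inhib_post"],
    )


_RESULT_COLUMNS = [
    "trial_id",
    "task",
    "block_index",
    "trial_index",
    "condition",
    "onset",
    "response",
    "rt",
    "correct",
]


def trial_results_to_frame(results: list[TrialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.trial_id,
                r.task.value,
                r.block_index,
                r.trial_index,
                r.condition,
                r.onset,
                "" if r.response is None else r.response,
                r.rt,
                r.correct,
            )
            for r in results
        ],
        columns=_RESULT_COLUMNS,
    )


def trial_results_from_frame(frame: pd.DataFrame) -> list[TrialResult]:
    results = []
    for r in frame.itertuples():
        response = None if (pd.isna(r.response) or r.response == "") else str(r.response)
        results.append(
            TrialResult(
                trial_id=int(r.trial_id),
                task=Task(r.task),
                block_index=int(r.block_index),
                trial_index=int(r.trial_index),
                condition=str(r.condition),
                onset=float(r.onset),
                response=response,
                rt=float(r.rt),
                correct=bool(r.correct),
            )
        )
    return results


def simulate_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Write a full cohort to ``outdir`` and return its manifest.

    Layout: ``subject-XX/phase-{pre,post}/task-<task>/`` with
    ``trials.csv`` and the native EEG container ``eeg.{dat,json,events.csv}``;
    ``manifest.json`` records group labels, latent targets and seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "master_seed": config.master_seed,
        "pre_post_r": config.pre_post_r,
        "tasks": [t.value for t in config.tasks],
        "subjects": [],
    }
    for sid, group in _subject_table(config):
        ss = _subject_seed(config.master_seed, sid)
        rng = np.random.default_rng(ss)
        entry = {"subject": sid, "group": group, "sessions": []}
        session_seeds = ss.spawn(len(config.tasks) * 2)
        k = 0
        for task in config.tasks:
            p = config.tar_params[group][task]
            tar_pre, tar_post = _draw_latent_pair(rng, p["pre"], p["post"], config.pre_post_r)
            for phase, target in (("pre", tar_pre), ("post", tar_post)):
                sess_dir = (
                    outdir
                    / f"subject-{sid:02d}"
                    / f"phase-{phase}"
                    / f"task-{task.value}"
                )
                sess_dir.mkdir(parents=True, exist_ok=True)
                behavior = _behavior_model_for(config, group, phase)
                trials, rec = simulate_session(
                    task, phase, target, config, session_seeds[k], behavior
                )
                k += 1
                trial_results_to_frame(trials).to_csv(
                    sess_dir / "trials.csv", index=False
                )
                write_recording(rec, sess_dir / "eeg")
                entry["sessions"].append(
                    {
                        "phase": phase,
                        "task": task.value,
                        "tar_target": target,
                        "path": str(sess_dir.relative_to(outdir)),
                    }
                )
        manifest["subjects"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
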