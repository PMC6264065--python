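"""Randomized session/experiment schedules.

A session is a 5-s spoken introduction followed by 16 consecutive 6-s
trials: trial 1 is a silent no-sound control, trials 2-6 present a
1000 Hz tone, trials 7-11 a 2000 Hz tone and trials 12-16 a 4000 Hz
tone, each block covering the five target intensities {30, 40, 50, 60,
70} dBA exactly once in random order.  Inter-trial intervals are drawn
uniformly from [2, 5] s.  An experiment repeats the session eight
times; session seeds are derived as master_seed + session index so a
whole experiment is reproducible from one integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

FREQUENCIES_HZ = (1000.0, 2000.0, 4000.0)
INTENSITIES_DBA = (30.0, 40.0, 50.0, 60.0, 70.0)
TRIAL_DURATION_S = 6.0
INTRO_DURATION_S = 5.0
N_TRIALS = 16
N_SESSIONS = 8
ITI_RANGE_S = (2.0, 5.0)


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int  # 1-based position within the session
    frequency: float | None
    intensity: float | None
    is_no_sound: bool = False
    duration: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        if self.is_no_sound != (self.frequency is None and self.intensity is None):
            raise ValueError("no-sound trials have no frequency/intensity and vice versa")
        if not self.is_no_sound:
            if self.frequency not in FREQUENCIES_HZ:
                raise ValueError(f"frequency {self.frequency} not in {FREQUENCIES_HZ}")
            if self.intensity not in INTENSITIES_DBA:
                raise ValueError(f"intensity {self.intensity} not in {INTENSITIES_DBA}")


@dataclass(frozen=True)
class SessionSpec:
    trials: tuple[TrialSpec, ...]
    inter_trial_intervals: tuple[float, ...]  # 15 durations in [2, 5] s
    intro_duration: float = INTRO_DURATION_S
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"a session has {N_TRIALS} trials")
        if not self.trials[0].is_no_sound:
            raise ValueError("trial 1 must be the no-sound control")
        if len(self.inter_trial_intervals) != N_TRIALS - 1:
            raise ValueError("need one inter-trial interval per trial gap")
        lo, hi = ITI_RANGE_S
        if any(not lo <= iti <= hi for iti in self.inter_trial_intervals):
            raise ValueError(f"inter-trial intervals must lie in [{lo}, {hi}] s")

    @property
    def duration(self) -> float:
        return (
            self.intro_duration
            + sum(t.duration for t in self.trials)
            + sum(self.inter_trial_intervals)
        )


@dataclass(frozen=True)
class ExperimentSpec:
    sessions: tuple[SessionSpec, ...]
    master_seed: int

    def __post_init__(self) -> None:
        if len(self.sessions) != N_SESSIONS:
            raise ValueError(f"an experiment has {N_SESSIONS} sessions")


def build_session(seed: int) -> SessionSpec:
    """Build one randomized 16-trial session, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    trials = [TrialSpec(1, None, None, is_no_sound=True)]
    idx = 2
    for freq in FREQUENCIES_HZ:
        for dba in rng.permutation(INTENSITIES_DBA):
            trials.append(TrialSpec(idx, freq, float(dba)))
            idx += 1
    itis = tuple(rng.uniform(*ITI_RANGE_S, size=N_TRIALS - 1).tolist())
    return SessionSpec(tuple(trials), itis, seed=seed)


def build_experiment(master_seed: int) -> ExperimentSpec:
    """Build the 8-session experiment; session i uses seed master_seed + i."""
    sessions = tuple(build_session(master_seed + i) for i in range(1, N_SESSIONS + 1))
    return ExperimentSpec(sessions, master_seed)


def schedule_events(experiment: ExperimentSpec) -> pd.DataFrame:
    """Per-trial onset table (one clock per session, starting at 0).

    Columns: session, trial, onset_s, frequency_Hz, intensity_dBA,
    is_no_sound.  Onsets accumulate the 5-s introduction, 6-s trials and
    the random inter-trial intervals.
    """
    rows = []
    for s_idx, session in enumerate(experiment.sessions, start=1):
        t = session.intro_duration
        for trial in session.trials:
            rows.append(
                {
                    "session": s_idx,
                    "trial": trial.trial_index,
                    "onset_s": t,
                    "frequency_Hz": trial.frequency,
                    "intensity_dBA": trial.intensity,
                    "is_no_sound": trial.is_no_sound,
                }
            )
            t += trial.duration
            if trial.trial_index < N_TRIALS:
                t += session.inter_trial_intervals[trial.trial_index - 1]
    return pd.DataFrame(rows)


def experiment_to_json(experiment: ExperimentSpec, path=None) -> str:
    """Serialize an experiment schedule to JSON (deterministic layout)."""
    payload = {
        "master_seed": experiment.master_seed,
        "sessions": [
            {
                "seed": s.seed,
                "intro_duration": s.intro_duration,
                "inter_trial_intervals": list(s.inter_trial_intervals),
                "trials": [asdict(t) for t in s.trials],
            }
            for s in experiment.sessions
        ],
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def experiment_from_json(source) -> ExperimentSpec:
    """Inverse of :func:`experiment_to_json` (path or JSON string)."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(text) as fh:
                payload = json.load(fh)
    sessions = tuple(
        SessionSpec(
            tuple(TrialSpec(**t) for t in s["trials"]),
            tuple(s["inter_trial_intervals"]),
            intro_duration=s["intro_duration"],
            seed=s["seed"],
        )
        for s in payload["sessions"]
    )
    return ExperimentSpec(sessions, payload["master_seed"])
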