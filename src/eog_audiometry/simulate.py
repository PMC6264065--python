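"""Synthetic listener: EOG simulation and staircase audiometry.

The simulator generates two-channel EOG recordings with the structure
the analysis assumes.  When a trial's sensation level SL = intensity -
true_threshold(frequency) is positive, the auditory oculogyric reflex
is modelled as a horizontal gaze oscillation phase-locked to the 1/3 Hz
source sweep:

    h(t) = gain * logistic(slope * SL) * sin(2*pi*t/3 + phi),

with per-trial phase jitter phi ~ Normal(0, reflex_phase_jitter).  The
logistic dose-response is a pragmatic monotone saturating law; nothing
downstream depends on its exact shape.  Inaudible and no-sound trials
carry no reflex component.  All trials additionally receive a slow
baseline drift with uniformly random phase, independent white sensor
noise per electrode, a common-mode component and per-electrode DC
offsets; the latter two cancel under bipolar derivation and DC removal
respectively, exercising those pipeline stages.

The companion staircase simulates conventional pure-tone audiometry
with the modified Hughson-Westlake procedure (down 10 dB after a
response, up 5 dB after a miss; threshold = lowest level answered on at
least 2 of 3 ascending presentations, on a 5-dB grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .features import Audiogram
from .pipeline import RawRecording, RAW_RATE_HZ
from .protocol import ExperimentSpec, SessionSpec, TrialSpec, schedule_events

DEFAULT_THRESHOLDS = {1000.0: 40.0, 2000.0: 40.0, 4000.0: 40.0}


@dataclass(frozen=True)
class SimulatedListener:
    """Ground-truth hearing and oculomotor response parameters.

    true_thresholds
        dBA per frequency; defaults to 40 dBA at 1, 2 and 4 kHz, the
        mid-grid elevation produced by noise-reduction earplugs over
        normal hearing.
    oculomotor_gain
        Peak horizontal EOG deflection (µV) of the reflex at high
        sensation level.
    psychometric_slope
        dB^-1 growth rate of the logistic reflex dose-response.
    reflex_phase_jitter
        SD (radians) of the per-trial phase offset between sweep and
        gaze oscillation.
    noise_sd
        White sensor noise SD (µV) per electrode.
    drift_amplitude / drift_frequency
        Slow baseline wander of the horizontal component (µV, Hz).
    common_mode_amplitude
        Amplitude (µV) of a slow component added identically to both
        electrodes (cancels in the bipolar derivation).
    dc_offset_sd
        SD (µV) of constant per-electrode offsets.
    """

    true_thresholds: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    oculomotor_gain: float = 40.0
    psychometric_slope: float = 0.1
    reflex_phase_jitter: float = 0.3
    noise_sd: float = 10.0
    drift_amplitude: float = 10.0
    drift_frequency: float = 0.05
    common_mode_amplitude: float = 30.0
    dc_offset_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.oculomotor_gain < 0 or self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("gain, noise_sd and drift_amplitude must be non-negative")
        for f, thr in self.true_thresholds.items():
            if not 0 <= thr <= 120:
                raise ValueError(f"threshold {thr} dBA at {f} Hz outside [0, 120]")

    def sensation_level(self, trial: TrialSpec) -> float | None:
        if trial.is_no_sound:
            return None
        return trial.intensity - self.true_thresholds[trial.frequency]

    def reflex_amplitude(self, sensation_level: float) -> float:
        """Reflex µV at a given SL (0 at or below threshold)."""
        if sensation_level <= 0:
            return 0.0
        return self.oculomotor_gain * float(expit(self.psychometric_slope * sensation_level))

    @property
    def audiogram(self) -> Audiogram:
        return Audiogram(dict(self.true_thresholds))


@dataclass
class SimulatedDataset:
    """Per-session raw recordings plus ground truth, one experiment."""

    recordings: list[RawRecording]
    trial_refs: list[list[tuple[int, int]]]  # per session, per event
    audiogram: Audiogram
    experiment: ExperimentSpec
    master_seed: int


def _trial_components(
    trial: TrialSpec,
    listener: SimulatedListener,
    rng: np.random.Generator,
    t: np.ndarray,
    sweep_frequency: float,
) -> np.ndarray:
    """Horizontal (left-minus-right) component of one trial, µV."""
    phi_reflex = rng.normal(0.0, listener.reflex_phase_jitter)
    phi_drift = rng.uniform(0.0, 2 * np.pi)
    sl = listener.sensation_level(trial)
    h = listener.drift_amplitude * np.sin(
        2 * np.pi * listener.drift_frequency * t + phi_drift
    )
    if sl is not None and sl > 0:
        amp = listener.reflex_amplitude(sl)
        h = h + amp * np.sin(2 * np.pi * sweep_frequency * t + phi_reflex)
    return h


def simulate_trial_eog(
    trial: TrialSpec,
    listener: SimulatedListener,
    seed,
    sample_rate: float = RAW_RATE_HZ,
    sweep_frequency: float = 1.0 / 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two raw channels (left_eog, right_eog) for one 6-s trial, µV."""
    rng = np.random.default_rng(seed)
    n = round(trial.duration * sample_rate)
    t = np.arange(n) / sample_rate
    h = _trial_components(trial, listener, rng, t, sweep_frequency)
    common = listener.common_mode_amplitude * np.sin(
        2 * np.pi * 0.1 * t + rng.uniform(0.0, 2 * np.pi)
    )
    dc_l, dc_r = rng.normal(0.0, listener.dc_offset_sd, size=2)
    noise_l = rng.normal(0.0, listener.noise_sd, size=n) if listener.noise_sd else 0.0
    noise_r = rng.normal(0.0, listener.noise_sd, size=n) if listener.noise_sd else 0.0
    left = h / 2 + common + dc_l + noise_l
    right = -h / 2 + common + dc_r + noise_r
    return left, right


def simulate_session(
    session: SessionSpec,
    session_index: int,
    listener: SimulatedListener,
    rng: np.random.Generator,
    sample_rate: float = RAW_RATE_HZ,
    sweep_frequency: float = 1.0 / 3.0,
) -> tuple[RawRecording, list[tuple[int, int]]]:
    """Continuous recording for one session with trigger events."""
    total = session.duration + 1.0  # 1 s tail so the last epoch fits comfortably
    n = round(total * sample_rate)
    t_all = np.arange(n) / sample_rate
    # session-wide background: common mode, noise, DC offsets, drift
    common = listener.common_mode_amplitude * np.sin(
        2 * np.pi * 0.1 * t_all + rng.uniform(0.0, 2 * np.pi)
    )
    dc_l, dc_r = rng.normal(0.0, listener.dc_offset_sd, size=2)
    drift = listener.drift_amplitude * np.sin(
        2 * np.pi * listener.drift_frequency * t_all + rng.uniform(0.0, 2 * np.pi)
    )
    h = drift.copy()
    events: list[tuple[int, str]] = []
    refs: list[tuple[int, int]] = []
    onset_t = session.intro_duration
    for trial in session.trials:
        onset = round(onset_t * sample_rate)
        n_trial = round(trial.duration * sample_rate)
        sl = listener.sensation_level(trial)
        phi = rng.normal(0.0, listener.reflex_phase_jitter)
        if sl is not None and sl > 0:
            amp = listener.reflex_amplitude(sl)
            tt = np.arange(n_trial) / sample_rate
            h[onset : onset + n_trial] += amp * np.sin(
                2 * np.pi * sweep_frequency * tt + phi
            )
        events.append((onset, f"s{session_index}t{trial.trial_index}"))
        refs.append((session_index, trial.trial_index))
        onset_t += trial.duration
        if trial.trial_index < len(session.trials):
            onset_t += session.inter_trial_intervals[trial.trial_index - 1]
    noise_l = rng.normal(0.0, listener.noise_sd, size=n) if listener.noise_sd else 0.0
    noise_r = rng.normal(0.0, listener.noise_sd, size=n) if listener.noise_sd else 0.0
    left = h / 2 + common + dc_l + noise_l
    right = -h / 2 + common + dc_r + noise_r
    return RawRecording(left, right, sample_rate, events), refs


def simulate_experiment(
    listener: SimulatedListener,
    experiment: ExperimentSpec,
    master_seed: int,
    sample_rate: float = RAW_RATE_HZ,
) -> SimulatedDataset:
    """Simulate all sessions of an experiment, deterministic from seed."""
    seq = np.random.SeedSequence(master_seed)
    children = seq.spawn(len(experiment.sessions))
    recordings, refs = [], []
    for i, (session, child) in enumerate(zip(experiment.sessions, children), start=1):
        rec, r = simulate_session(
            session, i, listener, np.random.default_rng(child), sample_rate
        )
        recordings.append(rec)
        refs.append(r)
    return SimulatedDataset(recordings, refs, listener.audiogram, experiment, master_seed)


def hughson_westlake_threshold(
    listener: SimulatedListener,
    frequency: float,
    seed=None,
    start_level: float = 60.0,
    step_up: float = 5.0,
    step_down: float = 10.0,
    floor: float = 0.0,
    ceiling: float = 100.0,
    response_slope: float | None = None,
    max_presentations: int = 200,
) -> float:
    """Simulated modified Hughson-Westlake pure-tone threshold (dBA).

    Responses are deterministic (heard iff level >= true threshold)
    unless ``response_slope`` is given, in which case the probability of
    a response is logistic in (level - threshold) with that slope.  The
    procedure descends ``step_down`` after each response and ascends
    ``step_up`` after each miss; the threshold is the lowest level with
    responses on >= 2 of up to 3 ascending presentations.
    """
    if frequency not in listener.true_thresholds:
        raise KeyError(f"no true threshold for {frequency} Hz")
    theta = listener.true_thresholds[frequency]
    rng = np.random.default_rng(seed)

    def respond(level: float) -> bool:
        if response_slope is None:
            return level >= theta
        return rng.random() < expit(response_slope * (level - theta))

    level = start_level
    ascending = False
    asc_hits: dict[float, int] = {}
    asc_tries: dict[float, int] = {}
    floor_hits = 0
    for _ in range(max_presentations):
        heard = respond(level)
        if heard and level == floor and not ascending:
            # cannot descend further; repeated responses at the output floor
            floor_hits += 1
            if floor_hits >= 2:
                return floor
        if ascending:
            asc_tries[level] = asc_tries.get(level, 0) + 1
            if heard:
                asc_hits[level] = asc_hits.get(level, 0) + 1
                if asc_hits[level] >= 2:
                    return level
        if heard:
            level = level - step_down
            ascending = False
            if level < floor:
                level = floor
        else:
            level = level + step_up
            ascending = True
            if level > ceiling:
                raise RuntimeError(
                    f"staircase exceeded ceiling {ceiling} dBA without convergence"
                )
    raise RuntimeError("staircase did not converge within the presentation budget")


def measure_audiogram(
    listener: SimulatedListener, frequencies=None, seed=None, **staircase_kwargs
) -> Audiogram:
    """Run the staircase at each frequency; returns measured PTTs."""
    if frequencies is None:
        frequencies = sorted(listener.true_thresholds)
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(list(frequencies)))
    thresholds = {
        float(f): hughson_westlake_threshold(listener, f, seed=c, **staircase_kwargs)
        for f, c in zip(frequencies, children)
    }
    return Audiogram(thresholds)
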