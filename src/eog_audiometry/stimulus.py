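"""Spatially moving pure-tone stimulus synthesis.

A virtual sound source sweeps 0° -> +90° -> -90° -> 0° in front of the
listener once per ``cycle_period`` (default 3 s, i.e. a 1/3 Hz sweep).
Movement is conveyed purely by interaural intensity differences over
headphones: at 0° azimuth both ears receive the tone 10 dB below the
trial's target intensity, at ±90° the ipsilateral ear receives the full
target intensity and the contralateral ear is silent.  Intermediate
azimuths are interpolated linearly in the dB domain, with the
contralateral ear fading toward a configurable silence floor (a linear
interpolation toward true silence is ill-defined in dB).

The sweep is realised as a stepwise intensity envelope: each 90° quarter
of the trajectory is divided into ``n_subsegments_per_quarter`` equal
sub-segments (six by default, i.e. five interior breakpoints per
quarter) and the per-ear level is held constant within a sub-segment,
with short linear crossfades between steps to avoid audible clicks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "TrajectoryModel",
    "PanningLaw",
    "Calibration",
    "StereoStimulus",
    "SILENT",
    "azimuth_at",
    "per_ear_level",
    "synthesize_trial",
    "amplitude_envelope",
    "envelope_period",
    "envelope_modulation_frequency",
    "write_wav",
    "read_wav",
]

#: Sentinel level (dBA) meaning "channel muted".
SILENT = -math.inf


@dataclass(frozen=True)
class TrajectoryModel:
    """Constant-angular-speed sweep 0° -> +90° -> -90° -> 0°.

    The full cycle traverses 4 x 90° = 360° of arc in ``cycle_period``
    seconds, so the angular speed is 360/cycle_period deg/s (120 deg/s
    for the default 3-s cycle).
    """

    cycle_period: float = 3.0
    extreme_azimuth: float = 90.0
    n_subsegments_per_quarter: int = 6

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be positive")
        if self.n_subsegments_per_quarter < 1:
            raise ValueError("need at least one sub-segment per quarter")


@dataclass(frozen=True)
class PanningLaw:
    """Interaural intensity panning anchored at 0° and ±90°.

    At 0° both ears sit ``front_attenuation_dB`` below ``target_dBA``;
    at ±90° the ipsilateral ear is at ``target_dBA`` and the other ear
    is silent.  ``silence_floor_dB`` (relative to target, negative) is
    the level at which the fading contralateral channel is muted.
    """

    target_dBA: float
    front_attenuation_dB: float = 10.0
    silence_floor_dB: float = -60.0

    def __post_init__(self) -> None:
        if self.silence_floor_dB >= -self.front_attenuation_dB:
            raise ValueError("silence floor must lie below the front level")


@dataclass(frozen=True)
class Calibration:
    """Map a dBA level to digital full-scale amplitude.

    amplitude(L) = ref_amplitude * 10**((L - ref_dBA) / 20); absolute
    playback calibration against a sound-level meter is out of scope, so
    only relative levels are meaningful.
    """

    ref_dBA: float = 70.0
    ref_amplitude: float = 0.5

    def amplitude(self, level_dBA: float) -> float:
        if level_dBA == SILENT:
            return 0.0
        return self.ref_amplitude * 10.0 ** ((level_dBA - self.ref_dBA) / 20.0)


@dataclass
class StereoStimulus:
    """Two-channel waveform for one trial (dimensionless, |x| <= 1)."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    frequency: float | None
    target_dBA: float | None
    duration: float
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")

    @property
    def n_samples(self) -> int:
        return self.left.size

    @property
    def is_silence(self) -> bool:
        return not (np.any(self.left) or np.any(self.right))


def azimuth_at(t, model: TrajectoryModel = TrajectoryModel()):
    """Azimuth (degrees) of the virtual source at time ``t`` seconds.

    Piecewise-linear, constant angular speed: 0 -> +extreme over the
    first quarter cycle, +extreme -> -extreme over the middle half,
    -extreme -> 0 over the last quarter.  Periodic in ``cycle_period``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    period = model.cycle_period
    ext = model.extreme_azimuth
    tm = np.mod(t, period)
    speed = 4.0 * ext / period  # deg/s
    az = np.where(
        tm < period / 4,
        speed * tm,
        np.where(
            tm < 3 * period / 4,
            ext - speed * (tm - period / 4),
            -ext + speed * (tm - 3 * period / 4),
        ),
    )
    return az if az.ndim else float(az)


def per_ear_level(azimuth: float, law: PanningLaw) -> tuple[float, float]:
    """Per-ear levels (left_dBA, right_dBA) at a given azimuth.

    Levels are interpolated linearly in dB between the three anchors
    (0°, ±90°).  The ipsilateral ear rises from target-front_attenuation
    at 0° to target at ±90°; the contralateral ear falls from the same
    front level to ``target + silence_floor_dB`` at ±90°.  A channel at
    or below the floor is reported as :data:`SILENT` (-inf).
    """
    a = float(azimuth)
    ext = 90.0
    if not -ext <= a <= ext:
        raise ValueError(f"azimuth {a} outside [-90, 90]")
    target = law.target_dBA
    front = target - law.front_attenuation_dB
    floor = target + law.silence_floor_dB
    frac = abs(a) / ext
    ipsi = front + frac * (target - front)
    contra = front + frac * (floor - front)
    if contra <= floor:
        contra = SILENT
    if a >= 0:
        left, right = contra, ipsi
    else:
        left, right = ipsi, contra
    if a == 0:
        left = right = front
    return left, right


def _envelope_breakpoints(
    duration: float,
    model: TrajectoryModel,
    law: PanningLaw,
    calibration: Calibration,
    crossfade: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stepwise per-ear amplitude envelopes with linear crossfades.

    Returns (times, left_amp, right_amp) suitable for np.interp.  The
    per-ear level is evaluated at the temporal midpoint of each
    sub-segment; each step transition is a linear ramp of ``crossfade``
    seconds centred on the step boundary.
    """
    step = model.cycle_period / (4 * model.n_subsegments_per_quarter)
    n_steps = int(math.ceil(duration / step))
    starts = np.arange(n_steps) * step
    mids = starts + step / 2
    amps_l = np.empty(n_steps)
    amps_r = np.empty(n_steps)
    for i, tm in enumerate(mids):
        lvl_l, lvl_r = per_ear_level(azimuth_at(tm % model.cycle_period, model), law)
        amps_l[i] = calibration.amplitude(lvl_l)
        amps_r[i] = calibration.amplitude(lvl_r)
    half = min(crossfade, step) / 2
    # breakpoints: hold A_k on [t_k + half, t_{k+1} - half], ramp between
    xp = np.empty(2 * n_steps)
    xp[0::2] = starts + half
    xp[1::2] = starts + step - half
    fp_l = np.repeat(amps_l, 2)
    fp_r = np.repeat(amps_r, 2)
    return xp, fp_l, fp_r


def synthesize_trial(
    frequency: float | None,
    target_dBA: float | None,
    duration: float = 6.0,
    sample_rate: float = 44100.0,
    model: TrajectoryModel | None = None,
    law: PanningLaw | None = None,
    calibration: Calibration | None = None,
    crossfade: float = 0.010,
    edge_ramp: float = 0.020,
) -> StereoStimulus:
    """Synthesize one spatially moving pure-tone trial.

    ``frequency=None`` (or ``target_dBA=None``) produces the silent
    no-sound trial.  The carrier is a phase-continuous sine at
    ``frequency``; each channel is the carrier times its stepwise
    intensity envelope, with raised-cosine onset/offset ramps of
    ``edge_ramp`` seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    model = model or TrajectoryModel()
    calibration = calibration or Calibration()
    n = round(duration * sample_rate)
    if frequency is None or target_dBA is None:
        z = np.zeros(n)
        return StereoStimulus(z, z.copy(), sample_rate, None, None, duration, calibration)
    if frequency >= sample_rate / 2:
        raise ValueError(
            f"frequency {frequency} Hz is at or above Nyquist ({sample_rate / 2} Hz)"
        )
    law = law or PanningLaw(target_dBA=target_dBA)
    peak = calibration.amplitude(law.target_dBA)
    if peak > 1.0:
        raise ValueError(
            f"target level {law.target_dBA} dBA maps to amplitude {peak:.3g} > full scale"
        )
    t = np.arange(n) / sample_rate
    carrier = np.sin(2 * np.pi * frequency * t)
    xp, fp_l, fp_r = _envelope_breakpoints(duration, model, law, calibration, crossfade)
    env_l = np.interp(t, xp, fp_l)
    env_r = np.interp(t, xp, fp_r)
    ramp = _edge_ramp(n, sample_rate, edge_ramp)
    left = carrier * env_l * ramp
    right = carrier * env_r * ramp
    return StereoStimulus(
        left, right, sample_rate, frequency, target_dBA, duration, calibration
    )


def _edge_ramp(n: int, sample_rate: float, edge_ramp: float) -> np.ndarray:
    ramp = np.ones(n)
    k = min(round(edge_ramp * sample_rate), n // 2)
    if k > 0:
        w = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        ramp[:k] = w
        ramp[-k:] = w[::-1]
    return ramp


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude envelope via the analytic signal."""
    from scipy.signal import hilbert

    return np.abs(hilbert(np.asarray(x, dtype=float)))


def envelope_period(
    x: np.ndarray,
    sample_rate: float,
    min_period: float = 1.0,
    max_period: float = 4.5,
) -> float:
    """Repetition period (s) of a channel's intensity envelope.

    Autocorrelates the mean-removed amplitude envelope (unbiased
    normalization) and returns the lag of the largest peak within
    [min_period, max_period] — for a 6-s trial with two panning cycles
    this recovers the 3-s cycle duration.
    """
    from scipy.signal import correlate

    env = amplitude_envelope(x)
    env = env - env.mean()
    n = env.size
    ac = correlate(env, env, mode="full", method="fft")[n - 1 :]
    lags = np.arange(n)
    with np.errstate(invalid="ignore"):
        ac = ac / (n - lags)  # unbiased
    lo = max(1, round(min_period * sample_rate))
    hi = min(n - 1, round(max_period * sample_rate))
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    return k / sample_rate


def envelope_modulation_frequency(x: np.ndarray, sample_rate: float) -> float:
    """Dominant frequency (Hz) of the intensity envelope via FFT peak."""
    env = amplitude_envelope(x)
    env = env - env.mean()
    spectrum = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(env.size, 1.0 / sample_rate)
    spectrum[0] = 0.0
    return float(freqs[np.argmax(spectrum)])


def write_wav(stimulus: StereoStimulus, path, bit_depth: str = "int16") -> None:
    """Write a stereo WAV file (``bit_depth``: 'int16' or 'float32')."""
    data = np.column_stack([stimulus.left, stimulus.right])
    if np.max(np.abs(data), initial=0.0) > 1.0:
        raise ValueError("stimulus exceeds full scale; refusing to clip")
    if bit_depth == "int16":
        data = np.round(data * 32767.0).astype(np.int16)
    elif bit_depth == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported bit depth {bit_depth!r}")
    wavfile.write(path, int(stimulus.sample_rate), data)


def read_wav(path) -> tuple[np.ndarray, np.ndarray, int]:
    """Read a stereo WAV back to float channels in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a 2-channel WAV file")
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    else:
        data = data.astype(float)
    return data[:, 0], data[:, 1], rate
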