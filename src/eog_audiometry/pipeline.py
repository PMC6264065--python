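"""Horizontal-EOG processing chain.

Raw two-channel recordings (left/right periocular electrodes, µV,
nominally 2048 Hz) are reduced to per-trial epochs of the horizontal
eye-movement component:

1. bipolar derivation: left_eog - right_eog (horizontal gaze shift);
2. down-sampling to 512 Hz with an anti-alias filter;
3. epoching into 6-s trials at the trigger onsets;
4. per-epoch DC offset removal;
5. fourth-order Butterworth band-pass, 0.2-0.4 Hz, applied zero-phase
   (forward-backward), isolating the 1/3 Hz component tracking the
   moving sound source.

Filtering a 6-s epoch with a 0.2 Hz filter is transient-dominated
unless the epoch is extended before filtering.  Because every epoch is
stimulus-locked and spans an integer number of 1/3 Hz sweep cycles, the
default extension is periodic: the (DC-removed) epoch is tiled
``pad_factor`` times on each side before filtfilt and the centre is
kept.  Reflection padding is available via ``pad_mode`` for signals
where periodic extension is inappropriate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps

EPOCH_DURATION_S = 6.0
RAW_RATE_HZ = 2048.0
PROCESSED_RATE_HZ = 512.0


class ProcessingStage(str, Enum):
    RAW_BIPOLAR = "raw-bipolar"
    DC_REMOVED = "dc-removed"
    FILTERED = "filtered"


@dataclass
class RawRecording:
    """Continuous two-channel EOG recording with trigger events.

    ``events`` is a list of (onset_sample, label) pairs; labels are
    free-form strings (the simulator uses "s{session}t{trial}").
    """

    left_eog: np.ndarray  # µV
    right_eog: np.ndarray  # µV
    sample_rate: float
    events: list[tuple[int, str]]

    def __post_init__(self) -> None:
        self.left_eog = np.asarray(self.left_eog, dtype=float)
        self.right_eog = np.asarray(self.right_eog, dtype=float)
        if self.left_eog.shape != self.right_eog.shape:
            raise ValueError("channels must have equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.left_eog.size
        for onset, label in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event {label!r} onset {onset} outside recording")

    @property
    def n_samples(self) -> int:
        return self.left_eog.size


@dataclass
class EogEpoch:
    """One processed 6-s trial of the horizontal EOG component."""

    samples: np.ndarray  # µV
    sample_rate: float
    trial_ref: tuple[int, int] | None = None  # (session, trial)
    stage: ProcessingStage = ProcessingStage.RAW_BIPOLAR

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def bipolar_derivation(rec: RawRecording) -> np.ndarray:
    """Horizontal EOG shift: left electrode minus right electrode."""
    if rec.left_eog is None:
        raise ValueError("missing channel: left_eog")
    if rec.right_eog is None:
        raise ValueError("missing channel: right_eog")
    return rec.left_eog - rec.right_eog


def downsample(
    x: np.ndarray, from_rate: float, to_rate: float, method: str = "fir"
) -> np.ndarray:
    """Anti-alias filter and decimate ``x`` from ``from_rate`` to ``to_rate``.

    ``method='fir'`` (default) uses a zero-phase FIR anti-alias filter;
    ``method='cheby'`` uses the order-8 Chebyshev-I IIR design.  Both
    are applied forward-backward, so a 0.33 Hz component passes with
    negligible amplitude error.  Non-integer rate ratios fall back to
    polyphase rational resampling.
    """
    if to_rate > from_rate:
        raise ValueError("to_rate must not exceed from_rate")
    if to_rate == from_rate:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    ratio = from_rate / to_rate
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        if method == "fir":
            # linear end-extension avoids FIR edge transients on finite records
            return sps.resample_poly(x, 1, q, padtype="line")
        if method == "cheby":
            return sps.decimate(x, q, ftype="iir", zero_phase=True)
        raise ValueError(f"unknown decimation method {method!r}")
    from fractions import Fraction

    frac = Fraction(to_rate / from_rate).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, padtype="line")


def extract_epochs(
    x: np.ndarray,
    events: list[tuple[int, str]],
    sample_rate: float,
    epoch_duration: float = EPOCH_DURATION_S,
    trial_refs: list[tuple[int, int]] | None = None,
) -> list[EogEpoch]:
    """Cut one epoch per trigger event, starting at the event onset."""
    n_epoch = round(epoch_duration * sample_rate)
    epochs = []
    for i, (onset, label) in enumerate(events):
        if onset + n_epoch > x.size:
            raise ValueError(
                f"epoch for event {label!r} (onset {onset}) extends past recording end"
            )
        ref = trial_refs[i] if trial_refs is not None else None
        epochs.append(
            EogEpoch(x[onset : onset + n_epoch].copy(), sample_rate, trial_ref=ref)
        )
    return epochs


def remove_dc(epoch: EogEpoch) -> EogEpoch:
    """Subtract the epoch's mean (gross DC offset of the electrode pair)."""
    if epoch.stage != ProcessingStage.RAW_BIPOLAR:
        raise ValueError(f"remove_dc expects a raw-bipolar epoch, got {epoch.stage}")
    return replace(
        epoch, samples=epoch.samples - epoch.samples.mean(), stage=ProcessingStage.DC_REMOVED
    )


def bandpass(
    epoch: EogEpoch,
    low: float = 0.2,
    high: float = 0.4,
    order: int = 4,
    pad_factor: int = 4,
    pad_mode: str = "wrap",
) -> EogEpoch:
    """Zero-phase Butterworth band-pass of one epoch.

    The ``order``-th order design is applied forward and backward
    (squared magnitude response, zero net phase).  The epoch is extended
    by ``pad_factor`` epoch lengths on each side before filtering
    (``pad_mode``: any np.pad mode, 'wrap' = periodic by default) and
    cropped back afterwards.
    """
    if epoch.stage != ProcessingStage.DC_REMOVED:
        raise ValueError(f"bandpass expects a dc-removed epoch, got {epoch.stage}")
    nyq = epoch.sample_rate / 2
    if not 0 < low < high < nyq:
        raise ValueError(f"need 0 < low < high < Nyquist; got ({low}, {high}) at fs={epoch.sample_rate}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=epoch.sample_rate, output="sos")
    x = epoch.samples
    p = pad_factor * x.size
    if p > 0:
        xp = np.pad(x, p, mode=pad_mode)
        y = sps.sosfiltfilt(sos, xp)[p : p + x.size]
    else:
        y = sps.sosfiltfilt(sos, x)
    return replace(epoch, samples=y, stage=ProcessingStage.FILTERED)


def process_recording(
    rec: RawRecording,
    target_rate: float = PROCESSED_RATE_HZ,
    epoch_duration: float = EPOCH_DURATION_S,
    low: float = 0.2,
    high: float = 0.4,
    order: int = 4,
    decimation: str = "fir",
    pad_factor: int = 4,
    pad_mode: str = "wrap",
    trial_refs: list[tuple[int, int]] | None = None,
) -> list[EogEpoch]:
    """Full chain: bipolar -> downsample -> epoch -> DC removal -> band-pass."""
    heog = bipolar_derivation(rec)
    heog = downsample(heog, rec.sample_rate, target_rate, method=decimation)
    scale = target_rate / rec.sample_rate
    events = [(round(onset * scale), label) for onset, label in rec.events]
    epochs = extract_epochs(heog, events, target_rate, epoch_duration, trial_refs)
    return [
        bandpass(remove_dc(ep), low, high, order, pad_factor, pad_mode) for ep in epochs
    ]


# ---------------------------------------------------------------------------
# readers / writers

def read_raw_csv(path, sample_rate: float | None = None) -> RawRecording:
    """Read the plain raw format: CSV with columns time, left_eog, right_eog."""
    df = pd.read_csv(path)
    for col in ("left_eog", "right_eog"):
        if col not in df.columns:
            raise ValueError(f"missing channel: {col}")
    if sample_rate is None:
        dt = np.diff(df["time"].to_numpy())
        sample_rate = 1.0 / float(np.median(dt))
    return RawRecording(
        df["left_eog"].to_numpy(float), df["right_eog"].to_numpy(float), sample_rate, []
    )


def write_raw_csv(rec: RawRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.sample_rate
    pd.DataFrame(
        {"time": t, "left_eog": rec.left_eog, "right_eog": rec.right_eog}
    ).to_csv(path, index=False)


def read_events_csv(path, sample_rate: float) -> list[tuple[int, str]]:
    """Read an event table (columns onset_s, label) into sample onsets."""
    df = pd.read_csv(path)
    return [
        (round(row.onset_s * sample_rate), str(row.label)) for row in df.itertuples()
    ]


def write_events_csv(events: list[tuple[int, str]], sample_rate: float, path) -> None:
    pd.DataFrame(
        {"onset_s": [o / sample_rate for o, _ in events], "label": [l for _, l in events]}
    ).to_csv(path, index=False)


def read_raw_bdf(path, left_channel: str = "EXG1", right_channel: str = "EXG2") -> RawRecording:
    """Read a BioSemi BDF/EDF recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading BDF/EDF files requires mne") from exc
    raw = mne.io.read_raw(path, preload=True, verbose="error")
    for ch in (left_channel, right_channel):
        if ch not in raw.ch_names:
            raise ValueError(f"missing channel: {ch}")
    data = raw.get_data(picks=[left_channel, right_channel]) * 1e6  # V -> µV
    try:
        ev = mne.find_events(raw, verbose="error")
        events = [(int(e[0]), str(int(e[2]))) for e in ev]
    except ValueError:
        events = []
    return RawRecording(data[0], data[1], float(raw.info["sfreq"]), events)


def write_epoch_csv(epoch: EogEpoch, path) -> None:
    t = np.arange(epoch.samples.size) / epoch.sample_rate
    pd.DataFrame({"time": t, "heog_uV": epoch.samples}).to_csv(path, index=False)
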