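"""Amplitude feature, normalization, audibility labelling and statistics.

The per-trial feature is the EOG amplitude: the maximum absolute value
of the filtered horizontal-EOG epoch.  Within each session every
amplitude is divided by the amplitude of that session's reference trial
(2000 Hz at 70 dBA — a level every normal-hearing listener can hear),
making the feature dimensionless and robust to inter-individual and
inter-session differences in corneo-retinal potential and electrode
gain.

Trials are labelled against the listener's pure-tone thresholds (PTTs):
intensity above the PTT at the trial's frequency -> audible, below ->
inaudible; trials presented exactly at the PTT are discarded, and the
silent trial 1 is kept as a no-sound control outside the comparison.
Session means of the normalized amplitude per condition form eight
audible/inaudible pairs that are compared with an exact two-sided
Wilcoxon signed-rank test; a Lilliefors/Kolmogorov-Smirnov normality
check motivates the nonparametric choice, and Bonferroni correction is
applied across participants.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import EogEpoch, ProcessingStage

REFERENCE_FREQUENCY_HZ = 2000.0
REFERENCE_INTENSITY_DBA = 70.0


class TrialLabel(str, Enum):
    AUDIBLE = "audible"
    INAUDIBLE = "inaudible"
    AT_THRESHOLD_DISCARDED = "at_threshold_discarded"
    NO_SOUND_CONTROL = "no_sound_control"


@dataclass
class TrialFeature:
    session: int
    trial: int
    frequency: float | None
    intensity: float | None
    raw_amplitude: float  # µV
    normalized_amplitude: float | None = None
    label: TrialLabel | None = None

    def __post_init__(self) -> None:
        if self.raw_amplitude < 0:
            raise ValueError("amplitude is non-negative by construction")


@dataclass(frozen=True)
class Audiogram:
    """Per-frequency pure-tone thresholds (dBA)."""

    thresholds: dict[float, float]

    def threshold(self, frequency: float) -> float:
        try:
            return self.thresholds[frequency]
        except KeyError:
            raise KeyError(f"no pure-tone threshold for {frequency} Hz") from None


@dataclass
class WilcoxonExactResult:
    statistic: float  # W+ = sum of positive ranks
    pvalue: float  # exact two-sided
    n_used: int  # pairs remaining after dropping zero differences


@dataclass
class ConditionSummary:
    """Paired per-session condition means plus the test results."""

    pairs: pd.DataFrame  # columns: session, inaudible_mean, audible_mean
    excluded_sessions: list[int]
    statistic: float
    p_raw: float
    p_adjusted: float | None = None


def eog_amplitude(epoch: EogEpoch) -> float:
    """EOG amplitude of a trial: max |filtered horizontal EOG| in µV."""
    if epoch.stage != ProcessingStage.FILTERED:
        raise ValueError(f"amplitude is defined on filtered epochs, got {epoch.stage}")
    if epoch.samples.size == 0:
        raise ValueError("empty epoch")
    return float(np.max(np.abs(epoch.samples)))


def normalize_amplitudes(
    features: list[TrialFeature],
    reference_frequency: float = REFERENCE_FREQUENCY_HZ,
    reference_intensity: float = REFERENCE_INTENSITY_DBA,
) -> list[TrialFeature]:
    """Divide every amplitude by its session's reference-trial amplitude."""
    out: list[TrialFeature] = []
    sessions = sorted({f.session for f in features})
    for s in sessions:
        in_session = [f for f in features if f.session == s]
        refs = [
            f
            for f in in_session
            if f.frequency == reference_frequency and f.intensity == reference_intensity
        ]
        if len(refs) != 1:
            raise ValueError(
                f"session {s}: expected exactly one reference trial "
                f"({reference_frequency} Hz, {reference_intensity} dBA), found {len(refs)}"
            )
        ref_amp = refs[0].raw_amplitude
        if ref_amp == 0:
            raise ValueError(f"session {s}: reference trial has zero amplitude")
        out.extend(
            replace(f, normalized_amplitude=f.raw_amplitude / ref_amp) for f in in_session
        )
    return out


def label_trial(feature: TrialFeature, audiogram: Audiogram) -> TrialLabel:
    """Audible / inaudible / at-threshold-discarded / no-sound-control."""
    if feature.frequency is None or feature.intensity is None:
        return TrialLabel.NO_SOUND_CONTROL
    ptt = audiogram.threshold(feature.frequency)
    if feature.intensity > ptt:
        return TrialLabel.AUDIBLE
    if feature.intensity < ptt:
        return TrialLabel.INAUDIBLE
    return TrialLabel.AT_THRESHOLD_DISCARDED


def label_features(
    features: list[TrialFeature], audiogram: Audiogram
) -> list[TrialFeature]:
    return [replace(f, label=label_trial(f, audiogram)) for f in features]


def summarize_sessions(
    features: list[TrialFeature], n_sessions: int = 8
) -> tuple[pd.DataFrame, list[int]]:
    """Per-session mean normalized amplitude for each condition.

    Returns (pairs, excluded_sessions): ``pairs`` has one row per
    session with both conditions non-empty; sessions lacking audible or
    inaudible trials are excluded with a warning.
    """
    if any(f.normalized_amplitude is None or f.label is None for f in features):
        raise ValueError("features must be normalized and labelled first")
    rows, excluded = [], []
    for s in range(1, n_sessions + 1):
        in_session = [f for f in features if f.session == s]
        aud = [f.normalized_amplitude for f in in_session if f.label == TrialLabel.AUDIBLE]
        inaud = [
            f.normalized_amplitude for f in in_session if f.label == TrialLabel.INAUDIBLE
        ]
        if not aud or not inaud:
            excluded.append(s)
            warnings.warn(
                f"session {s} lacks trials in one condition; excluded from pairing",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "session": s,
                "inaudible_mean": float(np.mean(inaud)),
                "audible_mean": float(np.mean(aud)),
            }
        )
    return pd.DataFrame(rows), excluded


def wilcoxon_signed_rank_exact(pairs) -> WilcoxonExactResult:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    ``pairs`` is a sequence of (a, b); differences d = a - b.  Zero
    differences are dropped, tied |d| receive mid-ranks, and the exact
    two-sided p-value is computed from the full null distribution of
    W+ over all 2^n equiprobable sign assignments, conditioned on the
    observed (possibly tied) rank multiset.  Valid for n up to ~25.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs supplied")
    d = np.asarray([float(a) - float(b) for a, b in pairs])
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    # doubled ranks are integers even with mid-ranks (ties give .5 steps)
    r2 = np.round(2 * ranks).astype(int)
    total2 = int(r2.sum())
    # null distribution of 2*W+ by shift-convolution over sign choices
    counts = np.zeros(total2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0**n
    w2 = int(round(2 * w_plus))
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    pvalue = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonExactResult(statistic=w_plus, pvalue=pvalue, n_used=n)


def wilcoxon_brute_force(pairs) -> WilcoxonExactResult:
    """Brute-force oracle: enumerate all 2^n sign assignments explicitly.

    Independent of :func:`wilcoxon_signed_rank_exact`; intended for
    verification at small n (n <= ~15).
    """
    pairs = list(pairs)
    d = np.asarray([float(a) - float(b) for a, b in pairs])
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    ws = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product((-1, 1), repeat=n)
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = float(np.mean(ws <= w_obs + eps))
    p_ge = float(np.mean(ws >= w_obs - eps))
    return WilcoxonExactResult(
        statistic=w_obs, pvalue=min(1.0, 2.0 * min(p_le, p_ge)), n_used=n
    )


def ks_normality_check(
    sample, method: str = "lilliefors", loc: float | None = None, scale: float | None = None
) -> float:
    """One-sample normality check; returns the p-value.

    ``method='lilliefors'`` (default) estimates mean and SD from the
    sample (Lilliefors correction of the KS test); ``method='ks'`` is
    the classical fixed-parameter KS test against Normal(loc, scale)
    (parameters default to the sample estimates, which makes the
    classical p conservative).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0:
        raise ValueError("degenerate sample with zero variance")
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(x, dist="norm")
        return float(p)
    if method == "ks":
        mu = float(np.mean(x)) if loc is None else loc
        sd = float(np.std(x, ddof=1)) if scale is None else scale
        return float(stats.kstest(x, "norm", args=(mu, sd)).pvalue)
    raise ValueError(f"unknown method {method!r}")


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: adjusted p = min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, p * m)


def features_to_frame(features: list[TrialFeature]) -> pd.DataFrame:
    """Features table with columns matching the on-disk CSV format."""
    return pd.DataFrame(
        {
            "session": [f.session for f in features],
            "trial": [f.trial for f in features],
            "frequency_Hz": [f.frequency for f in features],
            "intensity_dBA": [f.intensity for f in features],
            "raw_uV": [f.raw_amplitude for f in features],
            "normalized": [f.normalized_amplitude for f in features],
            "label": [f.label.value if f.label else None for f in features],
        }
    )
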