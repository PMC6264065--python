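import numpy as np
import pytest
from scipy import stats

from eog_audiometry import features as fs
from eog_audiometry.features import TrialLabel
from eog_audiometry.pipeline import ProcessingStage

from conftest import make_epoch


def feat(session, trial, freq, dba, amp):
    return fs.TrialFeature(session, trial, freq, dba, amp)


def make_session_features(session=1, ref_amp=10.0):
    """One 16-trial session; amplitudes are trial-index placeholders."""
    out = [feat(session, 1, None, None, 1.0)]
    idx = 2
    for f in (1000.0, 2000.0, 4000.0):
        for dba in (30.0, 40.0, 50.0, 60.0, 70.0):
            amp = ref_amp if (f, dba) == (2000.0, 70.0) else 0.5 * idx
            out.append(feat(session, idx, f, dba, amp))
            idx += 1
    return out


class TestAmplitude:
    def test_zero_epoch(self):
        ep = make_epoch(np.zeros(100), stage=ProcessingStage.FILTERED)
        assert fs.eog_amplitude(ep) == 0.0

    def test_max_absolute_value(self):
        ep = make_epoch([1.0, -3.0, 2.0], stage=ProcessingStage.FILTERED)
        assert fs.eog_amplitude(ep) == 3.0

    def test_dense_unit_sinusoid(self):
        t = np.linspace(0, 1, 10001)
        ep = make_epoch(np.sin(2 * np.pi * 5 * t), stage=ProcessingStage.FILTERED)
        assert fs.eog_amplitude(ep) == pytest.approx(1.0, abs=1e-4)

    def test_requires_filtered_stage(self):
        with pytest.raises(ValueError):
            fs.eog_amplitude(make_epoch([1.0]))

    def test_empty_epoch(self):
        with pytest.raises(ValueError):
            fs.eog_amplitude(make_epoch([], stage=ProcessingStage.FILTERED))


class TestNormalization:
    def test_reference_trial_maps_to_one(self):
        out = fs.normalize_amplitudes(make_session_features())
        ref = [f for f in out if f.frequency == 2000.0 and f.intensity == 70.0]
        assert ref[0].normalized_amplitude == 1.0

    def test_half_reference_maps_to_half(self):
        feats = [feat(1, 2, 2000.0, 70.0, 10.0), feat(1, 3, 1000.0, 50.0, 5.0)]
        out = fs.normalize_amplitudes(feats)
        assert out[1].normalized_amplitude == pytest.approx(0.5)

    def test_per_session_reference(self):
        feats = make_session_features(1, ref_amp=10.0) + make_session_features(2, ref_amp=20.0)
        out = fs.normalize_amplitudes(feats)
        for f in out:
            ref = 10.0 if f.session == 1 else 20.0
            assert f.normalized_amplitude == pytest.approx(f.raw_amplitude / ref)

    def test_scale_invariance(self):
        feats = make_session_features()
        scaled = [fs.TrialFeature(f.session, f.trial, f.frequency, f.intensity, 7.3 * f.raw_amplitude) for f in feats]
        a = [f.normalized_amplitude for f in fs.normalize_amplitudes(feats)]
        b = [f.normalized_amplitude for f in fs.normalize_amplitudes(scaled)]
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_reference_raises_naming_session(self):
        with pytest.raises(ValueError, match="session 1"):
            fs.normalize_amplitudes([feat(1, 2, 2000.0, 70.0, 0.0)])

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            fs.normalize_amplitudes([feat(1, 2, 1000.0, 50.0, 2.0)])


class TestLabelling:
    audiogram = fs.Audiogram({1000.0: 40.0, 2000.0: 40.0, 4000.0: 40.0})

    @pytest.mark.parametrize(
        "freq, dba, expected",
        [
            (1000.0, 50.0, TrialLabel.AUDIBLE),
            (1000.0, 30.0, TrialLabel.INAUDIBLE),
            (1000.0, 40.0, TrialLabel.AT_THRESHOLD_DISCARDED),
            (None, None, TrialLabel.NO_SOUND_CONTROL),
        ],
    )
    def test_label_rules(self, freq, dba, expected):
        assert fs.label_trial(feat(1, 2, freq, dba, 1.0), self.audiogram) == expected

    def test_unknown_frequency_raises(self):
        with pytest.raises(KeyError):
            fs.label_trial(feat(1, 2, 1000.0, 50.0, 1.0), fs.Audiogram({2000.0: 40.0}))

    def test_label_partition_sums_to_16(self):
        feats = fs.label_features(
            fs.normalize_amplitudes(make_session_features()), self.audiogram
        )
        counts = {label: 0 for label in TrialLabel}
        for f in feats:
            counts[f.label] += 1
        assert sum(counts.values()) == 16
        assert counts[TrialLabel.NO_SOUND_CONTROL] == 1
        # PTT 40 sits on the intensity grid: exactly one discard per frequency
        assert counts[TrialLabel.AT_THRESHOLD_DISCARDED] == 3
        assert counts[TrialLabel.AUDIBLE] == 9
        assert counts[TrialLabel.INAUDIBLE] == 3


class TestSummaries:
    def test_session_condition_means(self):
        feats = fs.label_features(
            fs.normalize_amplitudes(make_session_features()),
            fs.Audiogram({1000.0: 40.0, 2000.0: 40.0, 4000.0: 40.0}),
        )
        pairs, excluded = fs.summarize_sessions(feats, n_sessions=1)
        assert excluded == []
        aud = [f.normalized_amplitude for f in feats if f.label == TrialLabel.AUDIBLE]
        assert pairs.iloc[0].audible_mean == pytest.approx(np.mean(aud))

    def test_eight_sessions_give_eight_pairs(self):
        feats = []
        for s in range(1, 9):
            feats.extend(make_session_features(s))
        feats = fs.label_features(
            fs.normalize_amplitudes(feats), fs.Audiogram({1000.0: 40.0, 2000.0: 40.0, 4000.0: 40.0})
        )
        pairs, _ = fs.summarize_sessions(feats)
        assert len(pairs) == 8

    def test_session_missing_a_condition_is_flagged(self):
        # an audiogram below every tested intensity leaves no inaudible trials
        feats = fs.label_features(
            fs.normalize_amplitudes(make_session_features()), fs.Audiogram({1000.0: 0.0, 2000.0: 0.0, 4000.0: 0.0})
        )
        with pytest.warns(UserWarning, match="session 1"):
            pairs, excluded = fs.summarize_sessions(feats, n_sessions=1)
        assert excluded == [1]
        assert pairs.empty


class TestWilcoxonExact:
    def test_all_positive_n8(self):
        res = fs.wilcoxon_signed_rank_exact([(i + 1.0, 0.0) for i in range(8)])
        assert res.statistic == 36.0
        assert res.pvalue == pytest.approx(2 / 256)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            fs.wilcoxon_signed_rank_exact([(1.0, 1.0), (2.0, 2.0)])

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=9), rng.normal(size=9)
        fwd = fs.wilcoxon_signed_rank_exact(list(zip(a, b)))
        rev = fs.wilcoxon_signed_rank_exact(list(zip(b, a)))
        assert fwd.pvalue == pytest.approx(rev.pvalue)
        total = fwd.n_used * (fwd.n_used + 1) / 2
        assert fwd.statistic + rev.statistic == pytest.approx(total)

    def test_matches_brute_force_oracle_on_random_instances(self):
        """DP enumeration == explicit 2^n sign enumeration, incl. ties/zeros."""
        rng = np.random.default_rng(9)
        for trial in range(100):
            n = int(rng.integers(2, 11))
            if trial % 2:
                d = rng.integers(-4, 5, size=n).astype(float)  # forces ties/zeros
            else:
                d = rng.normal(size=n)
            if not np.any(d):
                continue
            pairs = [(float(x), 0.0) for x in d]
            ours = fs.wilcoxon_signed_rank_exact(pairs)
            oracle = fs.wilcoxon_brute_force(pairs)
            assert ours.statistic == pytest.approx(oracle.statistic)
            assert ours.pvalue == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=12)
        res = fs.wilcoxon_signed_rank_exact([(v, 0.0) for v in x])
        ref = stats.wilcoxon(x, method="exact", alternative="two-sided")
        # scipy reports W = min(W+, W-)
        assert min(res.statistic, res.n_used * (res.n_used + 1) / 2 - res.statistic) == ref.statistic
        assert res.pvalue == pytest.approx(ref.pvalue)


class TestNormalityCheck:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(11).normal(0, 1, 10000)
        assert fs.ks_normality_check(x) > 0.05

    def test_bimodal_sample_fails(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(-3, 0.3, 50), rng.normal(3, 0.3, 50)])
        assert fs.ks_normality_check(x) < 0.05

    def test_classical_ks_variant(self):
        x = np.random.default_rng(13).normal(0, 1, 500)
        assert fs.ks_normality_check(x, method="ks", loc=0.0, scale=1.0) > 0.05

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            fs.ks_normality_check(np.ones(10))


class TestBonferroni:
    def test_basic_scaling(self):
        assert fs.bonferroni_adjust([0.004], m=10) == pytest.approx([0.04])

    def test_clamped_at_one(self):
        assert fs.bonferroni_adjust([0.5], m=10) == pytest.approx([1.0])

    def test_single_test_identity(self):
        assert fs.bonferroni_adjust([0.3], m=1) == pytest.approx([0.3])

    def test_m_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            fs.bonferroni_adjust([0.1, 0.2], m=1)
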