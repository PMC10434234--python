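"""Synthetic generator: determinism, SNR calibration, phase locking."""

from dataclasses import replace

import numpy as np
import pytest

from ssvep_uac import (
    StimulusVocabulary,
    SynthConfig,
    generate_epoch,
    generate_session,
    signal_only_epoch,
)
from ssvep_uac.synth import (
    _band_power,
    _clean_signal,
    load_epoch_archive,
    save_epoch_archive,
)


@pytest.fixture
def ucsd_synth(ucsd_vocab):
    return SynthConfig(vocabulary=ucsd_vocab, sampling_rate=256.0,
                       epoch_length=1.0, snr_db=-10.0, seed=99)


class TestGenerateEpoch:
    def test_identical_coordinates_are_bitwise_identical(self, ucsd_synth):
        a = generate_epoch(ucsd_synth, 3, 1, 2)
        b = generate_epoch(ucsd_synth, 3, 1, 2)
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_trial_indices_differ(self, ucsd_synth):
        a = generate_epoch(ucsd_synth, 3, 1, 2)
        b = generate_epoch(ucsd_synth, 3, 1, 3)
        assert not np.array_equal(a.data, b.data)

    def test_epoch_geometry_follows_config(self, ucsd_synth):
        ep = generate_epoch(ucsd_synth, 0)
        assert ep.data.shape == (8, 256)
        assert ep.sampling_rate == 256.0

    def test_invalid_target_raises(self, ucsd_synth):
        with pytest.raises(IndexError):
            generate_epoch(ucsd_synth, 12)

    @pytest.mark.parametrize("kwargs", [
        dict(snr_db=np.inf), dict(noise_model="pink"), dict(harmonic_decay=0.0),
    ])
    def test_invalid_configs_raise(self, ucsd_vocab, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(vocabulary=ucsd_vocab, seed=0, **kwargs)

    @pytest.mark.parametrize("snr_db", [-10.0, 0.0])
    @pytest.mark.parametrize("noise_model", ["white", "one_over_f"])
    def test_realized_snr_matches_request_within_1db(self, ucsd_vocab,
                                                     snr_db, noise_model):
        cfg = SynthConfig(vocabulary=ucsd_vocab, sampling_rate=256.0,
                          snr_db=snr_db, noise_model=noise_model, seed=13)
        ratios = []
        for trial in range(100):
            target = trial % 12
            clean = _clean_signal(cfg, target)
            noise = generate_epoch(cfg, target, 0, trial).data - clean
            ratios.append(_band_power(clean, 256.0) / _band_power(noise, 256.0))
        mean_db = 10 * np.log10(np.mean(ratios))
        assert mean_db == pytest.approx(snr_db, abs=1.0)

    def test_fundamental_phase_locked_across_trials(self, ucsd_synth):
        # pre-noise response is a pure function of the target: circular
        # variance of the fundamental's phase across trials is ~0
        f = ucsd_synth.vocabulary.frequencies[5]
        t = np.arange(1, 257) / 256.0
        probe = np.exp(-2j * np.pi * f * t)
        phases = []
        for block in range(8):
            sig = signal_only_epoch(ucsd_synth, 5, block).data
            phases.append(np.angle(sig[0] @ probe))
        circ_var = 1 - np.abs(np.mean(np.exp(1j * np.array(phases))))
        assert circ_var < 1e-6

    def test_coherent_averaging_gains_18db_over_64_epochs(self, ucsd_synth):
        # averaging n phase-locked epochs leaves the signal untouched and
        # divides noise power by ~n: 10*log10(64) = 18.06 dB
        target = 4
        clean = _clean_signal(ucsd_synth, target)
        noises = np.stack([
            generate_epoch(ucsd_synth, target, 0, trial).data - clean
            for trial in range(64)
        ])
        p_one = np.mean([_band_power(n, 256.0) for n in noises])
        p_avg = _band_power(noises.mean(axis=0), 256.0)
        gain_db = 10 * np.log10(p_one / p_avg)
        assert gain_db == pytest.approx(10 * np.log10(64), abs=1.0)

    def test_near_noiseless_epochs_decode_perfectly(self, ucsd_vocab):
        from ssvep_uac import FBCCA

        cfg = SynthConfig(vocabulary=ucsd_vocab, sampling_rate=256.0,
                          snr_db=60.0, seed=21)
        clf = FBCCA(frequencies=ucsd_vocab, sampling_rate=256.0,
                    n_subbands=3, n_harmonics=3).fit()
        for target in range(12):
            ep = generate_epoch(cfg, target)
            assert int(np.argmax(clf.score_epoch(ep.data))) == target

    def test_block_drift_scales_amplitude_per_block(self, ucsd_synth):
        drifting = replace(ucsd_synth, block_drift=0.1)
        s0 = signal_only_epoch(drifting, 2, 0).data
        s3 = signal_only_epoch(drifting, 2, 3).data
        np.testing.assert_allclose(s3, s0 * 1.1**3, atol=1e-12)


class TestGenerateSession:
    def test_every_target_once_per_block(self, small_synth):
        stream = generate_session(small_synth, 4)
        assert len(stream) == 24
        for block in range(4):
            labels = sorted(lab for _, lab, b in stream if b == block)
            assert labels == list(range(6))

    def test_benchmark_scale_session_counts(self, bench_vocab):
        cfg = SynthConfig(vocabulary=bench_vocab, epoch_length=0.1, seed=2)
        stream = generate_session(cfg, 6)
        assert len(stream) == 240
        counts = np.bincount([lab for _, lab, _ in stream], minlength=40)
        assert (counts == 6).all()

    def test_fixed_seed_fixes_the_order(self, small_synth):
        order_a = [lab for _, lab, _ in generate_session(small_synth, 2)]
        order_b = [lab for _, lab, _ in generate_session(small_synth, 2)]
        assert order_a == order_b

    def test_different_seeds_give_different_orders(self, small_synth):
        other = replace(small_synth, seed=4321)
        order_a = [lab for _, lab, _ in generate_session(small_synth, 3)]
        order_b = [lab for _, lab, _ in generate_session(other, 3)]
        assert order_a != order_b


class TestEpochArchive:
    def test_round_trip(self, tmp_path, small_synth):
        stream = generate_session(small_synth, 2)
        path = tmp_path / "session.npz"
        save_epoch_archive(path, stream, small_synth)
        back, vocab, fs = load_epoch_archive(path)
        assert fs == 250.0
        assert vocab.frequencies == small_synth.vocabulary.frequencies
        assert len(back) == len(stream)
        for (ea, la, ba), (eb, lb, bb) in zip(stream, back):
            np.testing.assert_array_equal(ea.data, eb.data)
            assert (la, ba) == (lb, bb)
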