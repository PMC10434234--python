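"""Adaptive classifier: superposition, score integration, template updates."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.base import clone

from ssvep_uac import (
    FBCCA,
    UAC,
    StimulusVocabulary,
    SynthConfig,
    TemplateBank,
    generate_epoch,
    signal_only_epoch,
    superimpose,
)
from ssvep_uac.synth import _band_power


@pytest.fixture
def clf6(small_vocab):
    return UAC(frequencies=small_vocab, sampling_rate=250.0, n_subbands=2,
               n_harmonics=2, integration_weight=0.45).fit()


def epoch_of(config, target, block=0, trial=0):
    return generate_epoch(config, target, block, trial).data


class TestSuperimpose:
    def test_zero_bank_returns_epoch_unchanged(self, small_vocab, rng):
        bank = TemplateBank(small_vocab, 4, 125)
        x = rng.standard_normal((4, 125))
        np.testing.assert_array_equal(superimpose(x, bank, 2), x)

    def test_template_equal_to_epoch_doubles_it(self, small_vocab, rng):
        bank = TemplateBank(small_vocab, 4, 125)
        x = rng.standard_normal((4, 125))
        bank.templates[1] = x
        np.testing.assert_array_equal(superimpose(x, bank, 1), 2 * x)

    def test_shape_mismatch_raises(self, small_vocab, rng):
        bank = TemplateBank(small_vocab, 4, 125)
        with pytest.raises(ValueError):
            superimpose(rng.standard_normal((4, 100)), bank, 0)

    def test_matched_template_adds_narrowband_power_coherently(self, small_synth):
        # phase-locked signal adds coherently, noise incoherently
        wins = 0
        n_rep = 40
        for trial in range(n_rep):
            x = epoch_of(small_synth, 2, 0, trial)
            template = signal_only_epoch(small_synth, 2).data
            f = small_synth.vocabulary.frequencies[2]
            band = (f - 0.5, f + 0.5)
            p_aug = _band_power(x + template, 250.0, band)
            p_raw = _band_power(x, 250.0, band)
            wins += p_aug > p_raw
        assert wins >= int(0.95 * n_rep)


class TestScoreIntegration:
    def test_fresh_bank_template_scores_equal_static(self, clf6, small_synth):
        res = clf6.score_epoch(epoch_of(small_synth, 1))
        np.testing.assert_array_equal(res.template_scores, res.static_scores)
        np.testing.assert_allclose(
            res.integrated_scores, (1 + 0.45) * res.static_scores, rtol=1e-12
        )
        assert res.template_was_empty.all()
        assert res.label == res.static_label

    def test_zero_weight_reduces_to_static_fbcca(self, small_vocab, small_synth):
        uac = UAC(frequencies=small_vocab, sampling_rate=250.0, n_subbands=2,
                  n_harmonics=2, integration_weight=0.0).fit()
        fb = FBCCA(frequencies=small_vocab, sampling_rate=250.0, n_subbands=2,
                   n_harmonics=2).fit()
        for trial in range(8):
            x = epoch_of(small_synth, trial % 6, 0, trial)
            res = uac.classify_and_update(x)  # bank fills with estimates
            np.testing.assert_array_equal(res.integrated_scores,
                                          res.static_scores)
            assert res.label == int(np.argmax(fb.score_epoch(x)))

    def test_good_template_raises_true_frequency_score(self, small_synth):
        noisy = replace(small_synth, snr_db=-12.0)
        clf = UAC(frequencies=noisy.vocabulary, sampling_rate=250.0,
                  n_subbands=2, n_harmonics=2).fit()
        clf.init_bank(4, 125)
        clf.bank_.update(3, signal_only_epoch(noisy, 3).data * 2)
        wins = 0
        for trial in range(30):
            x = epoch_of(noisy, 3, 0, trial)
            res = clf.score_epoch(x)
            wins += res.template_scores[3] > res.static_scores[3]
        assert wins >= 27


class TestTemplateUpdate:
    def test_first_update_halves_the_epoch(self, clf6, small_synth):
        x = epoch_of(small_synth, 0)
        res = clf6.classify_and_update(x)
        np.testing.assert_array_equal(clf6.bank_.templates[res.label], x / 2)
        assert clf6.bank_.update_counts[res.label] == 1

    def test_two_identical_epochs_give_three_quarters(self, small_vocab):
        bank = TemplateBank(small_vocab, 2, 50)
        x = np.arange(100, dtype=float).reshape(2, 50)
        bank.update(4, x)
        bank.update(4, x)
        np.testing.assert_array_equal(bank.templates[4], 0.75 * x)

    def test_halving_recursion_converges_exponentially_not_as_mean(
        self, small_vocab
    ):
        # n identical epochs leave the template at X * (1 - 2^-n): an
        # exponentially-weighted average, not a running mean
        bank = TemplateBank(small_vocab, 2, 50)
        x = np.random.default_rng(3).integers(-8, 8, (2, 50)).astype(float)
        for n in range(1, 11):
            bank.update(0, x)
            np.testing.assert_array_equal(
                bank.templates[0], x * (1.0 - 2.0 ** (-n))
            )

    def test_running_mean_policy_averages_with_counts(self, small_vocab):
        bank = TemplateBank(small_vocab, 2, 50)
        rng = np.random.default_rng(4)
        epochs = [rng.standard_normal((2, 50)) for _ in range(5)]
        for e in epochs:
            bank.update_running_mean(2, e)
        np.testing.assert_allclose(bank.templates[2],
                                   np.mean(epochs, axis=0), atol=1e-12)

    def test_exactly_one_slot_changes_per_call(self, clf6, small_synth):
        for trial in range(6):
            before = clf6.bank_.templates.copy() if clf6.bank_ else None
            res = clf6.classify_and_update(epoch_of(small_synth, trial, 0, trial))
            if before is not None:
                changed = [
                    i for i in range(6)
                    if not np.array_equal(before[i], clf6.bank_.templates[i])
                ]
                assert changed in ([], [res.label])
        assert clf6.bank_.update_counts.sum() == 6

    def test_frozen_policy_leaves_bank_untouched(self, small_vocab, small_synth):
        clf = UAC(frequencies=small_vocab, sampling_rate=250.0, n_subbands=2,
                  n_harmonics=2, update_policy="frozen").fit()
        clf.init_bank(4, 125)
        for trial in range(4):
            clf.classify_and_update(epoch_of(small_synth, trial, 0, trial))
        assert clf.bank_.update_counts.sum() == 0
        assert not clf.bank_.templates.any()


class TestTemplateBankPersistence:
    def test_save_load_round_trip(self, tmp_path, small_vocab, rng):
        bank = TemplateBank(small_vocab, 4, 125)
        bank.update(2, rng.standard_normal((4, 125)))
        path = tmp_path / "bank.npz"
        bank.save(path)
        back = TemplateBank.load(path)
        np.testing.assert_array_equal(back.templates, bank.templates)
        np.testing.assert_array_equal(back.update_counts, bank.update_counts)
        assert back.vocabulary.frequencies == small_vocab.frequencies

    def test_set_bank_rejects_vocabulary_mismatch(self, clf6):
        other = TemplateBank(StimulusVocabulary([20.0, 21.0]), 4, 125)
        with pytest.raises(ValueError, match="vocabulary"):
            clf6.set_bank(other)


class TestEstimatorProtocol:
    def test_get_set_params_and_clone(self, clf6):
        assert clf6.get_params()["integration_weight"] == 0.45
        fresh = clone(clf6)
        fresh.set_params(integration_weight=0.65).fit()
        assert fresh.integration_weight == 0.65

    def test_invalid_update_policy_raises(self, small_vocab):
        with pytest.raises(ValueError, match="update_policy"):
            UAC(frequencies=small_vocab, update_policy="sometimes").fit()

    def test_predict_is_online_and_order_dependent(self, small_vocab,
                                                   small_synth):
        X = np.stack([epoch_of(small_synth, t % 6, 0, t) for t in range(12)])
        clf = UAC(frequencies=small_vocab, sampling_rate=250.0, n_subbands=2,
                  n_harmonics=2).fit()
        labels = clf.predict(X)
        assert labels.shape == (12,)
        assert clf.bank_.update_counts.sum() == 12
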