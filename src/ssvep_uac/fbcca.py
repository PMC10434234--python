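"""Static filter-bank CCA (FBCCA) scoring and classification.

For each candidate stimulus frequency f the epoch is filtered into D
sub-bands, the maximal canonical correlation rho_d between each
sub-band and the harmonic reference Y_f is computed, and the
discriminant score is the weighted sum of squared correlations

    score(f) = sum_d w(d) * rho_d**2,     w(d) = d**(-a) + b,

with a = 1.25, b = 0.25 by default.  The decision is the frequency
with the largest score (lowest index on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cca import EEGEpoch, _orthonormal_rows
from .filterbank import FilterBankSpec, apply_filter_bank, default_filter_bank
from .references import ReferenceSet, StimulusVocabulary

__all__ = ["FBCCA", "FBCCAConfig", "subband_weight", "fbcca_score", "fbcca_classify"]


def subband_weight(d: int, a: float = 1.25, b: float = 0.25) -> float:
    """Weight of sub-band d: ``d**(-a) + b`` (d is 1-based)."""
    if d < 1:
        raise ValueError(f"sub-band index must be >= 1, got {d}")
    return float(d) ** (-a) + b


@dataclass(frozen=True)
class FBCCAConfig:
    """Bundled FBCCA hyperparameters for serialization and the CLI."""

    filter_bank: FilterBankSpec
    n_harmonics: int = 5
    weight_a: float = 1.25
    weight_b: float = 0.25

    def weights(self) -> np.ndarray:
        return np.array(
            [subband_weight(d, self.weight_a, self.weight_b)
             for d in range(1, self.filter_bank.n_subbands + 1)]
        )


def _rho(qx: np.ndarray, qy: np.ndarray) -> float:
    """Largest canonical correlation from two orthonormal-row bases."""
    if qx.shape[0] == 0 or qy.shape[0] == 0:
        return 0.0
    s = np.linalg.svd(qx @ qy.T, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


class FBCCA(ClassifierMixin, BaseEstimator):
    """Training-free filter-bank CCA classifier for SSVEP epochs.

    Parameters
    ----------
    frequencies : sequence of float
        Stimulus vocabulary in Hz (class i <-> frequencies[i]).
    sampling_rate : float
        Epoch sampling rate in Hz.
    n_harmonics : int, default 5
        Harmonics in the sin/cos reference matrices.
    n_subbands : int, default 5
        Number of filter-bank sub-bands D (ignored when ``filter_bank``
        is given).
    weight_a, weight_b : float
        Sub-band weight parameters of ``w(d) = d**(-a) + b``.
    filter_bank : FilterBankSpec, optional
        Explicit bank design; defaults to pass-bands [8*d, 88] Hz.

    Attributes
    ----------
    vocabulary_ : StimulusVocabulary
    filter_bank_ : FilterBankSpec
    classes_ : ndarray of int
        Class indices 0..n_frequencies-1.

    Notes
    -----
    The method needs no training data; ``fit`` only resolves and
    validates the configuration, which makes the estimator usable in
    sklearn pipelines and model selection.  ``X`` passed to ``fit`` /
    ``predict`` is an array of shape (n_trials, n_channels, n_samples).
    """

    def __init__(self, frequencies=None, sampling_rate=250.0, n_harmonics=5,
                 n_subbands=5, weight_a=1.25, weight_b=0.25, filter_bank=None):
        self.frequencies = frequencies
        self.sampling_rate = sampling_rate
        self.n_harmonics = n_harmonics
        self.n_subbands = n_subbands
        self.weight_a = weight_a
        self.weight_b = weight_b
        self.filter_bank = filter_bank

    # -- configuration ------------------------------------------------

    def fit(self, X=None, y=None):
        """Resolve the vocabulary, filter bank and weights; X/y unused."""
        if self.frequencies is None:
            raise ValueError("frequencies must be provided")
        if isinstance(self.frequencies, StimulusVocabulary):
            self.vocabulary_ = self.frequencies
        else:
            self.vocabulary_ = StimulusVocabulary(self.frequencies)
        if self.filter_bank is not None:
            self.filter_bank_ = self.filter_bank
        else:
            self.filter_bank_ = default_filter_bank(self.n_subbands)
        self.weights_ = np.array(
            [subband_weight(d, self.weight_a, self.weight_b)
             for d in range(1, self.filter_bank_.n_subbands + 1)]
        )
        self.classes_ = np.arange(len(self.vocabulary_))
        self._ref_bases = {}  # n_samples -> list of orthonormal reference bases
        return self

    def _check_fitted(self):
        if not hasattr(self, "vocabulary_"):
            self.fit()

    def _reference_bases(self, n_samples: int) -> list:
        """Orthonormalized reference matrices, cached per epoch length."""
        self._check_fitted()
        if n_samples not in self._ref_bases:
            refs = ReferenceSet(self.vocabulary_, self.n_harmonics,
                                self.sampling_rate, n_samples)
            self._ref_bases[n_samples] = [_orthonormal_rows(m) for m in refs.matrices]
        return self._ref_bases[n_samples]

    # -- scoring ------------------------------------------------------

    def _subband_bases(self, epoch: np.ndarray) -> list:
        """Filter one (channels x samples) epoch and orthonormalize each band."""
        subbands = apply_filter_bank(epoch, self.filter_bank_, self.sampling_rate)
        return [_orthonormal_rows(sb) for sb in subbands]

    def _scores_from_bases(self, qx_bands: list, qy_list: list) -> np.ndarray:
        scores = np.zeros(len(qy_list))
        for w, qx in zip(self.weights_, qx_bands):
            for i, qy in enumerate(qy_list):
                scores[i] += w * _rho(qx, qy) ** 2
        return scores

    def score_epoch(self, epoch: np.ndarray) -> np.ndarray:
        """Per-frequency FBCCA scores for one (channels x samples) epoch."""
        self._check_fitted()
        epoch = np.asarray(epoch, dtype=float)
        qy_list = self._reference_bases(epoch.shape[-1])
        return self._scores_from_bases(self._subband_bases(epoch), qy_list)

    def decision_function(self, X) -> np.ndarray:
        """Score matrix of shape (n_trials, n_frequencies)."""
        X = self._as_trials(X)
        return np.vstack([self.score_epoch(x) for x in X])

    def predict(self, X) -> np.ndarray:
        """Decided frequency index per trial (argmax; lowest index on ties)."""
        return np.argmax(self.decision_function(X), axis=1)

    @staticmethod
    def _as_trials(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(
                f"X must have shape (n_trials, n_channels, n_samples), got {X.shape}"
            )
        return X


# -- functional wrappers ---------------------------------------------


def _estimator_for(vocabulary, config: FBCCAConfig, sampling_rate: float) -> FBCCA:
    return FBCCA(
        frequencies=vocabulary,
        sampling_rate=sampling_rate,
        n_harmonics=config.n_harmonics,
        weight_a=config.weight_a,
        weight_b=config.weight_b,
        filter_bank=config.filter_bank,
    ).fit()

def fbcca_score(epoch: EEGEpoch, frequency: float, config: FBCCAConfig,
                vocabulary: StimulusVocabulary) -> float:
    """Score of one epoch at one vocabulary frequency (thin wrapper)."""
    if frequency not in vocabulary.frequencies:
        raise ValueError(f"{frequency} Hz is not in the vocabulary")
    est = _estimator_for(vocabulary, config, epoch.sampling_rate)
    i = vocabulary.frequencies.index(frequency)
    return float(est.score_epoch(epoch.data)[i])


def fbcca_classify(epoch: EEGEpoch, vocabulary: StimulusVocabulary,
                   config: FBCCAConfig):
    """Classify one epoch; returns (label index, per-frequency scores)."""
    est = _estimator_for(vocabulary, config, epoch.sampling_rate)
    scores = est.score_epoch(epoch.data)
    return int(np.argmax(scores)), scores
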