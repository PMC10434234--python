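"""Unsupervised adaptive SSVEP classifier (UAC).

The adaptive classifier exploits the self-similarity of same-frequency
SSVEP responses: because the response is time- and phase-locked to the
stimulus, summing two epochs of the same target adds their stimulus
component coherently while the background EEG adds incoherently, so
the narrowband SNR rises; summing epochs of different targets lowers it.

The classifier keeps one template per stimulus frequency, initialized
to zero and built online from its own (estimated, possibly wrong)
labels.  For a test epoch X it computes, per frequency i:

    p_i  = FBCCA(X + Z_i, Y_i)     template-augmented score
    p'_i = FBCCA(X, Y_i)           static FBCCA score
    p~_i = p'_i + w * p_i          integrated score

decides argmax_i p~_i, then updates only the decided frequency's
template with the halving recursion

    Z' = (X + Z) / 2,

an exponentially-weighted average that favors recent trials.  No
confidence gating and no amplitude normalization are applied; wrong
decisions do corrupt templates, which is the method's documented
failure mode at low SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .fbcca import FBCCA, FBCCAConfig
from .filterbank import FilterBankSpec, apply_filter_bank
from .references import StimulusVocabulary
from .cca import _orthonormal_rows

__all__ = ["TemplateBank", "DecodeResult", "UACConfig", "UAC", "superimpose"]

BANK_FORMAT_VERSION = 1


class TemplateBank:
    """Per-frequency running templates (the adaptive classifier's state).

    Parameters
    ----------
    vocabulary : StimulusVocabulary
    n_channels, n_samples : int
        Fixed epoch geometry; all templates share it.

    Attributes
    ----------
    templates : ndarray, shape (n_frequencies, n_channels, n_samples)
        Initialized to zero.
    update_counts : ndarray of int
        Number of epochs absorbed per frequency.
    """

    def __init__(self, vocabulary: StimulusVocabulary, n_channels: int,
                 n_samples: int):
        if n_channels < 1 or n_samples < 2:
            raise ValueError("bank needs >= 1 channel and >= 2 samples")
        self.vocabulary = vocabulary
        self.templates = np.zeros((len(vocabulary), n_channels, n_samples))
        self.update_counts = np.zeros(len(vocabulary), dtype=int)

    @property
    def n_frequencies(self) -> int:
        return self.templates.shape[0]

    @property
    def shape(self):
        return self.templates.shape

    def is_empty(self, i: int) -> bool:
        return self.update_counts[i] == 0

    def update(self, i: int, epoch: np.ndarray) -> None:
        """Absorb an epoch at frequency i:  Z_i <- (X + Z_i) / 2."""
        epoch = np.asarray(epoch, dtype=float)
        if epoch.shape != self.templates.shape[1:]:
            raise ValueError(
                f"epoch shape {epoch.shape} != template shape "
                f"{self.templates.shape[1:]}"
            )
        self.templates[i] = (epoch + self.templates[i]) / 2.0
        self.update_counts[i] += 1

    def update_running_mean(self, i: int, epoch: np.ndarray) -> None:
        """Count-weighted running-mean variant: Z_i <- (n*Z_i + X)/(n+1)."""
        epoch = np.asarray(epoch, dtype=float)
        if epoch.shape != self.templates.shape[1:]:
            raise ValueError("epoch/template shape mismatch")
        n = self.update_counts[i]
        self.templates[i] = (n * self.templates[i] + epoch) / (n + 1)
        self.update_counts[i] += 1

    def copy(self) -> "TemplateBank":
        new = TemplateBank(self.vocabulary, self.templates.shape[1],
                           self.templates.shape[2])
        new.templates = self.templates.copy()
        new.update_counts = self.update_counts.copy()
        return new

    # -- persistence --------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a compressed array bundle with a versioned header."""
        header = {
            "format_version": BANK_FORMAT_VERSION,
            "frequencies": list(self.vocabulary.frequencies),
            "phases": list(self.vocabulary.phases) if self.vocabulary.phases else None,
        }
        np.savez_compressed(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            templates=self.templates,
            update_counts=self.update_counts,
        )

    @classmethod
    def load(cls, path) -> "TemplateBank":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"].tobytes()).decode())
            if header["format_version"] != BANK_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported bank format version {header['format_version']}"
                )
            vocab = StimulusVocabulary(header["frequencies"], header.get("phases"))
            bank = cls(vocab, z["templates"].shape[1], z["templates"].shape[2])
            bank.templates = z["templates"].copy()
            bank.update_counts = z["update_counts"].copy()
        return bank


def superimpose(epoch: np.ndarray, bank: TemplateBank,
                frequency_index: int) -> np.ndarray:
    """Elementwise sum of a test epoch with one frequency's template."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape != bank.templates.shape[1:]:
        raise ValueError(
            f"epoch shape {epoch.shape} incompatible with bank {bank.shape}"
        )
    return epoch + bank.templates[frequency_index]


@dataclass
class DecodeResult:
    """Per-trial decoding outcome.

    Attributes
    ----------
    label : int
        Decided frequency index (argmax of ``integrated_scores``;
        lowest index on ties).
    static_scores : ndarray
        Static FBCCA scores p' per frequency.
    template_scores : ndarray
        Template-augmented scores p per frequency.
    integrated_scores : ndarray
        p~ = p' + w * p per frequency.
    template_was_empty : ndarray of bool
        True where the template was still all-zero when scored.
    """

    label: int
    static_scores: np.ndarray
    template_scores: np.ndarray
    integrated_scores: np.ndarray
    template_was_empty: np.ndarray

    @property
    def static_label(self) -> int:
        return int(np.argmax(self.static_scores))


@dataclass(frozen=True)
class UACConfig:
    """Adaptive-classifier hyperparameters for serialization and the CLI."""

    fbcca: FBCCAConfig
    integration_weight: float = 0.45
    update_policy: str = "always"  # "always" | "frozen" | "running_mean"


class UAC(ClassifierMixin, BaseEstimator):
    """Unsupervised adaptive classifier over a static FBCCA core.

    Parameters
    ----------
    frequencies : sequence of float or StimulusVocabulary
        Stimulus vocabulary in Hz.
    sampling_rate : float
        Epoch sampling rate in Hz.
    integration_weight : float, default 0.45
        Weight w blending the template-augmented score into the static
        score (p~ = p' + w p).  0.45 suits 40-class keyboards; 0.65
        suits 12-class vocabularies.  w = 0 reduces the decision exactly
        to static FBCCA.
    update_policy : {"always", "frozen", "running_mean"}
        "always": halving recursion Z' = (X+Z)/2 after each decision.
        "frozen": never update (scores still use the current bank).
        "running_mean": count-weighted mean variant.
    n_harmonics, n_subbands, weight_a, weight_b, filter_bank
        Passed to the FBCCA core.

    Attributes
    ----------
    bank_ : TemplateBank
        Online template state; created lazily at the first decode (the
        epoch geometry fixes its shape) or explicitly via ``init_bank``.
    fbcca_ : FBCCA
        The static scoring core.

    Notes
    -----
    ``predict(X)`` processes trials in order, updating the bank after
    each decision (online causal order): each trial is scored strictly
    before the bank absorbs it.
    """

    def __init__(self, frequencies=None, sampling_rate=250.0,
                 integration_weight=0.45, update_policy="always",
                 n_harmonics=5, n_subbands=5, weight_a=1.25, weight_b=0.25,
                 filter_bank=None):
        self.frequencies = frequencies
        self.sampling_rate = sampling_rate
        self.integration_weight = integration_weight
        self.update_policy = update_policy
        self.n_harmonics = n_harmonics
        self.n_subbands = n_subbands
        self.weight_a = weight_a
        self.weight_b = weight_b
        self.filter_bank = filter_bank

    def fit(self, X=None, y=None):
        """Resolve configuration and reset the template bank; X/y unused."""
        if self.integration_weight < 0:
            raise ValueError("integration_weight must be >= 0")
        if self.update_policy not in ("always", "frozen", "running_mean"):
            raise ValueError(f"unknown update_policy {self.update_policy!r}")
        self.fbcca_ = FBCCA(
            frequencies=self.frequencies,
            sampling_rate=self.sampling_rate,
            n_harmonics=self.n_harmonics,
            n_subbands=self.n_subbands,
            weight_a=self.weight_a,
            weight_b=self.weight_b,
            filter_bank=self.filter_bank,
        ).fit()
        self.vocabulary_ = self.fbcca_.vocabulary_
        self.classes_ = self.fbcca_.classes_
        self.bank_ = None
        self._filtered_templates = {}  # freq index -> list of D filtered copies
        return self

    def _check_fitted(self):
        if not hasattr(self, "fbcca_"):
            self.fit()

    def init_bank(self, n_channels: int, n_samples: int) -> TemplateBank:
        """Create (or reset) the zero-initialized template bank."""
        self._check_fitted()
        self.bank_ = TemplateBank(self.vocabulary_, n_channels, n_samples)
        self._filtered_templates = {}
        return self.bank_

    def set_bank(self, bank: TemplateBank) -> None:
        """Adopt an existing bank (e.g., loaded from a previous session)."""
        self._check_fitted()
        if tuple(bank.vocabulary.frequencies) != self.vocabulary_.frequencies:
            raise ValueError("bank vocabulary does not match classifier vocabulary")
        self.bank_ = bank
        self._filtered_templates = {}

    def _ensure_bank(self, epoch: np.ndarray) -> None:
        if self.bank_ is None:
            self.init_bank(epoch.shape[0], epoch.shape[1])
        elif epoch.shape != self.bank_.templates.shape[1:]:
            raise ValueError(
                f"epoch shape {epoch.shape} != bank epoch shape "
                f"{self.bank_.templates.shape[1:]}"
            )

    # -- filtered-template cache --------------------------------------
    # Zero-phase filtering is linear, so filter(X + Z) = filter(X) +
    # filter(Z); caching the filtered templates (invalidated only for
    # the one slot each update touches) avoids refiltering the bank for
    # every frequency on every trial.

    def _template_subbands(self, i: int) -> list:
        if i not in self._filtered_templates:
            self._filtered_templates[i] = apply_filter_bank(
                self.bank_.templates[i], self.fbcca_.filter_bank_,
                self.sampling_rate)
        return self._filtered_templates[i]

    # -- decoding -----------------------------------------------------

    def score_epoch(self, epoch: np.ndarray) -> DecodeResult:
        """Score one (channels x samples) epoch without updating the bank."""
        self._check_fitted()
        epoch = np.asarray(epoch, dtype=float)
        self._ensure_bank(epoch)
        fb = self.fbcca_
        qy_list = fb._reference_bases(epoch.shape[-1])
        x_subbands = apply_filter_bank(epoch, fb.filter_bank_, self.sampling_rate)
        qx_bands = [_orthonormal_rows(sb) for sb in x_subbands]
        static = fb._scores_from_bases(qx_bands, qy_list)

        n_f = len(qy_list)
        template_scores = np.empty(n_f)
        empty = np.array([self.bank_.is_empty(i) for i in range(n_f)])
        from .fbcca import _rho
        for i in range(n_f):
            if empty[i]:
                # zero template: X + Z_i = X, so p_i = p'_i
                template_scores[i] = static[i]
                continue
            z_subbands = self._template_subbands(i)
            score = 0.0
            for w, xsb, zsb in zip(fb.weights_, x_subbands, z_subbands):
                q = _orthonormal_rows(xsb + zsb)
                score += w * _rho(q, qy_list[i]) ** 2
            template_scores[i] = score

        integrated = static + self.integration_weight * template_scores
        label = int(np.argmax(integrated))
        return DecodeResult(
            label=label,
            static_scores=static,
            template_scores=template_scores,
            integrated_scores=integrated,
            template_was_empty=empty,
        )

    def classify_and_update(self, epoch: np.ndarray) -> DecodeResult:
        """Score one epoch, then let the bank absorb it at the decided label.

        Under ``update_policy="frozen"`` the bank is left untouched.
        """
        result = self.score_epoch(epoch)
        epoch = np.asarray(epoch, dtype=float)
        if self.update_policy == "always":
            self.bank_.update(result.label, epoch)
            self._filtered_templates.pop(result.label, None)
        elif self.update_policy == "running_mean":
            self.bank_.update_running_mean(result.label, epoch)
            self._filtered_templates.pop(result.label, None)
        return result

    def decode(self, X, update: bool = True) -> list:
        """Decode trials in order; returns a list of DecodeResult."""
        X = FBCCA._as_trials(X)
        if update:
            return [self.classify_and_update(x) for x in X]
        return [self.score_epoch(x) for x in X]

    def predict(self, X) -> np.ndarray:
        """Online adaptive decoding: decide and update trial by trial."""
        return np.array([r.label for r in self.decode(X, update=True)])

    def decision_function(self, X) -> np.ndarray:
        """Integrated score matrix, updating the bank trial by trial."""
        return np.vstack([r.integrated_scores for r in self.decode(X, update=True)])
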