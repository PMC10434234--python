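"""Sequential-protocol evaluation of adaptive vs. static SSVEP decoding.

Replays a session the way an online BCI would see it: trials arrive in
order, the adaptive classifier decides each one before its template
bank absorbs it, and the static FBCCA decision on the raw epoch is
recorded alongside for a paired comparison.  Also provides the
information-transfer-rate (ITR) closed form, a block-accumulation
experiment (how the adaptive gain grows with usage), and a sweep over
the integration weight w.

Accuracy aggregation over cohorts averages per-subject first (mean
over that subject's blocks), then across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .uac import UAC

__all__ = [
    "ProtocolResult",
    "run_sequential_protocol",
    "information_transfer_rate",
    "trial_time_for_itr",
    "weight_sweep",
    "block_accumulation_experiment",
    "paired_accuracy_vectors",
]


@dataclass
class ProtocolResult:
    """Per-trial decoding records plus aggregate accuracies.

    Attributes
    ----------
    true_labels, static_labels, adaptive_labels : ndarray of int
    blocks : ndarray of int
        Block index per trial.
    static_scores, template_scores, integrated_scores : ndarray
        (n_trials, n_frequencies) score matrices.
    config : dict
        Resolved classifier parameters for provenance.
    """

    true_labels: np.ndarray
    static_labels: np.ndarray
    adaptive_labels: np.ndarray
    blocks: np.ndarray
    static_scores: np.ndarray
    template_scores: np.ndarray
    integrated_scores: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.true_labels)

    @property
    def static_accuracy(self) -> float:
        return float(np.mean(self.static_labels == self.true_labels))

    @property
    def adaptive_accuracy(self) -> float:
        return float(np.mean(self.adaptive_labels == self.true_labels))

    def per_block_accuracy(self) -> pd.DataFrame:
        """Accuracy of both methods per block."""
        rows = []
        for b in np.unique(self.blocks):
            m = self.blocks == b
            rows.append({
                "block": int(b),
                "static": float(np.mean(self.static_labels[m] == self.true_labels[m])),
                "adaptive": float(np.mean(self.adaptive_labels[m] == self.true_labels[m])),
            })
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "block": self.blocks,
            "true_label": self.true_labels,
            "static_label": self.static_labels,
            "adaptive_label": self.adaptive_labels,
        })


def run_sequential_protocol(stream, classifier: UAC) -> ProtocolResult:
    """Decode an ordered trial stream with a fresh online template bank.

    Parameters
    ----------
    stream : sequence of (EEGEpoch, true_label, block_index)
    classifier : UAC
        Used as configuration; a clean clone decodes the stream, so the
        caller's bank state is never touched.
    """
    clf = UAC(**classifier.get_params()).fit()
    true, stat, adapt, blocks = [], [], [], []
    s_scores, t_scores, i_scores = [], [], []
    for epoch, label, block in stream:
        res = clf.classify_and_update(epoch.data)
        true.append(label)
        stat.append(res.static_label)
        adapt.append(res.label)
        blocks.append(block)
        s_scores.append(res.static_scores)
        t_scores.append(res.template_scores)
        i_scores.append(res.integrated_scores)
    return ProtocolResult(
        true_labels=np.array(true),
        static_labels=np.array(stat),
        adaptive_labels=np.array(adapt),
        blocks=np.array(blocks),
        static_scores=np.vstack(s_scores),
        template_scores=np.vstack(t_scores),
        integrated_scores=np.vstack(i_scores),
        config=clf.get_params(),
    )


def information_transfer_rate(accuracy: float, n_targets: int,
                              trial_time: float) -> float:
    """ITR in bits/min for an N-choice selection at accuracy p.

    ITR = (60/T) * [log2 N + p log2 p + (1-p) log2((1-p)/(N-1))],
    with the p -> 0 and p -> 1 limits taken continuously (0 log 0 := 0).
    """
    p, n = float(accuracy), int(n_targets)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {p}")
    if n < 2:
        raise ValueError(f"need at least 2 targets, got {n}")
    if trial_time <= 0:
        raise ValueError(f"trial_time must be > 0, got {trial_time}")
    bits = np.log2(n)
    if p > 0.0:
        bits += p * np.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * np.log2((1.0 - p) / (n - 1))
    return float(60.0 / trial_time * bits)


def trial_time_for_itr(stimulus_duration: float,
                       gaze_shift_time: float = 0.5) -> float:
    """Selection time used by the ITR: stimulus time plus gaze shift."""
    if stimulus_duration < 0 or gaze_shift_time < 0:
        raise ValueError("durations must be non-negative")
    return stimulus_duration + gaze_shift_time


def weight_sweep(sessions, classifier: UAC, weights) -> pd.DataFrame:
    """Mean adaptive accuracy across sessions for each integration weight.

    Parameters
    ----------
    sessions : sequence of trial streams (one per simulated subject)
    classifier : UAC used as a parameter template
    weights : iterable of w values

    Returns
    -------
    DataFrame with columns ``w``, ``accuracy``; the best row (highest
    accuracy, lowest w on ties) is flagged in column ``selected``.
    """
    weights = list(weights)
    if not weights:
        raise ValueError("weight grid must be non-empty")
    rows = []
    for w in weights:
        clf = UAC(**{**classifier.get_params(), "integration_weight": w})
        accs = [run_sequential_protocol(s, clf).adaptive_accuracy
                for s in sessions]
        rows.append({"w": float(w), "accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best = int(np.argmax(table["accuracy"].to_numpy()))  # first max: lowest w
    table["selected"] = False
    table.loc[best, "selected"] = True
    return table


def block_accumulation_experiment(stream, classifier: UAC,
                                  max_blocks: int) -> pd.DataFrame:
    """Accuracy of both methods when only the first m blocks are available.

    For each m = 1..max_blocks the session is truncated to its first m
    blocks and decoded from a fresh bank, mirroring a user who has used
    the system for m blocks.
    """
    rows = []
    blocks = np.array([b for _, _, b in stream])
    for m in range(1, max_blocks + 1):
        sub = [t for t, b in zip(stream, blocks) if b < m]
        res = run_sequential_protocol(sub, classifier)
        rows.append({
            "n_blocks": m,
            "static": res.static_accuracy,
            "adaptive": res.adaptive_accuracy,
        })
    return pd.DataFrame(rows)


def paired_accuracy_vectors(results) -> tuple:
    """Per-subject (static, adaptive) accuracy vectors for paired tests.

    Suitable input for a Wilcoxon signed-rank test from a standard
    statistics library.
    """
    static = np.array([r.static_accuracy for r in results])
    adaptive = np.array([r.adaptive_accuracy for r in results])
    return static, adaptive
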