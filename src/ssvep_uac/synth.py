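"""Synthetic SSVEP epoch generator.

Emulates the structure of occipital EEG during flicker stimulation:
each target evokes sinusoids at its stimulus frequency and harmonics
with geometrically decaying amplitudes and a fixed per-target phase
(phase-locked across trials, which is what makes cross-trial averaging
coherent), mixed into channels through a fixed per-subject mixing
matrix, on top of additive broadband 1/f (or white) noise scaled to a
controlled SNR.  An optional per-block amplitude drift models slow
non-stationarity of the response.

SNR is defined as total harmonic signal power over total noise power
within the 6-90 Hz analysis band, both measured spectrally, with the
signal at its nominal (undrifted) amplitude; block drift therefore
changes the effective SNR, which is its purpose.

Determinism contract: every generated epoch is a pure function of
(seed, target_index, block_index, trial_index).

What this generator does not emulate: volume-conducted artifact
topographies (blinks, EMG), latency jitter of the visual response, and
spontaneous alpha rhythms overlapping the stimulus band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .cca import EEGEpoch
from .references import StimulusVocabulary

__all__ = [
    "SynthConfig",
    "generate_epoch",
    "signal_only_epoch",
    "generate_session",
    "save_epoch_archive",
    "load_epoch_archive",
]

ANALYSIS_BAND = (6.0, 90.0)  # Hz; band over which SNR is defined

# spawn-key tags keeping the generator's independent random streams apart
_KEY_MIXING = 1_000_003
_KEY_NOISE_MIX = 1_000_033
_KEY_ORDER = 1_000_081


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of a simulated recording session.

    Parameters
    ----------
    vocabulary : StimulusVocabulary
        Target frequencies; per-target phases default to i * pi/2 when
        the vocabulary carries none.
    sampling_rate : float, Hz
    epoch_length : float, seconds
    n_channels : int
        Occipital montage size (8 matches the usual O/PO electrode set).
    n_harmonics_signal : int
        Harmonics present in the evoked response.
    harmonic_decay : float
        Amplitude ratio between consecutive harmonics (amplitude of
        harmonic h is ``harmonic_decay**(h-1)``).
    snr_db : float
        Signal-to-noise ratio in dB within the 6-90 Hz band.
    noise_model : {"one_over_f", "white"}
    mixing : "random_orthonormal" or ndarray (n_channels, n_harmonics)
        Harmonic-to-channel gain pattern, fixed for the whole session.
    block_drift : float
        Per-block relative amplitude change: block b is scaled by
        ``(1 + block_drift)**b``.  0 disables non-stationarity.
    seed : int
        Mandatory; every random draw derives from it.
    """

    vocabulary: StimulusVocabulary
    sampling_rate: float = 250.0
    epoch_length: float = 1.0
    n_channels: int = 8
    n_harmonics_signal: int = 3
    harmonic_decay: float = 0.5
    snr_db: float = -10.0
    noise_model: str = "one_over_f"
    mixing: object = "random_orthonormal"
    block_drift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.n_samples < 2:
            raise ValueError("epoch must span at least 2 samples")
        if self.noise_model not in ("one_over_f", "white"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.harmonic_decay <= 0:
            raise ValueError("harmonic_decay must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))

    def phases(self) -> np.ndarray:
        if self.vocabulary.phases is not None:
            return np.asarray(self.vocabulary.phases)
        return (0.5 * np.pi * np.arange(len(self.vocabulary))) % (2 * np.pi)


def _rng(config: SynthConfig, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=spawn_key)
    )


def _mixing_matrix(config: SynthConfig) -> np.ndarray:
    """Fixed harmonic-to-channel mixing for the session."""
    if isinstance(config.mixing, str):
        if config.mixing != "random_orthonormal":
            raise ValueError(f"unknown mixing {config.mixing!r}")
        rng = _rng(config, _KEY_MIXING)
        g = rng.standard_normal((config.n_channels, config.n_harmonics_signal))
        q, _ = np.linalg.qr(g)
        return q[:, : config.n_harmonics_signal]
    m = np.asarray(config.mixing, dtype=float)
    if m.shape != (config.n_channels, config.n_harmonics_signal):
        raise ValueError(
            f"mixing must have shape ({config.n_channels}, "
            f"{config.n_harmonics_signal}), got {m.shape}"
        )
    return m


def _band_power(x: np.ndarray, fs: float, band=ANALYSIS_BAND) -> float:
    """Mean (over channels) spectral power inside the analysis band."""
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(x.shape[-1], d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.mean(np.sum(np.abs(spec[..., in_band]) ** 2, axis=-1)))


def _clean_signal(config: SynthConfig, target_index: int) -> np.ndarray:
    """Noiseless, undrifted multichannel response for one target."""
    n_f = len(config.vocabulary)
    if not 0 <= target_index < n_f:
        raise IndexError(f"target_index {target_index} outside vocabulary of {n_f}")
    f = config.vocabulary.frequencies[target_index]
    phi = config.phases()[target_index]
    t = np.arange(1, config.n_samples + 1) / config.sampling_rate
    harmonics = np.vstack([
        config.harmonic_decay ** (h - 1) * np.sin(2 * np.pi * h * f * t + h * phi)
        for h in range(1, config.n_harmonics_signal + 1)
    ])
    return _mixing_matrix(config) @ harmonics


def _noise(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale broadband noise, channel-correlated via orthonormal mixing."""
    nc, ns = config.n_channels, config.n_samples
    if config.noise_model == "white":
        raw = rng.standard_normal((nc, ns))
    else:
        # spectrally shaped white noise: power ~ 1/f above 1 Hz, flat below
        freqs = np.fft.rfftfreq(ns, d=1.0 / config.sampling_rate)
        shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
        shaping[0] = 0.0  # no DC
        spec = (rng.standard_normal((nc, freqs.size))
                + 1j * rng.standard_normal((nc, freqs.size))) * shaping
        raw = np.fft.irfft(spec, n=ns, axis=-1)
    mix_rng = _rng(config, _KEY_NOISE_MIX)
    q, _ = np.linalg.qr(mix_rng.standard_normal((nc, nc)))
    return q @ raw


def signal_only_epoch(config: SynthConfig, target_index: int,
                      block_index: int = 0) -> EEGEpoch:
    """Noiseless response epoch (with block drift applied)."""
    drift = (1.0 + config.block_drift) ** block_index
    return EEGEpoch(drift * _clean_signal(config, target_index),
                    config.sampling_rate)


def generate_epoch(config: SynthConfig, target_index: int,
                   block_index: int = 0, trial_index: int = 0) -> EEGEpoch:
    """One noisy trial; deterministic in (seed, target, block, trial)."""
    clean = _clean_signal(config, target_index)
    rng = _rng(config, target_index, block_index, trial_index)
    noise = _noise(config, rng)
    p_sig = _band_power(clean, config.sampling_rate)
    p_noise = _band_power(noise, config.sampling_rate)
    target_ratio = 10.0 ** (config.snr_db / 10.0)
    noise *= np.sqrt(p_sig / (p_noise * target_ratio))
    drift = (1.0 + config.block_drift) ** block_index
    return EEGEpoch(drift * clean + noise, config.sampling_rate)


def generate_session(config: SynthConfig, n_blocks: int) -> list:
    """Ordered trial stream: every target once per block, seeded random order.

    Returns a list of ``(EEGEpoch, true_label, block_index)`` tuples.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n_f = len(config.vocabulary)
    stream = []
    for block in range(n_blocks):
        order = _rng(config, _KEY_ORDER, block).permutation(n_f)
        for trial, target in enumerate(order):
            epoch = generate_epoch(config, int(target), block, trial)
            stream.append((epoch, int(target), block))
    return stream


# -- epoch archives ---------------------------------------------------


def save_epoch_archive(path, stream, config: SynthConfig) -> None:
    """Write a trial stream as a compressed bundle plus a JSON sidecar."""
    path = Path(path)
    epochs = np.stack([e.data for e, _, _ in stream])
    labels = np.array([lab for _, lab, _ in stream], dtype=int)
    blocks = np.array([b for _, _, b in stream], dtype=int)
    np.savez_compressed(path, epochs=epochs, labels=labels, blocks=blocks)
    sidecar = {
        "sampling_rate": config.sampling_rate,
        "frequencies": list(config.vocabulary.frequencies),
        "phases": (list(config.vocabulary.phases)
                   if config.vocabulary.phases else None),
        "n_trials": len(stream),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def load_epoch_archive(path):
    """Read an epoch archive; returns (stream, vocabulary, sampling_rate)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    vocab = StimulusVocabulary(sidecar["frequencies"], sidecar.get("phases"))
    fs = sidecar["sampling_rate"]
    with np.load(path) as z:
        stream = [
            (EEGEpoch(z["epochs"][i], fs), int(z["labels"][i]), int(z["blocks"][i]))
            for i in range(z["epochs"].shape[0])
        ]
    return stream, vocab, fs
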