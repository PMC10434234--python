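"""Readers for the two public SSVEP dataset layouts (MATLAB files).

Supports the 40-target benchmark layout (per-subject 4-D array of
channels x samples x targets x blocks at 250 Hz, 64-channel montage)
and the 12-target layout (targets x channels x samples x runs at
256 Hz, 8 occipital channels).  Files are supplied by the user; nothing
is downloaded.  Both MATLAB dialects are handled: v5 via scipy.io and
v7.3 (HDF5) via h5py.

Epoch extraction applies a configurable visual-latency offset (default
0.14 s — the typical visual-pathway delay; the analysis window starts
that long after flicker onset) and an analysis window of configurable
start and length.

Writers for the same layouts are provided so synthetic sessions can be
stored as fixture files and round-tripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.io import loadmat, savemat

from .cca import EEGEpoch
from .references import StimulusVocabulary

__all__ = [
    "BENCHMARK_MONTAGE",
    "OCCIPITAL_CHANNELS",
    "DatasetManifest",
    "read_benchmark_subject",
    "read_ucsd_subject",
    "write_benchmark_mat",
    "write_ucsd_mat",
]

# 64-channel montage of the benchmark recordings, in storage order.
BENCHMARK_MONTAGE = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F5", "F3", "F1", "Fz",
    "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2",
    "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "Cz", "C2", "C4",
    "C6", "T8", "M1", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4",
    "CP6", "TP8", "M2", "P7", "P5", "P3", "P1", "Pz", "P2", "P4",
    "P6", "P8", "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8", "CB1",
    "O1", "Oz", "O2", "CB2",
]

# standard occipital/parieto-occipital analysis subset
OCCIPITAL_CHANNELS = ["O1", "O2", "Oz", "PO3", "PO4", "POz", "PO5", "PO6"]

_LAYOUTS = {
    "benchmark40": {
        "sampling_rate": 250.0,
        "montage": BENCHMARK_MONTAGE,
        "stimulus_onset_s": 0.5,  # cue precedes flicker in each trial
        "vocabulary": StimulusVocabulary.benchmark40,
    },
    "ucsd12": {
        "sampling_rate": 256.0,
        "montage": OCCIPITAL_CHANNELS,
        "stimulus_onset_s": 0.5,
        "vocabulary": StimulusVocabulary.ucsd12,
    },
}


@dataclass(frozen=True)
class DatasetManifest:
    """How to cut epochs out of a stored subject file.

    Parameters
    ----------
    layout : {"benchmark40", "ucsd12"}
    channel_subset : list of str
        Channels to keep, in order; defaults to the occipital eight.
    latency_offset : float, seconds
        Visual-pathway delay between flicker onset and the analysis
        window (0.14 s default).
    epoch_window : (start, length), seconds
        Window relative to onset + latency.
    stimulus_onset_s : float or None
        Seconds of pre-flicker data stored at the start of each trial;
        None takes the layout default.
    """

    layout: str
    channel_subset: tuple = tuple(OCCIPITAL_CHANNELS)
    latency_offset: float = 0.14
    epoch_window: tuple = (0.0, 1.0)
    stimulus_onset_s: float = None

    def __post_init__(self):
        if self.layout not in _LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        montage = _LAYOUTS[self.layout]["montage"]
        missing = [c for c in self.channel_subset if c not in montage]
        if missing:
            raise ValueError(
                f"channels {missing} not in the {self.layout} montage"
            )

    @property
    def sampling_rate(self) -> float:
        return _LAYOUTS[self.layout]["sampling_rate"]

    @property
    def onset_s(self) -> float:
        if self.stimulus_onset_s is not None:
            return self.stimulus_onset_s
        return _LAYOUTS[self.layout]["stimulus_onset_s"]

    def channel_indices(self) -> list:
        montage = _LAYOUTS[self.layout]["montage"]
        return [montage.index(c) for c in self.channel_subset]

    def sample_slice(self, n_samples_available: int) -> slice:
        fs = self.sampling_rate
        start = int(round((self.onset_s + self.latency_offset
                           + self.epoch_window[0]) * fs))
        length = int(round(self.epoch_window[1] * fs))
        if start + length > n_samples_available:
            raise ValueError(
                f"epoch window needs samples [{start}, {start + length}) but "
                f"file holds only {n_samples_available} samples per trial"
            )
        return slice(start, start + length)

    def vocabulary(self) -> StimulusVocabulary:
        return _LAYOUTS[self.layout]["vocabulary"]()


def _load_mat_array(path, key: str) -> np.ndarray:
    """Read one array from a .mat file, v5 or v7.3 (HDF5) dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    if h5py.is_hdf5(path):
        # MATLAB v7.3 = HDF5, stored column-major; h5py yields the
        # transposed axis order
        with h5py.File(path, "r") as f:
            if key not in f:
                raise ValueError(f"dataset file {path} has no variable {key!r}")
            return np.asarray(f[key], dtype=float).T
    mat = loadmat(path)
    if key not in mat:
        raise ValueError(f"dataset file {path} has no variable {key!r}")
    return np.asarray(mat[key], dtype=float)


def read_benchmark_subject(path, manifest: DatasetManifest) -> list:
    """Read one benchmark-layout subject into a trial stream.

    The file must hold ``data`` shaped (channels, samples, targets,
    blocks).  Returns ``[(EEGEpoch, true_label, block_index), ...]``
    ordered by block, every target once per block.
    """
    if manifest.layout != "benchmark40":
        raise ValueError("manifest layout must be 'benchmark40'")
    data = _load_mat_array(path, "data")
    if data.ndim != 4:
        raise ValueError(
            f"benchmark layout expects a 4-D array (channels x samples x "
            f"targets x blocks), got shape {data.shape}"
        )
    chans = manifest.channel_indices()
    window = manifest.sample_slice(data.shape[1])
    stream = []
    for block in range(data.shape[3]):
        for target in range(data.shape[2]):
            cut = data[chans, window, target, block]
            stream.append(
                (EEGEpoch(cut, manifest.sampling_rate,
                          channel_names=list(manifest.channel_subset)),
                 target, block)
            )
    return stream


def read_ucsd_subject(path, manifest: DatasetManifest) -> list:
    """Read one 12-target-layout subject into a trial stream.

    The file must hold ``eeg`` shaped (targets, channels, samples,
    runs); a run plays the role of a block.
    """
    if manifest.layout != "ucsd12":
        raise ValueError("manifest layout must be 'ucsd12'")
    eeg = _load_mat_array(path, "eeg")
    if eeg.ndim != 4:
        raise ValueError(
            f"ucsd layout expects a 4-D array (targets x channels x samples "
            f"x runs), got shape {eeg.shape}"
        )
    chans = manifest.channel_indices()
    window = manifest.sample_slice(eeg.shape[2])
    stream = []
    for run in range(eeg.shape[3]):
        for target in range(eeg.shape[0]):
            cut = eeg[target, chans, window, run]
            stream.append(
                (EEGEpoch(cut, manifest.sampling_rate,
                          channel_names=list(manifest.channel_subset)),
                 target, run)
            )
    return stream


def write_benchmark_mat(path, data: np.ndarray) -> None:
    """Write a (channels x samples x targets x blocks) array as ``data``."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("benchmark layout needs a 4-D array")
    savemat(path, {"data": data}, do_compression=True)


def write_ucsd_mat(path, eeg: np.ndarray) -> None:
    """Write a (targets x channels x samples x runs) array as ``eeg``."""
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 4:
        raise ValueError("ucsd layout needs a 4-D array")
    savemat(path, {"eeg": eeg}, do_compression=True)
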