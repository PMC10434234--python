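"""Sinusoidal harmonic reference matrices for CCA-based SSVEP decoding.

A reference matrix for stimulus frequency ``f`` stacks cosine and sine
rows at the fundamental and its harmonics,

    Y_f = [cos(2*pi*f*t); sin(2*pi*f*t); ...;
           cos(2*pi*k*f*t); sin(2*pi*k*f*t)],   t = 1/fs, ..., Ns/fs,

where ``k`` is the number of harmonics, ``fs`` the sampling rate and
``Ns`` the number of samples.  The time axis starts at ``1/fs`` (not 0)
for bit-reproducibility of the standard construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["StimulusVocabulary", "ReferenceSet", "make_reference"]


@dataclass(frozen=True)
class StimulusVocabulary:
    """Ordered set of stimulus target frequencies (and optional phases).

    Parameters
    ----------
    frequencies : sequence of float
        Stimulus frequencies in Hz; non-empty, strictly positive, distinct.
    phases : sequence of float, optional
        Initial phases in radians, one per frequency.  Phases are used by
        the synthetic generator only; references carry no phase term.
    """

    frequencies: tuple[float, ...]
    phases: tuple[float, ...] | None = None

    def __init__(self, frequencies, phases=None):
        freqs = tuple(float(f) for f in frequencies)
        if len(freqs) == 0:
            raise ValueError("vocabulary needs at least one frequency")
        if any(f <= 0 for f in freqs):
            raise ValueError("all stimulus frequencies must be > 0 Hz")
        if len(set(freqs)) != len(freqs):
            raise ValueError("stimulus frequencies must be distinct")
        if phases is not None:
            phases = tuple(float(p) for p in phases)
            if len(phases) != len(freqs):
                raise ValueError(
                    f"phases length {len(phases)} != frequencies length {len(freqs)}"
                )
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "phases", phases)

    def __len__(self) -> int:
        return len(self.frequencies)

    @classmethod
    def benchmark40(cls) -> "StimulusVocabulary":
        """40-target keyboard vocabulary: 8-15.8 Hz in 0.2 Hz steps."""
        freqs = [round(8.0 + 0.2 * i, 10) for i in range(40)]
        phases = [(0.5 * np.pi * i) % (2 * np.pi) for i in range(40)]
        return cls(freqs, phases)

    @classmethod
    def ucsd12(cls) -> "StimulusVocabulary":
        """12-target vocabulary: f0 = 9.25 Hz, step 0.5 Hz, phase step 0.5*pi."""
        freqs = [9.25 + 0.5 * i for i in range(12)]
        phases = [(0.5 * np.pi * i) % (2 * np.pi) for i in range(12)]
        return cls(freqs, phases)

    @classmethod
    def from_json(cls, path) -> "StimulusVocabulary":
        spec = json.loads(Path(path).read_text())
        return cls(spec["frequencies"], spec.get("phases"))

    def to_json(self, path) -> None:
        spec = {"frequencies": list(self.frequencies)}
        if self.phases is not None:
            spec["phases"] = list(self.phases)
        Path(path).write_text(json.dumps(spec, indent=2))


def make_reference(
    frequency: float,
    n_harmonics: int,
    sampling_rate: float,
    n_samples: int,
) -> np.ndarray:
    """Build the harmonic sin/cos reference matrix for one frequency.

    Parameters
    ----------
    frequency : float
        Stimulus frequency in Hz (> 0).
    n_harmonics : int
        Number of harmonics ``k`` (>= 1); the fundamental counts as the
        first harmonic.
    sampling_rate : float
        Sampling rate in Hz.
    n_samples : int
        Number of time samples ``Ns`` (>= 1).

    Returns
    -------
    ndarray of shape (2 * n_harmonics, n_samples)
        Row ``2j`` is cos at harmonic ``j+1``, row ``2j+1`` is sin, with
        the time axis ``t = 1/fs, ..., Ns/fs``.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be > 0 Hz, got {frequency}")
    if n_harmonics < 1:
        raise ValueError(f"n_harmonics must be >= 1, got {n_harmonics}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be > 0 Hz, got {sampling_rate}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if n_harmonics * frequency >= sampling_rate / 2:
        warnings.warn(
            f"harmonic {n_harmonics} of {frequency} Hz is at or above the "
            f"Nyquist frequency {sampling_rate / 2} Hz; aliased rows follow",
            RuntimeWarning,
            stacklevel=2,
        )
    t = np.arange(1, n_samples + 1) / sampling_rate
    rows = np.empty((2 * n_harmonics, n_samples))
    for j in range(1, n_harmonics + 1):
        arg = 2.0 * np.pi * j * frequency * t
        rows[2 * (j - 1)] = np.cos(arg)
        rows[2 * (j - 1) + 1] = np.sin(arg)
    return rows


@dataclass
class ReferenceSet:
    """Per-frequency harmonic reference matrices for a vocabulary.

    Attributes
    ----------
    vocabulary : StimulusVocabulary
    n_harmonics : int
    sampling_rate : float
    n_samples : int
    matrices : list of ndarray
        One ``(2 * n_harmonics, n_samples)`` matrix per vocabulary entry.
    """

    vocabulary: StimulusVocabulary
    n_harmonics: int
    sampling_rate: float
    n_samples: int
    matrices: list = field(init=False)

    def __post_init__(self):
        self.matrices = [
            make_reference(f, self.n_harmonics, self.sampling_rate, self.n_samples)
            for f in self.vocabulary.frequencies
        ]

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.matrices[i]
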