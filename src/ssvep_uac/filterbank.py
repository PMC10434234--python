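"""Sub-band filter bank for FBCCA.

Decomposes an epoch into D band-pass filtered copies.  Each sub-band d
keeps [8*d, 88] Hz by default, so successive bands drop the lowest
harmonic while keeping the upper harmonics — the standard filter-bank
design for SSVEP, where sub-band d isolates harmonic content from the
d-th harmonic upward.  Filters are Chebyshev type-I band-passes applied
forward-backward (zero phase), which keeps filtering linear and
delay-free; both properties matter because the adaptive classifier
superimposes signals and filtering must commute with superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["FilterBankSpec", "apply_filter_bank", "default_filter_bank"]


@dataclass(frozen=True)
class FilterBankSpec:
    """Design of the D-band analysis filter bank.

    Parameters
    ----------
    band_edges : tuple of (low, high) pairs, Hz
        Passband edges per sub-band; each 0 < low < high < Nyquist of
        the signal it is applied to, with non-decreasing low edges.
    order : int
        Chebyshev type-I design order (per band-pass prototype).
    ripple_db : float
        Passband ripple in dB.
    pad_factor : int
        Mirror-padding length used by the zero-phase pass is
        ``pad_factor * (order + 1)`` samples.
    """

    band_edges: tuple
    order: int = 4
    ripple_db: float = 0.5
    pad_factor: int = 3

    def __post_init__(self):
        edges = tuple((float(lo), float(hi)) for lo, hi in self.band_edges)
        if len(edges) < 1:
            raise ValueError("filter bank needs at least one band")
        lows = [lo for lo, _ in edges]
        for d, (lo, hi) in enumerate(edges, start=1):
            if not (0 < lo < hi):
                raise ValueError(f"band {d}: need 0 < low < high, got ({lo}, {hi})")
        if lows != sorted(lows):
            raise ValueError("band low edges must be non-decreasing")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        object.__setattr__(self, "band_edges", edges)

    @property
    def n_subbands(self) -> int:
        return len(self.band_edges)

    @property
    def pad_len(self) -> int:
        return self.pad_factor * (self.order + 1)

    def to_dict(self) -> dict:
        return {
            "band_edges": [list(b) for b in self.band_edges],
            "order": self.order,
            "ripple_db": self.ripple_db,
            "pad_factor": self.pad_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBankSpec":
        return cls(
            band_edges=tuple(tuple(b) for b in d["band_edges"]),
            order=d.get("order", 4),
            ripple_db=d.get("ripple_db", 0.5),
            pad_factor=d.get("pad_factor", 3),
        )


def default_filter_bank(n_subbands: int, low_step: float = 8.0,
                        high: float = 88.0) -> FilterBankSpec:
    """Standard SSVEP bank: sub-band d passes [low_step * d, high] Hz."""
    if n_subbands < 1:
        raise ValueError("n_subbands must be >= 1")
    edges = tuple((low_step * d, high) for d in range(1, n_subbands + 1))
    return FilterBankSpec(band_edges=edges)


def _design_sos(spec: FilterBankSpec, band: tuple, fs: float) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(
            f"band ({lo}, {hi}) Hz: high edge must be below Nyquist {nyq} Hz"
        )
    return sps.cheby1(spec.order, spec.ripple_db, [lo, hi], btype="bandpass",
                      fs=fs, output="sos")


def apply_filter_bank(data: np.ndarray, spec: FilterBankSpec,
                      sampling_rate: float) -> list:
    """Filter a (channels x samples) array through every sub-band.

    Returns a list of D arrays, each the same shape as the input,
    filtered zero-phase (forward-backward with mirrored-edge padding).
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n = x.shape[-1]
    if n <= 3 * spec.order:
        raise ValueError(
            f"epoch of {n} samples is too short for an order-{spec.order} filter"
        )
    out = []
    for band in spec.band_edges:
        sos = _design_sos(spec, band, sampling_rate)
        out.append(
            sps.sosfiltfilt(sos, x, axis=-1, padtype="even",
                            padlen=min(spec.pad_len, n - 1))
        )
    return out
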