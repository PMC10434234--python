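"""Canonical correlation kernel for SSVEP decoding.

Computes the maximal canonical correlation

    rho = max_{w_X, w_Y} corr(w_X' X, w_Y' Y)

between a multichannel EEG epoch and a reference matrix.  The solver
centers each variable set, orthonormalizes both with an SVD (with
effective-rank truncation so flat channels cannot crash decoding), and
takes the largest singular value of the cross-product of the two
orthonormal bases.  This is numerically stabler than explicit
covariance inversion; tests validate it against a brute-force
covariance-eigendecomposition oracle.

All internal math uses variables-in-rows, samples-in-columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGEpoch", "max_canonical_correlation"]

# singular values below RANK_RTOL * sigma_max are treated as zero
RANK_RTOL = 1e-10


@dataclass
class EEGEpoch:
    """One trial's multichannel time series with sampling metadata.

    Parameters
    ----------
    data : ndarray
        Signal in microvolts.  Interpreted per ``orientation``.
    sampling_rate : float
        Sampling rate in Hz (> 0).
    channel_names : sequence of str, optional
        Ordered channel labels; defaults to ``ch0, ch1, ...``.
    orientation : {"channels_x_samples", "samples_x_channels"}
        Explicit layout of ``data``; never guessed from shape.  Stored
        internally as channels x samples.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list = None
    orientation: str = "channels_x_samples"

    def __post_init__(self):
        a = np.asarray(self.data, dtype=float)
        if a.ndim != 2:
            raise ValueError(f"epoch data must be 2-D, got shape {a.shape}")
        if self.orientation == "samples_x_channels":
            a = a.T
        elif self.orientation != "channels_x_samples":
            raise ValueError(f"unknown orientation {self.orientation!r}")
        self.orientation = "channels_x_samples"
        if a.shape[0] < 1 or a.shape[1] < 2:
            raise ValueError(
                f"epoch needs >= 1 channel and >= 2 samples, got {a.shape}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("epoch data contains NaN or Inf")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.data = a
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(a.shape[0])]
        elif len(self.channel_names) != a.shape[0]:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _orthonormal_rows(a: np.ndarray) -> np.ndarray:
    """Centered orthonormal basis (rows) of the row space of ``a``.

    Rows with effectively zero variance are dropped via singular-value
    truncation at ``RANK_RTOL * sigma_max``.
    """
    a = a - a.mean(axis=1, keepdims=True)
    # SVD of the (variables x samples) matrix: right singular vectors
    # spanning the sample-space are the orthonormal time courses.
    u, s, vt = np.linalg.svd(a, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.empty((0, a.shape[1]))
    keep = s > RANK_RTOL * s[0]
    return vt[keep]


def max_canonical_correlation(epoch_data: np.ndarray, reference: np.ndarray) -> float:
    """Largest canonical correlation between two variable sets.

    Parameters
    ----------
    epoch_data : ndarray, shape (n_channels, n_samples)
        Multichannel signal, variables in rows.
    reference : ndarray, shape (n_reference_rows, n_samples)
        Reference variable set sharing the samples axis.

    Returns
    -------
    float
        rho in [0, 1]; the maximum over projection vectors w_X, w_Y of
        the correlation between w_X' X and w_Y' Y.  Both sets are
        centered internally.  Degenerate (zero-variance) inputs give 0.
    """
    x = np.atleast_2d(np.asarray(epoch_data, dtype=float))
    y = np.atleast_2d(np.asarray(reference, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError(
            f"sample counts differ: epoch has {x.shape[1]}, reference {y.shape[1]}"
        )
    qx = _orthonormal_rows(x)
    qy = _orthonormal_rows(y)
    if qx.shape[0] == 0 or qy.shape[0] == 0:
        return 0.0
    s = np.linalg.svd(qx @ qy.T, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))
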