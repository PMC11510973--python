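"""Weighted phase lag index (WPLI) functional connectivity.

For two band-limited series x(t), y(t) with analytic signals a_x, a_y,
the instantaneous cross-spectrum is S(t) = a_x(t) conj(a_y(t)) and

    WPLI = |E[Im S]| / E[|Im S|]        (Vinck et al., 2011)

taken over time samples within one segment.  WPLI lies in [0, 1], is
insensitive to zero-lag (volume-conduction) coupling, and reaches 1 when
the imaginary cross-spectrum keeps a constant sign — e.g. a constant
phase lag.  When E[|Im S|] vanishes (no imaginary coupling) the index is
defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import Recording

#: below this mean |Im S| the 0/0 convention applies and WPLI is 0
EPS_DENOM = 1e-12

#: fraction of samples trimmed from each edge before averaging, to drop
#: Hilbert-transform edge effects
EDGE_TRIM_FRACTION = 0.05

MIN_SAMPLES = 64


class ConnectivityError(ValueError):
    """Raised on invalid connectivity inputs."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric WPLI matrix over channels, zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    band: str
    segment_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        n = len(self.channel_names)
        if v.shape != (n, n):
            raise ConnectivityError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T):
            raise ConnectivityError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ConnectivityError("diagonal must be exactly zero")
        if v.min() < 0 or v.max() > 1:
            raise ConnectivityError("WPLI entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ConnectivityError("expected 1-D channel series")
    if len(x) != len(y):
        raise ConnectivityError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < MIN_SAMPLES:
        raise ConnectivityError(f"need >= {MIN_SAMPLES} samples, got {len(x)}")
    return x, y


def _trim(n: int) -> slice:
    k = int(np.floor(EDGE_TRIM_FRACTION * n))
    return slice(k, n - k if k else n)


def cross_spectrum_series(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Instantaneous cross-spectrum S(t) = a_x(t) conj(a_y(t)), edges trimmed."""
    x, y = _check_pair(x, y)
    s = hilbert(x) * np.conj(hilbert(y))
    return s[_trim(len(s))]


def _wpli_from_im(im: np.ndarray) -> float:
    denom = np.mean(np.abs(im))
    if denom < EPS_DENOM:
        return 0.0
    return float(np.abs(np.mean(im)) / denom)


def wpli(x: np.ndarray, y: np.ndarray, epoch_len: int | None = None) -> float:
    """WPLI of one channel pair.

    ``epoch_len`` switches to the epoch-averaged estimator: the series is
    split into non-overlapping epochs of that many samples, the analytic
    signal is computed per epoch (edges trimmed per epoch), and the
    expectations are pooled over all epoch samples.
    """
    x, y = _check_pair(x, y)
    if epoch_len is None:
        return _wpli_from_im(cross_spectrum_series(x, y).imag)
    if epoch_len < MIN_SAMPLES:
        raise ConnectivityError(f"epoch_len must be >= {MIN_SAMPLES}")
    n_epochs = len(x) // epoch_len
    if n_epochs == 0:
        raise ConnectivityError("series shorter than one epoch")
    ims = [cross_spectrum_series(x[i * epoch_len:(i + 1) * epoch_len],
                                 y[i * epoch_len:(i + 1) * epoch_len]).imag
           for i in range(n_epochs)]
    return _wpli_from_im(np.concatenate(ims))


def wpli_matrix(rec: Recording, band: str | None = None,
                segment_id: str | None = None,
                epoch_len: int | None = None) -> ConnectivityMatrix:
    """All-pairs WPLI of a band-limited multichannel recording."""
    n = rec.n_channels
    if n < 2:
        raise ConnectivityError("need at least two channels")
    if rec.n_samples < MIN_SAMPLES:
        raise ConnectivityError(f"need >= {MIN_SAMPLES} samples")

    if epoch_len is None:
        analytic = hilbert(rec.samples, axis=-1)[:, _trim(rec.n_samples)]
        blocks = [analytic]
    else:
        n_epochs = rec.n_samples // epoch_len
        if n_epochs == 0:
            raise ConnectivityError("recording shorter than one epoch")
        blocks = []
        for e in range(n_epochs):
            seg = rec.samples[:, e * epoch_len:(e + 1) * epoch_len]
            blocks.append(hilbert(seg, axis=-1)[:, _trim(epoch_len)])

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            im = np.concatenate([(b[i] * np.conj(b[j])).imag for b in blocks])
            out[i, j] = out[j, i] = _wpli_from_im(im)
    band_name = band if band is not None else \
        ("COE" if rec.modality == "COE" else rec.modality)
    return ConnectivityMatrix(out, rec.channel_names, band_name, segment_id)
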