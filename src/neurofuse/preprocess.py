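"""Recordings, filtering, sub-band decomposition, cerebral oxygen exchange and labels.

The preprocessing chain mirrors a standard portable EEG/fNIRS protocol:
EEG (14-channel 10-20 frontal/temporal/parietal/occipital montage, 128 Hz)
is band-pass filtered 0.5-45 Hz and decomposed into the four classical
rhythms delta/theta/alpha/beta; fNIRS oxy-/deoxy-hemoglobin series
(6 prefrontal channels, 10 Hz) are band-pass filtered in the slow
hemodynamic range and combined into the cerebral oxygen exchange

    dCOE = dC_HbR - dC_HbO

which summarises oxygenation change per channel.  Segments are labelled
from the 6-point Fast Motion Sickness (FMS) self-report: a score of 1 is
the non-motion-sickness state (label 0), any score above 1 is motion
sickness (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import signal

#: canonical 14-channel montage, in device order
EEG_MONTAGE: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: six prefrontal fNIRS channels; 1/5 left, 3/2 midline, 4/6 right
FNIRS_CHANNELS: tuple[str, ...] = ("Ch1", "Ch2", "Ch3", "Ch4", "Ch5", "Ch6")

#: EEG rhythm bands in Hz.  The delta band nominally starts at 0 Hz but the
#: global 0.5 Hz high-pass makes 0.5 Hz the effective lower edge.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 32.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: broadband EEG filter (Hz)
EEG_BROADBAND: tuple[float, float] = (0.5, 45.0)

#: default fNIRS band-pass (Hz); keeps slow hemodynamics, rejects cardiac
#: and instrument noise
FNIRS_BAND: tuple[float, float] = (0.01, 0.2)

MODALITIES = ("EEG", "HBO", "HBR", "COE")


class PreprocessError(ValueError):
    """Raised on malformed recordings or invalid preprocessing requests."""


@dataclass(frozen=True)
class Recording:
    """A multichannel time series.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` float array.
    fs
        Sampling rate in Hz.
    channel_names
        One name per row of ``samples``.
    modality
        One of ``EEG``, ``HBO``, ``HBR``, ``COE``.
    t0
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    modality: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if samples.ndim != 2:
            raise PreprocessError("samples must be a 2-D (channels x time) array")
        if len(self.channel_names) != samples.shape[0]:
            raise PreprocessError(
                f"{len(self.channel_names)} channel names for "
                f"{samples.shape[0]} rows"
            )
        if not self.fs > 0:
            raise PreprocessError("sampling rate must be positive")
        if self.modality not in MODALITIES:
            raise PreprocessError(f"unknown modality {self.modality!r}")
        if np.isnan(samples).any():
            raise PreprocessError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise PreprocessError(f"no channel named {name!r}") from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray, modality: str | None = None) -> "Recording":
        return replace(self, samples=samples,
                       modality=self.modality if modality is None else modality)


# ---------------------------------------------------------------------------
# I/O

def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as CSV: a ``time`` column then one column per channel."""
    t = rec.t0 + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for name, row in zip(rec.channel_names, rec.samples):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.10g")


def _read_csv(path: Path, modality: str) -> Recording:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise PreprocessError(f"{path}: need a time column plus >= 1 channel")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise PreprocessError(f"{path}: fewer than two samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        bad = int(np.argmax(np.abs(dt - dt[0]) > 1e-6)) + 2
        raise PreprocessError(f"{path}: non-uniform time grid near row {bad}")
    fs = 1.0 / dt[0]
    names = [str(c) for c in df.columns[1:]]
    data = df.iloc[:, 1:].to_numpy(dtype=float).T
    if df.iloc[:, 1:].isna().any().any():
        raise PreprocessError(f"{path}: missing values in channel columns")
    rec = Recording(data, fs, tuple(names), modality, t0=float(t[0]))
    return _canonical_order(rec)


def _read_edf(path: Path, modality: str) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne scales assumed-microvolt EDF channels to volts; undo it so the
    # array matches the physical values stored in the file
    data = raw.get_data() * 1e6
    rec = Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names),
                    modality)
    return _canonical_order(rec)


def _canonical_order(rec: Recording) -> Recording:
    """Reorder full-montage recordings into canonical channel order."""
    canon: tuple[str, ...] | None = None
    if rec.modality == "EEG" and set(rec.channel_names) == set(EEG_MONTAGE):
        canon = EEG_MONTAGE
    elif rec.modality in ("HBO", "HBR", "COE") and \
            set(rec.channel_names) == set(FNIRS_CHANNELS):
        canon = FNIRS_CHANNELS
    if canon is None or rec.channel_names == canon:
        return rec
    order = [rec.channel_names.index(c) for c in canon]
    return Recording(rec.samples[order], rec.fs, canon, rec.modality, rec.t0)


def read_recording(path: str | Path, modality: str, dialect: str = "csv") -> Recording:
    """Read a recording from CSV (time column + channels) or EDF.

    EEG recordings carrying the full 14-channel montage (and fNIRS ones
    carrying all six channels) are reordered into canonical channel order
    regardless of column order on disk.
    """
    path = Path(path)
    if not path.exists():
        raise PreprocessError(f"no such file: {path}")
    if dialect == "csv":
        return _read_csv(path, modality)
    if dialect == "edf":
        return _read_edf(path, modality)
    raise PreprocessError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# filtering

def _design_sos(low: float, high: float, fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not (0 <= low < high):
        raise PreprocessError(f"invalid band ({low}, {high})")
    if high >= nyq:
        raise PreprocessError(
            f"band edge {high} Hz is at or above Nyquist ({nyq} Hz)")
    if low == 0:
        return signal.butter(order, high, btype="lowpass", fs=fs, output="sos")
    return signal.butter(order, (low, high), btype="bandpass", fs=fs,
                         output="sos")


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, order ``order``)."""
    sos = _design_sos(low, high, rec.fs, order)
    out = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return rec.with_samples(out)


def decompose_bands(eeg: Recording,
                    bands: Mapping[str, tuple[float, float]] = BANDS,
                    order: int = 4) -> dict[str, Recording]:
    """Split a broadband EEG recording into rhythm-band recordings."""
    if eeg.modality != "EEG":
        raise PreprocessError("band decomposition is defined for EEG input")
    return {name: bandpass(eeg, lo, hi, order=order)
            for name, (lo, hi) in bands.items()}


# ---------------------------------------------------------------------------
# fNIRS

def compute_coe(hbo: Recording, hbr: Recording) -> Recording:
    """Cerebral oxygen exchange: dCOE = dC_HbR - dC_HbO, samplewise."""
    if hbo.modality != "HBO" or hbr.modality != "HBR":
        raise PreprocessError("compute_coe expects an (HBO, HBR) pair")
    if hbo.samples.shape != hbr.samples.shape:
        raise PreprocessError("HbO/HbR shape mismatch")
    if hbo.fs != hbr.fs or hbo.channel_names != hbr.channel_names:
        raise PreprocessError("HbO/HbR sampling rate or channels differ")
    return Recording(hbr.samples - hbo.samples, hbo.fs, hbo.channel_names,
                     "COE", hbo.t0)


# ---------------------------------------------------------------------------
# labels and hooks

def label_segment(fms_score: int) -> int:
    """Map an FMS score (1..6) to a class label: 0 = no motion sickness."""
    score = int(fms_score)
    if score != fms_score or not 1 <= score <= 6:
        raise PreprocessError(f"FMS score must be an integer in 1..6, got {fms_score!r}")
    return 0 if score == 1 else 1


def artifact_hook(rec: Recording,
                  method: Callable[[np.ndarray], np.ndarray] | None = None) -> Recording:
    """Slot for artifact removal (ICA, motion-artifact correction).

    ``method=None`` is the identity; a callable must preserve the
    (channels x samples) shape.  Synthetic data carries no artifacts so the
    default pipeline runs with the identity hook.
    """
    if method is None:
        return rec
    out = np.asarray(method(rec.samples), dtype=float)
    if out.shape != rec.samples.shape:
        raise PreprocessError(
            f"artifact hook changed shape {rec.samples.shape} -> {out.shape}")
    return rec.with_samples(out)
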