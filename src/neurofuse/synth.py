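"""Synthetic EEG + fNIRS segments with planted phase-lag coupling.

The generator emulates the study conditions of a real-vehicle motion-
sickness recording: 5-minute segments, 14-channel EEG at 128 Hz with
rhythm-band oscillations, 6-channel prefrontal fNIRS at 10 Hz, and two
states (non-motion-sickness, NM, and motion-sickness, MS) that differ in
their coupling topology.  Each coupled channel pair shares a narrow-band
oscillation: the follower carries a constant-phase-lagged copy of the
leader's band component, mixed in proportion to the coupling strength.
A lagged copy has a constant-sign imaginary cross-spectrum, so the
weighted phase lag index of a strength-1 pair approaches 1 while
independent channels stay near the noise floor — the planted structure is
analytically recoverable by the connectivity stage.

Default topologies follow the qualitative physiology the pipeline is
meant to detect: prefrontal fNIRS coupling is denser in MS than NM, while
beta-band EEG coupling weakens in MS; theta-band coupling is shared by
both states as a non-discriminative control.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .preprocess import (
    BANDS,
    EEG_MONTAGE,
    FNIRS_CHANNELS,
    Recording,
    label_segment,
    write_recording_csv,
)

#: fNIRS oscillators live in the slow hemodynamic range (Hz)
FNIRS_OSC_BAND: tuple[float, float] = (0.01, 0.1)

#: per-band amplitudes (arbitrary units), roughly 1/f across rhythms
BAND_AMPLITUDES: dict[str, float] = {
    "delta": 1.0, "theta": 0.8, "alpha": 0.7, "beta": 0.5,
}


class SynthConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class CouplingSpec:
    """One planted coupling: follower copies the leader's band component.

    ``band`` is a rhythm name for EEG couplings or ``"coe"`` for fNIRS
    couplings (planted in the HbO oscillation and inherited by dCOE).
    ``phase_lag`` is in radians, in (-pi, pi]; ``strength`` in [0, 1] is
    the mixing proportion of the lagged copy in the follower.
    """

    leader: str
    follower: str
    band: str
    phase_lag: float
    strength: float

    def validate(self, eeg_channels: tuple[str, ...],
                 fnirs_channels: tuple[str, ...]) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise SynthConfigError(f"coupling strength {self.strength} not in [0, 1]")
        if not -math.pi < self.phase_lag <= math.pi:
            raise SynthConfigError(f"phase lag {self.phase_lag} not in (-pi, pi]")
        if self.band == "coe":
            known = fnirs_channels
        elif self.band in BANDS:
            known = eeg_channels
        else:
            raise SynthConfigError(f"unknown band {self.band!r}")
        for ch in (self.leader, self.follower):
            if ch not in known:
                raise SynthConfigError(
                    f"coupling references unknown channel {ch!r} for band {self.band!r}")
        if self.leader == self.follower:
            raise SynthConfigError("coupling leader and follower must differ")


def _beta_pairs() -> list[tuple[str, str]]:
    return [("F3", "FC5"), ("F4", "FC6"), ("O1", "O2"),
            ("P7", "P8"), ("T7", "T8"), ("AF3", "AF4")]


def default_nm_coupling() -> list[CouplingSpec]:
    """Non-motion-sickness topology: strong beta EEG, sparse prefrontal fNIRS."""
    specs = [CouplingSpec(a, b, "beta", math.pi / 3, 0.85)
             for a, b in _beta_pairs()]
    specs += [CouplingSpec("AF3", "F3", "theta", math.pi / 4, 0.6),
              CouplingSpec("AF4", "F4", "theta", -math.pi / 4, 0.6)]
    specs += [CouplingSpec("Ch1", "Ch5", "coe", math.pi / 3, 0.8)]
    return specs


def default_ms_coupling() -> list[CouplingSpec]:
    """Motion-sickness topology: abolished beta EEG coupling, dense prefrontal fNIRS.

    Long-range beta synchrony is absent in the MS state (its WPLI falls to
    the noise floor, well below the beta threshold), while prefrontal
    hemodynamic coupling densifies; theta coupling is common to both
    states as a non-discriminative control.
    """
    specs = [CouplingSpec("AF3", "F3", "theta", math.pi / 4, 0.6),
             CouplingSpec("AF4", "F4", "theta", -math.pi / 4, 0.6)]
    # hub star around the midline channel: every prefrontal channel shares
    # the hub oscillation at a distinct lag, so all pairs become coupled
    lags = {"Ch1": -2 * math.pi / 5, "Ch3": -math.pi / 5,
            "Ch4": math.pi / 5, "Ch5": 2 * math.pi / 5, "Ch6": 4 * math.pi / 5}
    specs += [CouplingSpec("Ch2", ch, "coe", lag, 0.85)
              for ch, lag in lags.items()]
    return specs


@dataclass(frozen=True)
class SynthConfig:
    """Dataset-level generator configuration.

    Defaults reproduce the study conditions: 61 NM + 75 MS five-minute
    segments, EEG at 128 Hz, fNIRS at 10 Hz.
    """

    n_segments_nm: int = 61
    n_segments_ms: int = 75
    segment_len: float = 300.0
    fs_eeg: float = 128.0
    fs_fnirs: float = 10.0
    coupling_nm: tuple[CouplingSpec, ...] = field(
        default_factory=lambda: tuple(default_nm_coupling()))
    coupling_ms: tuple[CouplingSpec, ...] = field(
        default_factory=lambda: tuple(default_ms_coupling()))
    noise_sd: float = 0.4
    seed: int = 0
    eeg_channels: tuple[str, ...] = EEG_MONTAGE
    fnirs_channels: tuple[str, ...] = FNIRS_CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "coupling_nm", tuple(self.coupling_nm))
        object.__setattr__(self, "coupling_ms", tuple(self.coupling_ms))
        if self.segment_len <= 0 or self.fs_eeg <= 0 or self.fs_fnirs <= 0:
            raise SynthConfigError("segment length and sampling rates must be positive")
        for specs in (self.coupling_nm, self.coupling_ms):
            seen: set[tuple[str, str]] = set()
            for spec in specs:
                spec.validate(tuple(self.eeg_channels),
                              tuple(self.fnirs_channels))
                key = (spec.follower, spec.band)
                if key in seen:
                    raise SynthConfigError(
                        f"channel {spec.follower!r} is a follower twice in "
                        f"band {spec.band!r}; couplings would overwrite")
                seen.add(key)

    def coupling_for(self, state: str) -> tuple[CouplingSpec, ...]:
        if state == "NM":
            return self.coupling_nm
        if state == "MS":
            return self.coupling_ms
        raise SynthConfigError(f"unknown state {state!r} (expected 'NM' or 'MS')")


@dataclass(frozen=True)
class LabeledSegmentPair:
    """One synthetic segment: EEG + fNIRS recordings with an FMS label."""

    eeg: Recording
    fnirs_hbo: Recording
    fnirs_hbr: Recording
    fms_score: int
    label: int
    subject_id: str
    segment_id: str

    def __post_init__(self) -> None:
        if self.label != label_segment(self.fms_score):
            raise SynthConfigError("label inconsistent with FMS score")
        if abs(self.eeg.duration - self.fnirs_hbo.duration) > 1.0 / self.fnirs_hbo.fs:
            raise SynthConfigError("EEG and fNIRS durations differ")


# ---------------------------------------------------------------------------
# signal building blocks

def _narrowband(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], order: int = 4) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (zero-phase Butterworth)."""
    white = rng.standard_normal(n)
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f (pink) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / np.sqrt(np.mean(x ** 2))


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Apply a constant phase lag to a narrow-band signal (analytic rotation)."""
    return np.real(sps.hilbert(x) * np.exp(-1j * lag))


# ---------------------------------------------------------------------------
# segment generators

def gen_eeg_segment(state: str, cfg: SynthConfig, seed: int) -> Recording:
    """Generate one EEG segment for the given state (``"NM"`` or ``"MS"``).

    Each channel is a sum over rhythm bands of narrow-band oscillators
    plus pink noise.  For every coupling in the state's map, the
    follower's band component is replaced by a (1-s)/s mixture of its own
    oscillator and a constant-phase-lagged copy of the leader's *base*
    oscillator (couplings do not chain).  Deterministic given ``seed``.
    """
    couplings = [c for c in cfg.coupling_for(state) if c.band in BANDS]
    rng = np.random.default_rng(seed)
    n = int(round(cfg.segment_len * cfg.fs_eeg))
    channels = tuple(cfg.eeg_channels)

    base: dict[tuple[str, str], np.ndarray] = {}
    for ch in channels:
        for band in BANDS:
            base[(ch, band)] = BAND_AMPLITUDES[band] * _narrowband(
                rng, n, cfg.fs_eeg, BANDS[band])

    comp = dict(base)
    for c in couplings:
        shifted = _phase_shift(base[(c.leader, c.band)], c.phase_lag)
        comp[(c.follower, c.band)] = (
            (1.0 - c.strength) * base[(c.follower, c.band)]
            + c.strength * shifted)

    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        x = sum(comp[(ch, band)] for band in BANDS)
        data[i] = x + cfg.noise_sd * _pink(rng, n)
    return Recording(data, cfg.fs_eeg, channels, "EEG")


def gen_fnirs_segment(state: str, cfg: SynthConfig,
                      seed: int) -> tuple[Recording, Recording]:
    """Generate one (HbO, HbR) fNIRS segment pair for the given state.

    HbO carries slow (0.01-0.1 Hz) oscillators with the state's planted
    couplings; HbR is anti-correlated with HbO plus independent noise and
    a slow drift, so the cerebral oxygen exchange dCOE = HbR - HbO
    inherits the planted coupling.
    """
    couplings = [c for c in cfg.coupling_for(state) if c.band == "coe"]
    rng = np.random.default_rng(seed)
    n = int(round(cfg.segment_len * cfg.fs_fnirs))
    channels = tuple(cfg.fnirs_channels)
    t = np.arange(n) / cfg.fs_fnirs

    base = {ch: _narrowband(rng, n, cfg.fs_fnirs, FNIRS_OSC_BAND)
            for ch in channels}
    comp = dict(base)
    for c in couplings:
        shifted = _phase_shift(base[c.leader], c.phase_lag)
        comp[c.follower] = ((1.0 - c.strength) * base[c.follower]
                            + c.strength * shifted)

    noise = 0.25 * cfg.noise_sd
    hbo = np.empty((len(channels), n))
    hbr = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        osc = comp[ch]
        drift = 0.15 * np.sin(2 * np.pi * 0.003 * t + rng.uniform(0, 2 * np.pi))
        hbo[i] = osc + drift + noise * rng.standard_normal(n)
        hbr[i] = -0.3 * osc + 0.5 * drift + noise * rng.standard_normal(n)
    return (Recording(hbo, cfg.fs_fnirs, channels, "HBO"),
            Recording(hbr, cfg.fs_fnirs, channels, "HBR"))


def gen_dataset(cfg: SynthConfig) -> list[LabeledSegmentPair]:
    """Generate the full labeled dataset (NM segments first, then MS)."""
    if cfg.n_segments_nm < 0 or cfg.n_segments_ms < 0 \
            or cfg.n_segments_nm + cfg.n_segments_ms <= 0:
        raise SynthConfigError("segment counts must be non-negative and sum > 0")
    master = np.random.default_rng(cfg.seed)
    n_total = cfg.n_segments_nm + cfg.n_segments_ms
    seg_seeds = master.integers(0, 2 ** 31 - 1, size=(n_total, 2))
    states = ["NM"] * cfg.n_segments_nm + ["MS"] * cfg.n_segments_ms
    fms = [1] * cfg.n_segments_nm + \
          list(master.integers(2, 7, size=cfg.n_segments_ms))

    pairs = []
    for i, state in enumerate(states):
        eeg = gen_eeg_segment(state, cfg, int(seg_seeds[i, 0]))
        hbo, hbr = gen_fnirs_segment(state, cfg, int(seg_seeds[i, 1]))
        score = int(fms[i])
        pairs.append(LabeledSegmentPair(
            eeg=eeg, fnirs_hbo=hbo, fnirs_hbr=hbr,
            fms_score=score, label=label_segment(score),
            subject_id=f"S{i // 6:02d}", segment_id=f"seg{i:03d}"))
    return pairs


# ---------------------------------------------------------------------------
# on-disk layout: one directory per segment

def write_dataset(pairs: list[LabeledSegmentPair], outdir: str | Path) -> None:
    """Write each segment as eeg.csv / fnirs_hbo.csv / fnirs_hbr.csv + labels.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        seg_dir = outdir / pair.segment_id
        seg_dir.mkdir(exist_ok=True)
        write_recording_csv(pair.eeg, seg_dir / "eeg.csv")
        write_recording_csv(pair.fnirs_hbo, seg_dir / "fnirs_hbo.csv")
        write_recording_csv(pair.fnirs_hbr, seg_dir / "fnirs_hbr.csv")
        meta = {"subject_id": pair.subject_id, "segment_id": pair.segment_id,
                "fms_score": pair.fms_score, "label": pair.label}
        (seg_dir / "labels.json").write_text(json.dumps(meta, indent=1))


def read_dataset(indir: str | Path) -> list[LabeledSegmentPair]:
    """Read a dataset written by :func:`write_dataset`."""
    from .preprocess import read_recording

    indir = Path(indir)
    pairs = []
    for seg_dir in sorted(p for p in indir.iterdir() if p.is_dir()):
        meta = json.loads((seg_dir / "labels.json").read_text())
        pairs.append(LabeledSegmentPair(
            eeg=read_recording(seg_dir / "eeg.csv", "EEG"),
            fnirs_hbo=read_recording(seg_dir / "fnirs_hbo.csv", "HBO"),
            fnirs_hbr=read_recording(seg_dir / "fnirs_hbr.csv", "HBR"),
            fms_score=int(meta["fms_score"]), label=int(meta["label"]),
            subject_id=str(meta["subject_id"]),
            segment_id=str(meta["segment_id"])))
    return pairs
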