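import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurofuse.preprocess import (
    BANDS,
    EEG_MONTAGE,
    PreprocessError,
    Recording,
    artifact_hook,
    bandpass,
    compute_coe,
    decompose_bands,
    label_segment,
    read_recording,
    write_recording_csv,
)

FS = 128.0


def tone(freq, n=int(10 * FS), fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t + phase)


def make_rec(rows, modality="EEG", names=None, fs=FS):
    rows = np.atleast_2d(rows)
    names = names or tuple(f"ch{i}" for i in range(rows.shape[0]))
    return Recording(rows, fs, names, modality)


def band_power_fraction(x, fs, band):
    from scipy.signal import periodogram
    f, p = periodogram(x, fs=fs)
    mask = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[mask], f[mask]) / np.trapezoid(p, f)


# ---------------------------------------------------------------------------
# I/O

def write_edf(path, data, fs, ch_names):
    """Minimal synthetic EDF writer (one data record), for test fixtures only."""
    n_ch, n_samp = data.shape
    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767
    hdr = b"0".ljust(8) + b"X".ljust(80) + b"X".ljust(80)
    hdr += b"01.01.24".ljust(8) + b"00.00.00".ljust(8)
    hdr += str(256 + 256 * n_ch).encode().ljust(8) + b"".ljust(44)
    hdr += b"1".ljust(8) + f"{n_samp / fs:g}".encode().ljust(8)
    hdr += str(n_ch).encode().ljust(4)
    for name in ch_names:
        hdr += name.encode().ljust(16)
    hdr += b"".ljust(80) * n_ch + b"uV".ljust(8) * n_ch
    for v in (phys_min, phys_max):
        hdr += f"{v:g}".encode().ljust(8) * n_ch
    for v in (dig_min, dig_max):
        hdr += str(v).encode().ljust(8) * n_ch
    hdr += b"".ljust(80) * n_ch + str(n_samp).encode().ljust(8) * n_ch
    hdr += b"".ljust(32) * n_ch
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    dig = np.round(data / scale).clip(dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(dig.tobytes())


def test_csv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    rec = make_rec(rng.standard_normal((14, 256)), names=EEG_MONTAGE)
    write_recording_csv(rec, tmp_path / "eeg.csv")
    back = read_recording(tmp_path / "eeg.csv", "EEG")
    assert back.channel_names == EEG_MONTAGE
    assert back.fs == pytest.approx(FS, rel=1e-6)
    np.testing.assert_allclose(back.samples, rec.samples, atol=1e-8)


def test_edf_matches_csv_twin(tmp_path):
    rng = np.random.default_rng(1)
    data = rng.standard_normal((3, 256)) * 50
    names = ("AF3", "F7", "F3")
    rec = Recording(data, FS, names, "EEG")
    write_recording_csv(rec, tmp_path / "a.csv")
    write_edf(tmp_path / "a.edf", data, FS, names)
    from_csv = read_recording(tmp_path / "a.csv", "EEG")
    from_edf = read_recording(tmp_path / "a.edf", "EEG", dialect="edf")
    assert from_edf.channel_names == from_csv.channel_names
    # EDF stores 16-bit integers; agreement up to quantization
    np.testing.assert_allclose(from_edf.samples, from_csv.samples, atol=0.06)


def test_shuffled_csv_columns_reordered_to_montage(tmp_path):
    rng = np.random.default_rng(2)
    rec = make_rec(rng.standard_normal((14, 128)), names=EEG_MONTAGE)
    shuffled = tuple(np.array(EEG_MONTAGE)[rng.permutation(14)])
    shuffled_rec = Recording(
        np.array([rec.channel(c) for c in shuffled]), FS, shuffled, "EEG")
    write_recording_csv(shuffled_rec, tmp_path / "s.csv")
    back = read_recording(tmp_path / "s.csv", "EEG")
    assert back.channel_names == EEG_MONTAGE
    np.testing.assert_allclose(back.samples, rec.samples, atol=1e-8)


def test_non_uniform_time_grid_rejected(tmp_path):
    lines = ["time,a", "0.0,1", "0.1,2", "0.25,3", "0.35,4"]
    (tmp_path / "bad.csv").write_text("\n".join(lines))
    with pytest.raises(PreprocessError, match="non-uniform"):
        read_recording(tmp_path / "bad.csv", "EEG")


# ---------------------------------------------------------------------------
# filtering

def test_bandpass_stopband_matches_designed_response():
    # the oracle is the designed filter's own magnitude response at 50 Hz,
    # squared for the forward-backward application
    from scipy.signal import butter, sosfreqz
    sos = butter(4, (0.5, 45.0), btype="bandpass", fs=FS, output="sos")
    _, h = sosfreqz(sos, worN=[50.0], fs=FS)
    expected = float(np.abs(h[0]) ** 2)

    x50 = tone(50.0, n=int(60 * FS))
    out = bandpass(make_rec(x50), *(0.5, 45.0)).samples[0]
    core = slice(512, -512)
    ratio = np.sqrt(np.mean(out[core]**2)) / np.sqrt(np.mean(x50[core]**2))
    assert ratio == pytest.approx(expected, rel=0.05)
    assert ratio < 0.2  # 50 Hz is clearly attenuated by the 0.5-45 Hz filter


def test_bandpass_passband_preserves_tone():
    x10 = tone(10.0)
    out = bandpass(make_rec(x10), 8.0, 12.0).samples[0]
    core = slice(256, -256)  # ignore filter edge transients
    ratio = np.sqrt(np.mean(out[core]**2)) / np.sqrt(np.mean(x10[core]**2))
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_bandpass_rejects_dc():
    const = np.ones((1, 1024))
    out = bandpass(make_rec(const), 0.5, 45.0).samples
    assert np.abs(out).max() < 1e-6


def test_bandpass_band_outside_nyquist():
    with pytest.raises(PreprocessError, match="Nyquist"):
        bandpass(make_rec(tone(5.0)), 0.5, 70.0)


@given(st.floats(-3, 3), st.floats(-3, 3))
def test_bandpass_linearity(a, b):
    rng = np.random.default_rng(99)
    x = rng.standard_normal(512)
    y = rng.standard_normal(512)
    fx = bandpass(make_rec(x), 4, 8).samples[0]
    fy = bandpass(make_rec(y), 4, 8).samples[0]
    combined = bandpass(make_rec(a * x + b * y), 4, 8).samples[0]
    np.testing.assert_allclose(combined, a * fx + b * fy,
                               rtol=1e-8, atol=1e-10)


def test_bandpass_zero_phase():
    x = tone(10.0)
    y = bandpass(make_rec(x), 8, 12).samples[0]
    core = slice(256, -256)
    lags = np.arange(-20, 21)
    xc = [np.dot(x[core], np.roll(y, lag)[core]) for lag in lags]
    assert lags[int(np.argmax(xc))] == 0


def test_decompose_bands_isolates_tones():
    mix = tone(2.0) + tone(6.0) + tone(10.0) + tone(20.0)
    out = decompose_bands(make_rec(mix))
    assert set(out) == set(BANDS)
    for band, (lo, hi) in BANDS.items():
        frac = band_power_fraction(out[band].samples[0], FS, (lo, hi))
        assert frac > 0.8, f"{band}: only {frac:.2f} of power in band"


def test_decompose_bands_idempotent_per_band():
    rms = lambda v: np.sqrt(np.mean(v**2))
    # band-centred content passes a second filtering unchanged
    rec = make_rec(tone(10.0, n=int(30 * FS)))
    once = decompose_bands(rec)["alpha"]
    twice = bandpass(once, *BANDS["alpha"])
    assert abs(rms(twice.samples) - rms(once.samples)) < 0.01 * rms(once.samples)
    # broadband noise keeps most power (loss only at the soft band edges)
    rng = np.random.default_rng(3)
    noisy = decompose_bands(make_rec(rng.standard_normal(int(30 * FS))))["alpha"]
    again = bandpass(noisy, *BANDS["alpha"])
    assert abs(rms(again.samples) - rms(noisy.samples)) < 0.1 * rms(noisy.samples)


def test_decompose_bands_rejects_non_eeg():
    rec = make_rec(np.zeros((2, 256)), modality="HBO")
    with pytest.raises(PreprocessError):
        decompose_bands(rec)


def test_decompose_silent_input():
    out = decompose_bands(make_rec(np.zeros((2, 512))))
    for band_rec in out.values():
        assert np.all(band_rec.samples == 0)


# ---------------------------------------------------------------------------
# COE, labels, hooks

def test_coe_is_hbr_minus_hbo():
    rng = np.random.default_rng(4)
    hbo = make_rec(rng.standard_normal((6, 100)), modality="HBO")
    hbr = Recording(rng.standard_normal((6, 100)), FS, hbo.channel_names, "HBR")
    coe = compute_coe(hbo, hbr)
    assert coe.modality == "COE"
    np.testing.assert_array_equal(coe.samples, hbr.samples - hbo.samples)

    same = Recording(hbo.samples, FS, hbo.channel_names, "HBR")
    assert np.all(compute_coe(hbo, same).samples == 0)

    const_hbo = make_rec(np.full((2, 50), 0.5), modality="HBO")
    const_hbr = Recording(np.full((2, 50), 2.0), FS,
                          const_hbo.channel_names, "HBR")
    assert np.all(compute_coe(const_hbo, const_hbr).samples == 1.5)


def test_coe_shape_mismatch():
    hbo = make_rec(np.zeros((6, 100)), modality="HBO")
    hbr = Recording(np.zeros((6, 99)), FS, hbo.channel_names, "HBR")
    with pytest.raises(PreprocessError):
        compute_coe(hbo, hbr)


@pytest.mark.parametrize("score,label", [(1, 0), (2, 1), (3, 1), (6, 1)])
def test_fms_labeling(score, label):
    assert label_segment(score) == label


@pytest.mark.parametrize("score", [0, 7, -1])
def test_fms_out_of_range(score):
    with pytest.raises(PreprocessError):
        label_segment(score)


def test_artifact_hook():
    rec = make_rec(np.ones((2, 100)))
    assert artifact_hook(rec) is rec
    np.testing.assert_array_equal(
        artifact_hook(rec, lambda x: x).samples, rec.samples)
    halved = artifact_hook(rec, lambda x: x / 2)
    assert np.sqrt(np.mean(halved.samples**2)) == pytest.approx(
        0.5 * np.sqrt(np.mean(rec.samples**2)))
    with pytest.raises(PreprocessError, match="shape"):
        artifact_hook(rec, lambda x: x[:1])
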