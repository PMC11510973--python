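"""Classifier-ready graph samples: node features, fusion, dataset assembly.

Each 5-minute segment becomes one graph per requested modality.  Nodes
are channels; the adjacency is the binarized WPLI network; every node
carries a 13-dimensional feature vector: nine time/frequency descriptors
of the channel's band-limited signal

    MAV, VAR, Max, Min, RMS, Kurtosis, Skewness,
    total spectral power, relative band power

plus four graph-theoretic descriptors of the node in its network

    degree, clustering coefficient, nodal global efficiency,
    nodal local efficiency.

The fused bimodal sample stacks the 14-node EEG graph and the 6-node
fNIRS graph into a 20-node graph whose adjacency is block-diagonal in
the two unaltered unimodal networks, plus weight-1 "bridge" edges that
connect each prefrontal fNIRS channel to its spatially nearest frontal
EEG electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.signal import periodogram

from . import network as bn
from .connectivity import wpli_matrix
from .network import DEFAULT_THRESHOLDS, BrainNetwork, binarize
from .preprocess import (
    BANDS,
    EEG_BROADBAND,
    FNIRS_BAND,
    Recording,
    bandpass,
    compute_coe,
    decompose_bands,
)
from .synth import FNIRS_OSC_BAND, LabeledSegmentPair

#: names of the 13 node features, in feature-vector order
FEATURE_NAMES: tuple[str, ...] = (
    "mav", "var", "max", "min", "rms", "kurtosis", "skewness",
    "total_power", "rel_band_power",
    "degree", "clustering", "global_efficiency", "local_efficiency",
)

N_FEATURES = len(FEATURE_NAMES)

#: fNIRS channel -> nearest frontal EEG electrodes (left 1/5, midline 3/2,
#: right 4/6 against the 10-20 frontal row)
DEFAULT_BRIDGE_MAP: dict[str, tuple[str, ...]] = {
    "Ch1": ("AF3",),
    "Ch2": ("AF3", "AF4"),
    "Ch3": ("AF3", "AF4"),
    "Ch4": ("AF4",),
    "Ch5": ("F7",),
    "Ch6": ("F8",),
}


class GraphBuildError(ValueError):
    """Raised on inconsistent graph-sample construction."""


@dataclass(frozen=True)
class GraphSample:
    """One graph: features, binary adjacency, names, label, modality tag."""

    node_features: np.ndarray
    adjacency: np.ndarray
    node_names: tuple[str, ...]
    y: int
    modality: str
    segment_id: str | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.node_features, dtype=float)
        a = np.asarray(self.adjacency)
        object.__setattr__(self, "node_features", x)
        object.__setattr__(self, "adjacency", a.astype(int))
        object.__setattr__(self, "node_names", tuple(self.node_names))
        n = len(self.node_names)
        if x.shape[0] != n or a.shape != (n, n):
            raise GraphBuildError("feature/adjacency shapes inconsistent with node names")
        if self.y not in (0, 1):
            raise GraphBuildError("label must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


# ---------------------------------------------------------------------------
# node features

def signal_features(x: np.ndarray, fs: float,
                    band: tuple[float, float] | None = None,
                    total_band: tuple[float, float] | None = None) -> np.ndarray:
    """Nine time/frequency descriptors of one channel series.

    ``band`` is the rhythm band whose relative power is reported;
    ``total_band`` bounds the total-power integral (default: the full
    spectrum).  Kurtosis is excess kurtosis; for a constant signal the
    zero-variance convention sets kurtosis and skewness to 0.
    """
    x = np.asarray(x, dtype=float)
    var = float(np.var(x))
    if var > 0:
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
        skew = float(stats.skew(x, bias=True))
    else:
        kurt = skew = 0.0

    freqs, psd = periodogram(x, fs=fs)
    lo, hi = total_band if total_band is not None else (0.0, fs / 2.0)
    in_total = (freqs >= lo) & (freqs <= hi)
    total_power = float(np.trapezoid(psd[in_total], freqs[in_total]))
    if band is not None and total_power > 0:
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        rel = float(np.trapezoid(psd[in_band], freqs[in_band])) / total_power
    else:
        rel = 1.0 if band is None else 0.0

    return np.array([
        float(np.mean(np.abs(x))),       # MAV
        var,                             # VAR
        float(np.max(x)),                # Max
        float(np.min(x)),                # Min
        float(np.sqrt(np.mean(x ** 2))), # RMS
        kurt,
        skew,
        total_power,
        rel,
    ])


def node_feature_matrix(rec: Recording, net: BrainNetwork,
                        band: tuple[float, float] | None = None,
                        total_band: tuple[float, float] | None = None) -> np.ndarray:
    """Stack the 13 per-node features for every channel of a recording.

    Graph features (degree, clustering, nodal global/local efficiency)
    come from the accompanying binary network; its node order must match
    the recording's channel order.
    """
    if net.channel_names != rec.channel_names:
        raise GraphBuildError("network and recording channel order differ")
    deg = bn.degree(net).astype(float)
    clust, _ = bn.clustering(net)
    _, eglob = bn.global_efficiency(net)
    _, eloc = bn.local_efficiency(net)
    rows = []
    for i in range(rec.n_channels):
        sig = signal_features(rec.samples[i], rec.fs, band=band,
                              total_band=total_band)
        rows.append(np.concatenate([sig, [deg[i], clust[i], eglob[i], eloc[i]]]))
    return np.asarray(rows)


def node_features(rec: Recording, net: BrainNetwork, node: int | str,
                  band: tuple[float, float] | None = None,
                  total_band: tuple[float, float] | None = None) -> np.ndarray:
    """The 13-vector for a single node (by index or channel name)."""
    idx = rec.channel_names.index(node) if isinstance(node, str) else int(node)
    return node_feature_matrix(rec, net, band=band, total_band=total_band)[idx]


# ---------------------------------------------------------------------------
# bimodal fusion

def build_bimodal_graph(eeg_sample: GraphSample, fnirs_sample: GraphSample,
                        bridge_map: Mapping[str, Sequence[str]] | None = None
                        ) -> GraphSample:
    """Stack an EEG and an fNIRS graph of the same segment into one graph.

    The fused adjacency is block-diagonal in the two unaltered unimodal
    adjacencies plus weight-1 bridge edges given by ``bridge_map``
    (fNIRS channel -> EEG channels).  Feature matrices are stacked
    row-wise, EEG nodes first.
    """
    if eeg_sample.y != fnirs_sample.y:
        raise GraphBuildError(
            f"label mismatch between modalities: {eeg_sample.y} vs {fnirs_sample.y}")
    if bridge_map is None:
        bridge_map = DEFAULT_BRIDGE_MAP
    n_e, n_f = eeg_sample.n_nodes, fnirs_sample.n_nodes
    n = n_e + n_f
    adj = np.zeros((n, n), dtype=int)
    adj[:n_e, :n_e] = eeg_sample.adjacency
    adj[n_e:, n_e:] = fnirs_sample.adjacency
    for fch, eeg_chs in bridge_map.items():
        if fch not in fnirs_sample.node_names:
            raise GraphBuildError(f"bridge map references unknown fNIRS channel {fch!r}")
        j = n_e + fnirs_sample.node_names.index(fch)
        for ech in eeg_chs:
            if ech not in eeg_sample.node_names:
                raise GraphBuildError(f"bridge map references unknown EEG channel {ech!r}")
            i = eeg_sample.node_names.index(ech)
            adj[i, j] = adj[j, i] = 1
    feats = np.vstack([eeg_sample.node_features, fnirs_sample.node_features])
    return GraphSample(
        feats, adj, eeg_sample.node_names + fnirs_sample.node_names,
        eeg_sample.y, f"fused:{eeg_sample.modality}",
        eeg_sample.segment_id)


# ---------------------------------------------------------------------------
# dataset assembly

def _fnirs_sample(pair: LabeledSegmentPair, threshold: float) -> GraphSample:
    hbo = bandpass(pair.fnirs_hbo, *FNIRS_BAND)
    hbr = bandpass(pair.fnirs_hbr, *FNIRS_BAND)
    coe = compute_coe(hbo, hbr)
    conn = wpli_matrix(coe, band="COE", segment_id=pair.segment_id)
    net = binarize(conn, threshold)
    feats = node_feature_matrix(coe, net, band=FNIRS_OSC_BAND)
    return GraphSample(feats, net.adjacency, net.channel_names, pair.label,
                       "fNIRS", pair.segment_id)


def _eeg_band_sample(pair: LabeledSegmentPair, band: str,
                     threshold: float) -> GraphSample:
    broadband = bandpass(pair.eeg, *EEG_BROADBAND)
    band_rec = decompose_bands(broadband, bands={band: BANDS[band]})[band]
    conn = wpli_matrix(band_rec, band=band, segment_id=pair.segment_id)
    net = binarize(conn, threshold)
    feats = node_feature_matrix(band_rec, net, band=BANDS[band],
                                total_band=EEG_BROADBAND)
    return GraphSample(feats, net.adjacency, net.channel_names, pair.label,
                       band, pair.segment_id)


def build_dataset(pairs: Iterable[LabeledSegmentPair],
                  modalities: Sequence[str] = ("fused:beta",),
                  thresholds: Mapping[str, float] | None = None,
                  bridge_map: Mapping[str, Sequence[str]] | None = None
                  ) -> list[GraphSample]:
    """Build graph samples for every segment and requested modality.

    ``modalities`` entries are ``"fnirs"``, a rhythm-band name
    (``"delta"`` ... ``"beta"``), or ``"fused:<band>"``.  ``thresholds``
    maps band names (and ``"COE"``) to binarization thresholds; the
    published per-band defaults are used where omitted.  Output order is
    segments (input order) x modalities (given order).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    samples: list[GraphSample] = []
    for pair in pairs:
        cache: dict[str, GraphSample] = {}

        def get(mod: str) -> GraphSample:
            if mod not in cache:
                if mod == "fnirs":
                    cache[mod] = _fnirs_sample(pair, thr["COE"])
                elif mod in BANDS:
                    cache[mod] = _eeg_band_sample(pair, mod, thr[mod])
                else:
                    raise GraphBuildError(f"unknown modality {mod!r}")
            return cache[mod]

        for mod in modalities:
            if mod.startswith("fused:"):
                band = mod.split(":", 1)[1]
                samples.append(build_bimodal_graph(get(band), get("fnirs"),
                                                   bridge_map=bridge_map))
            else:
                samples.append(get(mod))
    return samples


# ---------------------------------------------------------------------------
# serialization

def save_dataset(samples: Sequence[GraphSample], outdir: str | Path) -> None:
    """Write samples as JSON + adjacency TSV with a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["segment_id,modality,label,n_nodes"]
    for i, s in enumerate(samples):
        stem = f"sample{i:04d}"
        payload = {
            "segment_id": s.segment_id, "modality": s.modality,
            "label": s.y, "nodes": list(s.node_names),
            "feature_names": list(FEATURE_NAMES),
            "features": s.node_features.tolist(),
            "edges": [[s.node_names[a], s.node_names[b]]
                      for a, b in zip(*np.triu_indices(s.n_nodes, 1))
                      if s.adjacency[a, b]],
        }
        (outdir / f"{stem}.json").write_text(json.dumps(payload))
        np.savetxt(outdir / f"{stem}.adj.tsv", s.adjacency, fmt="%d",
                   delimiter="\t")
        rows.append(f"{s.segment_id},{s.modality},{s.y},{s.n_nodes}")
    (outdir / "manifest.csv").write_text("\n".join(rows) + "\n")


def load_dataset(indir: str | Path) -> list[GraphSample]:
    indir = Path(indir)
    samples = []
    for path in sorted(indir.glob("sample*.json")):
        d = json.loads(path.read_text())
        names = tuple(d["nodes"])
        n = len(names)
        adj = np.zeros((n, n), dtype=int)
        for a, b in d["edges"]:
            i, j = names.index(a), names.index(b)
            adj[i, j] = adj[j, i] = 1
        samples.append(GraphSample(np.asarray(d["features"]), adj, names,
                                   int(d["label"]), d["modality"],
                                   d["segment_id"]))
    return samples
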