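"""Staged end-to-end pipeline with manifests and reproducible seeding.

Stages (each writes its artifacts plus a ``manifest.json`` under the
working directory and refuses to run before its prerequisites):

    simulate      synthetic labeled EEG+fNIRS segments
    preprocess    filtered dCOE series + segment bookkeeping
    connectivity  per-segment WPLI matrices (per EEG band and dCOE)
    network       binarized brain networks with threshold provenance
    stats         group network metrics + Mann-Whitney comparison table
    dataset       classifier-ready graph samples per modality
    evaluate      stratified cross-validation of the GCN per modality
    report        human-readable summary tables

Band-limited EEG is not materialized on disk between stages (it would
multiply the raw data several-fold); the connectivity and dataset stages
re-derive band signals from the stored segments, which is cheap and keeps
every stage a pure function of the segment directory plus configuration.

One global seed fans out to per-stage seeds through a stable hash of
(seed, stage name), so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import network as bn
from .connectivity import ConnectivityMatrix, wpli_matrix
from .gcn import GCNConfig, evaluate_cv
from .graphs import build_dataset, save_dataset, load_dataset
from .network import (
    DEFAULT_THRESHOLDS,
    ThresholdInfeasibleError,
    binarize,
    select_threshold,
)
from .preprocess import (
    BANDS,
    EEG_BROADBAND,
    FNIRS_BAND,
    bandpass,
    compute_coe,
    decompose_bands,
    read_recording,
    write_recording_csv,
)
from .synth import SynthConfig, gen_dataset, read_dataset, write_dataset

STAGES = ("simulate", "preprocess", "connectivity", "network", "stats",
          "dataset", "train", "evaluate", "report")

PREREQUISITES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "preprocess": ("simulate",),
    "connectivity": ("preprocess",),
    "network": ("connectivity",),
    "stats": ("network",),
    "dataset": ("preprocess",),
    "train": ("dataset",),
    "evaluate": ("dataset",),
    "report": ("stats", "evaluate"),
}


class PipelineError(RuntimeError):
    pass


class PrerequisiteError(PipelineError):
    def __init__(self, stage: str, missing: str):
        super().__init__(
            f"stage {stage!r} needs the output of {missing!r}; "
            f"run `neurofuse {missing}` first")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, in one declarative object."""

    workdir: Path = Path("pipeline-out")
    seed: int = 0
    # simulation
    n_segments_nm: int = 61
    n_segments_ms: int = 75
    segment_len: float = 300.0
    # connectivity / networks
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    thresholds: Mapping[str, float] | str = "default"  # mapping | default | auto
    # classifier
    modalities: tuple[str, ...] = ("fnirs", "beta", "fused:beta")
    folds: int = 10
    gcn: GCNConfig = field(default_factory=GCNConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "workdir", Path(self.workdir))
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "modalities", tuple(self.modalities))
        unknown = [b for b in self.bands if b not in BANDS]
        if unknown:
            raise PipelineError(f"unknown bands {unknown}")
        if isinstance(self.thresholds, Mapping):
            bad = {k: v for k, v in self.thresholds.items()
                   if not 0.0 <= float(v) <= 1.0}
            if bad:
                raise PipelineError(f"thresholds outside [0, 1]: {bad}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML pipeline configuration."""
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    gcn = GCNConfig(**raw.pop("gcn", {}))
    thresholds = raw.pop("thresholds", "default")
    if isinstance(thresholds, dict):
        thresholds = {k: float(v) for k, v in thresholds.items()}
    return PipelineConfig(gcn=gcn, thresholds=thresholds, **raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256 of (seed, stage), below 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, Mapping):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    blob = json.dumps(enc(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    return config.workdir / stage


def _manifest_path(config: PipelineConfig, stage: str) -> Path:
    return _stage_dir(config, stage) / "manifest.json"


def _hash_tree(root: Path) -> str:
    h = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            h.update(path.name.encode())
            h.update(hashlib.sha256(path.read_bytes()).digest())
    return h.hexdigest()[:16]


def _write_manifest(config: PipelineConfig, stage: str) -> None:
    stage_dir = _stage_dir(config, stage)
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "seed": stage_seed(config.seed, stage),
        "inputs": {pre: _hash_tree(_stage_dir(config, pre))
                   for pre in PREREQUISITES[stage]},
        "output_hash": _hash_tree(stage_dir),
    }
    _manifest_path(config, stage).write_text(json.dumps(manifest, indent=1))


def _check_prereqs(config: PipelineConfig, stage: str) -> None:
    for pre in PREREQUISITES[stage]:
        if not _manifest_path(config, pre).exists():
            raise PrerequisiteError(stage, pre)


def _up_to_date(config: PipelineConfig, stage: str) -> bool:
    path = _manifest_path(config, stage)
    if not path.exists():
        return False
    manifest = json.loads(path.read_text())
    if manifest.get("config_hash") != _config_hash(config):
        return False
    for pre in PREREQUISITES[stage]:
        if manifest["inputs"].get(pre) != _hash_tree(_stage_dir(config, pre)):
            return False
    return True


# ---------------------------------------------------------------------------
# stage bodies

def _segments(config: PipelineConfig):
    return read_dataset(_stage_dir(config, "simulate") / "segments")


def _run_simulate(config: PipelineConfig) -> None:
    cfg = SynthConfig(n_segments_nm=config.n_segments_nm,
                      n_segments_ms=config.n_segments_ms,
                      segment_len=config.segment_len,
                      seed=stage_seed(config.seed, "simulate"))
    write_dataset(gen_dataset(cfg), _stage_dir(config, "simulate") / "segments")


def _run_preprocess(config: PipelineConfig) -> None:
    out = _stage_dir(config, "preprocess")
    index = []
    for pair in _segments(config):
        hbo = bandpass(pair.fnirs_hbo, *FNIRS_BAND)
        hbr = bandpass(pair.fnirs_hbr, *FNIRS_BAND)
        coe = compute_coe(hbo, hbr)
        seg_dir = out / pair.segment_id
        seg_dir.mkdir(parents=True, exist_ok=True)
        write_recording_csv(coe, seg_dir / "coe.csv")
        index.append({"segment_id": pair.segment_id, "label": pair.label,
                      "fms_score": pair.fms_score})
    (out / "index.json").write_text(json.dumps(index, indent=1))


def _run_connectivity(config: PipelineConfig) -> None:
    out = _stage_dir(config, "connectivity")
    out.mkdir(parents=True, exist_ok=True)
    for pair in _segments(config):
        broadband = bandpass(pair.eeg, *EEG_BROADBAND)
        band_recs = decompose_bands(
            broadband, bands={b: BANDS[b] for b in config.bands})
        for band, rec in band_recs.items():
            conn = wpli_matrix(rec, band=band, segment_id=pair.segment_id)
            np.savetxt(out / f"{pair.segment_id}_{band}.tsv", conn.values,
                       delimiter="\t", fmt="%.10g")
        coe = read_recording(
            _stage_dir(config, "preprocess") / pair.segment_id / "coe.csv",
            "COE")
        conn = wpli_matrix(coe, band="COE", segment_id=pair.segment_id)
        np.savetxt(out / f"{pair.segment_id}_COE.tsv", conn.values,
                   delimiter="\t", fmt="%.10g")


def _load_conns(config: PipelineConfig, band: str
                ) -> list[tuple[str, ConnectivityMatrix]]:
    from .preprocess import EEG_MONTAGE, FNIRS_CHANNELS

    names = FNIRS_CHANNELS if band == "COE" else EEG_MONTAGE
    conn_dir = _stage_dir(config, "connectivity")
    out = []
    for path in sorted(conn_dir.glob(f"*_{band}.tsv")):
        seg = path.name.rsplit("_", 1)[0]
        values = np.loadtxt(path, delimiter="\t")
        out.append((seg, ConnectivityMatrix(values, names, band, seg)))
    return out


def resolve_thresholds(config: PipelineConfig) -> dict[str, float]:
    """Per-band thresholds: explicit config, published defaults, or auto.

    ``auto`` runs the constrained search (mean degree >= ln N, sigma > 1)
    on the group-average matrix of each band.
    """
    band_keys = [*config.bands, "COE"]
    if config.thresholds == "default":
        return {b: DEFAULT_THRESHOLDS[b] for b in band_keys}
    if config.thresholds == "auto":
        seed = stage_seed(config.seed, "network")
        out = {}
        for band in band_keys:
            conns = [c for _, c in _load_conns(config, band)]
            out[band] = select_threshold(conns, seed=seed).threshold
        return out
    resolved = dict(DEFAULT_THRESHOLDS)
    resolved.update({k: float(v) for k, v in config.thresholds.items()})
    return {b: resolved[b] for b in band_keys}


def _run_network(config: PipelineConfig) -> None:
    out = _stage_dir(config, "network")
    out.mkdir(parents=True, exist_ok=True)
    thresholds = resolve_thresholds(config)
    for band, thr in thresholds.items():
        for seg, conn in _load_conns(config, band):
            net = binarize(conn, thr)
            np.savetxt(out / f"{seg}_{band}.adj.tsv", net.adjacency,
                       fmt="%d", delimiter="\t")
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=1))


def report_networks(config: PipelineConfig) -> dict:
    """Group comparison of network metrics per band (and dCOE).

    For every band, per-segment clustering coefficient, global efficiency
    and local efficiency are compared between the NM and MS groups with a
    Mann-Whitney test; the result is a table shaped like the usual
    NM-vs-MS network-parameter summaries (mean +/- SD with significance
    stars).
    """
    from .preprocess import EEG_MONTAGE, FNIRS_CHANNELS

    index = json.loads(
        (_stage_dir(config, "preprocess") / "index.json").read_text())
    labels = {e["segment_id"]: e["label"] for e in index}
    thresholds = json.loads(
        (_stage_dir(config, "network") / "thresholds.json").read_text())
    net_dir = _stage_dir(config, "network")

    table: dict[str, dict] = {}
    for band, thr in thresholds.items():
        names = FNIRS_CHANNELS if band == "COE" else EEG_MONTAGE
        metrics: dict[str, dict[int, list[float]]] = {
            "clustering": {0: [], 1: []},
            "global_efficiency": {0: [], 1: []},
            "local_efficiency": {0: [], 1: []},
        }
        for path in sorted(net_dir.glob(f"*_{band}.adj.tsv")):
            seg = path.name[:-len(f"_{band}.adj.tsv")]
            adj = np.loadtxt(path, delimiter="\t").astype(int)
            net = bn.BrainNetwork(adj, names, thr, band)
            y = labels[seg]
            metrics["clustering"][y].append(bn.clustering(net)[1])
            metrics["global_efficiency"][y].append(bn.global_efficiency(net)[0])
            metrics["local_efficiency"][y].append(bn.local_efficiency(net)[0])
        row = {}
        for metric, groups in metrics.items():
            nm, ms = groups[0], groups[1]
            cmp = bn.compare_groups(nm, ms)
            row[metric] = {
                "nm_mean": float(np.mean(nm)), "nm_sd": float(np.std(nm)),
                "ms_mean": float(np.mean(ms)), "ms_sd": float(np.std(ms)),
                "u": cmp.u, "p": cmp.p, "stars": cmp.stars,
            }
        table[band] = row
    return table


def _run_stats(config: PipelineConfig) -> None:
    out = _stage_dir(config, "stats")
    out.mkdir(parents=True, exist_ok=True)
    table = report_networks(config)
    (out / "report.json").write_text(json.dumps(table, indent=1))
    lines = ["band\tmetric\tNM\tMS\tp\tsig"]
    for band, row in table.items():
        for metric, r in row.items():
            lines.append(
                f"{band}\t{metric}\t{r['nm_mean']:.3f} +/- {r['nm_sd']:.3f}\t"
                f"{r['ms_mean']:.3f} +/- {r['ms_sd']:.3f}\t"
                f"{r['p']:.2g}\t{r['stars']}")
    (out / "table.tsv").write_text("\n".join(lines) + "\n")


def _run_dataset(config: PipelineConfig) -> None:
    out = _stage_dir(config, "dataset")
    pairs = _segments(config)
    thresholds = resolve_thresholds(config) \
        if config.thresholds == "auto" else None
    for mod in config.modalities:
        samples = build_dataset(pairs, modalities=(mod,),
                                thresholds=thresholds)
        save_dataset(samples, out / mod.replace(":", "_"))


def _run_train(config: PipelineConfig) -> None:
    """Train one model per modality on the full dataset; save checkpoints."""
    from .gcn import train as train_model

    out = _stage_dir(config, "train")
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "train")
    for mod in config.modalities:
        samples = load_dataset(
            _stage_dir(config, "dataset") / mod.replace(":", "_"))
        cfg = dataclasses.replace(config.gcn, seed=seed)
        model, history = train_model(samples, cfg)
        checkpoint = {
            "modality": mod,
            "seed": seed,
            "config": dataclasses.asdict(cfg),
            "final_loss": history[-1],
            "params": {k: v.tolist() for k, v in model.params.items()},
            "scalers": [[m.tolist(), s.tolist()] for m, s in model._scalers],
        }
        (out / f"{mod.replace(':', '_')}.checkpoint.json").write_text(
            json.dumps(checkpoint))


def _run_evaluate(config: PipelineConfig) -> None:
    out = _stage_dir(config, "evaluate")
    out.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, "evaluate")
    results = {}
    for mod in config.modalities:
        samples = load_dataset(
            _stage_dir(config, "dataset") / mod.replace(":", "_"))
        cfg = dataclasses.replace(config.gcn, seed=seed)
        report = evaluate_cv(samples, cfg, folds=config.folds)
        results[mod] = report.summary()
    (out / "report.json").write_text(json.dumps(results, indent=1))


def _run_report(config: PipelineConfig) -> None:
    out = _stage_dir(config, "report")
    out.mkdir(parents=True, exist_ok=True)
    perf = json.loads(
        (_stage_dir(config, "evaluate") / "report.json").read_text())
    lines = ["Brain network structure\tAccuracy\tF1 Score\tRecall\tPrecision"]
    for mod, m in perf.items():
        lines.append(f"{mod}\t{m['accuracy']:.3f}\t{m['f1']:.3f}\t"
                     f"{m['recall']:.3f}\t{m['precision']:.3f}")
    (out / "performance.tsv").write_text("\n".join(lines) + "\n")
    stats_table = (_stage_dir(config, "stats") / "table.tsv").read_text()
    (out / "network_metrics.tsv").write_text(stats_table)


_STAGE_BODIES = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "connectivity": _run_connectivity,
    "network": _run_network,
    "stats": _run_stats,
    "dataset": _run_dataset,
    "train": _run_train,
    "evaluate": _run_evaluate,
    "report": _run_report,
}


def run_stage(stage: str, config: PipelineConfig, force: bool = False) -> bool:
    """Run one stage; returns True if work was done, False if up to date."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; stages: {STAGES}")
    _check_prereqs(config, stage)
    if not force and _up_to_date(config, stage):
        return False
    stage_dir = _stage_dir(config, stage)
    stage_dir.mkdir(parents=True, exist_ok=True)
    _STAGE_BODIES[stage](config)
    _write_manifest(config, stage)
    return True


def run_all(config: PipelineConfig, force: bool = False) -> None:
    for stage in STAGES:
        run_stage(stage, config, force=force)
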