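# Pipeline configuration for the `neurofuse` CLI.
#
#   neurofuse run --config examples/pipeline.toml
#
# This small configuration finishes in a few minutes; remove the size
# overrides to run the full study conditions (61 NM / 75 MS five-minute
# segments, all four EEG bands).

workdir = "pipeline-out"
seed = 0

n_segments_nm = 12
n_segments_ms = 14
segment_len = 300.0

# EEG rhythm bands to analyse; dCOE connectivity is always included
bands = ["beta"]

# per-band binarization thresholds; "default" uses the published values
# (delta 0.36, theta 0.42, alpha 0.40, beta 0.26, fNIRS 0.35), "auto"
# searches for the largest threshold with mean degree >= ln(N) and
# small-world sigma > 1
thresholds = "default"

# graph samples to build and evaluate: "fnirs", a band name, or "fused:<band>"
modalities = ["fnirs", "beta", "fused:beta"]
folds = 5

[gcn]
lr = 1e-3
weight_decay = 5e-4
epochs = 200
batch_size = 16
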