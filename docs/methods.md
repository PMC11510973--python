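# Methods

This note documents the estimators, models and design choices in
`neurofuse`, and what the synthetic-data experiments do and do not show
about real recordings.

## Signals and preprocessing

Recordings are channels × time arrays with a sampling rate, channel
names and a modality tag (EEG, HbO, HbR, ΔCOE). The EEG montage is the
14-channel 10–20 subset AF3 F7 F3 FC5 T7 P7 O1 O2 P8 T8 FC6 F4 F8 AF4
at 128 Hz; fNIRS has six prefrontal channels (Ch1/Ch5 left, Ch3/Ch2
midline, Ch4/Ch6 right) at 10 Hz. CSV input carries a time column whose
grid must be uniform to 1 µs; EDF is read through `mne` (values are
interpreted as microvolts). Full-montage files are reordered to the
canonical channel order regardless of column order on disk.

All filtering is zero-phase (forward–backward) Butterworth of order 4.
EEG is broadband-filtered 0.5–45 Hz and decomposed into δ (0.5–4 Hz),
θ (4–8), α (8–12) and β (12–32). The δ band is implemented from 0.5 Hz:
the broadband high-pass makes content below 0.5 Hz unavailable, so a
nominal 0 Hz lower edge would be unreachable. The fNIRS band-pass
defaults to 0.01–0.2 Hz — wide enough for the slow hemodynamic
oscillations, rejecting drift below and cardiac/instrument noise above;
it is configurable. The cerebral oxygen exchange is the samplewise
difference ΔCOE = ΔC_HbR − ΔC_HbO.

Artifact removal (ICA for EEG, motion-artifact correction for fNIRS) is
a pass-through hook: synthetic data carry no artifacts, and the hook
gives real-data users a shape-checked slot for their own cleaning step
without the pipeline pretending to implement one.

Segments are 5 minutes, matching the FMS self-report cadence; a score
of 1 maps to label 0 (no motion sickness) and scores 2–6 to label 1.

## WPLI estimation

For band-limited series x, y with analytic signals a_x, a_y (computed
once per channel by FFT-based Hilbert transform), the instantaneous
cross-spectrum is S(t) = a_x(t)·conj(a_y(t)) and

    WPLI = |E[Im S]| / E[|Im S|].

The expectation runs over the time samples of one segment, after
trimming 5 % of samples from each edge to discard Hilbert edge effects.
Choices:

- **0/0 convention**: if E[|Im S|] < 1e-12 (e.g. y = x, zero lag) the
  index is defined as 0 — no imaginary coupling means no phase-lag
  evidence. This makes WPLI(x, x) = 0, consistent with the zero
  diagonal of connectivity matrices.
- **Epoched estimator**: an optional `epoch_len` splits the segment
  into non-overlapping epochs, computes the analytic signal per epoch
  and pools the expectations over all epoch samples. The default is
  the single-segment estimator.
- Inputs shorter than 64 samples are rejected.

The estimator is validated to 1e-10 against an independent explicit
time-loop implementation, and its null distribution on independent
white noise at the full segment length (38 400 samples) stays below 0.1
across 100 replicates. Note the null widens substantially for short or
very narrow-band segments (fewer effective degrees of freedom); tests
at reduced length use bounds derived for that length.

## Brain networks

Connectivity matrices are binarized strictly: an edge exists where
WPLI exceeds the threshold (so threshold 1.0 gives an empty graph).
Default thresholds are the published per-band values δ 0.36, θ 0.42,
α 0.40, β 0.26 and fNIRS 0.35. The automatic selector binarizes the
group-average matrix on a grid (step 0.02) and returns the **largest**
threshold satisfying both constraints — mean degree ≥ ln N and
small-world σ > 1 — maximizing sparsity subject to connectedness;
infeasible inputs raise an error listing the violated constraint at
every grid value.

Metrics (binary undirected graphs, `networkx` under the module
surface, all validated against exhaustive brute-force oracles):

- degree D_i; clustering C_i = 2E_i/(k_i(k_i−1)), 0 when k_i < 2;
- nodal global efficiency E(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij with 1/∞ = 0
  for unreachable pairs (Latora–Marchiori); network value is the node
  mean; nodal local efficiency is the global efficiency of the
  subgraph induced by i's neighbours (0 when k_i < 2);
- normalized betweenness (Brandes); **key nodes** are those exceeding
  mean + 1 SD of betweenness (a configurable top-k rule is provided);
  on a cycle no node exceeds the cut, on a star only the centre does;
- **small-world σ** = (C/C_rand)/(L/L_rand) against degree-preserving
  rewired surrogates (default 100, 10·m attempted swaps, seeded);
  L is the mean shortest path over reachable pairs. Graphs that admit
  no rewiring (complete graphs) keep their surrogates identical,
  giving σ = 1 exactly. σ requires a giant component of ≥ N−2 nodes.

Group differences use the two-sided Mann–Whitney U test (normal
approximation with tie correction; U itself is exact), starred
*** p<0.001, ** p<0.01, * p<0.05. At n = 3 per group the smallest
attainable two-sided p is 0.1, so significance claims need n ≥ 4.

## Graph samples and fusion

Each node carries 13 features: MAV, variance, max, min, RMS, excess
kurtosis, skewness (both 0 for constant signals), total spectral power,
relative band power, degree, clustering, nodal global efficiency and
nodal local efficiency. The canonical feature list names one "PSD"
entry but the feature dimension is fixed at 13; this implementation
resolves the count by splitting spectral power into two concrete
features — total power over the analysis band and relative power
within the sample's own rhythm band — and keeps the list configurable.

The fused sample stacks the EEG graph (14 nodes) over the fNIRS graph
(6 nodes). Its adjacency is block-diagonal in the two unaltered
unimodal networks plus weight-1 bridge edges connecting each fNIRS
channel to its spatially nearest frontal electrodes: Ch1↔AF3, Ch5↔F7
(left), Ch2↔{AF3, AF4}, Ch3↔{AF3, AF4} (midline), Ch4↔AF4, Ch6↔F8
(right). The map follows the stated left/midline/right optode placement
and is overridable.

## Classifier

The fused network is: two branch convolutions 13→30 (one per modality,
propagating only within each modality block), a fusion convolution
30→60 on the bimodal adjacency, TopK pooling 20→10, a convolution
60→90 on the pooled subgraph, TopK pooling 10→1, and a linear readout
90→2. Unimodal baselines use one branch and pool n→⌈n/2⌉→1 (14→7→1,
6→3→1). Design choices:

- **Propagation rule**: symmetric-normalized convolution with
  self-loops, X′ = ReLU(D̃^{−1/2}(A+I)D̃^{−1/2} X W) (Kipf–Welling); the
  branch layers use the block-diagonal adjacency so each modality is
  encoded independently before fusion.
- **TopK pooling**: scores s = X·p/‖p‖ with a learnable projection p;
  the k best nodes are kept (ties to the lower index, kept nodes stay
  in original order) and features are gated by tanh(s). The pooled
  adjacency is the induced subgraph, re-normalized for the next
  convolution.
- **Initialization**: He (fan-in) scaling for the convolution weights.
  Glorot scaling can initialize the whole ReLU stack dead — the loss
  pins at ln 2 and the model predicts the majority class for the whole
  run — which He scaling avoids; the readout uses Glorot.
- **Standardization**: features are z-scored per feature across the
  training split only (no leakage into validation folds); fused
  samples are standardized per modality block because EEG and ΔCOE
  features live on different physical scales.
- **Training**: Adam (lr 1e-3), L2 weight decay 5e-4 applied to all
  weights except the readout bias, 200 epochs, batch 16, seeded
  shuffling; no dropout. The entire backward pass is analytic and is
  verified against central finite differences to 1e-4 relative on a
  small fused graph.
- **Evaluation**: stratified 10-fold cross-validation; accuracy,
  binary F1 (positive class = motion sickness), recall, precision.
  Grid search evaluates every configuration by mean F1, breaking ties
  by higher accuracy, then smaller weight decay.

Logits are invariant to node permutations within each modality block
(score ties aside), since every stage is permutation-equivariant and
the readout consumes a single pooled node.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: 61 NM + 75 MS
five-minute segments (FMS 1 for NM, uniform 2–6 for MS), 14-channel
EEG at 128 Hz, 6-channel fNIRS at 10 Hz. Each EEG channel is a sum of
per-band narrow-band Gaussian oscillators (unit RMS, band amplitudes
1.0/0.8/0.7/0.5 for δ/θ/α/β, roughly 1/f across rhythms) plus pink
noise (default SD 0.4). Coupling is planted by lagged copies: the
follower's band component mixes (1−s) of its own oscillator with s of
the leader's *base* oscillator rotated by a constant phase lag
(couplings do not chain, and a channel may be a follower only once per
band). A lagged copy has a constant-sign imaginary cross-spectrum, so
strength-1 pairs reach WPLI ≈ 1 and the planted structure is
analytically recoverable. fNIRS HbO carries slow (0.01–0.1 Hz)
oscillators with the same mechanism plus drift and white noise; HbR is
anti-correlated (−0.3×) with independent noise, so ΔCOE inherits the
coupling.

Default topologies encode the qualitative physiology the pipeline
should detect: NM has strong (0.85) long-range β coupling on six
homologous pairs and a single left-prefrontal fNIRS coupling
(Ch1→Ch5, 0.8); MS abolishes the β coupling and densifies the
prefrontal network through a hub star around the midline channel Ch2
(strength 0.85, distinct lags per spoke, so every prefrontal pair
becomes coupled). θ coupling is present in both states as a
non-discriminative control. The β weakening is modeled as *absent*
coupling rather than reduced strength because a consistently lagged
copy at any moderate strength still yields WPLI above the β threshold
(the constant-sign imaginary component dominates the estimator) — at
the network level, "weakened synchrony" only manifests once the WPLI
falls below threshold.

The generator does **not** emulate: motion or ocular artifacts, raw
fNIRS light intensities (concentrations are emitted directly),
inter-subject variability, non-stationarity within segments, volume
conduction, or realistic scalp topographies. Consequently the
classifier's near-perfect synthetic F1 demonstrates that the pipeline
recovers planted structure end-to-end — not that comparable accuracy
would be reached on real recordings, where class differences are far
subtler.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full study scale
where it matters — 136 five-minute segments for classifier evaluation,
100-replicate WPLI nulls at full segment length, 200 random graphs for
metric validation, 20 replicate experiments at 30 segments/group for
the Mann–Whitney power measurement — and smaller sizes (1-minute
segments, few segments) for structural unit tests. All randomness
flows from explicit seeds (`numpy.random.default_rng`); the pipeline
derives per-stage seeds from the global seed by hashing, and identical
(config, seed) pairs reproduce every artifact bit-for-bit.

Known numerical edges: Butterworth sub-bands overlap softly at the
3 dB corners, so re-filtering a band output loses ~5 % RMS for
broadband content (band-centred content is preserved to <1 %); the
WPLI null is heavy-tailed for short narrow-band segments; CSV
round-trips are exact to 1e-8 (10 significant digits), while EDF
round-trips are quantized to the 16-bit integer grid.
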