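# asym

A NumPy-based implementation of a dual-stream behavioral time-series
classifier: paired audio and video feature sequences are refined by
bidirectional selective state-space (Bi-Mamba) blocks whose state-transition
dynamics are shared across modalities, aligned by bidirectional cross-modal
attention, fused through a three-level temporal feature pyramid in parallel
with a sigmoid-gated dynamic fusion unit, and classified after a Mamba-based
enhancement head. The package also ships the surrounding experimental
protocol: random-segment augmentation, stratified splitting, five-metric
evaluation, stratified k-fold comparison with exact one-sided Wilcoxon
signed-rank tests, calibration binning, attention-direction statistics,
analytic efficiency profiling, an ablation harness, and a synthetic
two-stream generator so everything is testable without external corpora.

No deep-learning framework is required: the model runs on a small
tape-based autodiff engine over NumPy (`asym.nn`), with the sequential
state-space recurrence JIT-compiled by numba when available (a pure-Python
fallback is built in).

## Layout

| module | contents |
|---|---|
| `asym.ssm_core` | diagonal SSM scan (literal recursions + selective parameterization), Bi-Mamba block/stack, cross-modal transition sharing |
| `asym.interaction` | front-end 1×1 projections, co-processed Bi-Mamba pair, bidirectional cross-attention, aligned-feature merge |
| `asym.fusion` | temporal pyramid (T, ⌊T/2⌋, ⌊T/4⌋), gated dynamic fusion, parallel/plain-concat/unimodal fusion variants |
| `asym.head` | residual conv blocks, enhancement Bi-Mamba stack, pooling + linear sigmoid classifier |
| `asym.data_io` | CSV manifests, random-segment augmentation, stratified splits, synthetic generator |
| `asym.evaluation` | metrics, Wilcoxon test, calibration, k-fold, attention stats, profiling, ablations |
| `asym.config` / `asym.cli` | layered YAML config with profiles (`dvlog`, `lmvd`, `synth`) and the `asym` command |
| `asym.model` / `asym.train` | end-to-end model assembly, Adam/BCE training loop, checkpoints |

## CLI

```bash
# generate a synthetic dataset (manifest.csv + per-sample .npy arrays)
asym synth --out data/synth --seed 1 --set synthetic.n_per_class=100

# assign a stratified split column
asym split --manifest data/synth/manifest.csv --ratios 7:1:2 --seed 1

# train (profile picks hyperparameters; --set overrides any dotted key)
asym train --profile synth --out runs/demo --seed 1

# evaluate a checkpoint (metrics JSON/CSV + ROC points)
asym evaluate --checkpoint runs/demo/checkpoint.npz --profile synth --seed 1

# 5-fold cross-validation, ablations, efficiency profile, attention maps
asym crossval -k 5 --profile synth
asym ablate --switches "-;audio_only;video_only;no_fpn,no_gd" --profile synth
asym profile --profile dvlog --lengths 500,1000,10000,20000,50000
asym inspect-attention --checkpoint runs/demo/checkpoint.npz --profile synth
```

Real corpora are consumed through the same CSV manifest
(`sample_id, audio_path, video_path, label[, split]`) pointing at per-sample
2-D arrays (`.npy` or delimited text): audio `T×F_a`, video `T×F_v`,
binary labels.

## Notes

* FLOPs are counted analytically as 2 × multiply-accumulates; the
  convention is stamped into every efficiency report.
* Cross-modal attention is the one quadratic-in-T stage; the state-space
  path is linear in sequence length.
* All randomness flows through explicit `numpy.random.Generator` seeds:
  parameter init, augmentation, fold assignment and the synthetic generator
  use independent named streams, so components can be re-seeded in
  isolation.
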