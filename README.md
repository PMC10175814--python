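# nodulemap

Differential regional-importance mapping for nodule malignancy classifiers.

A class-activation-map (CAM) of a global-average-pooling classifier is
partitioned into five equal-area nested level-set regions (outermost region I
to innermost region V), each region is perturbed with region-restricted FGSM
adversarial noise (positions re-randomized over repetitions, probabilities
averaged), and the per-region drop in ROC AUC — with DeLong pairwise
comparisons and paired t-tests across random dataset subsets — quantifies how
much each sub-nodular region contributes to the malignancy prediction. A
*malignancy heat map* variant rescales the malignant-class CAM by the
predicted malignancy probability, so peak color temperature encodes absolute
malignancy heat. Frequency-weighted ACR TI-RADS feature scoring compares the
ultrasound-feature risk profile of hot versus inactivated regions.

Because clinical ultrasound data cannot ship with the package, everything is
exercised end-to-end on a synthetic B-mode-like phantom: elliptical nodules
(optionally with irregular margins) in multiplicative speckle, with the
malignant class signal carried by localized cues (a very hypoechoic
sub-region plus punctate bright foci) whose ground-truth pixel masks make
regional-importance claims directly testable. The classifier is a small
pure-NumPy CNN (im2col convolutions, hand-written backprop) with a
global-average-pooling sum and a bias-free linear softmax head — exactly the
structure the CAM identity `S_i = Σ_xy M_i(x,y)` requires — trainable on one
CPU in under a minute.

## Modules

| module    | contents |
|-----------|----------|
| `phantom` | seeded synthetic nodule images, masks, cue masks, CSV manifests |
| `gapnet`  | NumPy CNN: training, forward pass exposing `g_k`, `G^k`, `ω`, `S_i`, `P_i`, input-space loss gradients |
| `heatmap` | CAM computation, bilinear upsampling, malignancy heat map, rendering |
| `regions` | equal-area level-set partition (quantile peeling), threshold sweeps |
| `perturb` | FGSM noise `δ = β·sign(∇_x L)`, region-restricted application, AUC-gradient β selection |
| `stats`   | ROC/AUC, DeLong's paired test, p-value matrices, subset splits, paired t-tests, Dice |
| `tirads`  | frequency-weighted ACR TI-RADS scoring of region feature profiles |
| `cli`     | experiment orchestration behind a `click` CLI |

## CLI

All commands read an optional YAML config (`--config`); flags override keys.

```bash
nodulemap simulate --outdir results              # phantom dataset + manifest
nodulemap train --outdir results                 # train classifier, save model.npz
nodulemap cam --model-path results/model.npz --mode malignancy
nodulemap regions --model-path results/model.npz # equal-area partitions
nodulemap perturb --model-path results/model.npz --select-beta
nodulemap experiment-regions --outdir results    # conventional-CAM experiment
nodulemap experiment-malignancy --outdir results # malignancy-heat-map experiment
nodulemap dice-eval --outdir results             # CAM support vs true masks
nodulemap tirads-report ratings.csv              # Table-style weighted scores
```

Experiment outputs: per-region AUC CSVs, DeLong and paired-t p-value
matrices, subset AUC tables, ROC/heat-tile figures, and a `provenance.json`
recording the exact config and seeds. Config example:

```yaml
phantom: {image_size: 64, benign_echogenicity: 0.53, malignant_echogenicity: 0.50}
n_benign: 200
n_malignant: 200
train: {epochs: 15, learning_rate: 0.003}
beta: 0.15
k_regions: 5
seed: 0
```

## Reproducibility

Every stochastic stage (phantom synthesis, weight init, shuffling, noise
positions, subset splits) derives from explicit integer seeds; identical
config + seed reproduces identical rasters and CSVs bit-for-bit.
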