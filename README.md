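# radcal

Calibrated per-region ensembles of convolutional classifiers for
abnormality detection in skeletal radiographs — a reusable library and CLI
covering the full pipeline: manifest/image ingestion, three baseline
network architectures, class-weighted training, study-level evaluation,
per-region learner designation with routed prediction, and class
activation maps. A seeded synthetic radiograph-study generator makes the
whole pipeline exercisable at desk scale (small images, CPU-only, no
dataset downloads).

Because no deep-learning framework is assumed, the networks run on a small
NumPy engine (`radcal.nn`) with explicit forward/backward passes and an
Adam optimizer; everything is float64 and fully seeded, so runs are
reproducible bit-for-bit.

## Layout

| module | contents |
|---|---|
| `radcal.data_io` | CSV manifests, the MURA-layout tree scanner, resize/normalize preprocessing, flip/rotate augmentation, shuffled batch streaming |
| `radcal.architectures` | declarative specs + builders: a 14-convolution VGG-style stack, a 25-block pre-activation residual net, the 169-weighted-layer densely connected net; closed-form parameter counting |
| `radcal.training` | per-region class weights, weighted cross-entropy, the Adam training loop with early stopping and validation checkpointing, per-region fine-tuning |
| `radcal.evaluation` | study-level decisioning (mean view probability, 0.5 threshold), ROC-AUC / accuracy / precision / recall / Cohen's kappa, percent-change tables vs a baseline |
| `radcal.ensembling` | probability-averaging ensemble; the 2-of-3 validation-metric designation rule and routed calibrated prediction |
| `radcal.cam` | class activation maps (classifier-weight or gradient weighting), overlays |
| `radcal.synthetic` | seeded generator of multi-view studies with planted, bounding-boxed lesions; controlled prediction tables with closed-form AUC |
| `radcal.reference` | published statistics of the public MURA benchmark used as worked-example inputs |

## CLI

Each subcommand writes its artifacts plus a `run_meta.json` (config echo,
seed, config hash) into `--out`:

```bash
radcal synth    --out runs/ds --seed 1 --image-size 32 --regions Elbow Wrist
radcal train    --manifest runs/ds/manifest.csv --arch tiny --image-size 32 \
                --epochs 20 --seed 1 --out runs/overall
radcal finetune --model runs/overall --manifest runs/ds/manifest.csv \
                --region Elbow --epochs 10 --seed 2 --out runs/ft_elbow
radcal evaluate --manifest runs/ds/manifest.csv \
                --models overall=runs/overall ft_elbow=runs/ft_elbow \
                --split validation --out runs/eval
radcal select   --metrics runs/eval/metrics.csv --out runs/sel
radcal predict  --manifest runs/ds/manifest.csv --selection runs/sel/selection.csv \
                --models Elbow=runs/ft_elbow Wrist=runs/overall --out runs/pred
radcal cam      --model runs/ft_elbow --image runs/ds/images/<id>.png --out runs/cam
```

`--arch` accepts `convnet`, `resnet`, `densenet` (the three reference
configurations, 256x256 input) and `tiny` (a small GAP-headed stack for
desk-scale runs).

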