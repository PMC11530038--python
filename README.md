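# lesionseg

A densely connected encoder–decoder segmentation network with three
attention mechanisms — additive attention gates on skip connections,
dual-pooling channel attention after each decoder concatenation, and a
scale-attention fusion of all decoder resolutions — for breast-ultrasound-
style lesion segmentation. The package is self-contained: it ships a
synthetic speckle-phantom generator so the full train/evaluate pipeline runs
end-to-end on one CPU with no external data, plus the five standard
pixel-overlap metrics (DSC, JSC, PPV, SEN, F1).

The network runs on a small purpose-built NumPy autograd engine
(`lesionseg.nn`) — no deep-learning framework required.

## Layout

| module | contents |
| --- | --- |
| `lesionseg.nn` | reverse-mode autograd: Tensor, conv2d, batchnorm, pooling, bilinear resize, Adam |
| `lesionseg.metrics` | confusion counts, DSC/JSC/PPV/SEN/F1, per-image reports, CSV export |
| `lesionseg.attention` | `AttentionGate`, `ChannelAttention`, `ScaleAttention` |
| `lesionseg.backbone` | dense blocks, transitions, decoder levels, the assembled `DenseAttentionUNet` |
| `lesionseg.data` | PNG folder datasets, resize/flip/scale augmentation, normalization, 80/20 split |
| `lesionseg.phantom` | speckled single-lesion phantom generator + dataset writer |
| `lesionseg.training` | he_normal init, cross-entropy loss, Adam training loop, checkpoints |
| `lesionseg.cli` | `lesionseg` command-line interface |

## CLI

```bash
# 1. generate a synthetic dataset (images/ + masks/ + manifest.json)
lesionseg make-phantoms --n 200 --size 64 --seed 0 data/

# 2. train (loads, splits 80/20, trains, writes checkpoint/history/split)
lesionseg train --config config.yaml --epochs 25 --seed 0 data/ run/

# 3. evaluate a checkpoint -> per-image metric CSV + mean row
lesionseg eval run/checkpoint.npz data/ metrics.csv

# 4. segment a folder of PNGs -> binary mask PNGs
lesionseg predict run/checkpoint.npz data/images preds/
```

`--config` takes a YAML file with `model` / `data` / `train` / `phantom`
sections; any flag overrides the file. Example:

```yaml
model:
  preset: small          # or "default" (wider, slower)
data:
  size: 64               # resize target, divisible by 16
  image_interp: bilinear # "nearest" for the 256x256 nearest-neighbour convention
train:
  epochs: 25
  batch_size: 8
  learning_rate: 1.0e-4
phantom:
  size: 64
  seed: 0
```

Dataset layout: `images/<id>.png` paired with `masks/<id>_mask.png`
(8-bit grayscale; masks 0/255, binarized at 0.5 on load).

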