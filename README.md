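# gpanet

Fine-grained image recognition built from four pieces:

- **CSP backbone** — a lightweight four-stage convolutional network. Each
  stage splits into a processed branch (`n` residual bottlenecks) and a 1×1
  shortcut branch, concatenates them, channel-shuffles, and downsamples with
  a stride-2 convolution. Stages 2–4 are exposed for the attention pyramid.
- **Cross-stage trilinear attention (CTA)** — per stage, a channel-relation
  matrix `rowsoftmax(msqrt((1/WH)·Xᵀφ(X)))` (with `msqrt` the signed square
  root) is projected back onto the companion map `φ(X)` to yield one spatial
  attention map per channel, each normalized to sum to 1.
- **Graph feature embedding (GFE)** — attention-pooled part descriptors
  become graph nodes; a cosine-similarity adjacency plus self-loops drives
  one step of `ReLU(D^-1/2 Ã D^-1/2 K W)`; per-level embeddings are fused by
  an adaptive tanh/softmax level attention into a single probability vector.
- **Detector pipeline** — a minimal grid-anchor head (one 1×1 convolution on
  stage-3 features) trained with CIoU box loss + class/objectness cross
  entropy, post-processed with hard NMS or linear-decay **Soft-NMS**.

Everything runs on a small numpy reverse-mode autodiff core (`gpanet.autograd`,
`gpanet.nn`) — no deep-learning framework is required. A synthetic
fine-grained "bird" generator (`gpanet.synthetic`) produces classification
crops and cluttered multi-object detection scenes with exact ground truth:
all classes share one body template and differ only in small parts (beak,
wing stripes, eye ring), with the continuous spread controlled by a
`similarity` knob.

## CLI

```bash
# generate an 8-class fine-grained classification dataset
gpanet generate --out data/cls --kind classification --n-classes 8 \
    --similarity 0.9 --n-items 400 --seed 0

# train the full model (or: backbone | backbone+cta | backbone+gfe)
gpanet train-cls --data data/cls --out runs/full --variant full \
    --epochs 14 --seed 0

# evaluate: writes metrics.json and confusion.png
gpanet evaluate --data data/cls --out runs/full --n-classes 8

# four-variant ablation table
gpanet ablate --data data/cls --out runs/ablation --epochs 14 --seed 0

# detection
gpanet generate --out data/det --kind detection --n-classes 4 --n-items 72
gpanet train-det --data data/det --out runs/det --n-classes 4 --epochs 12 --lr 0.02
gpanet evaluate --task detect --nms soft --data data/det --out runs/det --n-classes 4

# attention heat-map overlay for one image
gpanet heatmap --image data/cls/test/class_00/crop_0003.png --out runs/full --level 4
```

Configuration can also be given as YAML (`--config run.yaml`); CLI flags
override file values. `gpanet.pipeline.paper_profile()` holds the published
large-scale training regime (448 px, batch 128, 150 epochs, cosine period
20) as a named preset; the test surface uses the toy profile (64 px, 8
classes, ≤16 epochs) sized for a single CPU.

## Layout

```
src/gpanet/
  autograd.py    # numpy reverse-mode autodiff (conv2d, matmul, reductions…)
  nn.py          # layers, SGD + cosine annealing, precise-BN calibration
  backbone.py    # CSP stages, channel shuffle, backbone pyramid
  attention.py   # bilinear pooling, relation matrices, CTA pyramid, heatmaps
  graphs.py      # part pooling, adjacency, graph propagation, level fusion
  detection.py   # boxes, IoU, hard/soft NMS, grid-anchor head, YOLO label IO
  losses.py      # label smoothing, CE, CIoU, ACC/P/R/AP, confusion matrix
  synthetic.py   # species library, crop/scene rendering, dataset writer
  model.py       # GPANet variants (ablation switches)
  pipeline.py    # RunConfig, training loops, evaluation, ablation harness
  cli.py         # `gpanet` command group
```
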