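# axunet

Binary lesion segmentation with a parallel axial-attention / CNN encoder,
attention-gated feature fusion, and edge-aware training — as a tested,
CPU-only Python library and CLI.

## Who this is for

Medical-image segmentation of lesions (endoscopic polyps, stained glands,
nuclei) must capture both long-range context — is this bright patch part
of one large lesion? — and fine local texture at fuzzy, low-contrast
boundaries. Pure convolutional U-Nets model texture but not long-range
structure; pure transformer encoders do the reverse and are data-hungry.
`axunet` implements a hybrid U-shaped network whose encoder runs both in
parallel and fuses them at every scale, for researchers who want a small,
fully inspectable implementation of that design (the package ships its own
NumPy autodiff engine, so every gradient is reproducible and
framework-free).

## The model in brief

- **Encoder**: a residual stem (stages 1–2 of a bottleneck ResNet) feeds
  two *parallel units*; each pairs a transformer branch with a stride-2
  residual stage and merges them with global–local fusion (GLF).
- **Masked axial attention**: queries/keys come from row and column mean
  profiles, so the Q·K correlation stage costs O((H²+W²)·C) instead of
  O((HW)²·C); each axial correlation is reweighted by a distance mask

      mask[i,j] = 1 (i = j);  k·|i−j|² − k·a² + 1 (0 < |i−j| < a);  1 (|i−j| ≥ a)

  with k = 0.5 and a = half the axis length, which suppresses short-range
  pairs the CNN branch already covers.
- **GLF**: `f_out = conv(cat(conv(f_global), f_local · A_s · A_c))` — the
  global stream produces sigmoid spatial and channel gates applied to the
  local stream before concatenation.
- **Loss**: `0.5·L_BCE + 0.3·L_Dice + 0.2·L_Ohem(edge)`, where the edge
  term supervises a Canny-derived boundary band with online hard-example
  mining (top-25 % hardest pixels).
- **Metrics**: Dice = 2TP/(2TP+FP+FN), IoU, precision, recall; dataset
  scores are per-image means.

Training uses SGD (lr 0.01, momentum 0.9, weight
decay 1e-4), cosine annealing with warm restarts, batch 4, 8:1:1 splits,
best-validation-mDice checkpointing, and a rotation/flip/crop/elastic +
one-occlusion augmentation suite.

A deterministic synthetic generator (`axunet.synthdata`) renders fuzzy,
low-contrast blob lesions on textured backgrounds so the whole pipeline is
testable without downloads. See `docs/methods.md` for assumptions,
parameter meanings and limitations.

## Worked example

```python
from axunet import NetworkConfig, SynthConfig, TrainConfig, evaluate, fit, gen_sample

cfg = SynthConfig(image_size=64, seed=11)
train_set = [gen_sample(cfg, i) for i in range(200)]
holdout = [gen_sample(cfg, 200 + i) for i in range(50)]

record = fit(NetworkConfig.tiny(64),
             TrainConfig(max_epochs=15, val_fraction=0.1, test_fraction=0.0, seed=5),
             train_set, "runs/demo")
print(record.best_val_dice)                       # 0.9359 (epoch 14)
print(evaluate("runs/demo/best.npz", holdout))
```

prints (about two minutes on one CPU core):

```
0.9358883602402278
{'dice': 0.9313667689493045, 'iou': 0.8741950798010498,
 'precision': 0.9119088544605582, 'recall': 0.9560048598909218,
 'edge_bce': 0.3366944375163915}
```

i.e. the desk-scale model reaches a holdout mean Dice of 0.93 on unseen
synthetic lesions after 15 epochs: it finds ~96 % of lesion pixels
(recall) with ~91 % of predicted pixels correct (precision), and the edge
head's cross-entropy has dropped well below its untrained value (~0.8).

The same flow from the shell:

```sh
axunet synth --n 250 --out data/ --set synth.image_size=64
axunet train --data data/ --out runs/demo --tiny --seed 5
axunet eval  --checkpoint runs/demo/best.npz --data data/ --report report.tsv
axunet predict --checkpoint runs/demo/best.npz --images data/images --out preds/
```

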