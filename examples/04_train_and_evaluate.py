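"""Train a small SE variant on an easy synthetic task and run the evaluation suite.

Uses a reduced backbone and 32x32 images so the whole script finishes in well
under a minute on one CPU; the printed confusion matrix, percent metrics and
one-vs-rest AUC are the same outputs a full-scale run would produce.
"""

import warnings

import numpy as np

from cervnet.blocks import AttentionConfig
from cervnet.data import (EvalTransform, SyntheticConfig, TrainTransform,
                          compute_channel_stats, generate_synthetic_dataset,
                          stratified_split)
from cervnet.metrics import metrics, normalize_cm, roc_auc
from cervnet.model import ModelConfig, build_model
from cervnet.train import TrainConfig, evaluate, predict_scores, train

warnings.simplefilter("ignore")

records = generate_synthetic_dataset(SyntheticConfig(
    per_class_counts={k: 20 for k in range(5)}, image_size=32, noise_sd=0.0, seed=5))
tr, va = stratified_split(records, 0.9, seed=0)
mean, std = compute_channel_stats(tr)
ttf = TrainTransform(size=32, resize_short=None, mean=mean, std=std,
                     rng=np.random.default_rng(1))
etf = EvalTransform(size=32, resize_short=None, mean=mean, std=std)

model = build_model(ModelConfig(stem_channels=8, stage_repeats=(1, 1),
                                stage_channels=(16, 32), final_channels=32,
                                attention=AttentionConfig("se", 8)), seed=0)
cfg = TrainConfig(epochs=5, batch_size=16, seed=0)
model, history = train(model, tr, va, cfg, ttf, etf)
print("epoch  lr      loss    val_acc%")
for row in history.rows:
    print(f"{row['epoch']:>5d}  {row['lr']:.4f}  {row['train_loss']:.4f}  "
          f"{row['val_accuracy']:.1f}")

cm = evaluate(model, va, etf, 5)
print("\nconfusion matrix (rows = true class):\n", cm.counts)
norm, _ = normalize_cm(cm)
print("normalized diagonal (= per-class recall/100):", np.round(np.diag(norm), 3))
rep = metrics(cm)
labels, scores = predict_scores(model, va, etf)
print(f"accuracy {rep.accuracy:.1f}%  macro P/R/F1 "
      f"{rep.macro_precision:.1f}/{rep.macro_recall:.1f}/{rep.macro_f1:.1f}%  "
      f"macro AUC {roc_auc(scores, labels):.3f}")
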