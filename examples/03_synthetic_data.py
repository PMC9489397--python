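"""Generate a synthetic colposcopy-like dataset mirroring the clinical imbalance.

Each class has its own base hue, blob count and texture frequency; Gaussian pixel
noise controls how confusable the classes are.  The class proportions follow the
published clinical inventory (2352:780:2532:408:924) scaled down by a divisor.
"""

from cervnet.data import (SyntheticConfig, generate_synthetic_dataset, inventory,
                          scaled_table1_counts, stratified_split)

counts = scaled_table1_counts(divisor=50)
cfg = SyntheticConfig(per_class_counts=counts, image_size=64, noise_sd=0.05, seed=7)
records = generate_synthetic_dataset(cfg)

inv = inventory(records)
print("per-class counts:", inv.per_class_counts, "total:", inv.total)

train, val = stratified_split(records, train_fraction=0.9, seed=0)
print("90/10 split     :", inventory(train).per_class_counts, "train /",
      inventory(val).per_class_counts, "val")

train_g, val_g = stratified_split(records, 0.9, seed=0, group_aware=True)
leak = {r.group_id for r in train_g} & {r.group_id for r in val_g}
print("group-aware mode: no patient appears in both subsets ->", leak == set())
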