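"""Channel split, channel shuffle and SE gating on a toy feature map.

The split/shuffle pair is what lets the unit keep an untouched identity path and
still mix information across the two halves; SE gates rescale each channel by a
learned factor in (0, 1).
"""

import numpy as np

from cervnet.blocks import SEModule, channel_shuffle, channel_split, se_squeeze

x = np.arange(8, dtype=float).reshape(1, 8, 1, 1)
x1, x2 = channel_split(x)
print("split halves:", x1.ravel(), "|", x2.ravel())

shuffled = channel_shuffle(x, 2)
print("shuffle G=2 :", shuffled.ravel(), " (interleaves the two halves)")
restored = channel_shuffle(shuffled, 4)
print("inverse     :", restored.ravel(), " (shuffling with n=C/G undoes it)")

rng = np.random.default_rng(0)
u = rng.standard_normal((1, 8, 4, 4))
se = SEModule(channels=8, reduction_ratio=2)
z = se_squeeze(u)
gates = se.excite(z)
print("\nsqueezed descriptor z:", np.round(z.ravel(), 3))
print("SE gates (0,1):       ", np.round(gates.ravel(), 3))
print("output magnitude never exceeds input per channel:",
      bool((np.abs(se(u)) <= np.abs(u) + 1e-12).all()))
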