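"""The separable-convolution cost model and the variant complexity table.

A depthwise-separable conv replaces one dense N x N conv by a per-channel spatial
conv plus a 1 x 1 channel mixer; the multiply-count ratio collapses to
1/C_out + 1/N^2, independent of the feature-map size.
"""

from cervnet.blocks import AttentionConfig, ConvSpec, FeatureMapSpec
from cervnet.complexity import (conv_mults, dws_mults, model_complexity,
                                reduction_ratio)
from cervnet.model import ModelConfig, build_model

fmap = FeatureMapSpec(height=56, width=56, channels=64)
dense = conv_mults(fmap, ConvSpec(kernel_size=3, in_channels=64, out_channels=128))
sep = dws_mults(fmap, kernel_size=3, out_channels=128)
ratio = reduction_ratio(3, 128)
print(f"dense 3x3 conv 64->128 @56x56 : {dense:>12,d} mults")
print(f"separable                     : {sep:>12,d} mults")
print(f"ratio 1/128 + 1/9 = {float(ratio):.5f}  (exactly {ratio})")
print(f"check: ratio * dense == separable -> {ratio * dense == sep}\n")

print("variant    params       mults@224      size(MB)")
for kind in ("none", "se", "sk"):
    net = build_model(ModelConfig(attention=AttentionConfig(kind)), seed=0)
    rep = model_complexity(net, FeatureMapSpec(224, 224, 3))
    print(f"{kind:8s} {rep.total_params:>9,d} {rep.total_mults:>15,d}"
          f" {rep.size_bytes / 2**20:>10.2f}")
print("\nSE adds only the excitation bottlenecks; SK adds two conv branches per unit.")
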