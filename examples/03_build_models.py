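"""Build the four model variants and inspect their shapes.

The fused bottleneck concatenates Multi-Core Pooling (3 stride-1 max-pool
branches -> 1x1 convs, 768 channels at default width) with improved ASPP
(4 dilated convs + global-average pool, 1280 channels concatenated then
reduced to 512), giving 1280 bottleneck channels in the hybrid model.
"""

import numpy as np

from imau_seg import ArchitectureSpec, build_aspp_block, build_mcp_block, build_model
from imau_seg.nn.tensor import Tensor

# default-width bottleneck blocks on a deep 8x8x2048 feature map
spec = ArchitectureSpec()
x = Tensor(np.random.default_rng(0).normal(size=(1, 8, 8, 2048)).astype(np.float32))
mcp_out = build_mcp_block(2048, spec)(x)
cat, red = build_aspp_block(2048, spec).forward_detail(x)
print(f"MCP concatenation:  {mcp_out.shape[-1]} channels")
print(f"ASPP concatenation: {cat.shape[-1]} -> reduced {red.shape[-1]} channels")

# narrow (desk-scale) builds of all four variants
for variant in ("inceptionv3_unet", "mcp_unet", "aspp_unet", "imau_net"):
    s = ArchitectureSpec(variant=variant, width_multiplier=0.0625,
                         input_size=(160, 160, 3))
    model = build_model(s, seed=0)
    prob = model.predict(np.zeros((160, 160, 3), np.float32))
    print(f"{variant:17s} params {model.parameter_count:>9,d}  "
          f"bottleneck {model.endpoints['bottleneck']}  out {prob.shape}")
# Every variant maps (H, W, 3) -> (H, W) probabilities strictly inside (0, 1).
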