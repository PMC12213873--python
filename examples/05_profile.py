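"""Measure the parameter and FLOP budget of model configurations.

The profiler enumerates trainable parameters of the instantiated model
and accumulates multiply-accumulate (MAC) counts over one real forward
pass; GFLOPs are reported at 2 FLOPs per MAC. The shipped default at
256x256 lands at ~102 M parameters / ~135 GFLOPs; the width-reduced
smoke configuration is three orders of magnitude cheaper.
"""

from stripmamba import ModelConfig, SMOKE_CONFIG, profile

small = profile(ModelConfig(**SMOKE_CONFIG))
print("smoke configuration :", small)

print("profiling the full default (one 256x256 forward pass, ~1 min)...")
full = profile(ModelConfig())
print("default configuration:", full)
print("as machine-readable  :", full.as_dict())
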