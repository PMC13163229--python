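"""Build the canonical 224-px dual-stream network and print its layer table.

The totals (41,976,967 parameters, 41,923,335 trainable) are the published
accounting of the architecture; the non-trainable remainder is batch-norm
moving statistics. No weights are downloaded - counts are weight-independent.
"""

from dsanet import ModelConfig, build_model, summary

model = build_model(ModelConfig(), seed=0)
print(summary(model))
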