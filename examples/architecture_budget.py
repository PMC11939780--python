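"""Complexity accounting of the reference architecture.

Builds the full-width network and tallies trainable parameters and the
multiply-accumulate cost of one 256x256 forward pass, split by
operation kind (convolutions/MLPs, attention token products, FFTs).
"""

from dfdrnet.network import NetworkConfig, build_model, count_macs, count_parameters

model = build_model(NetworkConfig())
rep = count_macs(model, 256)

print(f"trainable parameters : {count_parameters(model):.2f} M")
print(f"MACs at 256x256      : {rep.total_gmac:.2f} GMac")
print(f"  convolutions + MLPs: {rep.conv_gmac:.2f} GMac")
print(f"  self-attention     : {rep.attention_gmac:.2f} GMac")
print(f"  FFT transforms     : {rep.fft_gmac:.3f} GMac")
print(f"DFDR blocks          : {model.num_dfdr_blocks()}")
# The parameter figure is the size of the model a GPU would train at full
# scale; the GMac figure is the arithmetic cost of segmenting one frame.
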