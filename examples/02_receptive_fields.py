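"""Receptive-field progression of the contracting residual blocks.

Each RB_l(C, k1, s1, 3, 1) block applies one downsampling convolution and two
3x3 stride-1 convolutions; the receptive field grows by the recursion
r_i = r_{i-1} + (k_i - 1) * j_{i-1} with jump j_i = j_{i-1} * s_i.  The five
shared blocks reach 140 px (covering a 128x128 classifier input); the sixth
segmenter block (kernel 4, stride 3) reaches 380 px, covering a whole limb
in a 432x432 slice.
"""

from myoseg.networks import receptive_fields, segmenter_blocks

blocks = segmenter_blocks(block6_kernel=4)
print("block  channels  receptive fields (conv1, conv2, conv3)")
for i, (b, rf) in enumerate(zip(blocks, receptive_fields(blocks)), 1):
    print(f"  {i}      {b.channels:5d}    {rf}")

literal = receptive_fields(segmenter_blocks(block6_kernel=3))[5]
print(f"sixth block with the literal kernel-3 reading instead: {literal}")
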