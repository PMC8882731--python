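"""Encode a DNA window with each of the six feature descriptors.

The 6-nt toy sequence ACGTNA makes the structure of every encoding
visible; a real prediction window is 41 nt with an adenine at the
center.
"""

import numpy as np

import methylvote as mv

seq = "ACGTNA"
print(f"sequence: {seq}")
print(f"dinucleotides: {mv.tokenize(seq, 2)}")

print("\nAMNF (running mono-nucleotide frequency):")
print(" ", np.round(mv.encode_amnf(seq), 2))
print("ADNF (running di-nucleotide frequency):")
print(" ", np.round(mv.encode_adnf(seq), 2))

oh1 = mv.encode_onehot1(seq)
oh2 = mv.encode_onehot2(seq)
print(f"\nOne-hot1: {oh1.astype(int)}  (dim {oh1.size} = 5 x {len(seq)})")
print(f"One-hot2 dimension: {oh2.size} = 25 x {len(seq) - 1}, "
      f"{int(oh2.sum())} ones")

dpcp = mv.encode_pcp(seq, mv.default_dinucleotide_table())
tpcp = mv.encode_pcp(seq, mv.default_trinucleotide_table())
print(f"DPCP dimension: {dpcp.size} = 25 tokens x 15 properties")
print(f"TPCP dimension: {tpcp.size} = 125 tokens x 11 properties")

window41 = "GT" * 10 + "A" + "CA" * 10
v = mv.encode_onehot2(window41)
print(f"\n41-nt window under One-hot2: dimension {v.size}, "
      f"{int(v.sum())} ones — one bit per overlapping dinucleotide")
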