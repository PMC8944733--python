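"""Local-alignment identity scoring and redundancy filtering.

Builds a tiny peptide set containing a known tumor-homing motif fragment,
scores pairs with Smith-Waterman/BLOSUM62 identity, and removes redundant
sequences at a 98% cutoff.
"""

from pepcsn import PeptideRecord, identity, redundancy_filter

a = PeptideRecord("frag", "CNGRC")
b = PeptideRecord("parent", "CNGRCGGKLA")
c = PeptideRecord("unrelated", "WWDDSSTTKK")

print("identity(frag, parent)    =", identity(a, b).value)
print("identity(frag, unrelated) =", round(identity(a, c).value, 3))
# 1.0 means the shorter peptide aligns as an exact substring of the longer;
# values near 0 mean no meaningful local alignment exists.

dup = PeptideRecord("dup", "CNGRCGGKLA")
kept = redundancy_filter([a, b, dup, c], cutoff=0.98)
print("kept after 98% dedup:", [r.id for r in kept])
# the sweep keeps the first record of each redundant group: 'frag' blocks
# both 'parent' and 'dup', which contain it exactly (identity 1.0)
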