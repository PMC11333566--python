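"""Build a compact indexed PBWT, query ranks, and invert it back.

Uses a small worked bit matrix so the per-site permutations are easy to
follow by eye.
"""

import numpy as np

from phaseprep import build_pbwt, invert_pbwt, rank0, rank1

rows = np.array(
    [[0, 1, 0, 1],
     [1, 1, 0, 0],
     [0, 1, 1, 0]], dtype=np.uint8)

p = build_pbwt(rows)
print("input rows (variant-major):")
for r in rows:
    print("  ", "".join(map(str, r)))
print("PBWT rows (reversed-prefix sorted order per site):")
for r, c in zip(p.pbwt_rows, p.cnt0):
    print("  ", "".join(map(str, r)), f"cnt0={c}")
print(f"final permutation: {p.final_permutation.tolist()}")
print(f"block zero-count index: {p.index.tolist()}")

site, pos = 2, 3
print(f"rank0(site={site}, pos={pos}) = {rank0(p, site, pos)}  "
      f"rank1 = {rank1(p, site, pos)}")
print("roundtrip from rows+cnt0 alone restores the input:",
      bool(np.array_equal(invert_pbwt(p), rows)))
print()
print("cnt0 is the boundary between the zero- and one-queue when routing the")
print("permutation to the next site; the index gives rank queries from one")
print("32-bit lookup plus a partial-block popcount.")
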