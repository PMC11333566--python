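"""Find set-maximal matches of a query haplotype and majority-fill untyped sites.

The query is a mosaic of two panel haplotypes with one switch, so its
set-maximal matches recover the two copied segments.
"""

import numpy as np

from phaseprep import SynthSpec, build_pbwt, fill_alleles, gen_panel, set_maximal_matches

spec = SynthSpec(n_haps=30, n_sites=40, seed=21)
panel = gen_panel(spec)

switch = 22
query = np.concatenate([panel.rows[:switch, 3], panel.rows[switch:, 11]]).astype(np.uint8)

pbwt = build_pbwt(panel.rows)
matches = set_maximal_matches(pbwt, query)
print(f"query copies haplotype 3 on [0,{switch}) and haplotype 11 on [{switch},40)")
print(f"{len(matches)} set-maximal matches (hap, start, end):")
for m in matches:
    print(f"  hap {m.hap:2d}  [{m.start:2d}, {m.end:2d})")

untyped = [5, 25, 39]
calls = fill_alleles(matches, panel, untyped)
print(f"majority-vote alleles at untyped sites {untyped}: {calls}")
print(f"true alleles of the mosaic there:               "
      f"{ {s: int(query[s]) for s in untyped} }")
print()
print("Each interval is an agreement no panel haplotype extends on either side;")
print("long matches covering the copied segments are expected, shorter ones are")
print("chance agreements with other haplotypes.")
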