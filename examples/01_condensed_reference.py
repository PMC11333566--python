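"""Score a reference panel against one target and build its condensed reference.

A small synthetic panel is drawn, one diploid target is sampled as a mosaic
of panel haplotypes, the K best-matching haplotypes are selected by
inconsistency count, and the condensed reference — alternating call-site
allele rows and OR-merged inconsistency segments — is printed.
"""

import numpy as np

from phaseprep import (
    SynthSpec,
    build_condensed,
    gen_panel,
    gen_targets,
    score_haplotypes,
    select_kbest,
)

spec = SynthSpec(n_haps=24, n_sites=16, mosaic_copy_rate=0.05, missing_rate=0.1, seed=4)
panel = gen_panel(spec)
(target,), _ = gen_targets(panel, spec, 1)

scores = score_haplotypes(panel, target)
sel = select_kbest(scores, 8)
cond = build_condensed(panel, target, sel)

print(f"panel: {panel.n_haps} haplotypes x {panel.n_sites} sites")
print(f"target call (heterozygous) sites: {np.flatnonzero(target.call).tolist()}")
print(f"scores of selected haplotypes:    {scores[sel.selected_indices].tolist()}")
print(f"condensed reference: {cond.rows.shape[0]} rows (2C+1 with C={cond.n_call_sites}), "
      f"width k={cond.k}")
for row, kind in zip(cond.rows, cond.row_kind):
    print(f"  {kind.name:8s} {''.join(map(str, row))}")
print()
print("SEGMENT rows mark, per selected haplotype, whether it contradicts any")
print("homozygous genotype in that between-call-site segment; CALLSITE rows are")
print("the raw alleles the phaser will decide between.  A column of zeros in")
print("every SEGMENT row is a haplotype fully consistent with the target.")
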