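"""Recovering a shared secondary signal with conditioning and masking.

Trait 1 carries two independent causal variants (A strong, B weaker); trait
2 is driven by B alone.  A single top-signal colocalisation compares A with
B and concludes "distinct variants" (H3), missing the shared signal.
Stepwise conditioning (or LD-masking, which needs no signed effects)
produces one analysis per lead-SNP pair and recovers the B-vs-B
colocalisation.
"""

import numpy as np

from coloctools import coloc_signals, label_comparison
from coloctools import simulate as sim

panel = sim.synth_haplotype_panel(M=200, block_size=20, seed=5)
common = panel.common_snps()
ld_panel = np.corrcoef(panel.haplotypes.T.astype(float)) ** 2
idx = {s: i for i, s in enumerate(panel.snp_ids)}
A, B = common[10], common[120]
assert ld_panel[idx[A], idx[B]] < 0.01  # independent LD blocks

truth = sim.SimTruth(
    "custom", causal1=[A, B], beta1=[1.0, 0.5], causal2=[B], beta2=[1.0]
)
d1, d2, _, (G1, _), (G2, _) = sim.simulate_trait_pair(
    panel, 5000, 5000, truth, seed=6, return_genotypes=True
)
ld1 = sim.genotype_ld(G1, panel.snp_ids)
ld2 = sim.genotype_ld(G2, panel.snp_ids)

print(f"truth: trait 1 causal at {A} (b=1.0) and {B} (b=0.5); trait 2 at {B}\n")

for mode in ("single", "cond", "mask"):
    rows = coloc_signals(d1, d2, ld1, ld2, mode, mode)
    print(f"{mode} mode ({len(rows)} comparison(s)):")
    for r in rows:
        lab = label_comparison(r.lead1, r.lead2, [A, B], ld1)
        print(
            f"  leads {r.lead1} vs {r.lead2} "
            f"[tags {lab.trait1_hit}:{lab.trait2_hit}]  "
            + "  ".join(f"PP.{h}={v:.3f}" for h, v in r.pp_dict.items())
        )
print(
    "\nsingle mode sees only the A-vs-B comparison (H3); cond/mask add the "
    "B-vs-B comparison, where PP.H4 ~ 1 reveals the shared secondary signal."
)
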