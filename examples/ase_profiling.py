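"""Allele-specific expression across fruit developmental stages.

Simulates replicated allele counts over the 13-stage fruit series (11 to
127 days after full bloom) with planted imbalance, runs the
negative-binomial ASE test (twofold + BH-adjusted p < 0.05), profiles
allele dominance and tests whether hybrid-ancestry genes are
over-represented among ASE genes.
"""

import numpy as np

from malus.ase import (
    ancestry_enrichment_test,
    ase_test,
    assignment_balance,
    dominance_profile,
)
from malus.simulate import DAF_STAGES, simulate_ase_counts

rng = np.random.default_rng(3)
n_genes = 800
effects = np.zeros((n_genes, len(DAF_STAGES)))
effects[:80, :] = 1.8          # consistent A-dominant genes
effects[80:100, :6] = 1.8      # dominance switches mid-development
effects[80:100, 6:] = -1.8

counts, truth = simulate_ase_counts(
    n_genes, stages=DAF_STAGES, replicates=3, effect_spec=effects,
    seed=3, mean_total=150, replicates_by_stage={11: 2},
)
balance = assignment_balance(counts)
overall = balance[balance["stage"] == "overall"].iloc[0]
print(f"read-assignment balance A:B = {overall['ratio']:.3f} (unbiased if ~1)")

calls = ase_test(counts)
ase_genes = calls.groupby("gene")["significant"].any()
print(f"ASE genes: {int(ase_genes.sum())} of {len(ase_genes)} tested "
      f"({ase_genes.mean():.0%})")

profile = dominance_profile(calls).set_index("gene")
print("dominance classes:", profile["class"].value_counts().to_dict())
# 'switching' genes change their higher-expressed allele between early and
# late fruit development - the signature of stage-specific cis-regulation.

hybrid = rng.random(n_genes) < 0.3
hybrid[:100] = rng.random(100) < 0.6  # ASE genes enriched for hybrid ancestry
odds, p = ancestry_enrichment_test(hybrid, ase_genes.reindex(range(n_genes), fill_value=False))
print(f"hybrid-ancestry enrichment among ASE genes: OR {odds:.2f}, p {p:.2e}")
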