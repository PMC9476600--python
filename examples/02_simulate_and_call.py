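"""Full pipeline on synthetic data with known ground truth.

Simulates two traits sharing 1% of their SNPs, runs genomic control,
condFDR/conjFDR and locus calling, then scores the calls against the
planted labels.
"""

import numpy as np

from crossfdr import SimConfig, call_shared_loci, harmonize_pair, run_cfdr, simulate_pair

cfg = SimConfig(n_snps=50_000, seed=2024)  # pi_shared=0.01, sigma2=25 defaults
table_a, table_b, truth = simulate_pair(cfg)
pair = harmonize_pair(table_a, table_b)
result = run_cfdr(pair)

print(f"SNPs harmonized     : {len(pair)}")
print(f"lambda (A, B)       : {result.gc_a.lam:.3f}, {result.gc_b.lam:.3f}")

loci = call_shared_loci(pair, result)  # ccFDR < 0.01 and p < 1e-5 in both
called = {l.snp_id for l in loci}
shared = set(truth.snp_ids[truth.mask("shared")])
print(f"called shared loci  : {len(loci)}")
print(f"  true positives    : {len(called & shared)}")
print(f"  false positives   : {len(called - shared)}")

relaxed = result.ccfdr < 0.05
lab_shared = truth.mask("shared")
sens = (relaxed & lab_shared).sum() / lab_shared.sum()
print(f"sensitivity @ ccFDR<0.05 : {sens:.2f}")
print("\nThe strict dual filter (ccFDR<0.01 AND p<1e-5 both) keeps the call")
print("set nearly free of non-shared SNPs; sensitivity is bounded by how")
print("many planted SNPs reach nominal significance in BOTH traits.")
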