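"""Pharmagenic enrichment: gene statistics, gene-set test, PES quintiles.

Simulates a GWAS in which the genes of a coagulation-like druggable
pathway carry the trait signal, computes MAGMA-style gene statistics at
the P-value-threshold bins, tests competitive enrichment, builds the
pathway polygenic score (PES), and estimates disease odds across PES
quintiles against the lowest quintile.
"""

import numpy as np

from pharmtri import scenarios

res = scenarios.pes_end_to_end_scenario(1, n=20_000)

enr = res["enrichment"]
print(f"Competitive enrichment at best P_T bin ({res['best_enrichment_bin']}):")
print(f"  coagulation-like pathway: beta {enr['beta_set']:.3f} "
      f"(se {enr['se']:.3f}), one-sided p {enr['one_sided_p']:.2e}")
null = res["null_enrichment"]
print(f"  matched null pathway:     beta {null['beta_set']:.3f} "
      f"(se {null['se']:.3f}), one-sided p {null['one_sided_p']:.2f}")

assoc = res["association"]
print(f"\nPES quintile dementia odds (reference: lowest quintile; "
      f"best P_T bin {res['best_pes_bin']}):")
for k in (2, 3, 4, 5):
    q = assoc["quintile_or"][k]
    lo, hi = q["ci"]
    print(f"  Q{k}: OR {q['or']:.2f} (95% CI {lo:.2f}-{hi:.2f})")
print(f"  per-SD log-odds: {assoc['per_sd_beta']:.3f} "
      f"(p {assoc['per_sd_p']:.1e})")
print(f"\nThe generator placed a top-vs-bottom-quintile OR of "
      f"{res['true_top_quintile_or']} on the true pathway genetic score;")
print("the Q5 estimate recovers it within its confidence interval (the mild")
print("shortfall reflects scoring with estimated GWAS weights), and the")
print("matched null pathway shows no enrichment.")
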