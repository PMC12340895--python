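"""Paired region x disease differential expression and spatial comparisons.

Simulates paired brain-region RNA-seq counts (cerebellum + DLPFC from each
of 20 subjects, half dementia cases) where a handful of genes are
up-regulated specifically in the DLPFC of cases, fits the paired NB GLM,
and runs Q3-normalized Wilcoxon comparisons on a small spatial panel.
"""

import numpy as np
import pandas as pd

from pharmtri import dge, synth

genes = [f"PCT{i + 1}" for i in range(5)] + [f"null{i + 1}" for i in range(45)]
log2fc = pd.DataFrame(0.0, index=genes,
                      columns=["region", "status", "interaction"])
log2fc.loc[[f"PCT{i + 1}" for i in range(5)], "interaction"] = 1.0
log2fc["region"] = 0.25

counts, design = synth.simulate_paired_counts(20, 0.1, log2fc, seed=3)
res = dge.fit_paired_nb(counts, design)

print("Region x status interaction (baseline: cerebellum in controls):")
cols = ["log2fc_interaction", "se_interaction", "p_interaction", "bh_q"]
print(res.loc[[f"PCT{i + 1}" for i in range(5)], cols].round(3).to_string())
hits = res.loc[res["bh_q"] < 0.05]
print(f"\n{len(hits)} genes pass BH q < 0.05 "
      f"({sum(h.startswith('PCT') for h in hits.index)} planted, "
      f"{sum(h.startswith('null') for h in hits.index)} null).")
print("Planted genes were simulated with interaction log2FC = 1: higher")
print("expression in the DLPFC of cases beyond region and status effects.")

# spatial arm: Q3-normalize ROIs and compare diagnosis groups per cell type
rng = np.random.default_rng(4)
n_roi = 18
base = rng.gamma(3.0, 20.0, (4, n_roi))
base[0, 12:] *= 2.0  # elevated first gene in dementia ROIs
expr = pd.DataFrame(base, index=["EPHB4", "NOS3", "GALK1", "SLK"],
                    columns=[f"roi{i}" for i in range(n_roi)])
meta = pd.DataFrame({
    "diagnosis": ["normal"] * 6 + ["MCI"] * 6 + ["dementia"] * 6,
    "cell_type": ["endothelial"] * n_roi,
}, index=expr.columns)
norm = dge.q3_normalize(expr)
wil = dge.celltype_wilcoxon(norm, meta)
print("\nEndothelial pairwise rank-sum tests (Q3-normalized):")
print(wil.loc[wil["gene"] == "EPHB4"].round(4).to_string(index=False))
print("EPHB4 was simulated 2x higher in dementia ROIs; the")
print("dementia-vs-normal contrast carries the small p-value.")
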