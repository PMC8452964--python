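"""The differential-statistics battery on planted effects.

Demonstrates (i) the per-gene paired t-test for differential
hydroxymethylation (DHGs) on a planted 2-fold shift, (ii) the exact
negative-binomial test for differential expression at a fixed, known
dispersion, and (iii) the Gaussian influence model that ties expression to
epigenomic covariates planted by the generator.
"""

import numpy as np
import pandas as pd

from pmdscape import differential as diff
from pmdscape import simulate

rng = np.random.default_rng(3)

# --- DHG paired t-test: 10% of genes get a 2-fold h-density shift ------------
rows = []
planted = set(range(10))
for g in range(100):
    x = rng.lognormal(0.0, 0.6, size=20)
    fold = 2.0 if g in planted else 1.0
    y = x * fold * np.exp(rng.normal(0.0, 0.25, size=20))
    rows += [(f"g{g}", "protein_coding", xi, yi) for xi, yi in zip(x, y)]
dhg = diff.dhg_paired_ttest(pd.DataFrame(rows, columns=["gene", "stratum", "x", "y"]))
sig = dhg[dhg.significant]
hits = sum(1 for g in planted if f"g{g}" in set(sig.gene))
print(f"DHG test: {len(sig)} significant of 100 genes; "
      f"{hits}/10 planted shifts recovered (q < 0.05)")

# --- exact NB test at fixed dispersion ---------------------------------------
rng2 = np.random.default_rng(11)
flat = rng2.poisson(rng2.integers(200, 400, size=8)[:, None], size=(8, 4))
counts = pd.DataFrame(
    np.vstack([[100, 110, 25, 30], flat]),
    index=["up_gene"] + [f"flat{i}" for i in range(8)],
    columns=["a1", "a2", "b1", "b2"],
)
groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
deg = diff.deg_exact_test(counts, groups, dispersion=1e-4, lfc_min=0.5)
print("\nDEG exact test (dispersion fixed at 1e-4):")
print(deg[["log2fc", "p", "q", "significant"]].round(4).to_string())

# --- influence model on planted expression effects ---------------------------
cfg = simulate.SimulationConfig(
    seed=33, chrom_lengths={"chr1": 4_000_000}, genes_per_mb=40.0,
    beta_hmch=0.6, beta_pmd_inside=-1.0, beta_enhancer=0.5, n_samples=6,
)
g = simulate.simulate_genome(cfg, np.random.default_rng(cfg.seed))
truth = simulate.plant_pmds(g, cfg, np.random.default_rng(1))
meths = simulate.simulate_methylomes(g, cfg, truth, np.random.default_rng(2))
feats = simulate.gene_epigenome_features(g, meths["cell0"], truth["cell0"])
mat, betas = simulate.simulate_expression(cfg, feats, np.random.default_rng(4))
y = np.log2(mat.mean(axis=1) / (feats["length"] / 1000.0) + 0.25)
model = diff.fit_influence_glm(y, feats)

print("\ninfluence model (log2 expression ~ epigenome flags):")
for name in ("hmch", "pmd_inside", "enhancer"):
    planted_log2 = betas[{"hmch": "hmch", "pmd_inside": "pmd_inside",
                          "enhancer": "enhancer"}[name]] / np.log(2)
    print(f"  {name:11s} fitted {model.params[name]:+.3f} "
          f"(SE {model.bse[name]:.3f}), planted {planted_log2:+.3f}")
print("\nFitted coefficients sit within ~2 SE of the planted log2 effects;"
      " genes inside PMDs are repressed, 5hmCH-marked genes are elevated.")
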