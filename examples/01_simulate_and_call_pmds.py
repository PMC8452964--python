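"""Simulate a methylome with planted PMDs, sequence it, and call the domains back.

Builds a 5-Mb genome, plants partially methylated domains covering ~30% of it
(uCG fraction 45% inside vs 12% outside), draws uTOP-seq-style reads at 3x
coverage per unmethylated CpG, and recovers the domains with the 10-kb window
caller.  The Jaccard index against the planted truth shows how faithfully the
window method reconstructs domain boundaries from noisy single-read evidence.
"""

import numpy as np

from pmdscape import density, pmd, simulate
from pmdscape.genome import overlap

cfg = simulate.SimulationConfig(seed=5, chrom_lengths={"chr1": 5_000_000}, n_cell_types=1)
rng = np.random.default_rng(cfg.seed)

genome = simulate.simulate_genome(cfg, rng)
truth = simulate.plant_pmds(genome, cfg, rng)
meths = simulate.simulate_methylomes(genome, cfg, truth, rng)
reads = simulate.simulate_reads(genome, meths["cell0"], cfg, rng, mode="u")

sites = genome.site_table()
coverage, unassigned = density.assign_reads_to_sites(reads, sites, cfg.max_offset)
calls = density.unit_coverage(coverage, sites, genome.cg_units) >= 1

windows = pmd.compute_window_fractions(calls, genome.cg_units, genome.layout)
called = pmd.call_pmds(windows, genome.layout)

inter = overlap(called[["chrom", "start", "end"]], truth["cell0"])["overlap"].sum()
union = ((called.end - called.start).sum()
         + (truth["cell0"].end - truth["cell0"].start).sum() - inter)

print(f"CpGs simulated:        {len(genome.cg_units):,}")
print(f"reads drawn:           {reads['count'].sum():,} ({unassigned} unassigned)")
print(f"planted PMDs:          {len(truth['cell0'])} covering "
      f"{(truth['cell0'].end - truth['cell0'].start).sum() / 5e6:.0%} of the genome")
print(f"called PMDs:           {len(called)}")
print(f"Jaccard(called,truth): {inter / union:.3f}")
print()
print("A Jaccard near 1 means the 30%-uCG/5-CpG window rule plus the 10-kb merge"
      " recovers the planted domains almost exactly from 3x read evidence.")
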