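"""Compute the kernel-normalized h-density track and its gene-element profile.

hmTOP-seq reads tag hydroxymethylated cytosines; h-density divides a
read-weighted kernel density by the local CpG density, removing library-size
and CpG-spacing effects.  The generator plants 5hmCG preferentially at
enhancers and gene 3' ends, so the element profile should peak in the 3'UTR —
the signature of active-gene-body hydroxymethylation.
"""

import numpy as np

from pmdscape import density, simulate

cfg = simulate.SimulationConfig(seed=8, chrom_lengths={"chr1": 3_000_000})
rng = np.random.default_rng(cfg.seed)

genome = simulate.simulate_genome(cfg, rng)
truth = simulate.plant_pmds(genome, cfg, rng)
meths = simulate.simulate_methylomes(genome, cfg, truth, rng)
reads = simulate.simulate_reads(genome, meths["cell0"], cfg, rng, mode="hm")

sites = genome.site_table()
coverage, _ = density.assign_reads_to_sites(reads, sites, cfg.max_offset)
track = density.compute_h_density(coverage, sites, genome.layout)

regions = density.aggregate_regions(track, width=50)
profile = density.profile_gene_elements(track, genome.annotations, flank=2000)

print(f"CpG sites in track:   {len(track):,} "
      f"({(~track['finite']).sum()} flagged non-finite)")
print(f"50-bp regions kept:   {len(regions):,}")
print()
print("mean h-density per gene element class:")
for cls, val in profile.items():
    bar = "#" * int(val / profile.max() * 30) if np.isfinite(val) else ""
    print(f"  {cls:14s} {val:8.3f}  {bar}")
print()
print("The 3'UTR class carries the strongest signal because the generator seeds"
      " 5hmCG at enhancers and gene 3' ends; upstream/intergenic stays near the"
      " background level.")
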