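"""SNP density around seed sites in a simulated genome.

A 6-base window slides from 18 bases upstream of the first seed base to 18
bases downstream; density is SNPs/kb pooled over all sites.  In the
simulated world, disruption SNPs are planted inside seed frames, so the seed
windows stand out against the flanks.
"""

import numpy as np

from seedvar import scan_utr, seed_average, window_density
from seedvar.simulate import SimulationConfig, simulate_world

world = simulate_world(SimulationConfig(rng_seed=0))
sites = []
for utr in world.utrs:
    sites.extend(scan_utr(utr, world.mirs, placement=world.placements[utr.name]))

profile = window_density(sites, world.snps)
print(f"{len(sites)} sites, {len(world.snps)} SNPs")
print(f"seed-window average density: {seed_average(profile):.2f} SNPs/kb")
peak = profile.density.max()
for off, d in zip(profile.offsets, profile.density):
    bar = "#" * int(40 * d / peak) if peak else ""
    marker = " <- seed" if 0 <= off < profile.window else ""
    print(f"{off:+4d} {d:7.2f} {bar}{marker}")
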