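"""Generate a synthetic landscape and inspect its ground truth.

Builds a small world — a smooth forest-cover field with lakes, a tree-height
raster, a land-class raster and an elevation model — plus modern surface
samples and fossil cores driven by a prescribed cover history.
"""

import numpy as np

from pollenmat import WorldConfig, generate_world

config = WorldConfig(n_modern=80, n_fossil_sites=6, samples_per_core=30,
                     resolution_m=3000.0, defect_fraction=0.2, seed=1)
world = generate_world(config)

land = world.cover.land_mask()
print(f"raster: {world.cover.shape[0]} x {world.cover.shape[1]} cells, "
      f"{(~land).sum()} water cells")
print(f"cover range on land: {world.cover.values[land].min():.1f}-"
      f"{world.cover.values[land].max():.1f} %")
print(f"modern samples: {len(world.modern)}, "
      f"defective: {(world.modern_truth['defect'] != '').sum()}")
print(f"fossil samples: {len(world.cores)} across {config.n_fossil_sites} sites, "
      f"ages {world.cores['age'].min():.0f} to {world.cores['age'].max():.0f} BP")

# the generator records the true cover behind every sample, so recovery can
# be scored later
truth = world.modern_truth["true_cover"]
print(f"true cover at modern sites: mean {truth.mean():.1f} %, sd {truth.std():.1f} %")
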