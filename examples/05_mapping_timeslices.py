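"""Timeslice binning and thin-plate-spline gridding of point estimates.

Fossil ages are partitioned into 49 slices (250-yr windows, 12,000-0 BP);
per-slice site values are interpolated over the elevation model in
(lon, lat, elev, age) with low-density and water masks.
"""

import numpy as np

from pollenmat import WorldConfig, generate_world, reconstruct_fossils, synthetic_dictionary
from pollenmat.calibration import build_calibration
from pollenmat.mapping import InterpolationConfig, TimesliceScheme, map_slices
from pollenmat.synthetic import frame_to_samples

scheme = TimesliceScheme()
print(f"timeslice scheme: {len(scheme.centers)} slices, "
      f"{scheme.centers[0]:.0f} to {scheme.centers[-1]:.0f} BP")
print(f"age 11,875 BP falls in the slice centered on {scheme.assign(11_875.0):.0f} BP "
      "(boundaries go to the younger slice)")

world = generate_world(WorldConfig(n_modern=100, n_fossil_sites=10,
                                   samples_per_core=40, resolution_m=4000.0, seed=5))
d = synthetic_dictionary()
entries = build_calibration(frame_to_samples(world.modern), world.cover, d,
                            height_raster=world.height, landclass_raster=world.landclass)
results = reconstruct_fossils(frame_to_samples(world.cores), entries, d)
fields = map_slices(results, world.elevation,
                    InterpolationConfig(min_sites=5, low_density_radius_km=150.0))
print(f"{len(fields)} slices gridded ({results['timeslice'].nunique()} had samples; "
      "sparse ones are skipped)")
f = fields[len(fields) // 2]
ok = ~f.combined_mask()
print(f"slice {f.timeslice:.0f} BP: cover {f.values[ok].min():.0f}-{f.values[ok].max():.0f} % "
      f"over {ok.sum()} unmasked cells")
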