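"""Generate a synthetic mapping region and inspect its structure.

Builds a 20 km x 20 km planar landscape (100 m pixels) with a rank-size
settlement hierarchy, land cover with water/built classes, a covariate
stack, and two nested admin levels whose census counts are drawn from a
known log-density model.
"""

import numpy as np

from popforest import LandscapeSpec, generate_landscape

land = generate_landscape(LandscapeSpec(seed=42))

print(f"grid: {land.template.n_rows} x {land.template.n_cols} pixels of "
      f"{land.template.pixel_width:.0f} m")
print(f"admin units: {len(land.coarse)} coarse / {len(land.fine)} fine")
print(f"total population: {land.fine.total():,}")

dens = land.fine.counts / land.fine.areas_km2()
print(f"fine-unit density range: {dens.min():.0f} - {dens.max():.0f} people/km^2")
print(f"covariate stack: {[l.name for l in land.stack]}")

water = (land.landcover.values == 210).mean()
built = np.isin(land.landcover.values, (190, 240)).mean()
print(f"land cover: {water:.1%} water, {built:.1%} built")

# The density range across fine units spans roughly two orders of
# magnitude: sparse countryside around 50 people/km^2 up to fully urban
# city-core units of several thousand.
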