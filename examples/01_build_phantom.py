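"""Build a head phantom, drop a random clot into it, place a sensor ring.

Prints the region composition and the clot geometry; the phantom is the
ground-truth velocity image later studies try to reconstruct.
"""

import numpy as np

from uctnet import Region, embed_clot, make_head_phantom, place_sensors, sample_clot, scaled_2d_spec

spec = scaled_2d_spec(grid=48, spacing=1.0)
phantom = make_head_phantom(spec)
clot = sample_clot(phantom, radius_range=(2.0, 3.5), clot_velocity=1700.0, seed=7)
sample = embed_clot(phantom, clot)
sensors = place_sensors(phantom, count=16)

print(f"grid {sample.shape} at {sample.spacing} mm")
for region in Region:
    n = int((sample.labels == np.uint8(region)).sum())
    v = sample.velocity[sample.labels == np.uint8(region)]
    vtxt = f"{v[0]:.0f} m/s" if n else "-"
    print(f"  {region.name:<6} {n:>5} cells  {vtxt}")
print(f"clot: center ({clot.center[0]:.1f}, {clot.center[1]:.1f}) mm, "
      f"radius {clot.radius:.2f} mm -> diameter {clot.diameter:.2f} mm")
print(f"sensors: {sensors.count} on a ring, all in water; first 3 at")
print(np.round(sensors.positions[:3], 1))
# The clot only ever replaces tissue cells; the skull ring and water bath are
# identical across samples — that static background is what makes whole-image
# correlation scores so high even before any clot is learned.
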