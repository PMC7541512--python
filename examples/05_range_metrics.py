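"""Range statistics: size, change, centre-of-gravity shift, Schoener's D.

Compares a current and a future binary range (the future range is smaller
and displaced north-east) and the overlap between two species' continuous
suitability surfaces.
"""

import numpy as np

from rangecast import (
    GridSpec,
    Layer,
    centre_of_gravity,
    cog_shift,
    range_change,
    range_size,
    schoener_d,
)

spec = GridSpec(50, 50, cellsize=1000.0)
current = np.zeros(spec.shape)
current[30:45, 5:25] = 1.0
future = np.zeros(spec.shape)
future[18:30, 14:30] = 1.0

cur = Layer(spec, "current", current)
fut = Layer(spec, "future", future)
print(f"range size: current {range_size(cur).cell_count} cells "
      f"({range_size(cur).area / 1e6:.0f} km^2), future {range_size(fut).cell_count} cells")
print(f"range change: {range_change(cur, fut):+.1f}%")

cog_now, cog_then = centre_of_gravity(cur), centre_of_gravity(fut)
dist, bearing = cog_shift(cog_now, cog_then)
print(f"centre of gravity moved {dist / 1000:.1f} km at bearing {bearing:.0f} deg "
      "(0 = North, 90 = East)")

rng = np.random.default_rng(0)
xs, ys = spec.centre_coords()
sp_a = Layer(spec, "a", np.exp(-(((xs - 20e3) ** 2 + (ys - 25e3) ** 2) / 2e8)))
sp_b = Layer(spec, "b", np.exp(-(((xs - 30e3) ** 2 + (ys - 25e3) ** 2) / 2e8)))
d = schoener_d(sp_a, sp_b).schoener_d
print(f"Schoener's D between two offset suitability hills: {d:.3f} "
      "(0 = no overlap, 1 = identical surfaces)")
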