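"""Generate a synthetic landscape and sample a virtual species from it.

Builds the 10-layer environment (climate, land cover, elevation,
imperviousness), derives the generalist virtual species' true suitability
surface, and draws presence-only records with sampling probability
proportional to suitability — the ground truth every later stage can be
checked against.
"""

import numpy as np

from rangecast import (
    GridSpec,
    LandscapeConfig,
    default_species,
    make_landscape,
    sample_occurrences,
    virtual_suitability,
)

config = LandscapeConfig(spec=GridSpec(100, 100, cellsize=1000.0), seed=42)
stack = make_landscape(config)
print("layers:", ", ".join(stack.names))
print(f"temperature: mean {stack['temperature'].values.mean():.2f} C, "
      f"sd {stack['temperature'].values.std():.2f} C")
print(f"impervious (sealed-soil) cells: {int(stack['imperviousness'].values.sum())}")

generalist, specialist = default_species()
suit = virtual_suitability(stack, generalist)
print(f"true suitability: min {suit.values.min():.3f}, max {suit.values.max():.3f}, "
      f"mean {suit.values.mean():.3f}")

occ = sample_occurrences(suit, n=200, seed=1, species=generalist.name)
suit_at_occ = np.array([suit.values[r, c] for r, c in occ.cells()])
print(f"sampled {len(occ)} presences; mean suitability at presences "
      f"{suit_at_occ.mean():.3f} vs landscape mean {suit.values.mean():.3f}")
print("presences concentrate in good habitat, as presence-only data should.")
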