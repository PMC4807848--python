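"""How much surface does a rounding cell have to hide?

A strongly spread fibroblast with ~31000 um^2 of membrane rounds into a cell
whose volume needs only ~2200 um^2 of smooth sphere: a 14-fold excess that
must be stored in surface structures.  If the storage is a carpet of equal
spherical bleb-like protrusions (BLiPs), the achievable excess is bounded:
the bound approaches 5 as the BLiPs shrink, so 14-fold excess demands
heterogeneous BLiP sizes (or non-spherical storage like tubules).
"""

import numpy as np

from blipsim.surface_math import (
    equal_blip_excess,
    excess_ratio,
    sphere_radius_from_area,
)

spread_area = 31000.0      # um^2, spread cell (both faces)
rounded_area = 2200.0      # um^2, smooth sphere enclosing the same volume

r_spread = sphere_radius_from_area(spread_area)
r_rounded = sphere_radius_from_area(rounded_area)
print(f"sphere holding the spread membrane : R = {r_spread:5.1f} um")
print(f"sphere holding the cell volume     : R = {r_rounded:5.1f} um")
print(f"excess surface ratio               : "
      f"{excess_ratio(spread_area, r_rounded):5.1f}x")

print("\nequal-BLiP storage bound (excess vs footprint coverage):")
for coverage in (0.25, 0.5, 0.9069, 1.0):
    tag = " (hexagonal disk packing)" if coverage == 0.9069 else \
          " (limit r -> 0)" if coverage == 1.0 else ""
    print(f"  coverage {coverage:6.4f} -> excess {equal_blip_excess(coverage):5.3f}{tag}")
print("The bound of 5 is well below 14: real cells must pack BLiPs of many "
      "sizes.")
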