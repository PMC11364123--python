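"""Build the three diode-array geometries used for measurement-based QA."""

import numpy as np

from complexiqa import build_layout

for kind in ("helical", "cross", "oblique_cross"):
    lay = build_layout(kind)
    r = np.hypot(lay.points[:, 0], lay.points[:, 1])
    print(f"{kind:14s}: {lay.n_points:4d} diodes, "
          f"radial extent {r.min():5.1f}..{r.max():5.1f} mm, "
          f"axial extent {lay.points[:, 2].min():6.1f}..{lay.points[:, 2].max():5.1f} mm")

# The helical array keeps every diode on a 105 mm cylinder (66 per ring x
# 21 rings = 1386); the cross arrays are two perpendicular 200 x 200 mm
# planes with 5 mm pitch in the central 60 x 60 mm and 10 mm outside; the
# oblique variant is the same lattice rotated 45 degrees about the axis.
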