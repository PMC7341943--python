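"""Box-counting fractal analysis of a mature rhizoid system.

Projects a 10 h simulated rhizoid system to 2-D, rasterises it at 0.5 µm
per pixel and computes the global box-counting dimension Db plus a radial
profile of locally resolved Db about the thallus.  Db = 1 means line-like,
2 means plane-filling; live mature cells sit in between and become less
fractal towards the growing edge.
"""

import numpy as np

from rhizomorph.fractal import box_count_db, local_db_map, radial_db_profile, rasterize
from rhizomorph.simulator import preset, simulate
from rhizomorph.swc import project_xy

params = preset("replete")
params.seed = 9
series, _ = simulate(params)
tree = series.trees[-1]

grid = rasterize(project_xy(tree), pixel_size=0.5)
result = local_db_map(grid, window_px=64, stride_px=16)
print(f"grid {grid.shape[0]}x{grid.shape[1]} px at {grid.pixel_size} um/px")
print(f"global Db = {result.db_global:.2f} (fit R^2 = {result.fit_r2:.3f})")

centre = (float(tree.root_position[0]), float(tree.root_position[1]))
profile = radial_db_profile(result, centre=centre, bin_width=20.0)
print(f"{'radius (um)':>12} {'mean local Db':>14}")
for r, db in profile:
    print(f"{r:12.0f} {db:14.2f}" if np.isfinite(db) else f"{r:12.0f} {'-':>14}")
print()
print("The profile decreasing outward mirrors the centre-dense, edge-sparse")
print("organisation of a feeding rhizoid system.")
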