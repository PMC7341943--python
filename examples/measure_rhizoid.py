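"""Measure a single traced rhizoid system.

Builds a small Y-shaped SWC trace (thallus root, 10 µm trunk, two 10 µm
daughter rhizoids), writes it to disk, reads it back and prints the full
morphometric suite.  All distances are micrometres.
"""

import tempfile
from pathlib import Path

from rhizomorph import read_swc, summarize

SWC = """\
# units: micrometres
1 1 0 0 0 2.0 -1
2 5 0 0 0 0.5 1
3 3 0 10 0 0.5 2
4 3 6 18 0 0.5 3
5 3 -6 18 0 0.5 3
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy_y.swc"
    path.write_text(SWC)
    tree = read_swc(path)

rec = summarize(tree)
print(f"total rhizoid length : {rec.total_length:.1f} um")
print(f"tips / bifurcations  : {rec.n_tips} / {rec.n_bifurcations}")
print(f"RGU (ratio/segment)  : {rec.rgu_ratio:.1f} / {rec.rgu_segment:.1f} um")
print(f"max Euclidean reach  : {rec.max_euclidean:.2f} um")
print(f"bifurcation angle    : {rec.mean_bif_angle:.2f} deg")
print(f"cover area           : {rec.cover_area:.1f} um^2")
print()
print("The RGU (total length / tip count) says how much filament the cell")
print("maintains per growing tip; the cover area is the hull of the")
print("territory its rhizoids span.")
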