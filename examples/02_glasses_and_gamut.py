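"""The red-glasses filter model and its effect on the monitor gamut.

Builds the logistic red-glasses transmittance, checks it against the
published characterisation of the physical glasses, and compares the
monitor's CIE 1931 gamut with and without the filter.
"""

import numpy as np

from chromadapt.display import (
    default_monitor,
    monitor_gamut,
    polygon_area,
    polygon_centroid,
    synth_red_glasses,
)

glasses = synth_red_glasses()
t = glasses.transmittance
print(f"transmittance at 550 nm: {t(550.0):.3f}  (spec of the physical glasses: < 0.10)")
print(f"transmittance at 620 nm: {t(620.0):.3f}  (spec of the physical glasses: > 0.90)\n")

mon = default_monitor()
g0 = monitor_gamut(mon)
g1 = monitor_gamut(mon, glasses)
print("gun primaries in CIE 1931 xy (rows: red, green, blue):")
print(np.round(g0, 4))
print("through the glasses:")
print(np.round(g1, 4))
print(f"\ngamut area: {polygon_area(g0):.4f} -> {polygon_area(g1):.4f} "
      "(the glasses compress the gamut)")
print(f"gamut centroid x: {polygon_centroid(g0)[0]:.3f} -> {polygon_centroid(g1)[0]:.3f} "
      "(and shift it toward red)")
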