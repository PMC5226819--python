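"""Map the single-cell response regimes over stimulus intensities.

Sweeps a coarse grid of (plateau influx, plateau [InsP3]) pairs and prints
which yield sustained oscillation (zone I, '.'), damped transients
(zone II, 'o') or a saturated non-oscillating response (zone III, '#').
A finer 20 x 20 sweep takes a few minutes; this 8 x 8 one is quick.
"""

import numpy as np

from cawave.presets import regime_map

jinf = np.geomspace(0.02, 12.0, 8)   # nM/s
ip3 = np.geomspace(0.2, 8.0, 8)      # uM

zones = regime_map(jinf, ip3, t_end=800.0)

sym = {"I": ".", "II": "o", "III": "#"}
print("          i_IP3,max (uM):", "  ".join(f"{v:5.2f}" for v in ip3))
for a in range(len(jinf) - 1, -1, -1):
    row = "      ".join(sym[z] for z in zones[a])
    print(f"i_JINF,max {jinf[a]:6.3f} nM/s   {row}")
print("\n. sustained oscillation   o damped transient   # saturation")
# the oscillatory zone is a connected island: too little drive never ignites
# spiking, too much drive (either parameter) locks the cell on a plateau.
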