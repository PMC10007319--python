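"""Evolve a luminance profile with the 1D shock filter.

A blurred two-spot profile is driven to its piecewise-constant steady
state; the surviving discontinuities mark the spot borders, which is the
primitive the whole gridding approach is built on.
"""

import numpy as np

from hexspot import ShockConfig, find_shock_inflexions, shock_filter_1d
from hexspot.profiles import plateau_pairs

x = np.arange(120, dtype=float)
profile = (1000 * np.exp(-((x - 40) ** 2) / (2 * 6.0 ** 2))
           + 800 * np.exp(-((x - 80) ** 2) / (2 * 6.0 ** 2)))

steady = shock_filter_1d(profile, ShockConfig())
min_jump = 0.1 * (steady.max() - steady.min())
inflexions = find_shock_inflexions(steady, min_jump)
pairs = plateau_pairs(steady, min_jump)

print(f"input : smooth, total variation {np.abs(np.diff(profile)).sum():.0f}")
print(f"output: piecewise constant, {inflexions.count} jumps at {inflexions.positions.tolist()}")
for up, down in pairs:
    centre = (up + 1 + down) / 2
    print(f"  plateau {up + 1}..{down}  ->  object centred at x = {centre:.1f}")
print("the two centres sit at the Gaussian bumps (x = 40 and 80);")
print("jump positions are where the original profile had its edges")
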