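"""Build minimum-jerk submovements and superpose them into a reach.

A submovement displaces the fingertip by its amplitude vector A over a
duration D, with the bell-shaped velocity profile 30 tau^2 (1-tau)^2.
Overlapping submovements simply add.
"""

import numpy as np

from submovekit import Submovement, TimeGrid, minjerk_velocity, position_trajectory, superpose

grid = TimeGrid.regular(1.6)  # 100 Hz, 1.6 s

# a 30 cm primary movement followed by an overlapping 8 cm correction
primary = Submovement(t0=0.0, D=0.7, A=np.array([28.0, 8.0, 10.0]))
correction = Submovement(t0=0.5, D=0.4, A=np.array([2.0, -0.5, 1.5]))

v1 = minjerk_velocity(primary, grid)
print(f"primary peak speed: {np.linalg.norm(v1, axis=1).max():.2f} cm/s "
      f"(analytic 15/8 * |A|/D = {15 / 8 * np.linalg.norm(primary.A) / primary.D:.2f})")

v = superpose([primary, correction], grid)
p = position_trajectory([primary, correction], np.zeros(3), grid)

total = primary.A + correction.A
print(f"final position: {np.round(p[-1], 3)} cm  (sum of amplitudes: {total})")
print("the reach lands exactly at the amplitude sum: displacement is conserved")
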