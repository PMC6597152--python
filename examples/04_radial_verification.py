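"""Verify the 2D level-set solver against the independent 1D radial solver.

For a circular explant the moving-boundary problem is radially symmetric, so
a 1D polar finite-difference solver with explicit front tracking provides an
independent reference.  The script prints the front radius from both solvers
at a few times and the worst relative disagreement over all frames.
"""

import math

import numpy as np

import epispread as ep

params = ep.ParameterSet(F_over_k=0.8, k_over_b=1000.0, alpha=0.5,
                         rho_unstressed=1500.0)
contour = ep.make_initial_contour("circle", area_mm2=math.pi * 0.3 ** 2)
grid = ep.Grid.square(2000.0, 10.0, x0=-1000.0, y0=-1000.0)

series = ep.simulate(contour, params, grid, ep.Schedule(t_end_h=4.0))
oracle = ep.simulate_radial(300.0, params, t_end_h=4.0)

r2d = np.sqrt(series.areas_mm2() / math.pi) * 1000.0
rel = np.abs(r2d - oracle.radius) / oracle.radius
for k in range(0, series.n_frames, 12):   # hourly
    print(f"t = {series.times[k]:4.1f} h   2D radius {r2d[k]:6.1f} um   "
          f"1D radius {oracle.radius[k]:6.1f} um   rel diff {rel[k]*100:.2f}%")
print(f"\nmax relative radius difference over {series.n_frames} frames:"
      f" {rel.max()*100:.2f}%")
print("(both solvers discretise the same front law; sub-2% agreement at"
      " h = 10 um is the expected first-order accuracy)")
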