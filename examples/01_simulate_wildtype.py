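"""Simulate the wild-type heart field and locate the signal boundary.

Runs the default scenario (normal receptor feedback, sFRP1 and N-acetyl
HS present, no dominant-negative receptor) over the full 1e5 s horizon
and reports where the Wnt-signal-active region ends.
"""
import numpy as np

from wntgrad import Scenario, edge_position, simulate
from wntgrad.fixtures import mass_balance_report

traj = simulate(Scenario())
omega = traj.omega[-1]
grid = traj.grid

peak = float(omega.max())
peak_x = float(grid.cell_centers[omega.argmax()])
threshold = 0.1 * peak
edge = edge_position(omega, threshold, grid)
rep = mass_balance_report(traj)

print(f"peak signal activity      : {peak:.3f} nM at x = {peak_x:.2f} um")
print(f"edge of active region     : {edge:.2f} um (threshold {threshold:.3f} nM)")
print(f"Wnt mass-balance residual : {rep['wnt_rel_err'].max():.2e} (relative)")
print(f"HS per-cell drift         : {rep['hs_max_cell_rel_err'].max():.2e} (relative)")
# The peak sits at the receptor bump's rising flank near the source; the
# edge position marks the model's pericardium/myocardium boundary, and the
# residuals confirm the integrator honoured the network's conservation laws.
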