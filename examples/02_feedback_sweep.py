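"""How receptor positive feedback steepens the signal gradient.

Sweeps the feedback gain (0 = none, 1 = normal, 5 = strong) and compares
the final activity profiles and the width of the signal-active region.
"""
import numpy as np

from wntgrad.experiments import run_feedback_sweep

res = run_feedback_sweep()
prof = res.tables["final_profiles"].pivot_table(
    index="x_um", columns="feedback", values="omega_nM")
widths = res.tables["widths"].pivot_table(
    index="threshold_nM", columns="feedback", values="width_um")
threshold = 0.1 * prof[0.0].max()
row = widths.iloc[int(np.argmin(np.abs(widths.index - threshold)))]

for fb in (0.0, 1.0, 5.0):
    print(f"feedback x{fb:g}: peak omega = {prof[fb].max():6.2f} nM, "
          f"steepest slope = {np.abs(np.diff(prof[fb])).max() / 0.5:5.2f} nM/um, "
          f"active width = {row[fb]:5.2f} um")
# Stronger feedback concentrates receptor production where signalling is
# already high: the peak grows, the gradient steepens, and the active
# region (width at a mid-gradient threshold) narrows.
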