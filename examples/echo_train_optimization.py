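"""Optimize the T2-weighted TSE echo train for SNR efficiency.

Sweeps refocusing flip angle (10-90 deg) against echo train length (30-200)
at TR 2500 ms for vessel-wall relaxation (T1/T2 = 1114/55 ms), scoring each
cell by center-echo intensity times acquisition duty cycle, and extracts the
per-ETL optimal flip (the "ridge").
"""

import numpy as np

from vwisim.optimize import compute_efficiency_grid, optimize_train
from vwisim.params import TissueParams, FlowSpec, vista_protocol
from vwisim.sequences import equivalent_te, vista_signal

grid = compute_efficiency_grid()
opt = optimize_train(grid)

print("SNR-efficiency optimization (TR 2500 ms, esp 3.6 ms, wall T1/T2 1114/55 ms)")
print(f"  grid argmax: flip {opt.best_flip_deg:.0f} deg at ETL {opt.best_etl}")
ridge = opt.ridge
for etl in (50, 90, 130, 170):
    f = float(ridge.loc[ridge.etl == etl, "flip_deg"].iloc[0])
    print(f"  ridge flip at ETL {etl:3d}: {f:5.1f} deg")
f130 = float(ridge.loc[ridge.etl == 130, "flip_deg"].iloc[0])
print(f"-> longer trains demand lower flips; at the protocol ETL of 130 the")
print(f"   optimum ({f130:.1f} deg) sits near the protocol's constant 32 deg choice.")

wall = TissueParams(1114.0, 55.0)
_, center = vista_signal(wall, FlowSpec(), vista_protocol())
print(f"\nCenter-echo amplitude of the 32-deg train: {center:.4f} of M0")
print(f"  pure T2 decay at the 255 ms effective TE would give {np.exp(-255 / 55):.4f};")
print(f"  the equivalent spin-echo TE is {equivalent_te(center, wall):.0f} ms —")
print("  the pseudo-steady train stores magnetization along z, preserving T2 contrast")
print("  at a much milder effective decay than the nominal echo time suggests.")
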