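"""The iMSDE first-gradient-moment tradeoff: suppression versus wall signal.

Larger flow-encoding moments (M1) dephase slow-moving spins (CSF, boundary
layer blood) more completely, but require longer encoding gradients, so the
vessel wall loses signal to T2 decay during the longer preparation.
"""

from vwisim.params import FlowSpec, TissueParams
from vwisim.sequences import flow_dephasing_factor, imsde_attenuation, merge_prep_duration

wall = TissueParams(1114.0, 55.0, 1.0, "wall")
fast_blood = FlowSpec(0.30, 0.9)   # carotid, recirculating
csf_like = FlowSpec(0.015, 1.0)    # slow pulsatile CSF

print("M1 (mT*ms^2/m)  prep (ms)  wall signal  blood residual  CSF residual")
for m1 in (500.0, 1000.0, 1500.0):
    prep = merge_prep_duration(m1)  # minimal duration at the 20 mT/m cap
    s_wall = imsde_attenuation(wall, FlowSpec(), m1, prep)
    f_blood = flow_dephasing_factor(fast_blood, m1)
    f_csf = flow_dephasing_factor(csf_like, m1)
    print(f"{m1:14.0f} {prep:10.1f} {s_wall:12.3f} {f_blood:15.4f} {f_csf:13.3f}")

print(
    "\nArterial blood is crushed at every moment tested, but the slow CSF"
    "\ncompartment needs M1 >= 1000 to fall below ~20% residual, while the wall"
    "\nsignal drops only a few percent per step — which is why the middle value"
    "\n(1000 mT*ms^2/m) is the selected operating point."
)
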