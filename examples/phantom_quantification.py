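"""Build the digital vessel phantom, acquire the three contrasts, measure SNR.

A bilateral carotid-to-MCA tube phantom is acquired with the three
black-blood sequences; cross-sections normal to the centerline at the five
named locations are reformatted and wall/lumen SNR measured with the
reference-tissue-noise convention.
"""

from vwisim.params import default_protocols
from vwisim.phantom import acquire, build_phantom, calibrate_noise, compact_scene
from vwisim.quantify import measure_volume, measurements_to_frame

protocols = default_protocols()
scene = compact_scene(seed=0)
built = build_phantom(scene)
scene.noise_sigma = calibrate_noise(scene, protocols, built=built)

for kind, proto in protocols.items():
    acq = acquire(built, proto, seed=0)
    df = measurements_to_frame(measure_volume(acq, built))
    table = df.groupby("location")[["snr_w", "snr_l", "cnr_w_l"]].mean().round(2)
    print(f"\n{kind}: bilateral-mean SNR by location")
    print(table.to_string())

print(
    "\nReading the tables: wall SNR dips at ICA C2/C5 (farthest from both"
    "\nsurface coils), the T2-weighted sequence brightens the MCA wall (CSF"
    "\npartial volume), and SNAP lumen SNR exceeds wall SNR but with opposite"
    "\npolarity — its wall-lumen contrast is the sum, not the difference."
)
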