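"""Simulate one e-nose recording and inspect its shape.

An aroma class is a pattern of steady-state amplitudes across the 8-sensor
MOS array. A recording is 2000 s at 1 Hz: 500 s clean-air baseline, a
1000 s odor exposure producing an exponential rise to a plateau, then
recovery.
"""

import numpy as np

from enosekit import SimulationConfig, default_profiles, default_sensor_array, simulate_measurement

profiles = default_profiles()
kona = next(p for p in profiles if p.label == "Kona")
m = simulate_measurement(kona, default_sensor_array(), SimulationConfig(seed=1))

print(f"label: {m.label}")
print(f"shape: {m.voltages.shape}  (seconds x sensors)")
print(f"sensors: {', '.join(m.sensor_names)}")
baseline = m.voltages[:500].mean(axis=0)
plateau = m.voltages[1200:1500].mean(axis=0)
for name, b, p in zip(m.sensor_names, baseline, plateau):
    print(f"  {name:8s} baseline {b:5.3f} V -> plateau {p:5.3f} V (excess {p - b:+.3f})")
# The plateau excess per sensor approximates the profile's amplitude
# vector; it is this pattern that identifies the origin.
print("largest plateau response:", m.sensor_names[int(np.argmax(plateau))])
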