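"""Extract stable-window subdivision-average features from recordings.

The 500-1500 s plateau is cut from each recording, split into 8 contiguous
subdivisions, and each subdivision is averaged per sensor: 8 sensors x 8
subdivisions = 64 features per recording.
"""

from enosekit import (
    SimulationConfig,
    StableWindow,
    default_profiles,
    default_sensor_array,
    extract_stable_window,
    features_to_frame,
    generate_dataset,
    stacked_sensor_means,
    subdivide_and_average,
)

sensors = default_sensor_array()
dataset = generate_dataset(default_profiles()[:3], 4, sensors, SimulationConfig(), seed=2)

window = StableWindow(500, 1500)
fvs = [subdivide_and_average(extract_stable_window(m, window), 8) for m in dataset]
df = features_to_frame(fvs, [s.name for s in sensors], 8)
print(df.iloc[:5, :6].to_string(index=False))
print(f"... feature table: {df.shape[0]} recordings x {df.shape[1] - 2} features")

# Per-origin, per-sensor mean voltages (the stacked-bar summary): the
# CO-sensitive MQ7 channel reads highest for every origin.
table = stacked_sensor_means(dataset)
print(table.round(3).to_string())
print("row maxima:", table.idxmax(axis=1).unique())
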