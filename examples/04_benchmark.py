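"""Benchmark classifier families on two-class and nine-class tasks.

Mirrors the experimental design: stratified 80/20 split, accuracy as the
metric, a balanced one-vs-rest task (Kona vs non-Kona) and the full
nine-origin multi-class task.
"""

from enosekit import (
    SimulationConfig,
    StableWindow,
    default_profiles,
    default_sensor_array,
    extract_stable_window,
    generate_dataset,
    make_one_vs_rest_task,
    report_accuracy_grid,
    run_benchmark,
    split_dataset,
    subdivide_and_average,
    SplitSpec,
)

dataset = generate_dataset(
    default_profiles(), 20, default_sensor_array(), SimulationConfig(), seed=4
)
fvs = [
    subdivide_and_average(extract_stable_window(m, StableWindow(500, 1500)), 8)
    for m in dataset
]
backends = ["decision_tree", "random_forest", "xgboost", "svm"]

train, test = split_dataset(fvs, SplitSpec(seed=4))
print(f"multiclass: {len(train)} train / {len(test)} test")
results = run_benchmark(train, test, backends, task="multiclass", seed=4)

task = make_one_vs_rest_task(fvs, "Kona", seed=4)
print(f"Kona vs rest: {task.n_positive} positive / {task.n_negative} negative")
btrain, btest = split_dataset(task.features, SplitSpec(seed=4))
results += run_benchmark(btrain, btest, backends, task="Kona", seed=4)

print(report_accuracy_grid(results).to_string(na_rep="NA"))
# Cells are test-set accuracies in [0, 1]; the default synthetic origins
# are well separated relative to sensor noise, so accuracies are near 1.
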