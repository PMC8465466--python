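"""Train small classifiers under a mini experiment grid.

Generates a planted-effect dataset, splits it 70/30, and compares two
configurations of the residual backbone — a high learning rate with
batch normalization against a low one without — reporting accuracy,
sensitivity and specificity per row, the same reporting shape used for
full transfer-learning grids.
"""

from facequant import cnn, synthgen

params = synthgen.SynthFaceParams(
    image_size=64, n_case=60, n_control=120, effect_amplitude=0.8, seed=3)
dataset = synthgen.generate_dataset(params)
train_set, test_set = synthgen.split_dataset(dataset, 0.7, seed=1)
print(f"{len(train_set)} training / {len(test_set)} test images")

grid = [
    cnn.ExperimentConfig(name="bn-on", backbone="small-resnet-like",
                         learning_rate=0.1, batch_norm=True,
                         input_size=64, epochs_max=8, seed=5),
    cnn.ExperimentConfig(name="bn-off", backbone="small-resnet-like",
                         learning_rate=0.01, batch_norm=False,
                         input_size=64, epochs_max=8, seed=5),
]
report = cnn.run_experiment_grid(grid, train_set, test_set)
print(report[["experiment", "learning_rate", "batch_norm", "TP", "FN", "FP",
              "TN", "ACC", "SEN", "SPE", "best"]].to_string(index=False))

print("\nACC/SEN/SPE are percentages on the held-out test set; the planted")
print("regional signal (amplitude 0.8) is strong, so both rows should be")
print("well above chance, and the best row is flagged.")
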