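"""Regional quantification of saliency heatmaps with chi-square comparison.

Generates synthetic heatmaps for 50 case faces (strong blobs in nose and
cheeks) and 50 control faces (weak uniform blobs), runs the
binarize -> blur -> contour -> size-filter -> per-region presence
pipeline, and prints the aggregated region table.
"""

import numpy as np

from facequant import faceregions, featquant, synthgen

rng = np.random.default_rng(0)
params = synthgen.SynthFaceParams(image_size=64, n_case=0, n_control=0)
EFFECT = {"nose", "left-cheek", "right-cheek"}

case_hits, control_hits = [], []
for group, sink in (("case", case_hits), ("control", control_hits)):
    for _ in range(50):
        lm = synthgen.jittered_landmarks(params, rng)
        partition = faceregions.partition_face(lm)
        weights = {r: (0.9 if group == "case" and r in EFFECT else 0.4)
                   for r in faceregions.REGION_NAMES}
        heat = synthgen.generate_heatmap(
            lm, weights, seed=int(rng.integers(2**31)),
            background_noise=0.2, partition=partition)
        sink.append(featquant.quantify_heatmap(heat, partition, min_size=3))

table = featquant.aggregate(case_hits, control_hits)
print(table[["region", "n_case", "p_case", "n_control", "p_control",
             "p_value", "direction"]].to_string(index=False))

print("\np_case/p_control are the percentages of images in each group with")
print("at least one surviving saliency feature in that region. The planted")
print("nose and cheek concentration shows up as case-higher rows with tiny")
print("chi-square p-values; the other regions stay near the noise floor.")
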