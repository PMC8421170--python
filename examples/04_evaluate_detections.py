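"""Score detections against ground truth and summarize across samples.

Detections on one frame are matched to the ground-truth objects within a
20 px gate: motile objects found are true positives, static objects left
alone are true negatives. Accuracy, sensitivity and specificity follow
from the pooled counts. The second half summarizes the bundled ten-sample
detection benchmark the same way results tables in the CASA literature
are reported: mean +/- population standard deviation.
"""

from spermtrack import (
    BackgroundParams,
    accuracy,
    init_mixture,
    match_to_ground_truth,
    sensitivity,
    specificity,
    summarize_performance,
    update_and_classify,
)
from spermtrack.datasets import load_detection_benchmark
from spermtrack.detection import detect_in_mask
from spermtrack.synthetic import benchmark_scene

seq, gt, config = benchmark_scene(seed=4, n_frames=60)
params = BackgroundParams(bg_t=0.5)
state = init_mixture(seq[0], params)
pooled = None
for idx in range(len(seq)):
    state, mask = update_and_classify(state, seq[idx], params)
    if idx >= params.burn_in_frames and (idx - params.burn_in_frames) % 10 == 0:
        detections = detect_in_mask(mask, idx)
        counts = match_to_ground_truth(detections, gt, idx)
        pooled = counts if pooled is None else pooled + counts

print(f"pooled over sampled frames: TP={pooled.tp} TN={pooled.tn} "
      f"FP={pooled.fp} FN={pooled.fn}")
print(f"accuracy {accuracy(pooled):.1f}%  sensitivity {sensitivity(pooled):.1f}%  "
      f"specificity {specificity(pooled):.1f}%")
print("A perfect run detects every motile head (no FN) and never fires on "
      "immotile cells or debris (no FP).")

bench = load_detection_benchmark()
rows = bench[bench.method == "mixture_model"]
summary = summarize_performance(
    list(zip(rows.accuracy, rows.sensitivity, rows.specificity))
).rounded()
print("\nbundled ten-sample benchmark, mixture-model detector:")
print(f"  accuracy    {summary['accuracy_mean']} +/- {summary['accuracy_std']} %")
print(f"  sensitivity {summary['sensitivity_mean']} +/- {summary['sensitivity_std']} %")
print(f"  specificity {summary['specificity_mean']} +/- {summary['specificity_std']} %")
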