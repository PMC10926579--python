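"""The validation protocol: random sample, confusion matrix, metrics.

Reproduces the chart-review arithmetic: a seeded simple random sample of
record ids, an actual-vs-predicted confusion matrix over four classes,
and accuracy / sensitivity / specificity with the review's correctness
convention (inconclusive samples extracted as "not detected" count as
correct; cancelled tests extracted as anything else do not).
"""

from egfrtext import ConfusionMatrix, compute_metrics, draw_sample

population = [f"test-{i:05d}" for i in range(8900)]
sample = draw_sample(population, n=362, seed=1)
print(f"review sample: {len(sample)} of {len(population)} tests "
      f"({len(sample) / len(population):.2%})")

# Reviewed outcome counts: rows = actual class, cells = predicted class.
cm = ConfusionMatrix.from_counts(
    {
        ("detected", "detected"): 35,
        ("not_detected", "not_detected"): 308,
        ("inconclusive", "not_detected"): 10,
        ("not_tested", "not_detected"): 9,
    }
)
metrics = compute_metrics(cm)
print(f"correct extractions: {metrics.n_correct}/{metrics.n_total}")
print(f"accuracy:    {metrics.accuracy:.1%}")
print(f"sensitivity: {metrics.sensitivity:.0%}  (detected samples recovered)")
print(f"specificity: {metrics.specificity:.0%}  (not-detected samples recovered)")
# The 9 misses are cancelled tests predicted not-detected: the failure mode
# the grammar's cancelled-test extension eliminates.
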