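"""Count-based evaluation: centroid matching and the confusion metrics.

Detected centroids are matched one-to-one to ground truth within a radius;
components removed by postprocessing count as true negatives.
"""

import entroseg as es

truth = [(10.0, 10.0), (30.0, 12.0), (18.0, 40.0), (44.0, 44.0)]
detected = [(11.0, 10.5), (29.0, 12.0), (18.5, 41.0), (5.0, 55.0)]  # one spurious

tp, fp, fn = es.match_detections(detected, truth, max_dist=4.0)
tn = es.true_negatives(count_before_post=9, count_after_post=4)
result = es.evaluate(tp, fp, fn, tn)

print(f"TP={result.tp}  FP={result.fp}  FN={result.fn}  TN={result.tn}")
print(f"accuracy    = {result.accuracy:.2f}%")
print(f"precision   = {result.precision:.2f}%")
print(f"sensitivity = {result.sensitivity:.2f}%")
print(f"specificity = {result.specificity:.2f}%")

# Three detections land within 4 px of a distinct truth centroid (TP=3); the
# fourth matches nothing (FP=1); one truth nucleus was missed (FN=1); five
# noise components were removed by postprocessing (TN=5).
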