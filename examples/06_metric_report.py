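"""Confusion-matrix metric report from raw label vectors."""

import json

from goaelm import confusion_counts, metric_report

y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
y_pred = [1, 1, 1, 1, 0, 0, 0, 0, 0, 1]

counts = confusion_counts(y_true, y_pred, positive_label=1)
print(f"TP={counts.tp} TN={counts.tn} FP={counts.fp} FN={counts.fn}")
print(json.dumps(metric_report(counts).to_dict(), indent=2))

# Eight indicators derive from the four counts; precision and PPV are the
# same quantity, and a metric with a zero denominator would be reported
# as null rather than a misleading zero.
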