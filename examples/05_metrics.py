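"""Confusion-matrix metrics, including F1 from published recall/precision.

Recomputes the F1 harmonic mean from the recall/precision rates reported
for the three optimizers in the reference comparison on BreakHis.
"""

from gacnn import ConfusionMatrix, accuracy, error_rate, f1, precision, recall

# F1 = 2 R P / (R + P) from each optimizer's recall/precision rates
for name, r, p in [
    ("gradient descent", 0.5561, 0.8437),
    ("adam", 0.7231, 0.9623),
    ("ga", 0.6943, 0.9471),
]:
    print(f"{name:17s} recall {r:.2%}  precision {p:.2%}  ->  F1 {f1(r, p):.2%}")

cm = ConfusionMatrix(tp=50, fp=5, tn=60, fn=15)
print(f"\nexample confusion matrix: {cm}")
print(f"accuracy {accuracy(cm):.3f}  error rate {error_rate(cm):.3f}  "
      f"recall {recall(cm):.3f}  precision {precision(cm):.3f}  f1 {f1(cm):.3f}")
# error rate is (FP+FN)/N — the quantity the genetic algorithm minimizes.
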