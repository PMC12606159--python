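"""Leave-one-out discriminant classification of the ten measurable types.

Draws a feature matrix at the published per-type means, standard
deviations and sample sizes (394 calls over 10 types), runs the
cross-validated discriminant analysis and prints the headline
statistics.  The structural pattern matches the field study: Moan is the
best-classified elemental type and combinational calls are confused
with their constituent elementals.
"""

from sealvoc.classify import loocv_classify
from sealvoc.synth import synth_feature_matrix

X, y = synth_feature_matrix(seed=0)
report = loocv_classify(X, y)

lo, hi = report.ci95
print(f"n = {report.n} calls, {len(report.classes)} vocal types")
print(f"accuracy {report.accuracy:.1f}%  (95% CI {lo:.1f}-{hi:.1f}%), "
      f"kappa {report.kappa:.2f}")
print(f"variance explained: LD1 {report.variance_explained[0]:.1f}%, "
      f"LD2 {report.variance_explained[1]:.1f}%")
print()
print("per-class correct classification vs chance:")
for c in report.classes:
    print(f"  {c:22s} {report.per_class_correct[c]:5.0f}%   "
          f"(chance {report.chance[c]}%)")
print()
print("row-normalized confusion (%):")
print(report.confusion_percent.to_string())
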