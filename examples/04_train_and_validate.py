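"""Train the imbalance-aware RBF-SVM and run the validation battery.

Uses an imbalanced cohort (150 unsuccessful vs. 45 successful) to mirror
the clinical class ratio, then reports hold-out metrics, hyperparameter
sensitivity, feature ablation and baseline comparison.
"""

import numpy as np

import preshock as ps

SELECTED = ["amplitude_qrs", "total_power2", "lf_power2"]

rng_spec = [(ps.NOROEA_SPEC, 150), (ps.ROEA_SPEC, 45)]
blocks = [ps.sample_feature_table((spec,), n_per_class=n, seed=2 + i)
          for i, (spec, n) in enumerate(rng_spec)]
X = np.vstack([b[0][SELECTED].to_numpy() for b in blocks])
y = np.concatenate([b[1] for b in blocks])

config = ps.TrainConfig(imbalance="both", seed=0)
model, report, details = ps.train_and_evaluate(X, y, config)

print(f"chosen C={details['C']}, gamma={details['gamma']}")
print(f"test accuracy {report.accuracy:.3f}, ROC-AUC {report.roc_auc:.3f}")
for code, metrics in report.per_class.items():
    name = model.label_names[code]
    print(f"  {name:>7}: precision {metrics['precision']:.3f} "
          f"recall {metrics['recall']:.3f} f1 {metrics['f1']:.3f}")

scaler = details["scaler"]
dev = ps.sensitivity(
    scaler.transform(X[details["train_idx"]]), y[details["train_idx"]],
    scaler.transform(X[details["test_idx"]]), y[details["test_idx"]],
    C=details["C"], gamma=details["gamma"], config=config,
)
print(f"accuracy deviation under +/-10% hyperparameter perturbation: {dev:.3f}")

import pandas as pd

table = ps.ablation(pd.DataFrame(X, columns=SELECTED), y, config=config)
print("\nablation (accuracy):")
print(table["accuracy"].round(3).to_string())

comparison = ps.compare_classifiers(pd.DataFrame(X, columns=SELECTED), y, config)
print("\nbaseline comparison:")
print(comparison.round(3))
# The SVM should sit at or above the linear baseline; small deviations
# under hyperparameter perturbation indicate a stable operating point.
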