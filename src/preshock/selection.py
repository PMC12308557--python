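"""Univariate feature screening: per-feature ROC-AUC and one-way ANOVA F.

Each candidate feature is scored by (a) the area under its ROC curve,
computed through the Mann-Whitney rank identity with half credit for ties,
and (b) the classical one-way F statistic.  The AUC is reported in
"discriminative" orientation, max(AUC, 1 - AUC), with a direction flag,
since a feature that is systematically *lower* in the positive class is
just as informative as one that is higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import DegenerateGroupsError


def feature_auc(values, labels, orient: bool = True) -> tuple[float, int]:
    """ROC-AUC of a single feature against binary labels.

    Returns ``(auc, direction)`` where ``direction`` is +1 if the positive
    class (the larger label value) tends to larger feature values, -1
    otherwise.  With ``orient=True`` (default) the AUC is folded to
    ``max(auc, 1 - auc)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    pos = values[labels == classes[1]]
    neg = values[labels == classes[0]]
    # Mann-Whitney U counts concordant positive/negative pairs (ties half).
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)
    direction = 1 if auc >= 0.5 else -1
    if orient:
        auc = max(auc, 1.0 - auc)
    return auc, direction


def anova_f(values, labels) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across label groups.

    F = (between-group mean square) / (within-group mean square) with
    (g - 1, n - g) degrees of freedom.

    Raises
    ------
    DegenerateGroupsError
        If any group has fewer than 2 members or the pooled within-group
        variance is zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == c] for c in np.unique(labels)]
    if len(groups) < 2:
        raise DegenerateGroupsError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise DegenerateGroupsError("each group needs at least 2 members")
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if ssw <= 0:
        raise DegenerateGroupsError("zero within-group variance")
    f_value, p_value = stats.f_oneway(*groups)
    return float(f_value), float(p_value)


@dataclass(frozen=True)
class SelectionReport:
    """Per-feature screening scores and the selected subset."""

    table: pd.DataFrame  # index: feature; columns: auc, direction, f_value, p_value, rank, selected
    k: int
    criterion: str

    @property
    def selected(self) -> list[str]:
        """Selected feature names, in rank order."""
        sel = self.table[self.table["selected"]].sort_values("rank")
        return list(sel.index)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "criterion": self.criterion,
            "features": {
                name: {
                    "auc": float(row["auc"]),
                    "direction": int(row["direction"]),
                    "f_value": float(row["f_value"]),
                    "p_value": float(row["p_value"]),
                    "rank": int(row["rank"]),
                    "selected": bool(row["selected"]),
                }
                for name, row in self.table.iterrows()
            },
        }


def rank_and_select(
    feature_matrix: pd.DataFrame,
    labels,
    k: int = 3,
    criterion: str = "auc",
) -> SelectionReport:
    """Score every feature, rank by ``criterion``, flag the top ``k``.

    Ties on the primary criterion are broken by the secondary one (F for
    AUC ranking and vice versa), then alphabetically by feature name.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > feature_matrix.shape[1]:
        raise ValueError(f"k={k} exceeds the {feature_matrix.shape[1]} features")
    if criterion not in ("auc", "f"):
        raise ValueError("criterion must be 'auc' or 'f'")
    labels = np.asarray(labels)

    rows = {}
    for name in feature_matrix.columns:
        auc, direction = feature_auc(feature_matrix[name].to_numpy(), labels)
        f_value, p_value = anova_f(feature_matrix[name].to_numpy(), labels)
        rows[name] = {
            "auc": auc,
            "direction": direction,
            "f_value": f_value,
            "p_value": p_value,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "feature"

    primary, secondary = ("auc", "f_value") if criterion == "auc" else ("f_value", "auc")
    # stable sort on (primary desc, secondary desc, name asc)
    order = table.assign(_name=table.index).sort_values(
        by=[primary, secondary, "_name"], ascending=[False, False, True], kind="mergesort"
    )
    table = table.loc[order.index]
    table["rank"] = np.arange(1, len(table) + 1)
    table["selected"] = table["rank"] <= k
    return SelectionReport(table=table, k=k, criterion=criterion)


def roc_points(values, labels) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold) for one feature."""
    from sklearn.metrics import roc_curve

    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    fpr, tpr, thr = roc_curve(labels == classes[1], np.asarray(values, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
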