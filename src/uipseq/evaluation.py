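"""ROC/AUC, sensitivity/specificity with confidence intervals, fold-wise
cross-validated AUC, and locked-classifier validation reporting.

AUC is the Mann-Whitney statistic with midrank tie handling; its CI uses
the DeLong variance estimate.  Proportion CIs are two-sided 95% exact
binomial (Clopper-Pearson).  Validation requires a locked artifact (a
classifier with a boundary); there is no code path that refits on test
data, and a patient-overlap audit flags any test patient seen in
training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

from .containers import CountMatrix
from .normalization import FrozenNormalization, apply_vst


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """Mann-Whitney AUC (midrank ties) plus ROC points at every distinct
    threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes required to compute an AUC")
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thr = roc_curve(y, s)
    roc = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return float(auc), roc


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """AUC with a DeLong (1988) asymptotic confidence interval, clipped to
    [0, 1]."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise EvaluationError("both classes required")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_r[:m] - pos_r) / n  # structural components for positives
    v10 = 1.0 - (all_r[m:] - neg_r) / m
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(auc), max(0.0, float(auc - z * se)), min(1.0, float(auc + z * se))


# ---------------------------------------------------------------------------
# Sensitivity / specificity
# ---------------------------------------------------------------------------


def sens_spec(calls, labels, alpha: float = 0.05) -> dict:
    """Sensitivity and specificity with Clopper-Pearson intervals.

    ``calls`` may be boolean/0-1 or the strings 'UIP'/'non-UIP'.  Zero
    denominators yield NaN point estimates flagged as undefined rather
    than an exception.
    """
    c = pd.Series(calls)
    if c.dtype == object:
        c = c.map({"UIP": 1, "non-UIP": 0})
        if c.isna().any():
            raise EvaluationError("calls must be 'UIP'/'non-UIP' or binary")
    c = c.to_numpy().astype(int)
    y = np.asarray(labels).astype(int)
    tp = int(((c == 1) & (y == 1)).sum())
    fn = int(((c == 0) & (y == 1)).sum())
    tn = int(((c == 0) & (y == 0)).sum())
    fp = int(((c == 1) & (y == 0)).sum())

    def _prop(k: int, n: int):
        if n == 0:
            return {"estimate": float("nan"), "ci": (float("nan"), float("nan")),
                    "undefined": True, "k": k, "n": n}
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        return {"estimate": k / n, "ci": (float(lo), float(hi)),
                "undefined": False, "k": k, "n": n}

    return {
        "sensitivity": _prop(tp, tp + fn),
        "specificity": _prop(tn, tn + fp),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


def cv_auc(fold_scores: Sequence[tuple]) -> dict:
    """Fold-mean AUC (the cross-validated AUC) and pooled-score AUC.

    ``fold_scores`` is an iterable of (scores, labels) per fold.  Folds
    with a single class are excluded from the mean with a warning; the
    pooled AUC always uses every score.
    """
    per_fold, pooled_s, pooled_y = [], [], []
    for i, (s, y) in enumerate(fold_scores):
        s = np.asarray(s, dtype=float)
        y = np.asarray(y).astype(int)
        pooled_s.append(s)
        pooled_y.append(y)
        if len(np.unique(y)) < 2:
            warnings.warn(f"fold {i} has a single class; excluded from fold-mean AUC")
            per_fold.append(np.nan)
        else:
            per_fold.append(roc_auc(s, y)[0])
    pooled_auc = roc_auc(np.concatenate(pooled_s), np.concatenate(pooled_y))[0]
    valid = [a for a in per_fold if not np.isnan(a)]
    mean_auc = float(np.mean(valid)) if len(valid) >= 1 else float("nan")
    return {"mean_auc": mean_auc, "pooled_auc": pooled_auc, "fold_aucs": per_fold}


# ---------------------------------------------------------------------------
# End-to-end validation of a locked classifier
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PerformanceReport:
    """Validation metrics for a locked classifier on a held-out cohort."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: dict
    specificity: dict
    confusion: dict
    score_quantiles: dict
    boundary: float
    model_hash: str
    dataset_hash: str
    overlap_audit_passed: bool
    overlapping_patients: list[str]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=float)

    def summary(self) -> str:
        se, sp = self.sensitivity, self.specificity
        lines = [
            "Independent validation of locked classifier",
            f"  model hash      : {self.model_hash}",
            f"  dataset hash    : {self.dataset_hash}",
            f"  boundary        : {self.boundary:.3f}",
            f"  AUC             : {self.auc:.3f} [{self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f}]",
            f"  sensitivity     : {se['estimate']:.3f} [{se['ci'][0]:.3f}-{se['ci'][1]:.3f}] ({se['k']}/{se['n']})",
            f"  specificity     : {sp['estimate']:.3f} [{sp['ci'][0]:.3f}-{sp['ci'][1]:.3f}] ({sp['k']}/{sp['n']})",
            f"  confusion       : {self.confusion}",
            f"  overlap audit   : {'pass' if self.overlap_audit_passed else 'FAIL'}",
        ]
        return "\n".join(lines)


def validate(
    model,
    test_counts: CountMatrix,
    frozen: FrozenNormalization,
    labels: pd.Series,
    train_patients: Optional[Sequence[str]] = None,
    patient_map: Optional[pd.Series] = None,
) -> PerformanceReport:
    """Score a blinded test cohort with a locked classifier and report.

    ``model`` must carry a locked boundary (prospective definition); the
    test counts are normalized with the frozen training artifact only.
    ``labels`` maps test sample/pool -> binary label.  When
    ``train_patients`` is given, any overlap with the test patients is
    flagged as an audit failure in the report.
    """
    if model.boundary is None:
        raise EvaluationError(
            "validation requires a locked artifact: the decision boundary "
            "must be set before test scores are computed"
        )
    if len(labels) == 0:
        raise EvaluationError("empty test set")
    expr = apply_vst(test_counts, frozen)
    scores = model.score(expr[list(labels.index)])
    from .boundary import classify

    calls = classify(scores, model.boundary)
    auc, lo, hi = delong_auc_ci(scores.to_numpy(), labels.to_numpy())
    ss = sens_spec(calls, labels)

    test_patients = (
        set(patient_map.loc[labels.index]) if patient_map is not None else set(labels.index)
    )
    overlap = sorted(test_patients & set(train_patients)) if train_patients else []
    q = np.quantile(scores.to_numpy(), [0.05, 0.25, 0.5, 0.75, 0.95])
    dataset_hash = hashlib.sha256(
        pd.util.hash_pandas_object(test_counts.df, index=True).to_numpy().tobytes()
    ).hexdigest()[:16]
    return PerformanceReport(
        auc=auc,
        auc_ci=(lo, hi),
        sensitivity=ss["sensitivity"],
        specificity=ss["specificity"],
        confusion=ss["confusion"],
        score_quantiles={"q05": q[0], "q25": q[1], "q50": q[2], "q75": q[3], "q95": q[4]},
        boundary=model.boundary,
        model_hash=model.content_hash(),
        dataset_hash=dataset_hash,
        overlap_audit_passed=not overlap,
        overlapping_patients=overlap,
    )
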