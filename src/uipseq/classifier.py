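"""Patient-stratified cross-validated penalized logistic classification.

The core fitted object is an elastic-net-penalized logistic regression,

    minimize  (1/n) * sum_i log(1 + exp(-y_i * (b + x_i' w)))
              + lambda * ( mixing * ||w||_1 + (1 - mixing)/2 * ||w||_2^2 ),

exposed statsmodels-style: :class:`ElasticNetLogit` is built from data and
``fit()`` returns an :class:`ElasticNetLogitResults` carrying estimates and
diagnostics.  The solver is an accelerated proximal-gradient method
(FISTA with objective-based restarts): the L1 part is handled by
soft-thresholding, the logistic loss plus ridge part by its gradient with
a step from the spectral norm of the design, so the optimizer is fully
deterministic.  Features are standardized internally (training mean 0,
SD 1) and the standardization is folded back into the exported weights
and intercept, so the serialized classifier scores raw VST expression.

Cross-validation treats the patient as the smallest unit: all samples of a
patient travel together between training and held-out sides of every fold
(leave-one-patient-out, or patient-stratified k-fold).  Hyper-parameters
are tuned by random search nested inside each fold, selecting the most
regularized candidate whose mean inner-CV binomial deviance lies within
one standard error of the minimum.

Classification scores are linear predictors (log-odds scale), not
probabilities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .mixing import NoiseModel, mix_within_patient, replicate_with_noise, vst_mixed
from .normalization import FrozenNormalization, estimate_size_factors


class ClassifierError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Fold:
    train_patients: tuple[str, ...]
    heldout_patients: tuple[str, ...]


@dataclasses.dataclass
class FoldPlan:
    folds: list[Fold]
    mode: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.folds:
            tr, ho = set(f.train_patients), set(f.heldout_patients)
            if tr & ho:
                raise ClassifierError("train and held-out patient sets overlap")
            if seen & ho:
                raise ClassifierError("a patient is held out in more than one fold")
            seen |= ho

    def heldout_patients(self) -> set[str]:
        return {p for f in self.folds for p in f.heldout_patients}


def make_fold_plan(
    patient_labels: pd.Series, mode: str = "lopo", k: int = 5, seed: int = 0
) -> FoldPlan:
    """LOPO (one fold per patient) or label-stratified patient k-fold.

    ``patient_labels`` maps patient -> binary label (1 = UIP).  Folds whose
    training partition would contain a single class are kept with a warning.
    """
    patients = list(patient_labels.index)
    labels = patient_labels.to_numpy()
    if mode == "lopo":
        folds = [
            Fold(tuple(p for p in patients if p != q), (q,)) for q in patients
        ]
        plan = FoldPlan(folds, "lopo")
    elif mode == "kfold":
        if len(patients) < 2 or len(np.unique(labels)) < 2:
            raise ClassifierError("k-fold needs >= 2 patients with both classes")
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = []
        pat = np.array(patients)
        for tr_idx, ho_idx in skf.split(pat, labels):
            folds.append(Fold(tuple(pat[tr_idx]), tuple(pat[ho_idx])))
        plan = FoldPlan(folds, f"kfold{k}")
    else:
        raise ClassifierError(f"unknown fold mode {mode!r}")
    for i, f in enumerate(plan.folds):
        tr_lab = patient_labels.loc[list(f.train_patients)]
        if tr_lab.nunique() < 2:
            warnings.warn(f"fold {i}: training partition contains a single class")
    return plan


# ---------------------------------------------------------------------------
# Elastic-net logistic model / results
# ---------------------------------------------------------------------------


def _spectral_norm_sq(Xs: np.ndarray, n_iter: int = 50) -> float:
    """Largest squared singular value of [Xs, 1] by power iteration."""
    n, p = Xs.shape
    v = np.full(p + 1, 1.0 / np.sqrt(p + 1))
    for _ in range(n_iter):
        u = Xs @ v[:-1] + v[-1]
        v_new = np.empty(p + 1)
        v_new[:-1] = Xs.T @ u
        v_new[-1] = u.sum()
        nrm = np.linalg.norm(v_new)
        if nrm == 0:  # pragma: no cover - degenerate all-zero design
            return 1.0
        v = v_new / nrm
    u = Xs @ v[:-1] + v[-1]
    return float(u @ u)


def _fista_enet(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    mixing: float,
    tol: float,
    max_iter: int,
    smax2: Optional[float] = None,
    w0: Optional[np.ndarray] = None,
    b0: float = 0.0,
) -> tuple[np.ndarray, float, int, bool]:
    """Accelerated proximal gradient (FISTA, restart on objective increase)
    for the standardized elastic-net logistic objective.  Returns
    (weights, intercept, iterations, converged); convergence is a maximum
    absolute coefficient change below ``tol``."""
    n, p = Xs.shape
    l1 = lam * mixing
    l2 = lam * (1.0 - mixing)
    if smax2 is None:
        smax2 = _spectral_norm_sq(Xs)
    step = 1.0 / (smax2 / (4.0 * n) + l2)

    w = np.zeros(p) if w0 is None else w0.copy()
    b = float(b0)
    zw, zb = w.copy(), b
    t = 1.0

    def objective(wv: np.ndarray, bv: float) -> float:
        z = Xs @ wv + bv
        loss = np.mean(np.logaddexp(0.0, -(2.0 * y - 1.0) * z))
        return loss + l1 * np.abs(wv).sum() + 0.5 * l2 * (wv @ wv)

    f_prev = objective(w, b)
    for it in range(1, max_iter + 1):
        z = Xs @ zw + zb
        resid = 1.0 / (1.0 + np.exp(-z)) - y
        grad_w = Xs.T @ resid / n + l2 * zw
        grad_b = resid.mean()
        w_new = zw - step * grad_w
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - step * l1, 0.0)
        b_new = zb - step * grad_b
        delta = max(float(np.max(np.abs(w_new - w))) if p else 0.0, abs(b_new - b))
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        if it % 10 == 0:  # monotonicity restart
            f = objective(w_new, b_new)
            if f > f_prev:
                t_new = 1.0
            f_prev = f
        momentum = (t - 1.0) / t_new
        zw = w_new + momentum * (w_new - w)
        zb = b_new + momentum * (b_new - b)
        w, b, t = w_new, b_new, t_new
        if delta < tol:
            return w, b, it, True
    return w, b, max_iter, False


class ElasticNetLogit:
    """Elastic-net penalized logistic regression model.

    Parameters
    ----------
    X : DataFrame, samples x genes (VST expression).
    y : binary labels (1 = UIP), aligned with X rows.
    lam : overall penalty strength lambda (on the mean-loss scale).
    mixing : L1 fraction in [0, 1]; 1 = lasso, 0 = ridge.
    """

    def __init__(self, X: pd.DataFrame, y, lam: float, mixing: float):
        self.X = X
        self.y = np.asarray(y).astype(int)
        if set(np.unique(self.y)) != {0, 1}:
            raise ClassifierError("labels must contain both classes (0 and 1)")
        if lam <= 0:
            raise ClassifierError("lambda must be positive")
        if not 0.0 <= mixing <= 1.0:
            raise ClassifierError("mixing must lie in [0, 1]")
        self.lam = float(lam)
        self.mixing = float(mixing)

    def fit(
        self,
        tol: float = 1e-7,
        max_iter: int = 50000,
        strict: bool = True,
    ) -> "ElasticNetLogitResults":
        """Fit by FISTA; ``tol`` is the maximum absolute coefficient change
        (standardized scale) declaring convergence.  Non-convergence raises
        unless ``strict=False``."""
        Xv = self.X.to_numpy(dtype=float)
        n = Xv.shape[0]
        mean = Xv.mean(axis=0)
        sd = Xv.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (Xv - mean) / sd_safe
        w_std, b_std, n_iter, converged = _fista_enet(
            Xs, self.y.astype(float), self.lam, self.mixing, tol, max_iter
        )
        if strict and not converged:
            raise ConvergenceError(
                f"FISTA did not converge within {max_iter} iterations "
                f"(lambda={self.lam:.4g}, mixing={self.mixing:.3g}, tol={tol:g})"
            )
        w = w_std / sd_safe
        w[sd == 0] = 0.0
        intercept = float(b_std - np.sum(w_std * mean / sd_safe))
        return ElasticNetLogitResults(
            model=self,
            params=pd.Series(w, index=self.X.columns, name="weight"),
            intercept=intercept,
            n_iter=n_iter,
        )


@dataclasses.dataclass
class ElasticNetLogitResults:
    """Fitted elastic-net logistic model: weights on the raw expression scale."""

    model: ElasticNetLogit
    params: pd.Series
    intercept: float
    n_iter: int

    @property
    def nonzero_genes(self) -> pd.Index:
        return self.params.index[self.params != 0]

    def linear_predictor(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(
            self.intercept + X[self.params.index].to_numpy() @ self.params.to_numpy(),
            index=X.index,
            name="score",
        )

    def summary(self) -> str:
        lines = [
            "Elastic-net penalized logistic regression",
            f"  n samples        : {self.model.X.shape[0]}",
            f"  n features       : {self.model.X.shape[1]}",
            f"  lambda           : {self.model.lam:.6g}",
            f"  mixing (L1 frac) : {self.model.mixing:.3g}",
            f"  nonzero weights  : {len(self.nonzero_genes)}",
            f"  intercept        : {self.intercept:.6g}",
            f"  iterations       : {self.n_iter}",
        ]
        top = self.params[self.params != 0].abs().sort_values(ascending=False).head(10)
        if len(top):
            lines.append("  largest |weights|:")
            for g in top.index:
                lines.append(f"    {g:<12s} {self.params[g]:+.4f}")
        return "\n".join(lines)

    def to_classifier(self, metadata: Optional[dict] = None) -> "TrainedClassifier":
        nz = self.params[self.params != 0]
        return TrainedClassifier(
            genes=list(nz.index),
            weights=nz.to_numpy().tolist(),
            intercept=self.intercept,
            lam=self.model.lam,
            mixing=self.model.mixing,
            metadata=metadata or {},
        )


@dataclasses.dataclass
class TrainedClassifier:
    """Serializable sparse linear classifier with an optionally locked boundary.

    ``score`` is the linear predictor intercept + sum(weight_g * expr_g)
    (log-odds scale).  Genes with zero weight are excluded from the gene list.
    """

    genes: list[str]
    weights: list[float]
    intercept: float
    lam: float
    mixing: float
    boundary: Optional[float] = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Score expression columns (genes x samples)."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise ClassifierError(f"expression lacks classifier genes: {missing[:5]}")
        w = np.asarray(self.weights)
        vals = self.intercept + w @ expr.loc[self.genes].to_numpy()
        return pd.Series(vals, index=expr.columns, name="score")

    def lock_boundary(self, boundary: float) -> None:
        self.boundary = float(boundary)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "genes": self.genes,
                "weights": self.weights,
                "intercept": self.intercept,
                "lam": self.lam,
                "mixing": self.mixing,
                "boundary": self.boundary,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genes": self.genes,
                    "weights": self.weights,
                    "intercept": self.intercept,
                    "lambda": self.lam,
                    "mixing": self.mixing,
                    "boundary": self.boundary,
                    "metadata": self.metadata,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "TrainedClassifier":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genes=d["genes"],
            weights=d["weights"],
            intercept=d["intercept"],
            lam=d["lambda"],
            mixing=d["mixing"],
            boundary=d.get("boundary"),
            metadata=d.get("metadata", {}),
        )


def train_penalized_logistic(
    expr: pd.DataFrame,
    labels: pd.Series,
    lam: float,
    mixing: float,
    tol: float = 1e-7,
    max_iter: int = 50000,
    metadata: Optional[dict] = None,
) -> TrainedClassifier:
    """Convenience wrapper: fit on expression (genes x samples) + per-sample
    binary labels and export the sparse classifier artifact."""
    X = expr.T.loc[labels.index]
    res = ElasticNetLogit(X, labels.to_numpy(), lam, mixing).fit(tol=tol, max_iter=max_iter)
    return res.to_classifier(metadata=metadata)


# ---------------------------------------------------------------------------
# Hyper-parameter search with the one-standard-error rule
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SearchSpec:
    """Random-search specification: log-uniform lambda, uniform mixing."""

    n_draws: int = 20
    lambda_range: tuple[float, float] = (1e-3, 1.0)
    mixing_range: tuple[float, float] = (0.1, 1.0)
    inner_k: int = 3
    seed: int = 0
    tol: float = 1e-4
    max_iter: int = 5000

    def draw(self) -> pd.DataFrame:
        if self.n_draws < 2:
            raise ClassifierError("random search needs n_draws >= 2")
        rng = np.random.default_rng(self.seed)
        lam = np.exp(
            rng.uniform(np.log(self.lambda_range[0]), np.log(self.lambda_range[1]), self.n_draws)
        )
        mix = rng.uniform(*self.mixing_range, self.n_draws)
        return pd.DataFrame({"lam": lam, "mixing": mix})


def binomial_deviance(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance of linear-predictor scores against 0/1 labels."""
    s = np.asarray(scores, dtype=float)
    ypm = 2.0 * np.asarray(y) - 1.0
    return float(np.mean(2.0 * np.logaddexp(0.0, -ypm * s)))


def one_se_select(table: pd.DataFrame) -> pd.Series:
    """One-standard-error rule: the most regularized candidate whose mean
    deviance is within one SE of the minimum.

    ``table`` needs columns lam, mixing, mean_deviance, se_deviance.
    Regularization order: lambda descending, then mixing descending.
    """
    if table.empty:
        raise ClassifierError("empty candidate table")
    best = table.loc[table["mean_deviance"].idxmin()]
    cut = best["mean_deviance"] + best["se_deviance"]
    ok = table[table["mean_deviance"] <= cut]
    ok = ok.sort_values(["lam", "mixing"], ascending=[False, False], kind="mergesort")
    return ok.iloc[0]


def tune_hyperparameters(
    expr: pd.DataFrame,
    labels: pd.Series,
    patient_map: pd.Series,
    search: SearchSpec,
    seed: int = 0,
    candidates: Optional[pd.DataFrame] = None,
) -> tuple[float, float, pd.DataFrame]:
    """Random-search + one-SE selection on an inner patient-stratified k-fold.

    Returns (lambda, mixing, candidate table with mean/SE inner deviance).
    """
    if candidates is None:
        candidates = search.draw()
    pm = patient_map.loc[labels.index]
    pat_labels = labels.groupby(pm).first()
    k = min(search.inner_k, max(2, int(pat_labels.value_counts().min())))
    plan = make_fold_plan(pat_labels, mode="kfold", k=k, seed=seed)

    # stronger penalties first so each candidate warm-starts from a sparser fit
    order = candidates.sort_values("lam", ascending=False).index
    fold_dev = np.full((len(candidates), len(plan.folds)), np.nan)
    for j, fold in enumerate(plan.folds):
        tr_mask = pm.isin(fold.train_patients)
        ho_mask = pm.isin(fold.heldout_patients)
        X_tr = expr.T.loc[labels.index[tr_mask]].to_numpy(dtype=float)
        y_tr = labels[tr_mask].to_numpy().astype(float)
        X_ho = expr.T.loc[labels.index[ho_mask]].to_numpy(dtype=float)
        y_ho = labels[ho_mask].to_numpy()
        if len(np.unique(y_tr)) < 2:
            continue
        mean = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        Xs_tr = (X_tr - mean) / sd
        Xs_ho = (X_ho - mean) / sd
        smax2 = _spectral_norm_sq(Xs_tr)
        w0, b0 = None, 0.0
        for c in order:
            row = candidates.loc[c]
            w, b, _, _ = _fista_enet(
                Xs_tr, y_tr, row["lam"], row["mixing"],
                tol=search.tol, max_iter=search.max_iter,
                smax2=smax2, w0=w0, b0=b0,
            )
            w0, b0 = w, b
            fold_dev[c, j] = binomial_deviance(Xs_ho @ w + b, y_ho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(fold_dev, axis=1)
        nfold = np.sum(~np.isnan(fold_dev), axis=1)
        se = np.nanstd(fold_dev, axis=1, ddof=1) / np.sqrt(np.maximum(nfold, 1))
    table = candidates.assign(mean_deviance=mean, se_deviance=se)
    if len(table) == 1:
        chosen = table.iloc[0]
    else:
        chosen = one_se_select(table.dropna(subset=["mean_deviance"]))
    return float(chosen["lam"]), float(chosen["mixing"]), table


# ---------------------------------------------------------------------------
# Score combination (generic ensemble interface)
# ---------------------------------------------------------------------------


def standardize_scores(scores: pd.Series, ref_mean: float, ref_sd: float) -> pd.Series:
    """Standardize a component's scores to its training mean 0 / SD 1."""
    if ref_sd <= 0:
        raise ClassifierError("reference SD must be positive")
    return (scores - ref_mean) / ref_sd


def ensemble_score(
    component_scores: Sequence[pd.Series], weights: Sequence[float]
) -> pd.Series:
    """Weighted mean of standardized per-column component scores."""
    if len(component_scores) != len(weights):
        raise ClassifierError("one weight per component required")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ClassifierError("ensemble weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ClassifierError(f"ensemble weights must sum to 1 (got {w.sum():.6f})")
    idx = component_scores[0].index
    for s in component_scores[1:]:
        if not s.index.equals(idx):
            raise ClassifierError("component score vectors cover different columns")
    stacked = np.vstack([s.to_numpy() for s in component_scores])
    return pd.Series(w @ stacked, index=idx, name="score")


# ---------------------------------------------------------------------------
# LOPO cross-validation runner
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CVResult:
    """Cross-validated scores with fold provenance and in-silico replicates.

    Every score is produced by a model whose training patient set excludes
    the scored patient; :meth:`audit_no_leakage` asserts this from the
    recorded provenance.
    """

    sample_scores: pd.DataFrame  # sample, patient, label, score, fold
    replicate_scores: pd.DataFrame  # patient, label, replicate, score
    fold_info: pd.DataFrame  # fold, heldout, n_train_patients, lam, mixing
    fold_train_patients: dict = dataclasses.field(default_factory=dict, repr=False)

    def pooled_auc(self, level: str = "sample") -> float:
        from .evaluation import roc_auc

        if level == "sample":
            auc, _ = roc_auc(self.sample_scores["score"], self.sample_scores["label"])
        elif level == "patient":
            per_pat = self.replicate_scores.groupby("patient").agg(
                score=("score", "mean"), label=("label", "first")
            )
            auc, _ = roc_auc(per_pat["score"], per_pat["label"])
        else:
            raise ClassifierError("level must be 'sample' or 'patient'")
        return auc

    def replicate_matrix(self) -> tuple[pd.DataFrame, pd.Series]:
        """(patients x replicates score matrix, per-patient labels)."""
        wide = self.replicate_scores.pivot(index="patient", columns="replicate", values="score")
        labels = self.replicate_scores.groupby("patient")["label"].first()
        return wide, labels.loc[wide.index]

    def audit_no_leakage(self) -> bool:
        for _, row in self.sample_scores.iterrows():
            if row["patient"] in self.fold_train_patients[row["fold"]]:
                raise ClassifierError(
                    f"leakage: patient {row['patient']} trained its own scoring fold"
                )
        for fold, pats in self.replicate_scores.groupby("fold")["patient"]:
            for p in pats.unique():
                if p in self.fold_train_patients[fold]:
                    raise ClassifierError(f"leakage: replicate scores for {p}")
        return True

    def summary(self) -> str:
        lines = [
            "Leave-one-patient-out cross-validation",
            f"  folds                     : {len(self.fold_info)}",
            f"  samples scored            : {len(self.sample_scores)}",
            f"  patients (in-silico reps) : {self.replicate_scores['patient'].nunique()}",
            f"  pooled sample-level AUC   : {self.pooled_auc('sample'):.3f}",
            f"  pooled patient-level AUC  : {self.pooled_auc('patient'):.3f}",
        ]
        return "\n".join(lines)

    def plot_scores(self, boundary: Optional[float] = None, ax=None):
        """Per-patient score strip plot: individual samples and the mean
        in-silico mixed score, patients ordered non-UIP then UIP."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        per_pat = self.replicate_scores.groupby("patient").agg(
            mix=("score", "mean"), label=("label", "first")
        )
        order = per_pat.sort_values(["label", "mix"]).index
        pos = {p: i for i, p in enumerate(order)}
        for _, row in self.sample_scores.iterrows():
            ax.plot(
                pos[row["patient"]], row["score"], marker="^",
                color="tab:red" if row["label"] else "tab:blue",
                alpha=0.5, linestyle="none", markersize=4,
            )
        for p, row in per_pat.iterrows():
            ax.plot(
                pos[p], row["mix"], marker="o",
                color="tab:red" if row["label"] else "tab:blue",
                linestyle="none", markersize=6,
            )
        if boundary is not None:
            ax.axhline(boundary, color="purple", linestyle="--", linewidth=1)
        ax.set_xlabel("patient (non-UIP left, UIP right)")
        ax.set_ylabel("cross-validated classification score")
        return ax


def run_lopo(
    expr: pd.DataFrame,
    counts: CountMatrix,
    labels: pd.Series,
    patient_map: pd.Series,
    frozen: FrozenNormalization,
    noise: NoiseModel,
    search: Optional[SearchSpec] = None,
    hyper: Optional[tuple[float, float]] = None,
    seed: int = 0,
    final_tol: float = 1e-6,
    final_max_iter: int = 50000,
) -> CVResult:
    """Leave-one-patient-out CV with replicated in-silico mixing.

    For each fold: tune hyper-parameters on the training patients (nested
    inner CV, one-SE rule) unless ``hyper`` fixes them, train on all other
    patients' samples, then score the held-out patient's individual samples
    and ``noise.n_replicates`` technical-noise replicates of that patient's
    in-silico mix.
    """
    if (search is None) == (hyper is None):
        raise ClassifierError("provide exactly one of search or hyper")
    labels = labels.dropna().astype(int)
    pm = patient_map.loc[labels.index]
    pat_labels = labels.groupby(pm).first()
    plan = make_fold_plan(pat_labels, mode="lopo")

    # frozen-path expression of in-silico mixes, computed once
    counts_lab = counts.subset_samples(list(labels.index))
    sf = frozen.size_factors(counts_lab)
    mixed = mix_within_patient(counts_lab.subset_genes(frozen.gene_order), sf, pm)
    expr_mixed = vst_mixed(mixed, frozen).loc[expr.index]

    candidates = search.draw() if search is not None else None
    seeds = np.random.SeedSequence(seed).spawn(len(plan.folds))

    sample_rows, rep_rows, fold_rows = [], [], []
    fold_train: dict[int, frozenset] = {}
    for i, fold in enumerate(plan.folds):
        heldout = fold.heldout_patients[0]
        tr_mask = pm.isin(fold.train_patients)
        tr_samples = labels.index[tr_mask]
        X_tr = expr.T.loc[tr_samples]
        y_tr = labels[tr_mask]
        rng = np.random.default_rng(seeds[i])
        if search is not None:
            lam, mixing, _ = tune_hyperparameters(
                expr[tr_samples], y_tr, pm[tr_samples],
                search, seed=int(rng.integers(2**31)), candidates=candidates,
            )
        else:
            lam, mixing = hyper
        res = ElasticNetLogit(X_tr, y_tr.to_numpy(), lam, mixing).fit(
            tol=final_tol, max_iter=final_max_iter
        )
        ho_samples = labels.index[pm == heldout]
        ho_scores = res.linear_predictor(expr.T.loc[ho_samples])
        for s in ho_samples:
            sample_rows.append((s, heldout, int(labels[s]), float(ho_scores[s]), i))

        reps = replicate_with_noise(expr_mixed[[heldout]], noise, rng=rng)
        w = res.params.to_numpy()
        rep_scores = res.intercept + reps[:, :, 0] @ w
        for r, sc in enumerate(rep_scores):
            rep_rows.append((heldout, int(pat_labels[heldout]), r, float(sc), i))
        fold_rows.append((i, heldout, len(fold.train_patients), lam, mixing))
        fold_train[i] = frozenset(fold.train_patients)

    sample_scores = pd.DataFrame(
        sample_rows, columns=["sample", "patient", "label", "score", "fold"]
    )
    replicate_scores = pd.DataFrame(
        rep_rows, columns=["patient", "label", "replicate", "score", "fold"]
    )
    fold_info = pd.DataFrame(
        fold_rows, columns=["fold", "heldout", "n_train_patients", "lam", "mixing"]
    )
    return CVResult(sample_scores, replicate_scores, fold_info, fold_train)
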