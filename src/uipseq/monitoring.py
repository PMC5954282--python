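"""Score-level batch-effect quantification and prospective monitoring.

Replicated pools scored across processing runs are decomposed with a
mixed-effects model (pool fixed, run random, mirroring the sentinel gene
model at score level):

    score = mu + pool + run + residual,

yielding between-run, intra-run (residual) and total SDs, each also
expressed as a percentage of the (5%, 95%) inter-quantile range of
reference scores so classifiers on different score scales can be
compared.  A monitoring threshold sigma_sv is derived in training as the
largest score-noise SD whose injection shifts mean sensitivity and
specificity at the locked boundary by no more than a tolerance; future
batches pass only while the control-sample score SD stays strictly below
sigma_sv.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Mapping

import numpy as np
import pandas as pd


class MonitoringError(ValueError):
    pass


@dataclasses.dataclass
class ScoreVariability:
    """Between-run / intra-run / total score SDs with range-normalized forms.

    ``sd_total`` is the root-sum-of-squares of the two components (exact
    identity by construction).
    """

    sd_between_run: float
    sd_intra_run: float
    reference_range: float

    def __post_init__(self) -> None:
        if self.sd_between_run < 0 or self.sd_intra_run < 0:
            raise MonitoringError("score SDs must be non-negative")
        if self.reference_range <= 0:
            raise MonitoringError("reference score range must be positive")

    @property
    def sd_total(self) -> float:
        return float(np.hypot(self.sd_between_run, self.sd_intra_run))

    def pct_of_range(self) -> dict[str, float]:
        r = self.reference_range
        return {
            "between_run": 100.0 * self.sd_between_run / r,
            "intra_run": 100.0 * self.sd_intra_run / r,
            "total": 100.0 * self.sd_total / r,
        }


def reference_score_range(reference_scores) -> float:
    """(5%, 95%) inter-quantile range of reference classification scores."""
    q5, q95 = np.quantile(np.asarray(reference_scores, dtype=float), [0.05, 0.95])
    return float(q95 - q5)


def estimate_score_variability(
    scores: pd.DataFrame, reference_scores
) -> ScoreVariability:
    """Variance components of classification scores from replicated pools.

    ``scores`` needs columns ``pool``, ``run``, ``score`` (one row per
    replicate measurement).  Balanced designs use closed-form ANOVA
    method-of-moments with the run mean square; unbalanced designs fall
    back to a REML fit.  Negative estimates are truncated at zero.
    """
    req = {"pool", "run", "score"}
    if not req <= set(scores.columns):
        raise MonitoringError(f"scores table needs columns {sorted(req)}")
    pools = pd.Categorical(scores["pool"])
    runs = pd.Categorical(scores["run"])
    np_, nr = len(pools.categories), len(runs.categories)
    if np_ < 2 or nr < 2:
        raise MonitoringError("need >= 2 pools and >= 2 runs")
    y = scores["score"].to_numpy(dtype=float)
    N = y.size
    cell = pd.crosstab(pools.codes, runs.codes).to_numpy()
    if (cell == 0).any() or N <= np_ + nr - 1:
        raise MonitoringError("degenerate design for score variance components")
    balanced = cell.min() == cell.max()

    if balanced:
        grand = y.mean()
        run_means = np.bincount(runs.codes, weights=y) / np.bincount(runs.codes)
        pool_means = np.bincount(pools.codes, weights=y) / np.bincount(pools.codes)
        n_per_run = N / nr
        ms_run = n_per_run * ((run_means - grand) ** 2).sum() / (nr - 1)
        fitted = pool_means[pools.codes] + run_means[runs.codes] - grand
        df_res = N - np_ - nr + 1
        sigma2_e = ((y - fitted) ** 2).sum() / df_res
        sigma2_run = max(0.0, (ms_run - sigma2_e) / n_per_run)
    else:
        import statsmodels.formula.api as smf

        data = pd.DataFrame(
            {"y": y, "pool": pools.astype(str), "run": runs.astype(str)}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("y ~ C(pool)", data, groups=data["run"]).fit(
                reml=True, method="lbfgs"
            )
        sigma2_run = max(0.0, float(fit.cov_re.iloc[0, 0]))
        sigma2_e = float(fit.scale)

    return ScoreVariability(
        sd_between_run=float(np.sqrt(sigma2_run)),
        sd_intra_run=float(np.sqrt(sigma2_e)),
        reference_range=reference_score_range(reference_scores),
    )


def compare_classifiers(variabilities: Mapping[str, ScoreVariability]) -> pd.DataFrame:
    """Rank classifiers by total score SD as a percentage of their score
    range, ascending (lower = more robust); ties keep name order."""
    rows = []
    for name in sorted(variabilities):
        v = variabilities[name]
        pct = v.pct_of_range()
        rows.append(
            (name, v.sd_between_run, v.sd_intra_run, v.sd_total, pct["total"])
        )
    df = pd.DataFrame(
        rows,
        columns=["classifier", "sd_between_run", "sd_intra_run", "sd_total", "pct_total"],
    )
    df = df.sort_values(["pct_total", "classifier"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


@dataclasses.dataclass
class MonitoringThreshold:
    """Maximum acceptable control-score SD before a batch fails monitoring."""

    sigma_sv: float
    tolerance: float
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_sv <= 0:
            raise MonitoringError("sigma_sv must be positive")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_json(cls, path: str) -> "MonitoringThreshold":
        with open(path) as fh:
            return cls(**json.load(fh))


def derive_sv_threshold(
    replicate_scores,
    labels,
    boundary: float,
    tolerance: float = 0.02,
    n_draws: int = 200,
    seed: int = 0,
    n_search: int = 30,
) -> MonitoringThreshold:
    """Largest score-noise SD that keeps performance within tolerance.

    Gaussian noise of SD ``s`` is added to every patient-level replicate
    score; the resulting shift in mean sensitivity and specificity at the
    locked boundary (averaged over ``n_draws`` Monte-Carlo draws with
    common random numbers) must stay at or below ``tolerance`` in absolute
    value.  The returned sigma_sv is found by bisection.
    """
    if tolerance <= 0:
        raise MonitoringError("tolerance must be positive")
    from .boundary import _replicate_matrix

    scores_list, y = _replicate_matrix(replicate_scores, labels)
    uip = y == 1
    rng = np.random.default_rng(seed)
    # common random numbers: one standard-normal tensor reused for every s
    eps = [rng.normal(size=(n_draws, len(s))) for s in scores_list]

    def perf(s: float) -> tuple[float, float]:
        call = np.array([
            ((sc[None, :] + s * e) > boundary).mean() for sc, e in zip(scores_list, eps)
        ])
        return float(call[uip].mean()), float(1.0 - call[~uip].mean())

    base_sens = np.mean([(sc > boundary).mean() for sc, u in zip(scores_list, uip) if u])
    base_spec = 1.0 - np.mean(
        [(sc > boundary).mean() for sc, u in zip(scores_list, uip) if not u]
    )

    def shift(s: float) -> float:
        sens, spec = perf(s)
        return max(abs(sens - base_sens), abs(spec - base_spec))

    all_scores = np.concatenate(scores_list)
    hi = max(float(all_scores.max() - all_scores.min()), 1e-6)
    if shift(hi) <= tolerance:
        return MonitoringThreshold(hi, tolerance, n_draws, seed)
    lo = 0.0
    for _ in range(n_search):
        mid = 0.5 * (lo + hi)
        if shift(mid) <= tolerance:
            lo = mid
        else:
            hi = mid
    sigma_sv = max(lo, 1e-9)
    return MonitoringThreshold(sigma_sv, tolerance, n_draws, seed)


def monitor_batch(
    control_scores: pd.DataFrame, threshold: MonitoringThreshold
) -> dict:
    """Gate a new processing batch on control-sample score stability.

    ``control_scores`` needs columns ``control`` and ``score`` (one row per
    control measurement per batch).  The pooled across-batch SD over
    controls must stay strictly below sigma_sv.
    """
    req = {"control", "score"}
    if not req <= set(control_scores.columns):
        raise MonitoringError(f"control scores need columns {sorted(req)}")
    per_control = control_scores.groupby("control")["score"]
    counts = per_control.count()
    if (counts < 2).all():
        raise MonitoringError("each control needs >= 2 batch measurements")
    ss, df = 0.0, 0
    per_sd = {}
    for name, grp in per_control:
        v = grp.to_numpy(dtype=float)
        if v.size < 2:
            continue
        ss += ((v - v.mean()) ** 2).sum()
        df += v.size - 1
        per_sd[name] = float(v.std(ddof=1))
    pooled_sd = float(np.sqrt(ss / df))
    passed = pooled_sd < threshold.sigma_sv
    return {
        "pass": bool(passed),
        "pooled_sd": pooled_sd,
        "sigma_sv": threshold.sigma_sv,
        "per_control_sd": per_sd,
    }
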