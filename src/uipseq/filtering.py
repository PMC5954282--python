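"""Gene-universe reduction: annotation class, expression level, and
sensitivity to processing batches.

The batch-sensitivity filter fits, per gene, a linear mixed-effects model
on variance-stabilized sentinel expression

    g_ij = mu + beta * sample_ij + batch_i + e_ij,

with the biological sentinel source a fixed effect and the processing
batch a random effect.  "Total variation" is read as
sigma2_batch + sigma2_e: fixed source effects are biological signal, not
technical noise (a switch to residual-only is provided downstream where
the composition matters).  Genes in the top fraction of total variation
are excluded.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

EXCLUDED_BIOTYPES = frozenset({"pseudogene", "rRNA", "TR_exon", "IG_exon"})


class FilterError(ValueError):
    pass


@dataclasses.dataclass
class GeneSet:
    """An ordered list of retained gene IDs with filter provenance."""

    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise FilterError("GeneSet contains duplicate gene IDs")
        self.genes = [str(g) for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)

    def to_text(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.genes) + "\n")

    @classmethod
    def from_text(cls, path: str, provenance: str = "file") -> "GeneSet":
        with open(path) as fh:
            genes = [line.strip() for line in fh if line.strip()]
        return cls(genes, provenance)


def filter_by_annotation(universe: GeneSet, annotation: pd.DataFrame) -> GeneSet:
    """Drop off-panel genes, then excluded biotypes (pseudogene, rRNA,
    TR/IG exon features).  ``annotation`` must cover the whole universe and
    carry ``biotype`` and ``in_target_panel`` columns."""
    missing = [g for g in universe if g not in annotation.index]
    if missing:
        raise FilterError(f"unannotated genes: {missing[:10]}")
    ann = annotation.loc[list(universe)]
    keep = ann["in_target_panel"].astype(bool) & ~ann["biotype"].isin(EXCLUDED_BIOTYPES)
    return GeneSet([g for g, k in zip(universe, keep) if k], provenance="annotation")


def filter_low_expression(
    counts,
    universe: GeneSet,
    total_floor: int = 5,
    presence_frac: float = 0.05,
) -> GeneSet:
    """Drop gene j when its summed raw count over training samples is below
    ``total_floor`` or it is detected (count > 0) in fewer than
    ``presence_frac`` of samples."""
    missing = [g for g in universe if g not in counts.genes]
    if missing:
        raise FilterError(f"counts do not cover the universe: {missing[:10]}")
    sub = counts.df.loc[list(universe)]
    total = sub.sum(axis=1)
    presence = (sub > 0).mean(axis=1)
    keep = (total >= total_floor) & (presence >= presence_frac)
    return GeneSet(list(sub.index[keep]), provenance="low_expression")


# ---------------------------------------------------------------------------
# Per-gene sentinel batch model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GeneBatchModels:
    """Per-gene variance decompositions from the sentinel mixed model.

    ``params`` is indexed by gene with columns ``mu``, ``sigma2_batch``,
    ``sigma2_e`` and ``total_variation`` (= sigma2_batch + sigma2_e);
    ``source_effects`` holds the fitted fixed source deviations.
    """

    params: pd.DataFrame
    source_effects: pd.DataFrame
    method: str = "anova-mom"

    def technical_sd(self, residual_only: bool = False) -> pd.Series:
        """Per-gene technical SD: sqrt(sigma2_batch + sigma2_e), or residual
        SD only when the batch component should be excluded."""
        if residual_only:
            v = self.params["sigma2_e"]
        else:
            v = self.params["sigma2_batch"] + self.params["sigma2_e"]
        return np.sqrt(v).rename("tau")


def fit_gene_batch_model(
    expr: pd.DataFrame, sentinel_meta: pd.DataFrame
) -> GeneBatchModels:
    """Fit g_ij = mu + beta*sample_ij + batch_i + e_ij for every gene.

    ``expr`` is VST expression restricted to sentinel columns;
    ``sentinel_meta`` maps each column to its biological ``source`` and
    processing ``batch``.  Balanced designs use closed-form ANOVA
    method-of-moments (vectorized over genes); unbalanced designs fall back
    to a per-gene profile-likelihood (REML) fit via statsmodels MixedLM.
    Negative variance estimates are truncated at zero.
    """
    cols = list(expr.columns)
    missing = [c for c in cols if c not in sentinel_meta.index]
    if missing:
        raise FilterError(f"sentinel metadata missing for columns: {missing[:5]}")
    meta = sentinel_meta.loc[cols]
    sources = pd.Categorical(meta["source"])
    batches = pd.Categorical(meta["batch"])
    ns, nb = len(sources.categories), len(batches.categories)
    if nb < 2 or ns < 2:
        raise FilterError("need >= 2 batches and >= 2 sentinel sources")
    cell = pd.crosstab(sources.codes, batches.codes)
    if (cell.to_numpy() == 0).any():
        raise FilterError("singular design: empty source x batch cells")
    balanced = cell.to_numpy().min() == cell.to_numpy().max()

    Y = expr.to_numpy(dtype=float)
    N = Y.shape[1]
    s_idx = np.asarray(sources.codes)
    b_idx = np.asarray(batches.codes)

    if balanced:
        grand = Y.mean(axis=1)
        S_ind = np.zeros((N, ns)); S_ind[np.arange(N), s_idx] = 1.0
        B_ind = np.zeros((N, nb)); B_ind[np.arange(N), b_idx] = 1.0
        s_means = (Y @ S_ind) / S_ind.sum(axis=0)
        b_means = (Y @ B_ind) / B_ind.sum(axis=0)
        n_per_batch = N / nb
        ms_batch = n_per_batch * ((b_means - grand[:, None]) ** 2).sum(axis=1) / (nb - 1)
        fitted = s_means[:, s_idx] + b_means[:, b_idx] - grand[:, None]
        df_res = N - ns - nb + 1
        if df_res < 1:
            raise FilterError("singular design: no residual degrees of freedom")
        sigma2_e = ((Y - fitted) ** 2).sum(axis=1) / df_res
        sigma2_b = np.maximum(0.0, (ms_batch - sigma2_e) / n_per_batch)
        source_eff = s_means - grand[:, None]
        method = "anova-mom"
    else:
        sigma2_b, sigma2_e, grand, source_eff = _fit_unbalanced(Y, s_idx, b_idx, ns)
        method = "reml"

    params = pd.DataFrame(
        {
            "mu": grand,
            "sigma2_batch": sigma2_b,
            "sigma2_e": sigma2_e,
            "total_variation": sigma2_b + sigma2_e,
        },
        index=expr.index,
    )
    source_effects = pd.DataFrame(
        source_eff, index=expr.index, columns=[str(c) for c in sources.categories]
    )
    return GeneBatchModels(params=params, source_effects=source_effects, method=method)


def _unbalanced_mom(y, s_idx, b_idx):
    """Henderson-style method-of-moments rescue for one gene on an
    unbalanced design (used when the REML fit fails numerically)."""
    N = y.size
    nb = b_idx.max() + 1
    ns = s_idx.max() + 1
    grand = y.mean()
    b_means = np.bincount(b_idx, weights=y, minlength=nb) / np.bincount(b_idx, minlength=nb)
    s_means = np.bincount(s_idx, weights=y, minlength=ns) / np.bincount(s_idx, minlength=ns)
    fitted = s_means[s_idx] + b_means[b_idx] - grand
    df_res = N - ns - nb + 1
    sigma2_e = ((y - fitted) ** 2).sum() / max(df_res, 1)
    n_b = np.bincount(b_idx, minlength=nb)
    ms_batch = (n_b * (b_means - grand) ** 2).sum() / (nb - 1)
    k = n_b.mean()
    return max(0.0, (ms_batch - sigma2_e) / k), sigma2_e


def _fit_unbalanced(Y, s_idx, b_idx, ns):
    """Per-gene REML fallback for unbalanced sentinel designs."""
    import statsmodels.formula.api as smf

    sigma2_b = np.empty(Y.shape[0])
    sigma2_e = np.empty(Y.shape[0])
    grand = Y.mean(axis=1)
    eff = np.zeros((Y.shape[0], ns))
    data = pd.DataFrame({"source": s_idx.astype(str), "batch": b_idx.astype(str)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in range(Y.shape[0]):
            data["y"] = Y[g]
            try:
                md = smf.mixedlm("y ~ C(source)", data, groups=data["batch"])
                fit = md.fit(reml=True, method="lbfgs")
                sigma2_b[g] = max(0.0, float(fit.cov_re.iloc[0, 0]))
                sigma2_e[g] = float(fit.scale)
            except (np.linalg.LinAlgError, ValueError):
                sigma2_b[g], sigma2_e[g] = _unbalanced_mom(Y[g], s_idx, b_idx)
            for s in range(ns):
                eff[g, s] = data.loc[data["source"] == str(s), "y"].mean() - grand[g]
    return sigma2_b, sigma2_e, grand, eff


def filter_batch_sensitive(
    models: GeneBatchModels, universe: GeneSet, top_fraction: float = 0.05
) -> GeneSet:
    """Exclude the top ``top_fraction`` of the universe by total variation
    (batch + residual variance); ties at the cut are broken by gene-ID
    lexicographic order so the removal set is deterministic."""
    if not 0.0 < top_fraction < 1.0:
        raise FilterError("top_fraction must lie in (0, 1)")
    missing = [g for g in universe if g not in models.params.index]
    if missing:
        raise FilterError(f"no fitted batch model for genes: {missing[:10]}")
    tv = models.params.loc[list(universe), "total_variation"]
    n_remove = math.ceil(top_fraction * len(universe))
    order = sorted(universe, key=lambda g: (-tv[g], g))
    removed = set(order[:n_remove])
    return GeneSet([g for g in universe if g not in removed], provenance="batch_sensitive")


def filter_report(
    universe: GeneSet, stages: Iterable[tuple[str, GeneSet]]
) -> pd.DataFrame:
    """Per-gene report of which stage (if any) removed it."""
    stage_of = {}
    current = set(universe)
    for name, gs in stages:
        kept = set(gs)
        for g in current - kept:
            stage_of[g] = name
        current = kept
    return pd.DataFrame(
        {
            "stage_removed": [stage_of.get(g, "") for g in universe],
            "retained": [g not in stage_of for g in universe],
        },
        index=pd.Index(list(universe), name="gene"),
    )
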