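"""Median-of-ratios size factors and a frozen variance-stabilizing transform.

Sequencing depth is equalized with the median-of-ratios method: each
sample's size factor is the median, over genes with an all-positive
reference, of its counts divided by the per-gene geometric mean of the
reference samples.  Depth-normalized counts are then mapped through a
closed-form parametric variance-stabilizing transformation (VST) derived
from the negative-binomial variance trend

    v(mu) = mu * (1 + alpha_e) + alpha_t * mu**2,

whose antiderivative of 1/sqrt(v), rescaled to base 2, is

    vst(q) = log2( (1 + alpha_e + 2*alpha_t*q
                    + 2*sqrt(alpha_t*q*(1 + alpha_e + alpha_t*q)))
                   / (4*alpha_t) ).

The transform is asymptotically log2(q) for large q.  The per-gene
geometric-mean reference and the trend parameters (alpha_t, alpha_e) are
*frozen* on the training set and reapplied verbatim to any later sample,
so a new sample's expression never depends on which other samples happen
to be processed alongside it.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd

from .containers import CountMatrix


class NormalizationError(ValueError):
    """Raised on unidentifiable size factors or invalid VST parameters."""


@dataclasses.dataclass
class SizeFactors:
    """Per-sample depth factors and the per-gene reference used to derive them.

    ``reference`` holds geometric means over the reference samples; genes
    with a zero count in any reference sample have reference 0 and are
    excluded from the median.
    """

    factors: pd.Series  # sample -> s_i > 0
    reference: pd.Series  # gene -> geometric mean (0 = unusable)

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise NormalizationError("size factors must be finite and positive")


def geometric_means(counts: CountMatrix) -> pd.Series:
    """Per-gene geometric mean across samples; 0 where any count is zero."""
    K = counts.values.astype(float)
    with np.errstate(divide="ignore"):
        logs = np.log(K)
    any_zero = (K == 0).any(axis=1)
    gm = np.exp(logs.mean(axis=1))
    gm[any_zero] = 0.0
    return pd.Series(gm, index=counts.genes, name="geomean")


def estimate_size_factors(
    counts: CountMatrix, reference: Optional[pd.Series] = None
) -> SizeFactors:
    """Median-of-ratios size factors against a (possibly frozen) reference.

    When ``reference`` is omitted it is computed from ``counts`` itself.
    Each sample's factor is the median over usable genes (reference > 0)
    of count / reference geometric mean.
    """
    if reference is None:
        reference = geometric_means(counts)
    else:
        reference = reference.reindex(counts.genes)
        if reference.isna().any():
            missing = reference.index[reference.isna()].tolist()
            raise NormalizationError(
                f"reference lacks geometric means for genes: {missing[:5]}"
            )
    ref = reference.to_numpy(dtype=float)
    usable = ref > 0
    if not usable.any():
        raise NormalizationError(
            "size factors unidentifiable: no gene with an all-positive reference"
        )
    ratios = counts.values[usable].astype(float) / ref[usable, None]
    s = np.median(ratios, axis=0)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        bad = counts.samples[(~np.isfinite(s)) | (s <= 0)].tolist()
        raise NormalizationError(
            f"size factors unidentifiable (zero/non-finite median) for samples: {bad[:5]}"
        )
    return SizeFactors(
        factors=pd.Series(s, index=counts.samples, name="size_factor"),
        reference=pd.Series(ref, index=counts.genes, name="geomean"),
    )


def normalized_counts(counts: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    """Depth-normalized counts C_ij = K_ij / s_i."""
    s = sf.factors.reindex(counts.samples)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise NormalizationError(f"no size factor for samples: {missing[:5]}")
    return counts.df / s.to_numpy()[None, :]


def fit_dispersion_trend(
    counts: CountMatrix,
    sf: SizeFactors,
    min_genes: int = 50,
    max_iter: int = 10,
    mad_cut: float = 2.0,
) -> tuple[float, float]:
    """Robust fit of the dispersion trend alpha(mu) = alpha_t + alpha_e / mu.

    Per-gene method-of-moments dispersions d_g = max(0, (var - mean)/mean^2)
    are computed on depth-normalized counts; genes with d_g <= 0 (including
    constant-count genes) are excluded.  The trend is fitted by iterated
    least squares of d on 1/mean with residual trimming beyond
    ``mad_cut`` MADs per iteration.
    """
    C = normalized_counts(counts, sf).to_numpy()
    mean = C.mean(axis=1)
    var = C.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (var - mean) / mean**2
    use = np.isfinite(d) & (d > 0) & (mean > 0)
    if use.sum() < min_genes:
        raise NormalizationError(
            f"dispersion trend needs >= {min_genes} genes with positive "
            f"method-of-moments dispersion, got {int(use.sum())}"
        )
    x = 1.0 / mean[use]
    y = d[use]
    keep = np.ones(x.size, dtype=bool)
    beta = None
    for _ in range(max_iter):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        beta, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        resid = y - (beta[0] + beta[1] * x)
        med = np.median(resid[keep])
        mad = 1.4826 * np.median(np.abs(resid[keep] - med))
        if mad <= 0:
            break
        new_keep = np.abs(resid - med) <= mad_cut * mad
        if new_keep.sum() < min_genes or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    if beta is None:  # pragma: no cover - defensive
        raise NormalizationError("dispersion trend fit did not run")
    alpha_t, alpha_e = float(beta[0]), float(beta[1])
    if alpha_e < 0:
        # refit pure-asymptotic model with the extra-Poisson term pinned at 0
        alpha_e = 0.0
        alpha_t = float(np.mean(y[keep]))
    if alpha_t <= 0:
        alpha_t = 1e-8  # Poisson-like data: vanishing asymptotic dispersion
    return alpha_t, alpha_e


def vst_values(q: np.ndarray, alpha_t: float, alpha_e: float) -> np.ndarray:
    """Closed-form VST of depth-normalized counts q >= 0."""
    if alpha_t <= 0:
        raise NormalizationError("alpha_t must be strictly positive")
    if alpha_e < 0:
        raise NormalizationError("alpha_e must be non-negative")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise NormalizationError("negative normalized counts")
    inner = (
        1.0
        + alpha_e
        + 2.0 * alpha_t * q
        + 2.0 * np.sqrt(alpha_t * q * (1.0 + alpha_e + alpha_t * q))
    )
    return np.log2(inner / (4.0 * alpha_t))


@dataclasses.dataclass
class FrozenNormalization:
    """Training-derived normalization locked for reuse on future samples."""

    gene_order: list[str]
    reference_geomeans: np.ndarray
    alpha_t: float
    alpha_e: float
    version: str = "1"

    def __post_init__(self) -> None:
        self.reference_geomeans = np.asarray(self.reference_geomeans, dtype=float)
        if len(self.gene_order) != self.reference_geomeans.size:
            raise NormalizationError("gene_order and reference_geomeans disagree")
        if self.alpha_t <= 0 or self.alpha_e < 0:
            raise NormalizationError("invalid frozen VST parameters")

    @property
    def reference(self) -> pd.Series:
        return pd.Series(self.reference_geomeans, index=self.gene_order, name="geomean")

    @classmethod
    def fit(cls, counts: CountMatrix) -> "FrozenNormalization":
        """Fit reference geometric means and dispersion trend on training counts."""
        sf = estimate_size_factors(counts)
        alpha_t, alpha_e = fit_dispersion_trend(counts, sf)
        return cls(
            gene_order=list(counts.genes),
            reference_geomeans=sf.reference.to_numpy(),
            alpha_t=alpha_t,
            alpha_e=alpha_e,
        )

    def size_factors(self, counts: CountMatrix) -> SizeFactors:
        self._check_genes(counts.genes)
        return estimate_size_factors(
            counts.subset_genes(self.gene_order), reference=self.reference
        )

    def _check_genes(self, genes: pd.Index) -> None:
        missing = [g for g in self.gene_order if g not in genes]
        if missing:
            raise NormalizationError(
                f"counts lack genes required by the frozen normalization: {missing[:5]}"
            )

    # -- serialization -------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "gene_order": self.gene_order,
            "reference_geomeans": self.reference_geomeans.tolist(),
            "alpha_t": self.alpha_t,
            "alpha_e": self.alpha_e,
            "version": self.version,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "FrozenNormalization":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            gene_order=payload["gene_order"],
            reference_geomeans=np.asarray(payload["reference_geomeans"]),
            alpha_t=payload["alpha_t"],
            alpha_e=payload["alpha_e"],
            version=payload.get("version", "1"),
        )


def apply_vst(counts: CountMatrix, frozen: FrozenNormalization) -> pd.DataFrame:
    """Frozen-path normalization: size factors against the frozen reference,
    then the frozen closed-form VST.  Each column depends only on its own
    counts and the frozen artifact."""
    frozen._check_genes(counts.genes)
    sub = counts.subset_genes(frozen.gene_order)
    sf = estimate_size_factors(sub, reference=frozen.reference)
    q = normalized_counts(sub, sf)
    return pd.DataFrame(
        vst_values(q.to_numpy(), frozen.alpha_t, frozen.alpha_e),
        index=sub.genes,
        columns=sub.samples,
    )
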