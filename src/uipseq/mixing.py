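"""In-silico within-patient sample mixing and technical-noise replication.

A patient-level pooled sample is simulated from individual biopsies by
averaging their depth-normalized counts:

    C_ij = K_ij / s_i,      K^p_j = (1/n_p) * sum_{i in I(p)} C_ij,

where I(p) indexes the patient's samples.  The frozen VST is then applied
to the mixed counts directly (the C values are already on the common
depth scale, so no size factor is re-estimated for the mixed column).
Technical-noise replicates add independent per-gene Gaussian noise on the
VST scale, with SD taken from the sentinel batch model.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .filtering import GeneBatchModels
from .normalization import FrozenNormalization, SizeFactors, normalized_counts, vst_values


class MixingError(ValueError):
    pass


@dataclasses.dataclass
class NoiseModel:
    """Per-gene technical SD on the VST scale and a replicate count."""

    tau: pd.Series
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.tau < 0).any():
            raise MixingError("technical SDs must be non-negative")
        if self.n_replicates < 1:
            raise MixingError("n_replicates must be >= 1")

    @classmethod
    def from_batch_models(
        cls,
        models: GeneBatchModels,
        residual_only: bool = False,
        n_replicates: int = 100,
        seed: int = 0,
    ) -> "NoiseModel":
        """tau_j = sqrt(sigma2_batch + sigma2_e) (or residual-only)."""
        return cls(
            tau=models.technical_sd(residual_only=residual_only),
            n_replicates=n_replicates,
            seed=seed,
        )


def mix_within_patient(
    counts: CountMatrix, sf: SizeFactors, patient_map: pd.Series
) -> pd.DataFrame:
    """In-silico mixed counts: one column per patient, the arithmetic mean of
    the patient's depth-normalized sample counts.  Mixing across patients is
    unsupported: every sample must map to exactly one patient."""
    pm = patient_map.reindex(counts.samples)
    if pm.isna().any():
        missing = pm.index[pm.isna()].tolist()
        raise MixingError(f"samples without a patient assignment: {missing[:5]}")
    C = normalized_counts(counts, sf)
    mixed = C.T.groupby(pm).mean().T
    empty = [p for p in pm.unique() if p not in mixed.columns]
    if empty:  # pragma: no cover - groupby cannot produce this
        raise MixingError(f"patients with zero samples: {empty[:5]}")
    return mixed


def vst_mixed(mixed: pd.DataFrame, frozen: FrozenNormalization) -> pd.DataFrame:
    """Frozen VST applied to mixed counts directly (no re-size-factoring)."""
    missing = [g for g in frozen.gene_order if g not in mixed.index]
    if missing:
        raise MixingError(f"mixed matrix lacks frozen genes: {missing[:5]}")
    sub = mixed.loc[frozen.gene_order]
    return pd.DataFrame(
        vst_values(sub.to_numpy(), frozen.alpha_t, frozen.alpha_e),
        index=sub.index,
        columns=sub.columns,
    )


def replicate_with_noise(
    expr: pd.DataFrame,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """R technical-noise replicates of a VST expression matrix.

    Returns an array of shape (R, n_genes, n_columns): replicate r is
    ``expr + eps_r`` with ``eps_r[j, :] ~ N(0, tau_j^2)`` independent across
    genes, columns and replicates.  Seeded via ``noise.seed`` unless an
    explicit generator is passed.
    """
    tau = noise.tau.reindex(expr.index)
    if tau.isna().any():
        missing = tau.index[tau.isna()].tolist()
        raise MixingError(f"no technical SD for genes: {missing[:5]}")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    base = expr.to_numpy(dtype=float)
    eps = rng.normal(
        0.0, 1.0, size=(noise.n_replicates, base.shape[0], base.shape[1])
    ) * tau.to_numpy()[None, :, None]
    return base[None, :, :] + eps


def concordance(
    insilico: pd.DataFrame,
    invitro: pd.DataFrame,
    pairing: pd.Series,
) -> tuple[pd.Series, float, float]:
    """Per-patient squared Pearson correlation across genes between paired
    in-silico and in-vitro columns.

    ``pairing`` maps in-vitro column name -> in-silico column (patient)
    name.  Returns (per-pair r^2, mean, SD over pairs).
    """
    if not insilico.index.equals(invitro.index):
        raise MixingError("gene indices differ between matrices")
    r2 = {}
    for vit_col, sil_col in pairing.items():
        if vit_col not in invitro.columns:
            raise MixingError(f"unpaired in-vitro column: {vit_col!r}")
        if sil_col not in insilico.columns:
            raise MixingError(f"unpaired in-silico column: {sil_col!r}")
        r = np.corrcoef(invitro[vit_col].to_numpy(), insilico[sil_col].to_numpy())[0, 1]
        r2[vit_col] = r**2
    r2 = pd.Series(r2, name="r2")
    return r2, float(r2.mean()), float(r2.std(ddof=1)) if len(r2) > 1 else 0.0
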