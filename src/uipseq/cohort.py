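"""Synthetic multi-biopsy RNA-seq cohort generator.

Emulates the data structure a UIP/non-UIP classifier-development study
produces: ~90 patients each contributing up to five transbronchial biopsy
(TBB) samples (typically two upper-lobe and three lower-lobe), a binary
patient label (UIP prevalence ~59%) over molecularly heterogeneous non-UIP
subtypes, sentinel samples replicated across processing batches, in-vitro
patient-level pools, and lobe-level pathology diagnoses aggregated to a
patient label.

Latent expression is defined on log2 scale as additive
baseline + class effect + subtype shift + lobe deviation + batch effect;
counts are drawn negative-binomial with a mean-dispersion trend
alpha(mu) = alpha_t + alpha_e / mu, matching the variance structure the
normalization/VST stage assumes.  Each non-UIP subtype shifts its own
disjoint random gene set so subtypes are molecularly distinct.
"""

from __future__ import annotations

import copy
import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

# ---------------------------------------------------------------------------
# Pathology vocabulary and label-assignment rules
# ---------------------------------------------------------------------------

UIP_SUBTYPES = ("Classic UIP", "Difficult UIP", "Favor UIP")
UNCLASSIFIABLE_FIBROSIS = "CIF-NOC"  # chronic interstitial fibrosis, NOC
NON_DIAGNOSTIC = "non-diagnostic"

#: Non-UIP pathology conditions the generator can assign to a lobe.
NONUIP_CONDITIONS = (
    "Organizing pneumonia",
    "Respiratory bronchiolitis",
    "Hypersensitivity pneumonitis",
    "Nonspecific interstitial pneumonia",
    "Sarcoidosis",
    "Bronchiolitis",
    "Emphysema",
    "Eosinophilic pneumonia",
    "Diffuse alveolar damage",
    "Pulmonary hypertension",
    "Pneumocystis pneumonia",
)

DIAGNOSIS_VOCABULARY = frozenset(
    UIP_SUBTYPES + NONUIP_CONDITIONS + (UNCLASSIFIABLE_FIBROSIS, NON_DIAGNOSTIC)
)

LOBES = ("upper", "middle", "lower")


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def assign_patient_label(lobe_diagnoses: Mapping[str, str] | Iterable[str]) -> str:
    """Aggregate per-lobe pathology diagnoses into a patient reference label.

    Rules: any lobe with any UIP subtype -> ``'UIP'``; otherwise any lobe
    with a non-UIP condition -> ``'non-UIP'``; when every lobe is
    non-diagnostic or unclassifiable fibrosis no label can be assigned and
    ``'unlabelable'`` is returned.
    """
    if isinstance(lobe_diagnoses, Mapping):
        values = list(lobe_diagnoses.values())
    else:
        values = list(lobe_diagnoses)
    if not values:
        raise ValueError("at least one lobe diagnosis is required")
    unknown = [v for v in values if v not in DIAGNOSIS_VOCABULARY]
    if unknown:
        raise ValueError(f"diagnoses outside the vocabulary: {unknown[:5]}")
    if any(v in UIP_SUBTYPES for v in values):
        return "UIP"
    if any(v in NONUIP_CONDITIONS for v in values):
        return "non-UIP"
    return "unlabelable"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SubtypeSpec:
    """A non-UIP pathology subtype: prevalence weight among non-UIP patients
    and the log2-scale SD of its mean shift on its own gene set."""

    name: str
    weight: float
    shift_sd: float = 0.8


def _default_subtypes() -> list[SubtypeSpec]:
    # prevalence weights loosely follow a training-set clinic mix
    raw = [
        ("Organizing pneumonia", 0.20),
        ("Respiratory bronchiolitis", 0.19),
        ("Sarcoidosis", 0.14),
        ("Hypersensitivity pneumonitis", 0.12),
        ("Nonspecific interstitial pneumonia", 0.12),
        ("Bronchiolitis", 0.11),
        ("Emphysema", 0.12),
    ]
    return [SubtypeSpec(name, w) for name, w in raw]


@dataclasses.dataclass
class CohortConfig:
    """Study-condition parameters for :func:`generate_cohort`.

    Defaults emulate the source study's structure at desk scale: 90
    patients, 3-5 biopsies each, 59% UIP prevalence, heterogeneous non-UIP
    subtypes on disjoint gene sets, 8 processing batches, and a
    negative-binomial dispersion trend.
    """

    n_patients: int = 90
    samples_per_patient_range: tuple[int, int] = (3, 5)
    n_genes: int = 2000
    frac_uip: float = 0.59
    nonuip_subtypes: list[SubtypeSpec] = dataclasses.field(
        default_factory=_default_subtypes
    )
    frac_informative_genes: float = 0.05
    effect_size_sd: float = 1.0
    lobe_effect_sd: float = 0.25
    batch_sd: float = 0.15
    n_batches: int = 8
    library_size_range: tuple[float, float] = (3e5, 1.5e6)
    dispersion_params: tuple[float, float] = (0.005, 2.0)
    discordant_lobe_rate: float = 3.0 / 90.0
    nondiagnostic_sample_rate: float = 0.05
    unlabelable_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be a positive integer")
        lo, hi = self.samples_per_patient_range
        if not (1 <= lo <= hi <= 5):
            raise CohortConfigError("samples_per_patient_range must lie within 1..5")
        if self.n_genes < 10:
            raise CohortConfigError("n_genes must be at least 10")
        if not 0.0 <= self.frac_uip <= 1.0:
            raise CohortConfigError("frac_uip must be a proportion in [0, 1]")
        if not self.nonuip_subtypes:
            raise CohortConfigError("nonuip_subtypes must be non-empty")
        wsum = sum(s.weight for s in self.nonuip_subtypes)
        if abs(wsum - 1.0) > 1e-8:
            raise CohortConfigError(
                f"nonuip_subtypes prevalence weights must sum to 1 (got {wsum:.6f})"
            )
        for s in self.nonuip_subtypes:
            if s.name not in NONUIP_CONDITIONS:
                raise CohortConfigError(
                    f"nonuip_subtypes name {s.name!r} outside the diagnosis vocabulary"
                )
            if s.shift_sd < 0:
                raise CohortConfigError("nonuip_subtypes shift_sd must be >= 0")
        if not 0.0 <= self.frac_informative_genes <= 1.0:
            raise CohortConfigError("frac_informative_genes must be in [0, 1]")
        for field in ("effect_size_sd", "lobe_effect_sd", "batch_sd"):
            if getattr(self, field) < 0:
                raise CohortConfigError(f"{field} must be non-negative")
        if self.n_batches < 1:
            raise CohortConfigError("n_batches must be >= 1")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise CohortConfigError("library_size_range must be a positive interval")
        alpha_t, alpha_e = self.dispersion_params
        if alpha_t <= 0:
            raise CohortConfigError("dispersion_params alpha_t must be > 0")
        if alpha_e < 0:
            raise CohortConfigError("dispersion_params alpha_e must be >= 0")
        for field in (
            "discordant_lobe_rate",
            "nondiagnostic_sample_rate",
            "unlabelable_rate",
        ):
            if not 0.0 <= getattr(self, field) <= 1.0:
                raise CohortConfigError(f"{field} must be a proportion in [0, 1]")


# ---------------------------------------------------------------------------
# Simulated cohort container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SimulatedCohort:
    """A generated cohort: counts, metadata, diagnoses and ground truth.

    ``sample_meta`` has one row per sample (patient, lobe, batch, role,
    diagnostic flag); ``gene_truth`` carries per-gene baselines, effects and
    annotation; ``patient_truth`` the simulated class, subtype and the
    reference label derived via :func:`assign_patient_label`.
    """

    counts: CountMatrix
    sample_meta: pd.DataFrame
    lobe_diagnoses: pd.DataFrame  # columns: patient, lobe, diagnosis
    gene_truth: pd.DataFrame
    patient_truth: pd.DataFrame
    config: CohortConfig
    # biological latent log2 expression per sample (pre batch effect),
    # retained so sentinel/pool generation can reuse it
    bio_log2: pd.DataFrame = dataclasses.field(repr=False, default=None)

    def __post_init__(self) -> None:
        meta_samples = pd.Index(self.sample_meta.index)
        if not meta_samples.equals(self.counts.samples):
            raise ValueError("sample_meta rows must match count matrix columns 1:1")

    @property
    def annotation(self) -> pd.DataFrame:
        """Gene annotation table (biotype, in_target_panel)."""
        return self.gene_truth[["biotype", "in_target_panel"]]

    def biopsy_samples(self) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["role"] == "biopsy"]

    def labeled_patients(self) -> pd.Index:
        """Patients with an assignable reference label (unlabelable excluded)."""
        ok = self.patient_truth["label"] != "unlabelable"
        return self.patient_truth.index[ok]

    def sample_labels(self, samples: Sequence[str] | None = None) -> pd.Series:
        """Per-sample binary label (1 = UIP) inherited from the patient label;
        samples of unlabelable patients are dropped."""
        meta = self.sample_meta if samples is None else self.sample_meta.loc[list(samples)]
        lab = self.patient_truth["label"].reindex(meta["patient"]).to_numpy()
        keep = lab != "unlabelable"
        return pd.Series(
            (lab[keep] == "UIP").astype(int), index=meta.index[keep], name="label"
        )

    # -- IO --------------------------------------------------------------
    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.counts.to_tsv(os.path.join(outdir, "counts.tsv"))
        self.sample_meta.to_csv(
            os.path.join(outdir, "sample_meta.tsv"), sep="\t", index_label="sample"
        )
        self.lobe_diagnoses.to_csv(
            os.path.join(outdir, "lobe_diagnoses.tsv"), sep="\t", index=False
        )
        self.gene_truth.to_csv(
            os.path.join(outdir, "gene_truth.tsv"), sep="\t", index_label="gene"
        )
        self.patient_truth.to_csv(
            os.path.join(outdir, "patient_truth.tsv"), sep="\t", index_label="patient"
        )


# ---------------------------------------------------------------------------
# Generation internals
# ---------------------------------------------------------------------------


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha_t: float, alpha_e: float) -> np.ndarray:
    """Negative-binomial counts with dispersion trend alpha(mu)=alpha_t+alpha_e/mu
    via the gamma-Poisson mixture."""
    mu = np.maximum(mu, 1e-12)
    alpha = alpha_t + alpha_e / mu
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def _lobe_pattern(n: int) -> list[str]:
    """Typical sampling: two upper-lobe and three lower-lobe biopsies."""
    full = ["upper", "upper", "lower", "lower", "lower"]
    if n >= 5:
        return full[:5]
    return {1: ["lower"], 2: ["upper", "lower"], 3: ["upper", "lower", "lower"],
            4: ["upper", "upper", "lower", "lower"]}[n]


def _counts_from_bio(
    rng: np.random.Generator,
    bio_log2: np.ndarray,
    batch_codes: np.ndarray,
    batch_effects: np.ndarray,
    lib_sizes: np.ndarray,
    alpha_t: float,
    alpha_e: float,
) -> np.ndarray:
    """Counts from biological latent log2 plus per-batch gene-level effects."""
    total = bio_log2 + batch_effects[:, batch_codes]
    q = np.exp2(total)
    p = q / q.sum(axis=0, keepdims=True)
    mu = p * lib_sizes[None, :]
    return _nb_counts(rng, mu, alpha_t, alpha_e)


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a seeded synthetic biopsy cohort per the configured conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_genes
    alpha_t, alpha_e = config.dispersion_params

    genes = np.array([f"G{i:05d}" for i in range(m)])

    # annotation: a small slice of the universe is off-panel or in excluded
    # biotypes; informative genes are drawn from the clean remainder so the
    # planted signal survives annotation filtering
    biotype = np.full(m, "protein_coding", dtype=object)
    in_panel = np.ones(m, dtype=bool)
    n_pseudo = int(round(0.03 * m))
    n_rrna = int(round(0.01 * m))
    n_trig = int(round(0.01 * m))
    n_offpanel = int(round(0.03 * m))
    special = rng.choice(m, size=n_pseudo + n_rrna + n_trig + n_offpanel, replace=False)
    biotype[special[:n_pseudo]] = "pseudogene"
    biotype[special[n_pseudo : n_pseudo + n_rrna]] = "rRNA"
    biotype[special[n_pseudo + n_rrna : n_pseudo + n_rrna + n_trig]] = "TR_exon"
    in_panel[special[n_pseudo + n_rrna + n_trig :]] = False
    clean = np.setdiff1d(np.arange(m), special)

    baseline = rng.normal(4.0, 2.0, size=m)

    # class-informative genes and disjoint per-subtype gene sets
    n_inf = int(round(config.frac_informative_genes * m))
    pool = rng.permutation(clean)
    inf_idx = pool[:n_inf]
    class_effect = np.zeros(m)
    class_effect[inf_idx] = rng.normal(0.0, config.effect_size_sd, size=n_inf)
    informative = np.zeros(m, dtype=bool)
    informative[inf_idx] = True

    subtype_sets: dict[str, np.ndarray] = {}
    subtype_shift = {}
    per_subtype = max(5, int(round(0.02 * m)))
    cursor = n_inf
    for sub in config.nonuip_subtypes:
        idx = pool[cursor : cursor + per_subtype]
        cursor += per_subtype
        shift = np.zeros(m)
        if idx.size:
            shift[idx] = rng.normal(0.0, sub.shift_sd, size=idx.size)
        subtype_sets[sub.name] = idx
        subtype_shift[sub.name] = shift

    # patients
    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    is_uip = rng.random(config.n_patients) < config.frac_uip
    sub_names = [s.name for s in config.nonuip_subtypes]
    sub_w = np.array([s.weight for s in config.nonuip_subtypes])
    subtype_of = np.where(
        is_uip, "UIP", rng.choice(sub_names, size=config.n_patients, p=sub_w)
    )

    n_unlab = int(round(config.unlabelable_rate * config.n_patients))
    unlabelable = np.zeros(config.n_patients, dtype=bool)
    if n_unlab:
        unlabelable[rng.choice(config.n_patients, size=n_unlab, replace=False)] = True

    uip_idx = np.flatnonzero(is_uip & ~unlabelable)
    n_disc = min(int(round(config.discordant_lobe_rate * config.n_patients)), uip_idx.size)
    discordant = np.zeros(config.n_patients, dtype=bool)
    if n_disc:
        discordant[rng.choice(uip_idx, size=n_disc, replace=False)] = True

    lo, hi = config.samples_per_patient_range
    n_samples_per_patient = rng.integers(lo, hi + 1, size=config.n_patients)

    sample_ids, sample_patient, sample_lobe = [], [], []
    for p, pid in enumerate(patients):
        for k, lobe in enumerate(_lobe_pattern(int(n_samples_per_patient[p]))):
            sample_ids.append(f"{pid}_S{k}")
            sample_patient.append(pid)
            sample_lobe.append(lobe)
    n = len(sample_ids)

    # batches: contiguous accrual blocks over the sample stream
    batch_codes = (np.arange(n) * config.n_batches) // n
    batch_ids = np.array([f"batch_{b:02d}" for b in range(config.n_batches)])
    batch_effects = rng.normal(0.0, config.batch_sd, size=(m, config.n_batches))

    # biological latent per sample
    patient_index = {pid: p for p, pid in enumerate(patients)}
    bio = np.empty((m, n))
    for i, (pid, _lobe) in enumerate(zip(sample_patient, sample_lobe)):
        p = patient_index[pid]
        mean = baseline.copy()
        if is_uip[p]:
            mean += class_effect
        else:
            mean += subtype_shift[subtype_of[p]]
        if config.lobe_effect_sd > 0:
            mean = mean + rng.normal(0.0, config.lobe_effect_sd, size=m)
        bio[:, i] = mean

    lib_sizes = rng.uniform(*config.library_size_range, size=n)
    K = _counts_from_bio(
        rng, bio, batch_codes, batch_effects, lib_sizes, alpha_t, alpha_e
    )

    counts = CountMatrix(pd.DataFrame(K, index=genes, columns=sample_ids))

    nondiag = rng.random(n) < config.nondiagnostic_sample_rate
    sample_meta = pd.DataFrame(
        {
            "patient": sample_patient,
            "lobe": sample_lobe,
            "batch": batch_ids[batch_codes],
            "role": "biopsy",
            "diagnostic": ~nondiag,
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    # lobe-level pathology diagnoses
    diag_rows = []
    for p, pid in enumerate(patients):
        lobes = sorted(set(_lobe_pattern(int(n_samples_per_patient[p]))))
        if unlabelable[p]:
            choices = [UNCLASSIFIABLE_FIBROSIS, NON_DIAGNOSTIC]
            diags = [choices[int(rng.integers(2))] for _ in lobes]
        elif is_uip[p]:
            diags = [str(rng.choice(UIP_SUBTYPES)) for _ in lobes]
            if discordant[p] and len(lobes) > 1:
                # one lobe carries a conflicting non-UIP diagnosis; the
                # aggregation rules still label the patient UIP
                diags[0] = str(rng.choice(sub_names))
        else:
            diags = [subtype_of[p] for _ in lobes]
            if len(lobes) > 1 and rng.random() < 0.15:
                diags[0] = NON_DIAGNOSTIC
        for lobe, d in zip(lobes, diags):
            diag_rows.append((pid, lobe, d))
    lobe_diagnoses = pd.DataFrame(diag_rows, columns=["patient", "lobe", "diagnosis"])

    labels = [
        assign_patient_label(
            lobe_diagnoses.loc[lobe_diagnoses["patient"] == pid, "diagnosis"].tolist()
        )
        for pid in patients
    ]

    subtype_shifted = np.zeros(m, dtype=bool)
    for idx in subtype_sets.values():
        subtype_shifted[idx] = True
    gene_truth = pd.DataFrame(
        {
            "baseline_log2": baseline,
            "informative": informative,
            "class_effect": class_effect,
            "subtype_shifted": subtype_shifted,
            "biotype": biotype,
            "in_target_panel": in_panel,
        },
        index=pd.Index(genes, name="gene"),
    )
    patient_truth = pd.DataFrame(
        {
            "true_class": np.where(is_uip, "UIP", "non-UIP"),
            "subtype": subtype_of,
            "discordant": discordant,
            "label": labels,
        },
        index=pd.Index(patients, name="patient"),
    )

    return SimulatedCohort(
        counts=counts,
        sample_meta=sample_meta,
        lobe_diagnoses=lobe_diagnoses,
        gene_truth=gene_truth,
        patient_truth=patient_truth,
        config=config,
        bio_log2=pd.DataFrame(bio, index=genes, columns=sample_ids),
    )


# ---------------------------------------------------------------------------
# Sentinels, in-vitro pools, validation cohorts
# ---------------------------------------------------------------------------


def generate_sentinels(
    cohort: SimulatedCohort,
    n_sentinels: int = 8,
    n_batches: int = 8,
    seed: int = 0,
) -> SimulatedCohort:
    """Append sentinel samples: fixed biological sources re-processed in every
    one of ``n_batches`` new batches, exposing batch variability."""
    if n_sentinels < 1:
        raise ValueError("n_sentinels must be >= 1")
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2: variance components unidentifiable")
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    m = cfg.n_genes
    alpha_t, alpha_e = cfg.dispersion_params

    baseline = cohort.gene_truth["baseline_log2"].to_numpy()
    class_effect = cohort.gene_truth["class_effect"].to_numpy()

    # each source is a fresh patient-like TBB with its own biology
    sources = np.empty((m, n_sentinels))
    for s in range(n_sentinels):
        mean = baseline.copy()
        if rng.random() < cfg.frac_uip:
            mean += class_effect
        if cfg.lobe_effect_sd > 0:
            mean = mean + rng.normal(0.0, cfg.lobe_effect_sd, size=m)
        sources[:, s] = mean

    batch_effects = rng.normal(0.0, cfg.batch_sd, size=(m, n_batches))
    bio = np.repeat(sources, n_batches, axis=1)  # source-major ordering
    batch_codes = np.tile(np.arange(n_batches), n_sentinels)
    lib_sizes = rng.uniform(*cfg.library_size_range, size=n_sentinels * n_batches)
    K = _counts_from_bio(rng, bio, batch_codes, batch_effects, lib_sizes, alpha_t, alpha_e)

    ids = [
        f"SENT{s:02d}_B{b:02d}" for s in range(n_sentinels) for b in range(n_batches)
    ]
    new_counts = CountMatrix(pd.DataFrame(K, index=cohort.counts.genes, columns=ids))
    new_meta = pd.DataFrame(
        {
            "patient": [f"sentinel_{s:02d}" for s in range(n_sentinels) for _ in range(n_batches)],
            "lobe": "lower",
            "batch": [f"sentinel_batch_{b:02d}" for _ in range(n_sentinels) for b in range(n_batches)],
            "role": "sentinel",
            "diagnostic": True,
        },
        index=pd.Index(ids, name="sample"),
    )

    out = copy.copy(cohort)
    out.counts = cohort.counts.concat(new_counts)
    out.sample_meta = pd.concat([cohort.sample_meta, new_meta])
    out.bio_log2 = pd.concat(
        [cohort.bio_log2, pd.DataFrame(bio, index=cohort.counts.genes, columns=ids)],
        axis=1,
    )
    return out


def _pool_latent(cohort: SimulatedCohort, sample_ids: Sequence[str]) -> np.ndarray:
    """Equal-mass mixture of sample-level latent expression on linear scale."""
    bio = cohort.bio_log2[list(sample_ids)].to_numpy()
    q = np.exp2(bio)
    p = q / q.sum(axis=0, keepdims=True)  # each sample contributes equal RNA mass
    return p.mean(axis=1)


def generate_invitro_pools(
    cohort: SimulatedCohort,
    patient_ids: Sequence[str],
    seed: int = 0,
    n_replicates: int = 1,
    batch_prefix: str = "pool_batch",
) -> SimulatedCohort:
    """Append one in-vitro pooled sample (optionally replicated across fresh
    batches) per named patient: the pool's latent expression is the
    equal-mass mixture of that patient's biopsies, re-counted with fresh
    technical noise in a new processing batch."""
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    alpha_t, alpha_e = cfg.dispersion_params
    biopsies = cohort.sample_meta[cohort.sample_meta["role"] == "biopsy"]

    latents, ids, meta_rows = [], [], []
    for pid in patient_ids:
        samp = biopsies.index[biopsies["patient"] == pid]
        if len(samp) == 0:
            raise ValueError(f"unknown patient or patient without biopsies: {pid!r}")
        p = _pool_latent(cohort, samp)
        for r in range(n_replicates):
            latents.append(p)
            ids.append(f"POOL_{pid}" + (f"_R{r}" if n_replicates > 1 else ""))
            meta_rows.append((pid, f"{batch_prefix}_{r:02d}"))

    P = np.column_stack(latents)
    m = P.shape[0]
    batch_names = sorted({b for _, b in meta_rows})
    batch_effects = rng.normal(0.0, cfg.batch_sd, size=(m, len(batch_names)))
    batch_codes = np.array([batch_names.index(b) for _, b in meta_rows])
    lib_sizes = rng.uniform(*cfg.library_size_range, size=len(ids))
    mu = P * lib_sizes[None, :] * np.exp2(batch_effects[:, batch_codes])
    mu = mu / mu.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    K = _nb_counts(rng, mu, alpha_t, alpha_e)

    new_counts = CountMatrix(pd.DataFrame(K, index=cohort.counts.genes, columns=ids))
    new_meta = pd.DataFrame(
        {
            "patient": [p for p, _ in meta_rows],
            "lobe": "pooled",
            "batch": [b for _, b in meta_rows],
            "role": "pool",
            "diagnostic": True,
        },
        index=pd.Index(ids, name="sample"),
    )
    out = copy.copy(cohort)
    out.counts = cohort.counts.concat(new_counts)
    out.sample_meta = pd.concat([cohort.sample_meta, new_meta])
    out.bio_log2 = pd.concat(
        [cohort.bio_log2, pd.DataFrame(np.log2(P), index=cohort.counts.genes, columns=ids)],
        axis=1,
    )
    return out


def generate_validation_cohort(
    cohort: SimulatedCohort,
    n_patients: int = 49,
    frac_uip: float = 0.47,
    seed: int = 1,
) -> SimulatedCohort:
    """An independent test cohort from the same gene-level ground truth:
    new patients, each represented by a single pooled sample of 3-5 fresh
    biopsies (mirroring one sequencing run per validation patient)."""
    cfg = dataclasses.replace(
        copy.deepcopy(cohort.config),
        n_patients=n_patients,
        frac_uip=frac_uip,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9173]))
    m = cfg.n_genes
    alpha_t, alpha_e = cfg.dispersion_params
    baseline = cohort.gene_truth["baseline_log2"].to_numpy()
    class_effect = cohort.gene_truth["class_effect"].to_numpy()

    # reconstruct the subtype shift fields deterministically is not possible
    # from truth tables alone, so subtype shifts are redrawn per subtype on
    # fresh gene sets -- validation non-UIP heterogeneity need not coincide
    # with training subtype signatures (it does not in the clinic either)
    sub_names = [s.name for s in cfg.nonuip_subtypes]
    sub_w = np.array([s.weight for s in cfg.nonuip_subtypes])
    per_subtype = max(5, int(round(0.02 * m)))
    subtype_shift = {}
    for sub in cfg.nonuip_subtypes:
        idx = rng.choice(m, size=per_subtype, replace=False)
        shift = np.zeros(m)
        shift[idx] = rng.normal(0.0, sub.shift_sd, size=per_subtype)
        subtype_shift[sub.name] = shift

    patients = [f"T{i:03d}" for i in range(n_patients)]
    is_uip = rng.random(n_patients) < frac_uip
    subtype_of = np.where(is_uip, "UIP", rng.choice(sub_names, size=n_patients, p=sub_w))
    lo, hi = cfg.samples_per_patient_range
    n_tbb = rng.integers(lo, hi + 1, size=n_patients)

    latents = np.empty((m, n_patients))
    for p in range(n_patients):
        mean = baseline.copy()
        if is_uip[p]:
            mean += class_effect
        else:
            mean += subtype_shift[subtype_of[p]]
        comps = []
        for _ in range(int(n_tbb[p])):
            b = mean + rng.normal(0.0, cfg.lobe_effect_sd, size=m)
            q = np.exp2(b)
            comps.append(q / q.sum())
        latents[:, p] = np.mean(comps, axis=0)

    n_batches = max(2, n_patients // 16)
    batch_codes = (np.arange(n_patients) * n_batches) // n_patients
    batch_effects = rng.normal(0.0, cfg.batch_sd, size=(m, n_batches))
    lib_sizes = rng.uniform(*cfg.library_size_range, size=n_patients)
    mu = latents * np.exp2(batch_effects[:, batch_codes])
    mu = mu / mu.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    K = _nb_counts(rng, mu, alpha_t, alpha_e)

    ids = [f"POOL_{p}" for p in patients]
    counts = CountMatrix(pd.DataFrame(K, index=cohort.counts.genes, columns=ids))
    sample_meta = pd.DataFrame(
        {
            "patient": patients,
            "lobe": "pooled",
            "batch": [f"val_batch_{b:02d}" for b in batch_codes],
            "role": "pool",
            "diagnostic": True,
        },
        index=pd.Index(ids, name="sample"),
    )
    lobe_rows = []
    for p, pid in enumerate(patients):
        if is_uip[p]:
            lobe_rows += [(pid, "upper", str(rng.choice(UIP_SUBTYPES))),
                          (pid, "lower", str(rng.choice(UIP_SUBTYPES)))]
        else:
            lobe_rows += [(pid, "upper", subtype_of[p]), (pid, "lower", subtype_of[p])]
    lobe_diagnoses = pd.DataFrame(lobe_rows, columns=["patient", "lobe", "diagnosis"])
    labels = [
        assign_patient_label(
            lobe_diagnoses.loc[lobe_diagnoses["patient"] == pid, "diagnosis"].tolist()
        )
        for pid in patients
    ]
    patient_truth = pd.DataFrame(
        {
            "true_class": np.where(is_uip, "UIP", "non-UIP"),
            "subtype": subtype_of,
            "discordant": False,
            "label": labels,
        },
        index=pd.Index(patients, name="patient"),
    )
    return SimulatedCohort(
        counts=counts,
        sample_meta=sample_meta,
        lobe_diagnoses=lobe_diagnoses,
        gene_truth=cohort.gene_truth.copy(),
        patient_truth=patient_truth,
        config=cfg,
        bio_log2=pd.DataFrame(np.log2(latents), index=cohort.counts.genes, columns=ids),
    )
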