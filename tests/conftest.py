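"""Shared fixtures: a small synthetic cohort and its derived artifacts.

All fixtures are generated programmatically and seeded, so the suite is
fully deterministic and needs no stored data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import uipseq as u
from uipseq.filtering import GeneSet


@pytest.fixture(scope="session")
def small_cohort() -> u.SimulatedCohort:
    cfg = u.CohortConfig(n_patients=24, n_genes=300, seed=7)
    cohort = u.generate_cohort(cfg)
    cohort = u.generate_sentinels(cohort, n_sentinels=4, n_batches=4, seed=8)
    pids = list(cohort.labeled_patients()[:6])
    return u.generate_invitro_pools(cohort, pids, seed=9)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Frozen normalization, filters, expression and noise model for the
    small cohort, computed once."""
    c = small_cohort
    bio = c.counts.subset_samples(list(c.biopsy_samples()))
    frozen = u.FrozenNormalization.fit(bio)
    universe = GeneSet(list(c.counts.genes), "universe")
    g_ann = u.filter_by_annotation(universe, c.annotation)
    g_expr = u.filter_low_expression(bio, g_ann)
    expr_all = u.apply_vst(c.counts, frozen)
    sent = c.sample_meta.index[c.sample_meta["role"] == "sentinel"]
    sent_meta = pd.DataFrame(
        {
            "source": c.sample_meta.loc[sent, "patient"],
            "batch": c.sample_meta.loc[sent, "batch"],
        }
    )
    models = u.fit_gene_batch_model(expr_all[sent].loc[list(g_expr)], sent_meta)
    g_final = u.filter_batch_sensitive(models, g_expr)
    labels = c.sample_labels(list(c.biopsy_samples()))
    pm = c.sample_meta.loc[labels.index, "patient"]
    expr = expr_all.loc[list(g_final), labels.index]
    noise = u.NoiseModel(
        tau=models.technical_sd().reindex(expr.index), n_replicates=25, seed=5
    )
    return {
        "cohort": c,
        "bio": bio,
        "frozen": frozen,
        "universe": universe,
        "genes_annotation": g_ann,
        "genes_expression": g_expr,
        "genes_final": g_final,
        "batch_models": models,
        "sentinel_meta": sent_meta,
        "expr_all": expr_all,
        "expr": expr,
        "labels": labels,
        "patient_map": pm,
        "noise": noise,
    }


@pytest.fixture(scope="session")
def small_cv(small_pipeline):
    """A fixed-hyperparameter LOPO run on the small cohort."""
    p = small_pipeline
    cv = u.run_lopo(
        p["expr"],
        p["bio"],
        p["labels"],
        p["patient_map"],
        p["frozen"],
        p["noise"],
        hyper=(0.02, 0.5),
        seed=17,
    )
    return cv


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
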