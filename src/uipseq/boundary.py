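"""Prospective decision-boundary selection and score thresholding.

The boundary is locked from replicated in-silico patient-level LOPO CV
scores before any test data is seen.  A grid of candidate thresholds is
evaluated by averaging sensitivity and specificity over noise replicates
(per-patient call probability first, then an unweighted mean across
patients, so duplicating a patient's replicate set changes nothing); the
admissible set requires mean specificity strictly above ``spec_min`` and
mean sensitivity at or above ``sens_floor``, and the selected boundary
maximizes specificity, then sensitivity, then takes the smallest
candidate.  Calls use the strict rule: score above the boundary is UIP,
at-or-below is non-UIP.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np
import pandas as pd


class BoundaryError(ValueError):
    pass


@dataclasses.dataclass
class BoundarySelection:
    """A locked boundary plus the full candidate table that produced it."""

    boundary: float
    table: pd.DataFrame  # boundary, sensitivity, specificity, admissible
    criteria_met: bool
    spec_min: float
    sens_floor: float
    grid_step: float

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "boundary": self.boundary,
                    "criteria_met": self.criteria_met,
                    "spec_min": self.spec_min,
                    "sens_floor": self.sens_floor,
                    "grid_step": self.grid_step,
                    "candidates": self.table.to_dict(orient="list"),
                },
                fh,
            )


def _replicate_matrix(replicate_scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Normalize input to (per-patient list of replicate score arrays, labels)."""
    if isinstance(replicate_scores, pd.DataFrame) and {
        "patient",
        "replicate",
        "score",
    } <= set(replicate_scores.columns):
        groups = {
            p: g["score"].to_numpy() for p, g in replicate_scores.groupby("patient")
        }
    elif isinstance(replicate_scores, pd.DataFrame):
        groups = {p: replicate_scores.loc[p].to_numpy() for p in replicate_scores.index}
    else:
        raise BoundaryError("replicate_scores must be a long or wide DataFrame")
    lab = pd.Series(labels)
    missing = [p for p in groups if p not in lab.index]
    if missing:
        raise BoundaryError(f"labels missing for patients: {missing[:5]}")
    patients = sorted(groups)
    return [groups[p] for p in patients], lab.loc[patients].to_numpy().astype(int)


def select_boundary(
    replicate_scores,
    labels,
    spec_min: float = 0.90,
    sens_floor: float = 0.65,
    grid_step: float = 0.01,
    tie_tol: float = 0.0,
) -> BoundarySelection:
    """Choose the decision boundary from per-patient replicate scores.

    ``replicate_scores`` is either a long DataFrame (patient, replicate,
    score) or a wide patients-x-replicates matrix; ``labels`` maps patient
    -> binary (1 = UIP).  When no candidate satisfies both criteria, the
    maximizer of specificity subject to the sensitivity floor is returned
    with ``criteria_met=False``.
    """
    scores_list, y = _replicate_matrix(replicate_scores, labels)
    if len(scores_list) == 0 or sum(len(s) for s in scores_list) == 0:
        raise BoundaryError("empty replicate scores")
    if len(np.unique(y)) < 2:
        raise BoundaryError("both classes required to select a boundary")

    all_scores = np.concatenate(scores_list)
    lo, hi = all_scores.min() - grid_step, all_scores.max() + grid_step
    n_steps = int(np.floor((hi - lo) / grid_step + 1e-9)) + 1
    grid = lo + grid_step * np.arange(n_steps)

    # per-patient call probability P(score > b), then unweighted patient mean
    call_prob = np.vstack([
        (s[:, None] > grid[None, :]).mean(axis=0) for s in scores_list
    ])  # patients x grid
    uip = y == 1
    sens = call_prob[uip].mean(axis=0)
    spec = 1.0 - call_prob[~uip].mean(axis=0)

    table = pd.DataFrame({"boundary": grid, "sensitivity": sens, "specificity": spec})
    admissible = (spec > spec_min) & (sens >= sens_floor)
    table["admissible"] = admissible

    def _pick(mask: np.ndarray) -> float:
        cand = table[mask]
        best_spec = cand["specificity"].max()
        cand = cand[cand["specificity"] >= best_spec - tie_tol]
        best_sens = cand["sensitivity"].max()
        cand = cand[cand["sensitivity"] >= best_sens - tie_tol]
        return float(cand["boundary"].min())

    if admissible.any():
        boundary = _pick(admissible)
        met = True
    else:
        fallback = (sens >= sens_floor)
        boundary = _pick(fallback if fallback.any() else np.ones_like(admissible, dtype=bool))
        met = False
    return BoundarySelection(
        boundary=boundary,
        table=table,
        criteria_met=met,
        spec_min=spec_min,
        sens_floor=sens_floor,
        grid_step=grid_step,
    )


def classify(scores, boundary: float) -> pd.Series:
    """Call UIP iff score > boundary; scores equal to or below the boundary
    are called non-UIP."""
    if not np.isfinite(boundary):
        raise BoundaryError("boundary must be finite")
    s = pd.Series(scores)
    return pd.Series(
        np.where(s.to_numpy() > boundary, "UIP", "non-UIP"), index=s.index, name="call"
    )
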