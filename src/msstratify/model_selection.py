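"""Cross-validated choice of the subtype count and fold-to-fold similarity.

The number of subtypes C is chosen by subject-level K-fold cross-validation:
for each fold the model hierarchy (C = 1..max) is refit on the training
subjects and the mixture log-likelihood of the held-out subjects is
recorded, per-subject normalized so folds of slightly different size are
comparable.  The C maximizing the mean held-out log-likelihood wins.

Consistency of each subtype's progression pattern across folds (CVS) is the
mean, over events, of the Bhattacharyya coefficient between the event's
positional distribution in the fold model and in the full model, after
matching fold subtypes to full-model subtypes by optimal assignment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.model_selection import KFold

from .sustain import (
    EventGrid,
    PositionalVarianceDiagram,
    SuStaInModel,
    fit_sustain,
    mixture_log_likelihood,
)


def bhattacharyya_coefficient(p: np.ndarray, q: np.ndarray) -> float:
    """BC(p, q) = sum_k sqrt(p_k q_k); 1 iff p = q, 0 for disjoint supports."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("distributions must each sum to 1")
    return float(np.sqrt(p * q).sum())


@dataclasses.dataclass
class CVResult:
    """Held-out log-likelihood per subtype count and the chosen C."""

    table: pd.DataFrame          # columns: C, mean_heldout_ll, sd_heldout_ll
    per_fold: pd.DataFrame       # columns: fold, C, heldout_ll_per_subject
    chosen_C: int
    fold_subjects: list[np.ndarray]
    fold_models: list[list[SuStaInModel]]
    seed: int


def cross_validate(
    X: np.ndarray,
    grid: EventGrid,
    sigma=1.0,
    max_subtypes: int = 4,
    folds: int = 10,
    seed: int = 0,
    n_startpoints: int = 25,
    n_split_tries: int = 3,
) -> CVResult:
    """Subject-level K-fold CV of the subtype hierarchy.

    Folds partition the subjects; each subject is held out exactly once and
    the held-out mixture log-likelihood is never computed on subjects seen
    in training (asserted by bookkeeping).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    if folds > n:
        raise ValueError("more folds than subjects")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    records = []
    fold_subjects: list[np.ndarray] = []
    fold_models: list[list[SuStaInModel]] = []
    seen = np.zeros(n, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
        assert not set(train_idx) & set(test_idx)
        seen[test_idx] += 1
        fold_subjects.append(test_idx)
        models = fit_sustain(
            X[train_idx], grid, sigma, max_subtypes=max_subtypes,
            n_startpoints=n_startpoints, seed=seed * 1000 + fold,
            n_split_tries=n_split_tries,
        )
        fold_models.append(models)
        for m in models:
            ll, _ = mixture_log_likelihood(X[test_idx], m.sequences, m.fractions, grid, m.sigma)
            records.append({"fold": fold, "C": m.n_subtypes, "heldout_ll_per_subject": ll / len(test_idx)})
    assert np.all(seen == 1), "each subject must be held out exactly once"
    per_fold = pd.DataFrame(records)
    table = (
        per_fold.groupby("C")["heldout_ll_per_subject"]
        .agg(mean_heldout_ll="mean", sd_heldout_ll="std")
        .reset_index()
    )
    chosen = int(table.loc[table["mean_heldout_ll"].idxmax(), "C"])
    return CVResult(table, per_fold, chosen, fold_subjects, fold_models, seed)


def match_subtypes(fold_pvd: PositionalVarianceDiagram, full_pvd: PositionalVarianceDiagram) -> np.ndarray:
    """Optimal one-to-one matching of fold subtypes to full-model subtypes by
    total event-wise Bhattacharyya similarity.  Returns ``match`` with
    ``match[c_full] = c_fold``."""
    C = len(full_pvd.matrices)
    if len(fold_pvd.matrices) != C:
        raise ValueError("fold and full models must have the same subtype count")
    sim = np.zeros((C, C))
    for cf in range(C):
        for cg in range(C):
            sim[cf, cg] = sum(
                bhattacharyya_coefficient(fold_pvd.matrices[cf][e], full_pvd.matrices[cg][e])
                for e in range(fold_pvd.grid.n_events)
            )
    row, col = linear_sum_assignment(-sim)
    match = np.empty(C, dtype=int)
    match[col] = row
    return match


def cross_validation_similarity(
    full_pvd: PositionalVarianceDiagram,
    fold_pvds: list[PositionalVarianceDiagram],
) -> pd.DataFrame:
    """CVS per subtype: mean over events of the Bhattacharyya coefficient
    between fold and full positional distributions, averaged over folds
    (mean and SD reported)."""
    grid = full_pvd.grid
    for fp in fold_pvds:
        if fp.grid.biomarkers != grid.biomarkers or fp.grid.levels != grid.levels:
            raise ValueError("fold PVDs must share the full model's event grid")
    C = len(full_pvd.matrices)
    per_fold = np.zeros((len(fold_pvds), C))
    for i, fp in enumerate(fold_pvds):
        match = match_subtypes(fp, full_pvd)
        for c in range(C):
            bcs = [
                bhattacharyya_coefficient(fp.matrices[match[c]][e], full_pvd.matrices[c][e])
                for e in range(grid.n_events)
            ]
            per_fold[i, c] = float(np.mean(bcs))
    return pd.DataFrame(
        {
            "subtype": np.arange(C),
            "cvs_mean": per_fold.mean(axis=0),
            "cvs_sd": per_fold.std(axis=0, ddof=1) if len(fold_pvds) > 1 else np.zeros(C),
        }
    )
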