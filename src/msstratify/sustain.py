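"""z-score event-based subtype-and-stage inference (SuStaIn-style).

The model describes disease progression as an ordered sequence of *events*,
each event being one biomarker crossing a fixed abnormality level (z = 1, 2
or 3 relative to a reference population).  A subject at stage ``k`` has
passed the first ``k`` events of their subtype's sequence.  Between events a
biomarker's expected z-score evolves piecewise-linearly: anchored at 0 at
stage 0, at each of its event levels at the event's position, and at
``z_max`` at the final stage.  Observed z-scores are the expected trajectory
value plus Gaussian noise, and the stage is marginalized with a uniform
prior, giving a mixture likelihood over subtypes and stages.

Fitting is hierarchical: the single-subtype maximum-likelihood sequence is
found by greedy event reinsertion from random restarts; ``C``-subtype models
are initialized by splitting clusters of the ``(C-1)``-subtype solution and
refined by alternating sequence/mixture-fraction optimization.  Positional
uncertainty is summarized by Metropolis-Hastings sampling over sequences
(positional variance diagrams).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data_model import BiomarkerTable

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# event grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EventGrid:
    """Discrete z-score events: which abnormality levels each biomarker can reach.

    ``levels[i]`` is the ascending tuple of retained z-levels (subset of
    {1, 2, 3}) for ``biomarkers[i]``; ``z_max[i]`` is the trajectory ceiling
    (must exceed the last retained level).
    """

    biomarkers: tuple[str, ...]
    levels: tuple[tuple[float, ...], ...]
    z_max: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.biomarkers) or len(self.z_max) != len(self.biomarkers):
            raise ValueError("levels and z_max must align with biomarkers")
        for b, lv, zm in zip(self.biomarkers, self.levels, self.z_max):
            if not lv:
                raise ValueError(f"biomarker {b!r} has no retained levels")
            if list(lv) != sorted(set(lv)):
                raise ValueError(f"levels for {b!r} must be strictly ascending")
            if not set(lv) <= {1.0, 2.0, 3.0}:
                raise ValueError(f"levels for {b!r} must be drawn from {{1,2,3}}")
            if not zm > lv[-1]:
                raise ValueError(f"z_max for {b!r} must exceed its last level")

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def n_events(self) -> int:
        return sum(len(lv) for lv in self.levels)

    @property
    def events(self) -> list[tuple[int, float]]:
        """Events as (biomarker index, z-level), grouped by biomarker,
        ascending level — the canonical event indexing."""
        return [(bi, z) for bi, lv in enumerate(self.levels) for z in lv]

    def event_indices_of(self, bi: int) -> np.ndarray:
        """Indices (into :attr:`events`) of biomarker ``bi``'s events, ascending level."""
        offset = sum(len(lv) for lv in self.levels[:bi])
        return np.arange(offset, offset + len(self.levels[bi]))

    def event_labels(self) -> list[str]:
        return [f"{self.biomarkers[bi]}:z{z:g}" for bi, z in self.events]


def build_event_grid(
    z_table: BiomarkerTable,
    levels: Sequence[float] = (1.0, 2.0, 3.0),
    min_fraction: float = 0.05,
    z_max_default: float = 5.0,
) -> EventGrid:
    """Retain level ``z`` for a biomarker iff at least ``min_fraction`` of
    baseline subjects reach ``z_i >= z``; drop (with a warning) biomarkers
    with no retained level.
    """
    if z_table.scale != "zscore":
        raise ValueError("event grid must be built from a z-scored table")
    base = z_table.baseline()
    names, kept_levels, z_maxes = [], [], []
    for b in base.biomarkers:
        x = base.df[b].dropna().to_numpy(float)
        kept = tuple(z for z in sorted(levels) if np.mean(x >= z) >= min_fraction)
        if not kept:
            warnings.warn(f"biomarker {b!r}: no z-level reached by >= {min_fraction:.0%} of subjects; dropped")
            continue
        names.append(b)
        kept_levels.append(kept)
        z_maxes.append(max(z_max_default, kept[-1] + 1.0))
    if not names:
        raise ValueError("empty event grid: no biomarker retains any z-level")
    return EventGrid(tuple(names), tuple(kept_levels), tuple(z_maxes))


# ---------------------------------------------------------------------------
# sequences and trajectories
# ---------------------------------------------------------------------------

def is_valid_sequence(seq: np.ndarray, grid: EventGrid) -> bool:
    """A sequence is a permutation of all events in which each biomarker's
    levels appear in ascending order of position."""
    seq = np.asarray(seq)
    n = grid.n_events
    if seq.shape != (n,) or not np.array_equal(np.sort(seq), np.arange(n)):
        return False
    pos = np.empty(n, dtype=int)
    pos[seq] = np.arange(n)
    for bi in range(grid.n_biomarkers):
        idx = grid.event_indices_of(bi)
        if np.any(np.diff(pos[idx]) < 0):
            return False
    return True


def random_valid_sequence(grid: EventGrid, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over valid sequences: permute events, then reassign each
    biomarker's events to its own slots in ascending-level order."""
    n = grid.n_events
    perm = rng.permutation(n)
    pos = np.empty(n, dtype=int)
    pos[perm] = np.arange(n)
    seq = np.empty(n, dtype=int)
    for bi in range(grid.n_biomarkers):
        idx = grid.event_indices_of(bi)
        slots = np.sort(pos[idx])
        seq[slots] = idx
    return seq


def event_positions(seq: np.ndarray) -> np.ndarray:
    """1-based position of each event in the sequence."""
    pos = np.empty(len(seq), dtype=int)
    pos[np.asarray(seq)] = np.arange(1, len(seq) + 1)
    return pos


def expected_matrix(seq: np.ndarray, grid: EventGrid) -> np.ndarray:
    """Expected z per (biomarker, stage): shape (n_biomarkers, N+1).

    Piecewise linear through (0, 0), (position of each event, its level) and
    (N, z_max); if a biomarker's last event sits at position N the event
    anchor takes precedence over the ceiling anchor.
    """
    n = grid.n_events
    pos = event_positions(seq)
    stages = np.arange(n + 1, dtype=float)
    E = np.empty((grid.n_biomarkers, n + 1))
    for bi in range(grid.n_biomarkers):
        idx = grid.event_indices_of(bi)
        xs = [0.0] + [float(p) for p in pos[idx]] + [float(n)]
        ys = [0.0] + list(grid.levels[bi]) + [grid.z_max[bi]]
        if xs[-2] == xs[-1]:  # last event at final stage: keep the event anchor
            xs, ys = xs[:-1], ys[:-1]
        E[bi] = np.interp(stages, xs, ys)
    return E


def expected_value(seq: np.ndarray, grid: EventGrid, biomarker: str, stage: int) -> float:
    """Expected z-score of ``biomarker`` at integer ``stage`` (0..N)."""
    if not (0 <= stage <= grid.n_events):
        raise ValueError(f"stage must lie in 0..{grid.n_events}")
    bi = grid.biomarkers.index(biomarker)
    return float(expected_matrix(seq, grid)[bi, int(stage)])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _as_sigma(sigma, grid: EventGrid) -> np.ndarray:
    s = np.asarray(sigma, dtype=float)
    if s.ndim == 0:
        s = np.full(grid.n_biomarkers, float(s))
    if s.shape != (grid.n_biomarkers,):
        raise ValueError("sigma must be scalar or one value per biomarker")
    if np.any(s <= 0):
        raise ValueError("sigma must be > 0")
    return s


def stage_loglik_matrix(X: np.ndarray, seq: np.ndarray, grid: EventGrid, sigma) -> np.ndarray:
    """Per-subject, per-stage log-likelihood, shape (n, N+1).

    Each entry is the log product over *observed* biomarkers of the normal
    density of z around the stage's expected profile; missing (NaN) values
    contribute a factor of one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    s = _as_sigma(sigma, grid)
    E = expected_matrix(seq, grid)  # (B, N+1)
    obs = ~np.isnan(X)
    Xf = np.where(obs, X, 0.0)
    resid = (Xf[:, :, None] - E[None, :, :]) / s[None, :, None]
    ll = -0.5 * resid**2 - (np.log(s) + _LOG_SQRT_2PI)[None, :, None]
    ll = np.where(obs[:, :, None], ll, 0.0)
    return ll.sum(axis=1)


def stage_likelihoods(z: np.ndarray, seq: np.ndarray, grid: EventGrid, sigma) -> np.ndarray:
    """Likelihood of one z-vector at each stage 0..N (length N+1)."""
    return np.exp(stage_loglik_matrix(np.atleast_2d(z), seq, grid, sigma)[0])


def sequence_log_likelihood(X: np.ndarray, seq: np.ndarray, grid: EventGrid, sigma) -> float:
    """Data log-likelihood under one sequence with a uniform stage prior:
    sum_j log( (1/(N+1)) sum_k L_jk )."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.any(np.isinf(X)):
        raise ValueError("non-finite biomarker values")
    ll = stage_loglik_matrix(X, seq, grid, sigma)
    return float(np.sum(logsumexp(ll, axis=1) - np.log(grid.n_events + 1)))


def _subject_logliks(X, seqs, grid, sigma) -> np.ndarray:
    """Per-subject marginal log-likelihood under each subtype: (n, C)."""
    out = [logsumexp(stage_loglik_matrix(X, s, grid, sigma), axis=1) - np.log(grid.n_events + 1) for s in seqs]
    return np.stack(out, axis=1)


def mixture_log_likelihood(X, seqs, fractions, grid, sigma) -> tuple[float, np.ndarray]:
    """Total mixture log-likelihood and per-subject subtype responsibilities."""
    lls = _subject_logliks(X, seqs, grid, sigma)
    lw = lls + np.log(np.asarray(fractions))[None, :]
    tot = logsumexp(lw, axis=1)
    resp = np.exp(lw - tot[:, None])
    return float(tot.sum()), resp


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _greedy_optimize(X, seq, grid, sigma, max_passes: int = 50) -> tuple[np.ndarray, float]:
    """Greedy single-event reinsertion to a fixed point.

    One pass removes each event in turn and re-inserts it at the valid
    position maximizing the sequence log-likelihood (ties: lowest position).
    """
    seq = np.array(seq, dtype=int)
    n = grid.n_events
    best_ll = sequence_log_likelihood(X, seq, grid, sigma)
    for _ in range(max_passes):
        improved = False
        for ev in range(n):
            cur = int(np.where(seq == ev)[0][0])
            reduced = np.delete(seq, cur)
            bi = grid.events[ev][0]
            sibs = grid.event_indices_of(bi)
            rank = int(np.where(sibs == ev)[0][0])
            lo = 0 if rank == 0 else int(np.where(reduced == sibs[rank - 1])[0][0]) + 1
            hi = n - 1 if rank == len(sibs) - 1 else int(np.where(reduced == sibs[rank + 1])[0][0])
            cand_ll = np.full(n, -np.inf)
            for p in range(lo, hi + 1):
                cand = np.insert(reduced, p, ev)
                cand_ll[p] = sequence_log_likelihood(X, cand, grid, sigma)
            p_best = int(np.argmax(cand_ll))
            if cand_ll[p_best] > best_ll + 1e-12:
                seq = np.insert(reduced, p_best, ev)
                best_ll = cand_ll[p_best]
                improved = True
        if not improved:
            break
    return seq, best_ll


def fit_single_subtype(
    X: np.ndarray,
    grid: EventGrid,
    sigma=1.0,
    n_startpoints: int = 25,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood sequence over ``n_startpoints`` random restarts of
    greedy reinsertion.  Deterministic given the seed."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(X) > 1 and np.all(np.nanstd(X, axis=0) < 1e-12):
        warnings.warn("degenerate data: all subjects identical; sequence is arbitrary among optima")
    best_seq, best_ll = None, -np.inf
    for _ in range(max(1, n_startpoints)):
        start = random_valid_sequence(grid, rng)
        seq, ll = _greedy_optimize(X, start, grid, sigma)
        if ll > best_ll:
            best_seq, best_ll = seq, ll
    return best_seq, best_ll


@dataclasses.dataclass
class SuStaInModel:
    """A fitted C-subtype model: sequences, mixture fractions, noise scale."""

    grid: EventGrid
    sequences: list[np.ndarray]
    fractions: np.ndarray
    sigma: np.ndarray
    log_likelihood: float
    seed: int | None = None
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    mcmc_samples: list[np.ndarray] | None = None  # per subtype: (n_samples, N)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if not np.isclose(self.fractions.sum(), 1.0) or np.any(self.fractions < 0):
            raise ValueError("fractions must be a simplex vector")
        for s in self.sequences:
            if not is_valid_sequence(s, self.grid):
                raise ValueError("invalid subtype sequence")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)


def _refit_fractions_sequences(X, seqs, fractions, grid, sigma, max_iter=100, tol=1e-6):
    """Alternating optimization: soft fraction update, hard-assigned greedy
    sequence refits; stops when the total log-likelihood gain falls below tol."""
    seqs = [np.array(s) for s in seqs]
    fractions = np.asarray(fractions, dtype=float)
    ll_old, resp = mixture_log_likelihood(X, seqs, fractions, grid, sigma)
    for _ in range(max_iter):
        fractions = np.clip(resp.mean(axis=0), 1e-9, None)
        fractions = fractions / fractions.sum()
        hard = np.argmax(resp, axis=1)
        for c in range(len(seqs)):
            sub = X[hard == c]
            if len(sub):
                seqs[c], _ = _greedy_optimize(sub, seqs[c], grid, sigma)
        ll_new, resp = mixture_log_likelihood(X, seqs, fractions, grid, sigma)
        if ll_new - ll_old < tol:
            ll_old = max(ll_new, ll_old)
            break
        ll_old = ll_new
    return seqs, fractions, ll_old


def _best_sequence(X, warm_start, grid, sigma, n_startpoints, rng):
    """Greedy fit from a warm start plus random restarts; best LL wins."""
    seq, ll = _greedy_optimize(X, warm_start, grid, sigma)
    seq_r, ll_r = fit_single_subtype(X, grid, sigma, n_startpoints=n_startpoints, seed=rng)
    return seq if ll >= ll_r else seq_r


def fit_sustain(
    X: np.ndarray,
    grid: EventGrid,
    sigma=1.0,
    max_subtypes: int = 4,
    n_startpoints: int = 25,
    seed: int = 0,
    n_split_tries: int = 3,
) -> list[SuStaInModel]:
    """Fit models with C = 1..max_subtypes hierarchically.

    The C-subtype model is seeded from the best (C-1) solution: each of its
    clusters (ML-assigned subjects) is randomly bipartitioned
    ``n_split_tries`` times, each half refit by greedy search, and the split
    whose refined model attains the highest likelihood is kept.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if max_subtypes > len(X):
        raise ValueError("more subtypes than subjects")
    rng = np.random.default_rng(seed)
    s = _as_sigma(sigma, grid)

    seq1, ll1 = fit_single_subtype(X, grid, s, n_startpoints=n_startpoints, seed=rng)
    models = [
        SuStaInModel(grid, [seq1], np.array([1.0]), s, ll1, seed=seed,
                     hyperparameters={"n_startpoints": n_startpoints, "C": 1})
    ]
    for C in range(2, max_subtypes + 1):
        prev = models[-1]
        _, resp = mixture_log_likelihood(X, prev.sequences, prev.fractions, grid, s)
        hard = np.argmax(resp, axis=1)
        best = None
        for c_split in range(prev.n_subtypes):
            members = np.where(hard == c_split)[0]
            if len(members) < 2:
                continue
            for _ in range(n_split_tries):
                mask = rng.random(len(members)) < 0.5
                if mask.all() or (~mask).all():
                    mask[rng.integers(len(mask))] = ~mask[rng.integers(len(mask))]
                half_a, half_b = members[mask], members[~mask]
                if not len(half_a) or not len(half_b):
                    continue
                # refit each half from the parent sequence and from random
                # restarts: mirrored subtypes make the parent a strong local
                # optimum that pure warm starts cannot escape
                n_half = max(2, n_startpoints // 2)
                seq_a = _best_sequence(X[half_a], prev.sequences[c_split], grid, s, n_half, rng)
                seq_b = _best_sequence(X[half_b], prev.sequences[c_split], grid, s, n_half, rng)
                seqs = [np.array(q) for i, q in enumerate(prev.sequences) if i != c_split] + [seq_a, seq_b]
                fracs = np.full(C, 1.0 / C)
                seqs, fracs, ll = _refit_fractions_sequences(X, seqs, fracs, grid, s)
                if best is None or ll > best[2]:
                    best = (seqs, fracs, ll)
        if best is None:
            break
        models.append(
            SuStaInModel(grid, best[0], best[1], s, best[2], seed=seed,
                         hyperparameters={"n_startpoints": n_startpoints, "C": C,
                                          "n_split_tries": n_split_tries})
        )
    return models


# ---------------------------------------------------------------------------
# MCMC positional uncertainty
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PositionalVarianceDiagram:
    """Per-subtype matrix of P(event occupies position); rows are events in
    the grid's canonical order, columns are positions 1..N."""

    grid: EventGrid
    matrices: list[np.ndarray]  # per subtype, (N, N), rows sum to 1

    def __post_init__(self) -> None:
        for m in self.matrices:
            if not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("PVD rows must sum to 1")
            if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
                raise ValueError("PVD entries must lie in [0,1]")


def pvd_from_samples(samples: np.ndarray, n_events: int) -> np.ndarray:
    """Empirical event-by-position frequencies from sampled sequences."""
    samples = np.atleast_2d(samples)
    mat = np.zeros((n_events, n_events))
    for seq in samples:
        mat[seq, np.arange(n_events)] += 1.0
    return mat / len(samples)


def mcmc_positional_uncertainty(
    X: np.ndarray,
    model: SuStaInModel,
    n_samples: int = 10_000,
    seed: int = 0,
    burn_in_fraction: float = 0.1,
) -> PositionalVarianceDiagram:
    """Metropolis-Hastings over subtype sequences with fractions held fixed.

    Proposal: pick a subtype and swap two of its event positions; proposals
    breaking a biomarker's within-level ordering are rejected outright (the
    chain stays put), keeping the kernel symmetric.  The first
    ``burn_in_fraction`` of the ``n_samples`` recorded states is discarded.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    grid, s = model.grid, model.sigma
    n = grid.n_events
    seqs = [np.array(q) for q in model.sequences]
    ll, _ = mixture_log_likelihood(X, seqs, model.fractions, grid, s)
    kept: list[list[np.ndarray]] = [[] for _ in seqs]
    for it in range(n_samples):
        c = int(rng.integers(len(seqs)))
        i, j = rng.integers(n), rng.integers(n)
        if i != j:
            cand = seqs[c].copy()
            cand[i], cand[j] = cand[j], cand[i]
            if is_valid_sequence(cand, grid):
                new_seqs = list(seqs)
                new_seqs[c] = cand
                ll_new, _ = mixture_log_likelihood(X, new_seqs, model.fractions, grid, s)
                if np.log(rng.random()) < ll_new - ll:
                    seqs, ll = new_seqs, ll_new
        for c2 in range(len(seqs)):
            kept[c2].append(seqs[c2].copy())
    burn = int(burn_in_fraction * n_samples)
    if burn >= n_samples:
        burn = n_samples - 1
    sample_arrays = [np.array(k[burn:]) for k in kept]
    model.mcmc_samples = sample_arrays
    return PositionalVarianceDiagram(grid, [pvd_from_samples(a, n) for a in sample_arrays])


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SubjectAssignment:
    """Probabilistic subtype and stage assignment for one z-vector."""

    subtype_posterior: np.ndarray
    ml_subtype: int
    subtype_probability: float
    stage_posterior: np.ndarray
    ml_stage: int
    expected_stage: float


def assign(model: SuStaInModel, z: np.ndarray) -> SubjectAssignment:
    """Posterior subtype (mixing fractions as prior, stage marginalized) and
    posterior stage conditional on the ML subtype."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty z-vector")
    grid = model.grid
    ll = np.stack([stage_loglik_matrix(z[None, :], s, grid, model.sigma)[0] for s in model.sequences])
    marg = logsumexp(ll, axis=1) - np.log(grid.n_events + 1)
    lw = marg + np.log(model.fractions)
    post = np.exp(lw - logsumexp(lw))
    ml_subtype = int(np.argmax(post))
    stage_ll = ll[ml_subtype]
    stage_post = np.exp(stage_ll - logsumexp(stage_ll))
    stages = np.arange(grid.n_events + 1)
    return SubjectAssignment(
        subtype_posterior=post,
        ml_subtype=ml_subtype,
        subtype_probability=float(post[ml_subtype]),
        stage_posterior=stage_post,
        ml_stage=int(np.argmax(stage_post)),
        expected_stage=float(stage_post @ stages),
    )


def assign_table(model: SuStaInModel, table: BiomarkerTable) -> "pd.DataFrame":
    """Per-visit assignments for every row of a z-scored table."""
    import pandas as pd

    if table.scale != "zscore":
        raise ValueError("assignment requires a z-scored table")
    X = table.values(list(model.grid.biomarkers))
    records = []
    meta = table.df[["subject_id", "visit_index", "years_from_baseline"]]
    for i in range(len(X)):
        a = assign(model, X[i])
        records.append(
            {
                "subject_id": meta.iloc[i, 0],
                "visit_index": int(meta.iloc[i, 1]),
                "years_from_baseline": float(meta.iloc[i, 2]),
                "ml_subtype": a.ml_subtype,
                "subtype_probability": a.subtype_probability,
                "ml_stage": a.ml_stage,
                "expected_stage": a.expected_stage,
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def label_subtypes(
    model: SuStaInModel,
    dgm_biomarkers: Sequence[str],
    cortical_biomarkers: Sequence[str],
    lesion_biomarker: str | None = None,
) -> dict[int, str]:
    """Name subtypes by atrophy pattern: the subtype whose deep-gray-matter
    events occupy the earliest mean positions is "DGM-first", the other
    "cortex-first"; single-subtype models get "undifferentiated"."""
    grid = model.grid
    for name in list(dgm_biomarkers) + list(cortical_biomarkers):
        if name not in grid.biomarkers:
            raise ValueError(f"biomarker {name!r} not in the event grid")
    if model.n_subtypes == 1:
        warnings.warn("single-subtype model: labelling as 'undifferentiated'")
        return {0: "undifferentiated"}

    def mean_dgm_position(seq) -> float:
        pos = event_positions(seq)
        idx = np.concatenate([grid.event_indices_of(grid.biomarkers.index(b)) for b in dgm_biomarkers])
        return float(np.mean(pos[idx]))

    scores = [mean_dgm_position(s) for s in model.sequences]
    order = np.argsort(scores, kind="mergesort")
    if model.n_subtypes == 2 and scores[0] == scores[1]:
        warnings.warn("DGM positions tied; breaking tie by lesion-event position")
        if lesion_biomarker is not None and lesion_biomarker in grid.biomarkers:
            li = grid.biomarkers.index(lesion_biomarker)
            lp = [float(np.mean(event_positions(s)[grid.event_indices_of(li)])) for s in model.sequences]
            order = np.argsort(lp, kind="mergesort")[::-1]  # later lesion accrual => DGM-first
    labels: dict[int, str] = {}
    for rank, c in enumerate(order):
        if rank == 0:
            labels[int(c)] = "DGM-first"
        elif rank == len(order) - 1:
            labels[int(c)] = "cortex-first"
        else:
            labels[int(c)] = f"intermediate-{rank}"
    return labels
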