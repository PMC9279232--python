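"""Longitudinal validation: subtype stability and stage-change dynamics.

Subtype stability across a subject's repeated visits is summarized with
Krippendorff's nominal alpha (units = subjects, values = per-visit subtype
labels), with a subject-resampling percentile bootstrap CI.  The rate of
stage change over follow-up time is estimated with a multilevel linear
model (random intercepts and slopes per subject, maximum likelihood), with
optional moderation of the time slope by baseline subtype or baseline stage
via interaction terms; a negative baseline-stage x time interaction is the
"plateau" signature (flatter slopes at higher baseline stages).  The same
machinery fits per-biomarker z-trajectories.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Krippendorff's alpha (nominal)
# ---------------------------------------------------------------------------

def _alpha_nominal(units: list[np.ndarray]) -> float:
    """Nominal-level alpha via the coincidence-matrix formulation.

    ``units`` holds each subject's observed labels; only subjects with >= 2
    labels contribute pairable values.  alpha = 1 - D_o/D_e with
    D_o = (1/n) sum_{c != k} o_ck and D_e = (1/(n(n-1))) sum_{c != k} n_c n_k.
    """
    pairable = [np.asarray(u) for u in units if len(u) >= 2]
    if not pairable:
        raise ValueError("alpha needs at least one unit with >= 2 values")
    values = sorted(set(np.concatenate(pairable).tolist()))
    vindex = {v: i for i, v in enumerate(values)}
    V = len(values)
    o = np.zeros((V, V))
    for u in pairable:
        m = len(u)
        counts = np.zeros(V)
        for lab in u:
            counts[vindex[lab]] += 1
        # ordered within-unit pairs, weighted 1/(m-1)
        pair = np.outer(counts, counts) - np.diag(counts)
        o += pair / (m - 1)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    if V < 2:
        raise ValueError("alpha is undefined with a single label overall (D_e = 0)")
    d_o = o.sum() - np.trace(o)
    d_e = (np.outer(n_c, n_c).sum() - (n_c * n_c).sum()) / (n - 1)
    return float(1.0 - d_o / d_e)


@dataclasses.dataclass
class StabilityResult:
    alpha: float
    ci_low: float
    ci_high: float
    n_subjects_included: int
    probability_threshold: float | None
    bootstrap_reps: int


def krippendorff_alpha_nominal(
    labels: pd.DataFrame,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    probability_threshold: float | None = None,
) -> StabilityResult:
    """Alpha over a long-format label table (columns ``subject_id``,
    ``label``), with a subject-resampling percentile bootstrap CI.

    The bootstrap resamples whole subjects (units) with replacement;
    degenerate resamples (a single label overall) are redrawn.
    """
    units = [grp["label"].to_numpy() for _, grp in labels.groupby("subject_id", sort=False)]
    alpha = _alpha_nominal(units)
    rng = np.random.default_rng(seed)
    boots = []
    attempts = 0
    while len(boots) < bootstrap_reps and attempts < bootstrap_reps * 10:
        attempts += 1
        idx = rng.integers(len(units), size=len(units))
        try:
            boots.append(_alpha_nominal([units[i] for i in idx]))
        except ValueError:
            continue
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    lo = min(float(lo), alpha)
    hi = max(float(hi), alpha)
    return StabilityResult(alpha, lo, hi, len(units), probability_threshold, bootstrap_reps)


def filter_by_assignment_probability(assignments: pd.DataFrame, threshold: float) -> np.ndarray:
    """Subjects whose *baseline* subtype assignment probability is >= threshold."""
    base = assignments[assignments["visit_index"] == 0]
    keep = base.loc[base["subtype_probability"] >= threshold, "subject_id"]
    return keep.to_numpy()


def subjects_retaining_subtype(assignments: pd.DataFrame) -> np.ndarray:
    """Subjects whose ML subtype is identical at every visit to baseline's."""
    stable = assignments.groupby("subject_id")["ml_subtype"].nunique() == 1
    return stable.index[stable].to_numpy()


# ---------------------------------------------------------------------------
# multilevel models
# ---------------------------------------------------------------------------

def _fit_lmm_ml(y, X, Z, group_codes):
    """Maximum-likelihood fit of a linear mixed model with one grouping
    factor and a 2-dimensional random effect (intercept + slope).

    y : (N,) outcome; X : (N, p) fixed-effects design; Z : (N, 2) random-
    effects design (ones and time); group_codes : (N,) integer subject ids.

    The marginal covariance per subject is V_i = Z_i G Z_i' + s2 I with
    G = L L' parameterized by its Cholesky factor (log-diagonals), and the
    fixed effects are profiled out by GLS inside each likelihood
    evaluation.  Subjects are bucketed by group size so all per-subject
    inverses run as batched LAPACK calls; this keeps a fit in the tens of
    milliseconds, which the replicate-heavy validation analyses need.

    Returns (beta, cov_beta, G, s2, loglik, converged).
    """
    from scipy.optimize import minimize as _minimize

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    codes = np.asarray(group_codes)
    order = np.argsort(codes, kind="mergesort")
    y, X, Z, codes = y[order], X[order], Z[order], codes[order]
    _, starts, counts = np.unique(codes, return_index=True, return_counts=True)
    p = X.shape[1]
    N = len(y)

    buckets = []  # (Xb, yb, Zb) stacked per group size
    for m in np.unique(counts):
        idx = starts[counts == m]
        rows = (idx[:, None] + np.arange(m)[None, :]).ravel()
        g = len(idx)
        buckets.append(
            (X[rows].reshape(g, m, p), y[rows].reshape(g, m), Z[rows].reshape(g, m, 2))
        )

    def components(theta):
        s2 = np.exp(theta[0])
        L = np.array([[np.exp(theta[1]), 0.0], [theta[2], np.exp(theta[3])]])
        G = L @ L.T
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for Xb, yb, Zb in buckets:
            m = yb.shape[1]
            V = Zb @ G @ np.swapaxes(Zb, 1, 2) + s2 * np.eye(m)[None]
            Vinv = np.linalg.inv(V)
            sign, ld = np.linalg.slogdet(V)
            logdet += float(ld.sum())
            VX = Vinv @ Xb
            xtvx += np.einsum("gmp,gmq->pq", Xb, VX)
            Vy = np.einsum("gmn,gn->gm", Vinv, yb)
            xtvy += np.einsum("gmp,gm->p", Xb, Vy)
            ytvy += float(np.einsum("gm,gm->", yb, Vy))
        return s2, G, xtvx, xtvy, ytvy, logdet

    def negll(theta):
        if not np.all(np.isfinite(theta)):
            return 1e12
        try:
            _, _, xtvx, xtvy, ytvy, logdet = components(theta)
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return 1e12
        rss = ytvy - beta @ xtvy
        ll = -0.5 * (N * np.log(2 * np.pi) + logdet + rss)
        return -ll if np.isfinite(ll) else 1e12

    # moment-based start: split the OLS residual variance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = max(float(np.var(y - X @ beta0)), 1e-8)
    theta0 = np.array([np.log(resid_var / 2), np.log(np.sqrt(resid_var / 2)), 0.0, np.log(0.1)])
    res = _minimize(negll, theta0, method="Nelder-Mead",
                    options={"maxiter": 1200, "xatol": 1e-6, "fatol": 1e-9})
    res2 = _minimize(negll, res.x, method="L-BFGS-B", options={"maxiter": 200})
    theta = res2.x if res2.fun <= res.fun else res.x
    s2, G, xtvx, xtvy, ytvy, logdet = components(theta)
    beta = np.linalg.solve(xtvx, xtvy)
    cov_beta = np.linalg.inv(xtvx)
    ll = -0.5 * (N * np.log(2 * np.pi) + logdet + (ytvy - beta @ xtvy))
    return beta, cov_beta, G, s2, float(ll), bool(res.success or res2.success)


@dataclasses.dataclass
class LongitudinalFit:
    """Fixed effects with Wald CIs/p-values plus variance components from a
    random-intercept + random-slope model."""

    fixed_effects: pd.DataFrame  # index: term; columns: b, se, ci_low, ci_high, p
    random_effects: dict        # intercept_var, slope_var, intercept_slope_cov
    residual_var: float
    n_subjects: int
    n_observations: int
    converged: bool
    outcome: str

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "b"])


def fit_stage_change(
    long_table: pd.DataFrame,
    outcome: str = "stage",
    time: str = "years_from_baseline",
    moderator: str | None = None,
    group: str = "subject_id",
) -> LongitudinalFit:
    """Multilevel linear model of ``outcome`` on follow-up time nested within
    subjects (random intercepts and slopes, ML).  With a ``moderator`` the
    main effect and moderator x time interaction are added and the
    interaction's Wald test quantifies slope moderation.
    """
    needed = [outcome, time] + ([moderator] if moderator else [])
    df = long_table.dropna(subset=needed).copy()
    if df[group].nunique() < 2:
        raise ValueError("multilevel model needs >= 2 subjects")
    exact = _exact_fit_if_deterministic(df, outcome, time, moderator, group)
    if exact is not None:
        return exact

    y = df[outcome].to_numpy(float)
    t = df[time].to_numpy(float)
    cols = {"Intercept": np.ones(len(df)), time: t}
    if moderator is not None:
        m = df[moderator].to_numpy(float)
        cols[moderator] = m
        cols[f"{time}:{moderator}"] = t * m
    X = np.column_stack(list(cols.values()))
    Z = np.column_stack([np.ones(len(df)), t])
    codes = pd.factorize(df[group])[0]

    beta, cov_beta, G, s2, ll, converged = _fit_lmm_ml(y, X, Z, codes)
    if not converged or not np.all(np.isfinite(beta)):
        raise RuntimeError(
            f"mixed model failed to converge (outcome {outcome!r}, "
            f"{df[group].nunique()} subjects, {len(df)} observations)"
        )
    from scipy.stats import norm

    se = np.sqrt(np.diag(cov_beta))
    zstat = beta / se
    fe = pd.DataFrame(
        {
            "b": beta,
            "se": se,
            "ci_low": beta - norm.ppf(0.975) * se,
            "ci_high": beta + norm.ppf(0.975) * se,
            "p": 2 * norm.sf(np.abs(zstat)),
        },
        index=list(cols.keys()),
    )
    re = {
        "intercept_var": float(G[0, 0]),
        "slope_var": float(G[1, 1]),
        "intercept_slope_cov": float(G[0, 1]),
    }
    return LongitudinalFit(
        fixed_effects=fe,
        random_effects=re,
        residual_var=float(s2),
        n_subjects=df[group].nunique(),
        n_observations=len(df),
        converged=converged,
        outcome=outcome,
    )


def _exact_fit_if_deterministic(df, outcome, time, moderator, group):
    """Degenerate (noise-free) data make the mixed likelihood singular: if a
    per-subject linear model reproduces the outcome exactly, report that
    exact solution (zero variances, point CIs) instead of a NaN fit."""
    intercepts, slopes, rss, n_obs = [], [], 0.0, 0
    for _, grp in df.groupby(group, sort=False):
        t = grp[time].to_numpy(float)
        y = grp[outcome].to_numpy(float)
        A = np.column_stack([np.ones(len(t)), t])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss += float(np.sum((y - A @ beta) ** 2))
        n_obs += len(y)
        intercepts.append(beta[0])
        slopes.append(beta[1])
    scale = max(1.0, float(np.var(df[outcome].to_numpy(float))))
    if rss / n_obs > 1e-16 * scale:
        return None
    intercepts, slopes = np.array(intercepts), np.array(slopes)
    n_subj = len(intercepts)
    terms = {"Intercept": float(np.mean(intercepts)), time: float(np.mean(slopes))}
    if moderator is not None:
        m = df.groupby(group)[moderator].first().to_numpy(float)
        A = np.column_stack([np.ones(n_subj), m])
        bi, *_ = np.linalg.lstsq(A, intercepts, rcond=None)
        bs, *_ = np.linalg.lstsq(A, slopes, rcond=None)
        terms = {
            "Intercept": float(bi[0]),
            time: float(bs[0]),
            moderator: float(bi[1]),
            f"{time}:{moderator}": float(bs[1]),
        }
    fe = pd.DataFrame(
        {
            "b": pd.Series(terms),
            "se": 0.0,
            "ci_low": pd.Series(terms),
            "ci_high": pd.Series(terms),
            "p": 0.0,
        }
    )
    return LongitudinalFit(
        fixed_effects=fe,
        random_effects={
            "intercept_var": float(np.var(intercepts)),
            "slope_var": float(np.var(slopes)),
            "intercept_slope_cov": float(np.cov(intercepts, slopes)[0, 1]) if n_subj > 1 else 0.0,
        },
        residual_var=0.0,
        n_subjects=n_subj,
        n_observations=n_obs,
        converged=True,
        outcome=outcome,
    )


def fit_biomarker_trajectories(
    z_visits: pd.DataFrame,
    biomarkers: list[str],
    assignments: pd.DataFrame | None = None,
    time: str = "years_from_baseline",
    moderator: str | None = None,
) -> dict[str, LongitudinalFit]:
    """One stage-change-style model per biomarker z-score (same machinery,
    the biomarker as outcome).  ``assignments`` (if given) contributes the
    moderator columns via a key join."""
    df = z_visits.copy()
    if assignments is not None:
        cols = ["subject_id", "visit_index", "ml_subtype", "ml_stage"]
        df = df.merge(assignments[cols], on=["subject_id", "visit_index"], how="left")
    fits = {}
    for b in biomarkers:
        fits[b] = fit_stage_change(df, outcome=b, time=time, moderator=moderator)
    return fits
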