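"""Clinical-outcome regressions with bootstrap confidence intervals.

Baseline disability (EDSS, ordinal 0-10 in 0.5 steps) and long-term
outcomes (motor and cognitive disability on 0-3 scales, transition to a
secondary-progressive course) are regressed on baseline subtype, stage,
their interaction, age and sex; longitudinal outcomes additionally adjust
for follow-up time and disease-modifying therapy (DMT).  Subtype is coded
0 = DGM-first, 1 = cortex-first; DMT 0 = no therapy, 1 = interferon,
2 = glatiramer acetate, 3 = natalizumab; SP course = 1, RR course = 0.

Ordinal outcomes use a proportional-odds (cumulative logit) model, binary
outcomes a logistic model.  Headline fits, Wald tests and pseudo-R² come
from statsmodels; percentile bootstrap CIs (default 5000 subject resamples)
refit the same likelihood with a warm-started L-BFGS maximizer so large
resample counts stay tractable.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

BASELINE_PREDICTORS = ("subtype", "stage", "subtype_x_stage", "age", "sex")
LONGTERM_PREDICTORS = BASELINE_PREDICTORS + ("fu_time", "dmt")

#: analysis-table column feeding each named outcome
OUTCOME_COLUMNS = {
    "baseline_edss": "baseline_edss",
    "lt_edss": "motor_disability_lt",
    "lt_bicams": "cognitive_disability_lt",
    "lt_sp": "sp_transition",
}


@dataclasses.dataclass
class OutcomeFit:
    """A fitted ordinal or logistic outcome model with bootstrap CIs."""

    family: str                 # "ordinal" | "logistic"
    outcome: str
    params: pd.DataFrame        # index: predictor; b, se, ci_low, ci_high, stat, p
    overall: dict               # llf, llnull, minus2ll, lr_stat, lr_p, mcfadden_r2, nagelkerke_r2
    n: int
    bootstrap_reps: int
    seed: int

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "b"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_outcome_design(
    analysis_table: pd.DataFrame,
    outcome_name: str,
    use_expected_stage: bool = False,
    include_baseline_edss: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor block and outcome vector for one named outcome.

    Baseline models use subtype, stage, subtype x stage, age and sex;
    long-term models add follow-up time and DMT code (and, optionally,
    baseline EDSS).  The interaction column is the elementwise product of
    the coded subtype and the stage.  Rows with a missing outcome or
    predictor are dropped.
    """
    if outcome_name not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome_name!r}; expected one of {sorted(OUTCOME_COLUMNS)}")
    col = OUTCOME_COLUMNS[outcome_name]
    for required in ("subtype_coded", "age_years", "sex", col):
        if required not in analysis_table.columns:
            raise ValueError(f"analysis table missing required column {required!r}")
    stage_col = "expected_stage" if use_expected_stage else "ml_stage"
    if stage_col not in analysis_table.columns:
        raise ValueError(f"analysis table missing stage column {stage_col!r}")

    df = analysis_table
    sex = df["sex"].map({"F": 0, "M": 1}) if df["sex"].dtype == object else df["sex"]
    design = pd.DataFrame(
        {
            "subtype": df["subtype_coded"].astype(float),
            "stage": df[stage_col].astype(float),
            "age": df["age_years"].astype(float),
            "sex": sex.astype(float),
        }
    )
    design["subtype_x_stage"] = design["subtype"] * design["stage"]
    if outcome_name != "baseline_edss":
        design["fu_time"] = df["fu_time_years"].astype(float)
        design["dmt"] = df["dmt_code"].astype(float)
        if include_baseline_edss:
            design["baseline_edss"] = df["baseline_edss"].astype(float)
        order = [p for p in LONGTERM_PREDICTORS] + (["baseline_edss"] if include_baseline_edss else [])
    else:
        order = list(BASELINE_PREDICTORS)
    design = design[order]
    outcome = pd.to_numeric(df[col], errors="coerce")
    keep = outcome.notna() & design.notna().all(axis=1)
    return design[keep].reset_index(drop=True), outcome[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# fast likelihood engines for the bootstrap loop
# ---------------------------------------------------------------------------

def _po_unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    beta = theta[:p]
    cuts = np.empty(len(theta) - p)
    cuts[0] = theta[p]
    if len(cuts) > 1:
        cuts[1:] = np.exp(theta[p + 1:])
    return beta, np.cumsum(cuts)


def _po_negll_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, n_cat: int):
    """Negative log-likelihood and gradient of the cumulative-logit model
    P(y <= j) = expit(tau_j - x beta), thresholds parameterized as
    (tau_0, log-increments) to stay ordered."""
    n, p = X.shape
    beta, tau = _po_unpack(theta, p)
    xb = X @ beta
    big = 1e3
    upper = np.where(y == n_cat - 1, big, tau[np.minimum(y, n_cat - 2)] - xb)
    lower = np.where(y == 0, -big, tau[np.maximum(y - 1, 0)] - xb)
    Fu, Fl = expit(upper), expit(lower)
    D = np.clip(Fu - Fl, 1e-300, None)
    negll = -np.sum(np.log(D))

    fu = Fu * (1.0 - Fu)
    fl = Fl * (1.0 - Fl)
    fu = np.where(y == n_cat - 1, 0.0, fu)
    fl = np.where(y == 0, 0.0, fl)
    w = (fu - fl) / D
    g_beta = X.T @ w  # d(-ll)/d beta = + sum x (fu-fl)/D

    g_tau = np.zeros(n_cat - 1)
    np.add.at(g_tau, np.minimum(y, n_cat - 2), np.where(y == n_cat - 1, 0.0, -fu / D))
    np.add.at(g_tau, np.maximum(y - 1, 0), np.where(y == 0, 0.0, fl / D))
    # chain rule to (tau_0, log-increments)
    g_theta_cuts = np.empty(n_cat - 1)
    rev = np.cumsum(g_tau[::-1])[::-1]
    g_theta_cuts[0] = rev[0]
    if n_cat > 2:
        g_theta_cuts[1:] = rev[1:] * np.exp(theta[p + 1:])
    return negll, np.concatenate([g_beta, g_theta_cuts])


def _fit_po(X: np.ndarray, y: np.ndarray, n_cat: int, start: np.ndarray) -> np.ndarray:
    # standardize columns so L-BFGS sees a well-conditioned problem
    p = X.shape[1]
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    start_s = start.copy()
    start_s[:p] = start[:p] * scale
    res = minimize(
        _po_negll_grad, start_s, args=(Xs, y, n_cat), jac=True,
        method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    out = res.x.copy()
    out[:p] = out[:p] / scale
    return out


def _logit_negll_grad(theta: np.ndarray, X1: np.ndarray, y: np.ndarray):
    mu = expit(X1 @ theta)
    eps = 1e-12
    negll = -np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
    return negll, X1.T @ (mu - y)


def _fit_logit(X1: np.ndarray, y: np.ndarray, start: np.ndarray) -> np.ndarray:
    res = minimize(
        _logit_negll_grad, start, args=(X1, y), jac=True,
        method="L-BFGS-B", options={"maxiter": 200, "ftol": 1e-10},
    )
    return res.x


def _nagelkerke(llf: float, llnull: float, n: int) -> float:
    cox_snell = 1.0 - np.exp((2.0 / n) * (llnull - llf))
    denom = 1.0 - np.exp((2.0 / n) * llnull)
    return float(cox_snell / denom) if denom > 0 else np.nan


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------

def ordinal_outcome_model(
    outcome: pd.Series,
    design: pd.DataFrame,
    bootstrap_reps: int = 5000,
    seed: int = 0,
) -> OutcomeFit:
    """Proportional-odds model of an ordinal outcome on the design block.

    Coefficients, Wald tests and pseudo-R² come from statsmodels'
    cumulative-logit fit; CIs are percentile bootstrap over subjects.
    Quasi-complete separation or non-convergence raises.
    """
    y_raw = np.asarray(outcome, dtype=float)
    X = design.to_numpy(dtype=float)
    cats = np.unique(y_raw)
    if len(cats) < 2:
        raise ValueError("ordinal outcome has fewer than 2 observed levels")
    y = np.searchsorted(cats, y_raw)
    n_cat = len(cats)

    endog = pd.Series(pd.Categorical(y, categories=np.arange(n_cat), ordered=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(endog, X, distr="logit")
        # warm start from the in-package maximizer (same likelihood)
        p0 = X.shape[1]
        rough = _fit_po(X, y, n_cat, np.concatenate([np.zeros(p0), [0.0], np.full(n_cat - 2, 0.0)]))
        res = model.fit(start_params=rough, method="bfgs", maxiter=500, disp=False)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(method="nm", maxiter=5000, disp=False)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("ordinal model failed to converge (possible separation)")
    # intercept-only cumulative-logit ML is the empirical distribution
    counts = np.bincount(y, minlength=n_cat).astype(float)
    llnull_ord = float(np.sum(counts * np.log(counts / counts.sum())))

    p = X.shape[1]
    beta = np.asarray(res.params)[:p]
    se = np.asarray(res.bse)[:p]
    stat = beta / se
    pvals = np.asarray(res.pvalues)[:p]

    start = _sm_po_start(res.params, p, n_cat)
    ci = _bootstrap_ci(
        lambda Xb, yb, st: _po_unpack(_fit_po(Xb, yb, n_cat, st), p)[0],
        X, y, start, p, bootstrap_reps, seed, stratify=y,
    )

    llf, llnull = float(res.llf), llnull_ord
    lr = 2.0 * (llf - llnull)
    from scipy.stats import chi2

    overall = {
        "llf": llf,
        "llnull": llnull,
        "minus2ll": -2.0 * llf,
        "lr_stat": lr,
        "lr_p": float(chi2.sf(lr, df=p)),
        "mcfadden_r2": float(1.0 - llf / llnull),
        "nagelkerke_r2": _nagelkerke(llf, llnull, len(y)),
    }
    params = pd.DataFrame(
        {"b": beta, "se": se, "ci_low": ci[0], "ci_high": ci[1], "stat": stat, "p": pvals},
        index=list(design.columns),
    )
    return OutcomeFit("ordinal", outcome.name or "outcome", params, overall, len(y), bootstrap_reps, seed)


def _sm_po_start(sm_params, p: int, n_cat: int) -> np.ndarray:
    """statsmodels OrderedModel already stores thresholds as
    (first cut, log-increments) after the betas — reuse directly."""
    return np.asarray(sm_params, dtype=float).copy()


def logistic_outcome_model(
    outcome: pd.Series,
    design: pd.DataFrame,
    bootstrap_reps: int = 5000,
    seed: int = 0,
) -> OutcomeFit:
    """Binary logistic model (e.g. SP transition, coded SP = 1, RR = 0) with
    Nagelkerke pseudo-R² and -2LL, percentile bootstrap CIs over subjects."""
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("binary outcome has no variation")
    X = design.to_numpy(dtype=float)
    X1 = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X1).fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logistic model failed to converge (possible separation)")

    p = X.shape[1]
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    start = beta.copy()
    ci = _bootstrap_ci(
        lambda Xb, yb, st: _fit_logit(sm.add_constant(Xb, has_constant="add"), yb, st),
        X, y, start, p + 1, bootstrap_reps, seed, stratify=y.astype(int),
    )
    llf, llnull = float(res.llf), float(res.llnull)
    lr = 2.0 * (llf - llnull)
    from scipy.stats import chi2

    overall = {
        "llf": llf,
        "llnull": llnull,
        "minus2ll": -2.0 * llf,
        "lr_stat": lr,
        "lr_p": float(chi2.sf(lr, df=p)),
        "mcfadden_r2": float(res.prsquared),
        "nagelkerke_r2": _nagelkerke(llf, llnull, len(y)),
    }
    params = pd.DataFrame(
        {
            "b": beta,
            "se": se,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "stat": beta / se,
            "p": np.asarray(res.pvalues),
        },
        index=["constant"] + list(design.columns),
    )
    return OutcomeFit("logistic", outcome.name or "outcome", params, overall, len(y), bootstrap_reps, seed)


def _bootstrap_ci(refit, X, y, start, n_out, reps, seed, stratify=None, level=0.95):
    """Percentile bootstrap over subjects (rows).  Resamples whose outcome
    collapses to a single level are redrawn."""
    rng = np.random.default_rng(seed)
    n = len(y)
    est = np.empty((reps, n_out))
    a = (1.0 - level) / 2.0
    for r in range(reps):
        for _ in range(100):
            idx = rng.integers(n, size=n)
            if len(np.unique(y[idx])) >= 2:
                break
        est[r] = refit(X[idx], y[idx], start)
    lo = np.percentile(est, 100 * a, axis=0)
    hi = np.percentile(est, 100 * (1 - a), axis=0)
    return lo, hi


def fit_outcome(
    analysis_table: pd.DataFrame,
    outcome_name: str,
    bootstrap_reps: int = 5000,
    seed: int = 0,
    **design_kwargs,
) -> OutcomeFit:
    """Build the named outcome's design and fit the appropriate family
    (logistic for SP transition, proportional odds otherwise)."""
    design, outcome = build_outcome_design(analysis_table, outcome_name, **design_kwargs)
    outcome = outcome.rename(outcome_name)
    if outcome_name == "lt_sp":
        return logistic_outcome_model(outcome, design, bootstrap_reps, seed)
    return ordinal_outcome_model(outcome, design, bootstrap_reps, seed)
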