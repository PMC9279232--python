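import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msstratify import (
    filter_by_assignment_probability,
    fit_biomarker_trajectories,
    fit_stage_change,
    krippendorff_alpha_nominal,
    subjects_retaining_subtype,
)
from msstratify.longitudinal import _alpha_nominal

from _oracles import kripp_alpha_oracle


def _labels(units: dict) -> pd.DataFrame:
    rows = [{"subject_id": sid, "label": lab} for sid, labs in units.items() for lab in labs]
    return pd.DataFrame(rows)


def test_alpha_one_on_perfect_agreement():
    res = krippendorff_alpha_nominal(_labels({"a": [0, 0, 0], "b": [1, 1], "c": [0, 0]}), bootstrap_reps=50, seed=0)
    assert res.alpha == pytest.approx(1.0)
    assert res.ci_low <= res.alpha <= res.ci_high


def test_alpha_matches_pairwise_oracle_on_small_tables():
    rng = np.random.default_rng(0)
    for _ in range(20):
        units = {f"s{i}": rng.integers(0, 3, size=rng.integers(1, 5)).tolist() for i in range(8)}
        flat = [u for u in units.values() if len(u) >= 2]
        if len(set(x for u in flat for x in u)) < 2:
            continue
        mine = _alpha_nominal([np.array(u) for u in units.values()])
        oracle = kripp_alpha_oracle(units.values())
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_alpha_example_two_subjects():
    # (1,1) and (1,2): alpha from the independent pairwise formula
    units = {"a": [1, 1], "b": [1, 2]}
    assert _alpha_nominal([np.array([1, 1]), np.array([1, 2])]) == pytest.approx(
        kripp_alpha_oracle(units.values()), abs=1e-12
    )


def test_alpha_undefined_for_single_label():
    with pytest.raises(ValueError, match="undefined|single label"):
        krippendorff_alpha_nominal(_labels({"a": [0, 0], "b": [0, 0]}), bootstrap_reps=10, seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(perm=st.permutations([0, 1, 2]))
def test_alpha_invariant_under_relabeling(perm):
    rng = np.random.default_rng(4)
    units = [rng.integers(0, 3, size=rng.integers(2, 5)) for _ in range(10)]
    relabeled = [np.array([perm[x] for x in u]) for u in units]
    assert _alpha_nominal(relabeled) == pytest.approx(_alpha_nominal(units), abs=1e-12)


def test_alpha_ignores_single_visit_subjects():
    units = {"a": [0, 1], "b": [1, 1], "c": [0]}
    with_single = _alpha_nominal([np.array(u) for u in units.values()])
    without = _alpha_nominal([np.array([0, 1]), np.array([1, 1])])
    assert with_single == pytest.approx(without, abs=1e-12)


def test_alpha_near_zero_under_shuffled_labels():
    rng = np.random.default_rng(1)
    alphas = []
    for seed in range(7):
        units = [rng.integers(0, 2, size=3) for _ in range(300)]
        try:
            alphas.append(_alpha_nominal(units))
        except ValueError:
            alphas.append(0.0)
    assert abs(np.median(alphas)) < 0.05


def test_probability_threshold_filter_monotone():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "c"],
            "visit_index": [0, 1, 0, 0],
            "subtype_probability": [0.97, 0.5, 0.96, 0.80],
            "ml_subtype": [0, 0, 1, 1],
        }
    )
    all_s = filter_by_assignment_probability(df, 0.0)
    s95 = filter_by_assignment_probability(df, 0.95)
    s99 = filter_by_assignment_probability(df, 0.99)
    assert set(all_s) == {"a", "b", "c"}
    assert set(s95) == {"a", "b"}
    assert set(s99) <= set(s95)
    assert set(subjects_retaining_subtype(df)) == {"a", "b", "c"}


def _simulate_stages(n, beta, slope_sd, resid_sd, seed, plateau=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        k0 = rng.uniform(0, 15)
        slope = beta + plateau * k0 + rng.normal(0, slope_sd)
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.6, 1.4, size=2))])
        for v, t in enumerate(times):
            rows.append(
                {
                    "subject_id": f"S{i:04d}",
                    "visit_index": v,
                    "years_from_baseline": t,
                    "baseline_stage": k0,
                    "stage": k0 + slope * t + rng.normal(0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


def test_noise_free_common_slope_recovered_exactly():
    df = _simulate_stages(40, 0.2, 0.0, 0.0, seed=0)
    fit = fit_stage_change(df)
    assert fit.coef("years_from_baseline") == pytest.approx(0.2, abs=1e-6)


def test_slope_recovery_with_random_effects():
    df = _simulate_stages(300, 0.2, 0.1, 0.5, seed=1)
    fit = fit_stage_change(df)
    b = fit.coef("years_from_baseline")
    assert abs(b - 0.2) < 0.05
    lo, hi = fit.fixed_effects.loc["years_from_baseline", ["ci_low", "ci_high"]]
    assert lo < b < hi
    assert fit.random_effects["slope_var"] >= 0


def test_plateau_interaction_detected():
    df = _simulate_stages(250, 0.5, 0.05, 0.3, seed=2, plateau=-0.03)
    fit = fit_stage_change(df, moderator="baseline_stage")
    inter = [t for t in fit.fixed_effects.index if ":" in t][0]
    assert fit.coef(inter) < 0


def test_mixed_model_agrees_with_statsmodels():
    """The in-package profiled-GLS ML fitter reproduces statsmodels MixedLM
    (random intercept + slope, ML) on a shared fixture."""
    import warnings

    import statsmodels.formula.api as smf

    df = _simulate_stages(120, 0.25, 0.1, 0.5, seed=8)
    fit = fit_stage_change(df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(
            "stage ~ years_from_baseline", df, groups=df["subject_id"],
            re_formula="~years_from_baseline",
        ).fit(reml=False, method="powell", maxiter=2000)
    np.testing.assert_allclose(fit.fixed_effects["b"].to_numpy(), res.fe_params.to_numpy(), atol=2e-3)
    assert fit.residual_var == pytest.approx(float(res.scale), rel=0.05)
    assert fit.random_effects["intercept_var"] == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), rel=0.05)


def test_biomarker_trajectories_one_fit_per_biomarker():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(30):
        times = [0.0, 1.0, 2.0]
        for v, t in enumerate(times):
            rows.append(
                {
                    "subject_id": f"S{i:03d}",
                    "visit_index": v,
                    "years_from_baseline": t,
                    "gm_a": 0.1 * t,           # deterministic worsening
                    "gm_b": rng.normal(),      # no trend
                }
            )
    fits = fit_biomarker_trajectories(pd.DataFrame(rows), ["gm_a", "gm_b"])
    assert set(fits) == {"gm_a", "gm_b"}
    assert fits["gm_a"].coef("years_from_baseline") == pytest.approx(0.1, abs=1e-6)
    lo, hi = fits["gm_b"].fixed_effects.loc["years_from_baseline", ["ci_low", "ci_high"]]
    assert lo < 0 < hi
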