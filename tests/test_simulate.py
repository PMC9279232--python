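import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from msstratify import (
    SimulationConfig,
    apply_zscore,
    generate_clinical_outcomes,
    generate_longitudinal_visits,
    generate_patient_cohort,
    generate_reference_populations,
)
from msstratify.sustain import is_valid_sequence
from msstratify.zscore import fit_reference_stats


def test_generators_are_pure_functions_of_config_and_seed(small_config):
    h1, e1 = generate_reference_populations(small_config, 5)
    h2, e2 = generate_reference_populations(small_config, 5)
    pd.testing.assert_frame_equal(h1.df, h2.df)
    pd.testing.assert_frame_equal(e1.df, e2.df)
    b1, t1 = generate_patient_cohort(small_config, 5)
    b2, t2 = generate_patient_cohort(small_config, 5)
    pd.testing.assert_frame_equal(b1.df, b2.df)
    c1 = generate_clinical_outcomes(t1, small_config, 5)
    c2 = generate_clinical_outcomes(t2, small_config, 5)
    pd.testing.assert_frame_equal(c1.df, c2.df)


def test_hc_self_zscore_is_standard_normal(small_config):
    hc, _ = generate_reference_populations(small_config, 0)
    stats = fit_reference_stats(hc, flip=-1)
    z = apply_zscore(hc, stats)
    for b in z.biomarkers:
        assert abs(z.df[b].mean()) < 1e-12
        assert abs(z.df[b].std(ddof=1) - 1.0) < 1e-12


def test_hc_norms_recovered_at_large_n(small_config):
    cfg = dataclasses.replace(small_config, n_hc=1000)
    hc, _ = generate_reference_populations(cfg, 1)
    stats = cfg.reference_stats()
    for b in cfg.gm_biomarkers:
        se = stats.sd[b] / np.sqrt(1000)
        assert abs(hc.df[b].mean() - stats.mean[b]) < 4 * se


def test_patient_zscore_roundtrip_recovers_latent(small_config):
    """Raw -> z with the generator's own stats must invert the construction."""
    cfg = dataclasses.replace(small_config, sigma_gen=1e-9, n_patients=100)
    base, truth = generate_patient_cohort(cfg, 7)
    z = apply_zscore(base, cfg.reference_stats())
    grid = cfg.grid()
    from msstratify.sustain import expected_matrix

    for c, seq in enumerate(truth.sequences):
        E = expected_matrix(seq, grid)
        members = truth.subjects["true_subtype"].to_numpy() == c
        stages = truth.subjects.loc[members, "true_baseline_stage"].to_numpy(int)
        Z = z.values(list(grid.biomarkers))[members]
        np.testing.assert_allclose(Z, E[:, stages].T, atol=1e-6)


def test_subtype_proportions_match_fractions(small_config):
    cfg = dataclasses.replace(small_config, n_patients=2000)
    _, truth = generate_patient_cohort(cfg, 3)
    p_hat = (truth.subjects["true_subtype"] == 0).mean()
    se = np.sqrt(0.6 * 0.4 / 2000)
    assert abs(p_hat - 0.6) < 3 * se


def test_true_sequences_valid_and_mirrored(small_config):
    grid = small_config.grid()
    s0, s1 = small_config.true_sequences()
    assert is_valid_sequence(s0, grid) and is_valid_sequence(s1, grid)
    assert not np.array_equal(s0, s1)


def test_longitudinal_latent_stage_kinematics(small_config):
    cfg = dataclasses.replace(small_config, plateau=0.0, random_slope_sd=0.0, beta_time=0.2)
    _, truth = generate_patient_cohort(cfg, 2)
    _, lt = generate_longitudinal_visits(truth, cfg, 2)
    merged = lt.visits.merge(lt.subjects[["subject_id", "true_baseline_stage"]], on="subject_id")
    n_events = cfg.grid().n_events
    unclipped = merged["true_baseline_stage"] + 0.2 * merged["years_from_baseline"]
    expect = np.clip(unclipped, 0, n_events)
    np.testing.assert_allclose(merged["true_stage"], expect, atol=1e-12)
    assert (merged["true_stage"] <= n_events).all()


def test_visit_schedule_emulates_study_density():
    cfg = SimulationConfig(n_patients=400)
    _, truth = generate_patient_cohort(cfg, 0)
    _, lt = generate_longitudinal_visits(truth, cfg, 0)
    per_subject = lt.visits.groupby("subject_id").size()
    assert 2.2 < per_subject.mean() < 3.2  # ~2.7 visits/patient on average


def test_clinical_outcomes_null_coefficients_break_association(small_config):
    blocks = small_config.outcome_blocks
    null_blocks = {
        k: {**v, **{t: 0.0 for t in v if t not in ("thresholds", "levels", "intercept")}}
        for k, v in blocks.items()
    }
    cfg = dataclasses.replace(small_config, n_patients=400, outcome_blocks=null_blocks)
    _, truth = generate_patient_cohort(cfg, 11)
    clin = generate_clinical_outcomes(truth, cfg, 11)
    stage_tertile = pd.qcut(truth.subjects["true_baseline_stage"], 3, labels=False)
    table = pd.crosstab(stage_tertile, clin.df["motor_disability_lt"])
    _, p, *_ = chi2_contingency(table)
    assert p > 0.05


def test_clinical_outcomes_stage_gradient(small_config):
    blocks = {**small_config.outcome_blocks}
    blocks["motor_disability_lt"] = {**blocks["motor_disability_lt"], "stage": 0.6}
    cfg = dataclasses.replace(small_config, n_patients=600, outcome_blocks=blocks)
    _, truth = generate_patient_cohort(cfg, 13)
    clin = generate_clinical_outcomes(truth, cfg, 13)
    df = truth.subjects.merge(clin.df, on="subject_id")
    tertile = pd.qcut(df["true_baseline_stage"], 3, labels=False)
    means = df.groupby(tertile)["motor_disability_lt"].mean()
    assert means.iloc[0] < means.iloc[1] < means.iloc[2]


def test_missing_coefficient_block_term_raises(small_config):
    blocks = {k: dict(v) for k, v in small_config.outcome_blocks.items()}
    del blocks["baseline_edss"]["stage"]
    cfg = dataclasses.replace(small_config, outcome_blocks=blocks)
    _, truth = generate_patient_cohort(cfg, 1)
    with pytest.raises(ValueError, match="missing terms"):
        generate_clinical_outcomes(truth, cfg, 1)
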