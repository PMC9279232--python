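import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from msstratify import (
    BiomarkerTable,
    EventGrid,
    assign,
    build_event_grid,
    expected_value,
    fit_single_subtype,
    fit_sustain,
    label_subtypes,
    mcmc_positional_uncertainty,
    sequence_log_likelihood,
    stage_likelihoods,
)
from msstratify.simulate import SimulationConfig, generate_patient_cohort
from msstratify.sustain import (
    event_positions,
    expected_matrix,
    is_valid_sequence,
    mixture_log_likelihood,
    random_valid_sequence,
)
from msstratify.zscore import apply_zscore

from _oracles import sequence_ll_oracle, stage_likelihoods_oracle, valid_permutations


def _ztable(values: dict):
    n = len(next(iter(values.values())))
    return BiomarkerTable(
        pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "visit_index": 0,
                "years_from_baseline": 0.0,
                "age_years": 40.0,
                "sex": "F",
                **values,
            }
        ),
        scale="zscore",
    )


# ---------------------------------------------------------------------------
# event grid
# ---------------------------------------------------------------------------

def test_grid_retains_levels_by_five_percent_rule():
    # 100 subjects: 20 reach >=1, 10 reach >=2, 4 reach >=3
    vals = np.concatenate([np.full(80, 0.0), np.full(10, 1.5), np.full(6, 2.5), np.full(4, 3.5)])
    grid = build_event_grid(_ztable({"A": vals, "B": np.linspace(1, 4, 100)}))
    assert grid.levels[grid.biomarkers.index("A")] == (1.0, 2.0)


def test_grid_boundary_exactly_five_percent_retained():
    vals = np.concatenate([np.full(95, 0.0), np.full(5, 1.5)])
    grid = build_event_grid(_ztable({"A": vals, "B": np.linspace(1, 4, 100)}))
    assert 1.0 in grid.levels[grid.biomarkers.index("A")]


def test_grid_drops_unreached_biomarker_with_warning():
    with pytest.warns(UserWarning, match="dropped"):
        grid = build_event_grid(_ztable({"A": np.full(50, 0.2), "B": np.linspace(1, 4, 50)}))
    assert grid.biomarkers == ("B",)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def test_expected_value_anchors_and_interpolation(toy_grid):
    seq = np.array([0, 1])  # A:z1 at position 1, B:z1 at position 2
    assert expected_value(seq, toy_grid, "A", 0) == 0.0
    assert expected_value(seq, toy_grid, "B", 0) == 0.0
    assert expected_value(seq, toy_grid, "A", 1) == 1.0
    assert expected_value(seq, toy_grid, "B", 2) == 1.0
    assert expected_value(seq, toy_grid, "B", 1) == pytest.approx(0.5)  # halfway to its event


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_expected_value_nondecreasing_in_stage(seed):
    grid = EventGrid(("A", "B", "C"), ((1.0, 2.0), (1.0,), (1.0, 2.0, 3.0)), (5.0, 5.0, 5.0))
    seq = random_valid_sequence(grid, np.random.default_rng(seed))
    assert is_valid_sequence(seq, grid)
    E = expected_matrix(seq, grid)
    assert np.all(np.diff(E, axis=1) >= -1e-12)
    # event anchors are hit exactly
    pos = event_positions(seq)
    for e, (bi, z) in enumerate(grid.events):
        assert E[bi, pos[e]] == pytest.approx(z)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_stage_likelihoods_match_hand_computed_product(toy_grid):
    z = np.array([0.8, 0.1])
    seq = np.array([0, 1])
    got = stage_likelihoods(z, seq, toy_grid, sigma=1.0)
    expected = stage_likelihoods_oracle(z, seq, toy_grid, np.ones(2))
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_stage_likelihoods_argmax_at_generating_stage(three_event_grid):
    seq = np.array([0, 2, 1])  # A:z1, B:z1, A:z2
    E = expected_matrix(seq, three_event_grid)
    for k in range(4):
        like = stage_likelihoods(E[:, k], seq, three_event_grid, sigma=1.0)
        assert int(np.argmax(like)) == k


def test_all_missing_vector_gives_uniform_stage_likelihood(three_event_grid):
    like = stage_likelihoods(np.array([np.nan, np.nan]), np.array([0, 2, 1]), three_event_grid, sigma=1.0)
    np.testing.assert_allclose(like, like[0])


def test_sequence_ll_additive_and_permutation_invariant(toy_grid):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 2))
    seq = np.array([1, 0])
    ll = sequence_log_likelihood(X, seq, toy_grid, 1.0)
    assert sequence_log_likelihood(np.vstack([X, X]), seq, toy_grid, 1.0) == pytest.approx(2 * ll)
    assert sequence_log_likelihood(X[::-1], seq, toy_grid, 1.0) == pytest.approx(ll)


def test_sequence_ll_one_event_closed_form():
    """1 subject, 1 biomarker, 1 event: a two-term Gaussian mixture."""
    grid = EventGrid(("A",), ((1.0,),), (5.0,))
    z = 0.4
    phi = lambda x, mu: np.exp(-0.5 * (x - mu) ** 2) / np.sqrt(2 * np.pi)
    expected = np.log(0.5 * (phi(z, 0.0) + phi(z, 1.0)))
    got = sequence_log_likelihood(np.array([[z]]), np.array([0]), grid, 1.0)
    assert got == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_single_subtype_deterministic_and_matches_enumeration(three_event_grid):
    rng = np.random.default_rng(5)
    X = rng.normal(0.5, 1.0, size=(12, 2))
    seq_a, ll_a = fit_single_subtype(X, three_event_grid, 1.0, n_startpoints=6, seed=42)
    seq_b, ll_b = fit_single_subtype(X, three_event_grid, 1.0, n_startpoints=6, seed=42)
    np.testing.assert_array_equal(seq_a, seq_b)
    assert ll_a == ll_b
    best = max(sequence_log_likelihood(X, s, three_event_grid, 1.0) for s in valid_permutations(three_event_grid))
    assert ll_a == pytest.approx(best, abs=1e-8)


def test_noise_free_cohort_recovers_generating_sequence(small_config):
    cfg = dataclasses.replace(small_config, sigma_gen=0.05, fractions=(1.0,), n_patients=200)
    grid = cfg.grid()
    base, truth = generate_patient_cohort(cfg, seed=11)
    z = apply_zscore(base, cfg.reference_stats())
    X = z.values(list(grid.biomarkers))
    seq, _ = fit_single_subtype(X, grid, 1.0, n_startpoints=8, seed=0)
    np.testing.assert_array_equal(seq, truth.sequences[0])


def test_fit_sustain_consistency_and_fraction_simplex(small_config):
    cfg = dataclasses.replace(small_config, n_patients=150)
    grid = cfg.grid()
    base, _ = generate_patient_cohort(cfg, seed=3)
    X = apply_zscore(base, cfg.reference_stats()).values(list(grid.biomarkers))
    models = fit_sustain(X, grid, 1.0, max_subtypes=2, n_startpoints=4, seed=1, n_split_tries=2)
    seq1, ll1 = fit_single_subtype(X, grid, 1.0, n_startpoints=4, seed=1)
    assert models[0].log_likelihood == pytest.approx(ll1)
    for m in models:
        assert m.fractions.sum() == pytest.approx(1.0)
        assert np.all(m.fractions >= 0)
    assert models[1].log_likelihood >= models[0].log_likelihood - 1e-6


def test_fit_sustain_rejects_more_subtypes_than_subjects(toy_grid):
    with pytest.raises(ValueError, match="subjects"):
        fit_sustain(np.zeros((2, 2)), toy_grid, 1.0, max_subtypes=3, n_startpoints=1)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def test_mcmc_single_sample_is_ml_permutation_matrix(toy_grid):
    X = np.array([[0.1, 0.05], [1.2, 0.9]])
    seq, ll = fit_single_subtype(X, toy_grid, 1.0, n_startpoints=4, seed=0)
    from msstratify.sustain import SuStaInModel

    model = SuStaInModel(toy_grid, [seq], np.array([1.0]), np.ones(2), ll)
    pvd = mcmc_positional_uncertainty(X, model, n_samples=1, seed=0)
    mat = pvd.matrices[0]
    assert set(np.unique(mat)) <= {0.0, 1.0}
    np.testing.assert_array_equal(np.argmax(mat, axis=1), event_positions(seq) - 1)


def test_mcmc_samples_all_valid_and_rows_sum_to_one(three_event_grid):
    rng = np.random.default_rng(1)
    X = rng.normal(0.5, 1.0, size=(10, 2))
    seq, ll = fit_single_subtype(X, three_event_grid, 1.0, n_startpoints=4, seed=0)
    from msstratify.sustain import SuStaInModel

    model = SuStaInModel(three_event_grid, [seq], np.array([1.0]), np.ones(2), ll)
    pvd = mcmc_positional_uncertainty(X, model, n_samples=500, seed=2)
    np.testing.assert_allclose(pvd.matrices[0].sum(axis=1), 1.0)
    for s in model.mcmc_samples[0]:
        assert is_valid_sequence(s, three_event_grid)


# ---------------------------------------------------------------------------
# assignment and labelling
# ---------------------------------------------------------------------------

def test_assignment_posteriors_and_zero_vector(three_event_grid):
    from msstratify.sustain import SuStaInModel

    seqs = [np.array([0, 2, 1]), np.array([2, 0, 1])]
    model = SuStaInModel(three_event_grid, seqs, np.array([0.5, 0.5]), np.ones(2), 0.0)
    a = assign(model, np.zeros(2))
    assert a.ml_stage == 0
    assert a.subtype_posterior.sum() == pytest.approx(1.0)
    assert a.stage_posterior.sum() == pytest.approx(1.0)
    assert a.ml_subtype == int(np.argmax(a.subtype_posterior))


def test_assignment_recovers_generating_stage(small_config):
    cfg = dataclasses.replace(small_config, sigma_gen=0.05, fractions=(1.0,), n_patients=80)
    grid = cfg.grid()
    base, truth = generate_patient_cohort(cfg, seed=21)
    z = apply_zscore(base, cfg.reference_stats())
    X = z.values(list(grid.biomarkers))
    from msstratify.sustain import SuStaInModel

    model = SuStaInModel(grid, [truth.sequences[0]], np.array([1.0]), np.full(grid.n_biomarkers, 0.05), 0.0)
    stages = truth.subjects["true_baseline_stage"].to_numpy()
    hits = sum(assign(model, X[i]).ml_stage == stages[i] for i in range(len(X)))
    assert hits / len(X) >= 0.95


def test_label_subtypes_rule_and_symmetry(small_config):
    cfg = small_config
    grid = cfg.grid()
    s0, s1 = cfg.true_sequences()
    from msstratify.sustain import SuStaInModel

    model = SuStaInModel(grid, [s0, s1], np.array([0.5, 0.5]), np.ones(grid.n_biomarkers), 0.0)
    labels = label_subtypes(model, cfg.dgm_biomarkers, cfg.cortical_biomarkers, cfg.lesion_biomarker)
    assert labels == {0: "DGM-first", 1: "cortex-first"}
    mirrored = SuStaInModel(grid, [s1, s0], np.array([0.5, 0.5]), np.ones(grid.n_biomarkers), 0.0)
    assert label_subtypes(mirrored, cfg.dgm_biomarkers, cfg.cortical_biomarkers) == {
        0: "cortex-first",
        1: "DGM-first",
    }
    single = SuStaInModel(grid, [s0], np.array([1.0]), np.ones(grid.n_biomarkers), 0.0)
    with pytest.warns(UserWarning, match="undifferentiated"):
        assert label_subtypes(single, cfg.dgm_biomarkers, cfg.cortical_biomarkers) == {0: "undifferentiated"}
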