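import numpy as np
import pytest

from funcfeat.generalization import (
    FaithfulnessMatrix,
    TargetSpec,
    accuracy_error,
    accuracy_error_summary,
    build_generalization_set,
    classify_faithful,
    diagnostic_components,
    signed_distance,
    simulate_identification,
)

# ----------------------------------------------------------- faithfulness


def test_perfect_reconstruction_is_faithful():
    assert classify_faithful(np.array([1.0]), np.array([0.5]), np.array([1.0]))[0]


def test_reconstruction_at_chance_is_not_faithful():
    out = classify_faithful(np.array([0.5]), np.array([0.5]), np.array([1.0]))
    assert not out[0]


def test_matches_elementwise_inequality_oracle():
    rng = np.random.default_rng(0)
    recon, chance, truth = rng.standard_normal((3, 20))
    out = classify_faithful(recon, chance, truth)
    for v in range(20):
        assert out[v] == (abs(chance[v] - truth[v]) > abs(recon[v] - truth[v]))


def test_nan_distances_raise():
    with pytest.raises(ValueError, match="NaN"):
        classify_faithful(np.array([np.nan]), np.array([0.0]), np.array([0.0]))


def test_signed_distance_signs():
    normals = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    proto = np.zeros(6)
    verts = np.array([2.0, 0.0, 0.0, -3.0, 0.0, 0.0])
    d = signed_distance(verts, proto, normals)
    np.testing.assert_allclose(d, [2.0, -3.0])


# --------------------------------------------------- diagnostic components


def _block_faithfulness(n_obs=6, n_targets=2, v=40, seed=0):
    """Two disjoint vertex blocks, one per target group, plus jitter."""
    rng = np.random.default_rng(seed)
    F = np.zeros((v, n_obs * n_targets))
    for o in range(n_obs):
        for t in range(n_targets):
            col = o * n_targets + t
            lo, hi = (0, v // 2) if t == 0 else (v // 2, v)
            F[lo:hi, col] = 1.0
            flip = rng.choice(v, size=2, replace=False)
            F[flip, col] = 1.0 - F[flip, col]
    return FaithfulnessMatrix(values=F, n_observers=n_obs, n_targets=n_targets)


def test_planted_blocks_recovered():
    F = _block_faithfulness()
    diags = diagnostic_components(F, k=4, seed=1)
    v = F.values.shape[0]
    own0 = diags[0].C_D[: v // 2].mean()
    other0 = diags[0].C_D[v // 2 :].mean()
    assert own0 > 0.7 and other0 < 0.3
    own1 = diags[1].C_D[v // 2 :].mean()
    other1 = diags[1].C_D[: v // 2].mean()
    assert own1 > 0.7 and other1 < 0.3


def test_complement_exact_everywhere():
    diags = diagnostic_components(_block_faithfulness(seed=2), k=4, seed=2)
    for d in diags.values():
        np.testing.assert_array_equal(d.C_D + d.C_N, np.ones_like(d.C_D))
        assert d.C_D.max() <= 1.0


def test_single_component_normalized_to_max_one():
    F = _block_faithfulness(seed=3)
    diags = diagnostic_components(F, k=1, seed=3)
    for d in diags.values():
        if d.contributing.any():
            np.testing.assert_allclose(d.C_D.max(), 1.0)


def test_threshold_above_all_loadings_warns_and_zeroes():
    F = _block_faithfulness(seed=4)
    with pytest.warns(UserWarning, match="no contributing"):
        diags = diagnostic_components(F, k=4, loading_threshold=1e9, seed=4)
    assert np.all(diags[0].C_D == 0)


def test_all_zero_matrix_raises():
    F = FaithfulnessMatrix(values=np.zeros((10, 4)), n_observers=2, n_targets=2)
    with pytest.raises(ValueError, match="zero"):
        diagnostic_components(F)


def test_nmf_seeded_determinism():
    F = _block_faithfulness(seed=5)
    a = diagnostic_components(F, k=4, seed=9)
    b = diagnostic_components(F, k=4, seed=9)
    np.testing.assert_array_equal(a[0].C_D, b[0].C_D)


# ------------------------------------------------------- stimulus builder


@pytest.fixture()
def target_specs(tiny_model):
    rng = np.random.default_rng(6)
    V = tiny_model.n_vertices
    specs = []
    for t, (sex, eth) in enumerate([("female", "other"), ("male", "east_asian")]):
        factors = {"sex": sex, "age": 40.0, "ethnicity": eth}
        gt = tiny_model.prototype(factors) + rng.standard_normal(3 * V)
        C_D = rng.uniform(0, 1, V)
        C_D /= C_D.max()
        specs.append(TargetSpec(name=f"target_{t}", ground_truth=gt, factors=factors, C_D=C_D))
    return specs


def test_default_build_emits_50_per_target(tiny_model, target_specs):
    stimuli = build_generalization_set(tiny_model, target_specs)
    assert len(stimuli) == 2 * 2 * 5 * 5
    per_target = [s for s in stimuli if s.target == "target_0"]
    assert len(per_target) == 50


def test_count_formula_holds_for_any_configuration(tiny_model, target_specs):
    stimuli = build_generalization_set(
        tiny_model, target_specs[:1], amps=(0.5, 1.0), conditions=("view_0", "age_80")
    )
    assert len(stimuli) == 1 * 2 * 2 * 2


def test_alpha_zero_gives_categorical_average(tiny_model, target_specs):
    stimuli = build_generalization_set(
        tiny_model, target_specs[:1], amps=(0.0,), conditions=("view_0",)
    )
    for s in stimuli:
        np.testing.assert_allclose(s.vertices, tiny_model.prototype(s.factors))


def test_full_diagnostic_alpha_one_recovers_ground_truth(tiny_model, target_specs):
    spec = target_specs[0]
    spec.C_D = np.ones_like(spec.C_D)
    stimuli = build_generalization_set(tiny_model, [spec], amps=(1.0,), conditions=("view_0",))
    diag = [s for s in stimuli if s.diagnosticity == "D"][0]
    np.testing.assert_allclose(diag.vertices, spec.ground_truth)


def test_condition_edits_factors(tiny_model, target_specs):
    stimuli = build_generalization_set(tiny_model, target_specs[:1], amps=(1.0,))
    by_cond = {s.condition: s for s in stimuli if s.diagnosticity == "D"}
    assert by_cond["age_80"].factors["age"] == 80.0
    assert by_cond["sex_swap"].factors["sex"] != target_specs[0].factors["sex"]
    assert by_cond["view_-30"].view_angle == -30


def test_unknown_condition_raises(tiny_model, target_specs):
    with pytest.raises(ValueError, match="unknown"):
        build_generalization_set(tiny_model, target_specs[:1], conditions=("upside_down",))


# ---------------------------------------------------------- identification


def test_own_diagnostic_face_identified_by_faithful_models(tiny_model, target_specs):
    # distance raters centered on each target's ground truth: a target's own
    # high-amplification diagnostic face must be assigned to it
    stimuli = build_generalization_set(tiny_model, target_specs, amps=(1.67,),
                                       conditions=("view_0",))
    preds = np.empty((2, len(stimuli)))
    for t, spec in enumerate(target_specs):
        for i, s in enumerate(stimuli):
            preds[t, i] = -np.linalg.norm(s.vertices - spec.ground_truth)
    true_targets = np.array([int(s.target.split("_")[1]) for s in stimuli])
    result = simulate_identification(preds, true_targets)
    diag = np.array([s.diagnosticity == "D" for s in stimuli])
    assert result.accuracies[diag].mean() == 1.0


def test_identical_scores_tie_to_target_zero():
    preds = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
    result = simulate_identification(preds, np.array([1, 2]))
    assert np.all(result.choices == 0)
    assert result.n_ties == 2


def test_constant_predictions_raise():
    preds = np.array([[1.0, 1.0], [0.0, 1.0]])
    with pytest.raises(ValueError, match="constant"):
        simulate_identification(preds, np.array([0, 1]))


def test_accuracy_error_examples():
    np.testing.assert_array_equal(
        accuracy_error(np.array([1.0, 0.6]), np.array([1.0, 0.6])), [0.0, 0.0]
    )
    np.testing.assert_allclose(accuracy_error(np.array([1.0]), np.array([0.8])), [0.2])
    with pytest.raises(ValueError):
        accuracy_error(np.ones(3), np.ones(2))


def test_accuracy_error_matches_elementwise_oracle():
    rng = np.random.default_rng(7)
    model = rng.integers(0, 2, 50).astype(float)
    ref = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], 50)
    err = accuracy_error(model, ref)
    np.testing.assert_array_equal(err, np.abs(model - ref))


def test_bootstrap_summary_reproducible():
    errors = np.array([0.0, 0.2, 0.2, 0.4, 1.0])
    m1, ci1 = accuracy_error_summary(errors, seed=0)
    m2, ci2 = accuracy_error_summary(errors, seed=0)
    assert m1 == m2 == 0.2 and ci1 == ci2
    assert ci1[0] <= m1 <= ci1[1]
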