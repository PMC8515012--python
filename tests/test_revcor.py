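import numpy as np
import pytest

from funcfeat.forward import LambdaSearch, nested_cv_fit, ridge_solve, space_from_components
from funcfeat.revcor import (
    amplification_tuning,
    choose_faces,
    mass_univariate_fit,
    sphere_normals,
    template_metrics,
)

# ------------------------------------------------------------ choose_faces


def test_strict_maximum_chosen():
    preds = np.array([0.1, 0.9, 0.5, 0.2, 0.3, 0.4])
    arrays = np.arange(6).reshape(1, 6)
    chosen, stim, rating = choose_faces(preds, arrays)
    assert chosen[0] == 1 and stim[0] == 1 and rating[0] == 0.9


def test_all_equal_ties_resolve_to_index_zero():
    preds = np.full(6, 2.0)
    chosen, _, _ = choose_faces(preds, np.arange(6).reshape(1, 6))
    assert chosen[0] == 0


def test_missing_prediction_names_trial():
    preds = np.array([0.1, np.nan, 0.2, 0.3, 0.4, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="trial 0"):
        choose_faces(preds, np.arange(12).reshape(2, 6))


def test_closed_loop_choices_reproduced(tiny_model):
    # a forward model fit to a noiseless observer reproduces its choices
    from funcfeat.synth import ObserverSpec, generate_stimulus_set, simulate_session

    factors = {"sex": "female", "age": 30.0, "ethnicity": "other"}
    K = tiny_model.n_components
    rng = np.random.default_rng(0)
    obs = ObserverSpec(np.zeros(K), rng.uniform(0.5, 1.5, K), noise_sd=0.0, kind="linear")
    stimuli = generate_stimulus_set(tiny_model, 180 * 6, factors=factors, seed=1)
    session = simulate_session(obs, stimuli, 180)
    comps = np.stack([s.components for s in stimuli])
    fit = nested_cv_fit(
        space_from_components("shape", comps[session.chosen_stimulus_indices]),
        session.ratings.astype(float), fold_len=20,
        search=LambdaSearch(coarse_step=10.0, refine_offsets=((-4.0, 4.0),)),
    )
    # a perfectly fit model (the observer's own weights) reproduces choices
    perfect, _, _ = choose_faces(comps @ obs.srf_weights, session.candidate_indices)
    assert np.mean(perfect == session.chosen) >= 0.99
    # the nested-CV fit comes close
    chosen, _, _ = choose_faces(fit.predict(comps), session.candidate_indices)
    assert np.mean(chosen == session.chosen) >= 0.95


# ----------------------------------------------------- mass-univariate fit


def test_exact_linear_relation_recovered():
    r = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    F = (2.0 + 3.0 * r)[:, None]
    fit = mass_univariate_fit(F, r)
    np.testing.assert_allclose(fit.b0, [2.0], atol=1e-12)
    np.testing.assert_allclose(fit.b1, [3.0], atol=1e-12)


def test_independent_feature_slope_within_standard_error():
    rng = np.random.default_rng(1)
    n = 10_000
    r = rng.integers(1, 7, n).astype(float)
    F = rng.standard_normal((n, 1))
    fit = mass_univariate_fit(F, r)
    se = 1.0 / np.sqrt(np.sum((r - r.mean()) ** 2))
    assert abs(fit.b1[0]) < 3 * se


def test_ols_matches_per_coordinate_closed_form():
    rng = np.random.default_rng(2)
    r = rng.standard_normal(40)
    F = rng.standard_normal((40, 7))
    fit = mass_univariate_fit(F, r)
    X = np.column_stack([np.ones(40), r])
    for j in range(7):
        b = np.linalg.solve(X.T @ X, X.T @ F[:, j])
        np.testing.assert_allclose([fit.b0[j], fit.b1[j]], b, atol=1e-10)


def test_robust_estimator_downweights_outliers():
    rng = np.random.default_rng(3)
    r = rng.standard_normal(200)
    F = (1.0 + 2.0 * r)[:, None] + 0.1 * rng.standard_normal((200, 1))
    F[:5] += 50.0  # gross outliers
    ols = mass_univariate_fit(F, r)
    rob = mass_univariate_fit(F, r, estimator="robust")
    assert abs(rob.b1[0] - 2.0) < abs(ols.b1[0] - 2.0)


def test_constant_ratings_raise():
    with pytest.raises(ValueError, match="constant"):
        mass_univariate_fit(np.random.default_rng(0).standard_normal((10, 2)), np.ones(10))


def test_slopes_proportional_to_forward_weights_on_whitened_toy():
    # with whitened predictors, reverse slopes invert the forward weights
    rng = np.random.default_rng(4)
    n, k = 400, 5
    q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    X = q * np.sqrt(n)  # X'X = n I
    y = X @ rng.uniform(0.5, 1.5, k) + 0.1 * rng.standard_normal(n)
    forward = ridge_solve(X, y - y.mean(), [0.0])
    reverse = mass_univariate_fit(X, y).b1
    ratio = reverse / forward
    np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)


# ------------------------------------------------------------------ tuning


def _revcor(b0, b1):
    from funcfeat.revcor.fit import RevCorFit

    return RevCorFit(b0=np.asarray(b0, float), b1=np.asarray(b1, float))


def test_linear_responder_monotone_with_peak_at_grid_end():
    rng = np.random.default_rng(5)
    b1 = rng.standard_normal(6)
    w = b1 * 2.0  # responder aligned with the slope field
    curve = amplification_tuning(_revcor(np.zeros(6), b1), lambda f: f @ w)
    assert np.all(np.diff(curve.responses) >= -1e-12)
    assert curve.peak_amp == curve.amplifications[-1]


def test_distance_responder_interior_peak_matches_fine_grid_oracle():
    rng = np.random.default_rng(6)
    b0 = rng.standard_normal(8)
    b1 = rng.standard_normal(8)
    target = b0 + 7.3 * b1 + 0.01 * rng.standard_normal(8)
    responder = lambda f: -np.sum((f - target) ** 2, axis=1)
    grid = np.arange(0.0, 50.0 + 1e-9, 0.5)
    curve = amplification_tuning(_revcor(b0, b1), responder, grid)
    fine = np.arange(0.0, 50.0001, 0.001)
    oracle_peak = fine[np.argmax(responder(b0[None] + fine[:, None] * b1[None]))]
    assert abs(curve.peak_amp - oracle_peak) <= 0.5
    assert 0 < curve.peak_amp < 50


def test_zero_slope_flat_curve_first_maximum():
    curve = amplification_tuning(_revcor(np.ones(4), np.zeros(4)), lambda f: f.sum(axis=1))
    assert curve.peak_amp == 0.0


def test_empty_grid_raises():
    with pytest.raises(ValueError, match="empty"):
        amplification_tuning(_revcor(np.ones(3), np.ones(3)), lambda f: f.sum(axis=1),
                             np.array([]))


# ----------------------------------------------------------------- metrics


def test_identical_templates_perfect_metrics():
    rng = np.random.default_rng(7)
    proto = rng.standard_normal(30)
    t = proto + rng.standard_normal(30)
    mae, r = template_metrics(t, t, proto)
    assert mae == 0.0
    np.testing.assert_allclose(r, 1.0)


def test_prototype_template_gives_error_code():
    rng = np.random.default_rng(8)
    proto = rng.standard_normal(30)
    ref = proto + rng.standard_normal(30)
    mae, r = template_metrics(proto, ref, proto)
    assert np.isnan(r)


def test_mae_matches_elementwise_oracle():
    rng = np.random.default_rng(9)
    proto = rng.standard_normal(30)
    a = proto + rng.standard_normal(30)
    b = proto + rng.standard_normal(30)
    mae, _ = template_metrics(a, b, proto)
    np.testing.assert_allclose(mae, np.mean(np.abs(a - b)), atol=1e-12)


def test_sphere_normals_are_unit_and_deterministic():
    n1 = sphere_normals(50)
    n2 = sphere_normals(50)
    np.testing.assert_array_equal(n1, n2)
    np.testing.assert_allclose(np.linalg.norm(n1, axis=1), 1.0, atol=1e-12)


def test_template_recovery_noiseless_observer(tiny_model):
    # reverse-correlated slope field aligns with the observer's template
    # direction in vertex space (linear-SRF observer, no noise)
    from funcfeat.synth import ObserverSpec, generate_stimulus_set, simulate_session

    factors = {"sex": "male", "age": 40.0, "ethnicity": "east_asian"}
    K = tiny_model.n_components
    corrs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.5, 1.5, K)
        obs = ObserverSpec(np.zeros(K), w, noise_sd=0.0, kind="linear", seed=seed)
        stimuli = generate_stimulus_set(tiny_model, 180 * 6, factors=factors, seed=seed + 50)
        session = simulate_session(obs, stimuli, 180)
        comps = np.stack([s.components for s in stimuli])
        verts = (comps * tiny_model.component_scale) @ tiny_model.U_shape.T
        fit = mass_univariate_fit(
            verts[session.chosen_stimulus_indices], session.ratings.astype(float)
        )
        true_direction = tiny_model.U_shape @ (tiny_model.component_scale * w)
        corrs.append(np.corrcoef(fit.b1, true_direction)[0, 1])
    assert np.median(corrs) >= 0.95


def test_faithful_embedding_template_beats_noise_embedding(tiny_model):
    # humanness ordering: a shape-faithful embedding's recovered template is
    # closer to the observer's template than a pure-noise embedding's
    from funcfeat.forward import LambdaSearch, nested_cv_fit, space_from_components
    from funcfeat.synth import (
        EmbeddingSpec,
        ObserverSpec,
        generate_embedding,
        generate_stimulus_set,
        simulate_session,
    )

    factors = {"sex": "female", "age": 30.0, "ethnicity": "other"}
    K = tiny_model.n_components
    search = LambdaSearch(coarse_step=10.0, refine_offsets=((-4.0, 4.0),))
    for seed in range(5):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.5, 1.5, K)
        obs = ObserverSpec(np.zeros(K), w, noise_sd=0.0, kind="linear", seed=seed)
        stimuli = generate_stimulus_set(tiny_model, 180 * 6, factors=factors, seed=seed + 10)
        session = simulate_session(obs, stimuli, 180)
        comps = np.stack([s.components for s in stimuli])
        verts = (comps * tiny_model.component_scale) @ tiny_model.U_shape.T
        true_direction = tiny_model.U_shape @ (tiny_model.component_scale * w)

        maes = {}
        for name, fid, noise in (("faithful", 0.95, 0.05), ("noise", 0.0, 1.0)):
            spec = EmbeddingSpec(name=name, dim=24, shape_fidelity=fid, noise_sd=noise,
                                 seed=seed)
            emb = generate_embedding(spec, stimuli, tiny_model)
            fit = nested_cv_fit(
                space_from_components(name, emb.values[session.chosen_stimulus_indices]),
                session.ratings.astype(float), fold_len=20, search=search,
            )
            rc = mass_univariate_fit(verts[session.chosen_stimulus_indices],
                                     fit.oof_predictions)
            direction = rc.b1 / np.linalg.norm(rc.b1)
            ref = true_direction / np.linalg.norm(true_direction)
            maes[name] = np.mean(np.abs(direction - ref))
        assert maes["faithful"] < maes["noise"]
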