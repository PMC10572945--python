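"""Gravitational neocognitron: mass formulas, force law, population update,
forward pass, and training behavior."""

import numpy as np
import pytest

from sonomass import egnnn as eg


def make_blobs(n_per_class=50, seed=0, spread=0.5):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
    x = np.vstack([rng.normal(c, spread, size=(n_per_class, 2)) for c in centers])
    y = np.repeat(["a", "b", "c"], n_per_class)
    return x, y


# ---------------------------------------------------------------------------
# masses and forces


def test_mass_formula_example():
    m, q = eg.compute_masses(np.array([2.0, 5.0, 8.0]))
    assert m == pytest.approx([1.0, 0.5, 0.0])
    assert q == pytest.approx([2 / 3, 1 / 3, 0.0])


def test_equal_losses_give_uniform_masses():
    m, q = eg.compute_masses(np.array([3.0, 3.0, 3.0, 3.0]))
    assert q == pytest.approx([0.25] * 4)


def test_mass_normalization(rng):
    _, q = eg.compute_masses(rng.random(17))
    assert q.sum() == pytest.approx(1.0)


def test_empty_losses_rejected():
    with pytest.raises(ValueError, match="empty"):
        eg.compute_masses(np.array([]))


def test_zero_mass_agent_exerts_no_force():
    assert eg.force_magnitude(0.5, 0.0, 1.0, c=100.0) == 0.0


def test_coincident_agents_force_is_finite():
    got = eg.force_magnitude(0.4, 0.6, 0.0, c=10.0, rho=1e-3)
    assert got == pytest.approx(10.0 * 0.4 * 0.6 / 1e-3)


def test_force_halves_when_distance_doubles():
    f1 = eg.force_magnitude(0.5, 0.5, 1.0, c=1.0, dist_exponent=1.0, rho=1e-15)
    f2 = eg.force_magnitude(0.5, 0.5, 2.0, c=1.0, dist_exponent=1.0, rho=1e-15)
    assert f1 / f2 == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# population update


def test_zero_forces_zero_velocity_is_fixed_point(rng):
    pos = rng.random((5, 3))
    vel = np.zeros_like(pos)
    new_pos, new_vel = eg.update_agents(
        pos, vel, np.zeros_like(pos), np.ones(5), rng
    )
    assert np.array_equal(new_pos, pos)
    assert np.array_equal(new_vel, vel)


def test_positions_clipped_to_unit_box(rng):
    pos = np.full((3, 2), 0.95)
    vel = np.zeros_like(pos)
    forces = np.full((3, 2), 50.0)
    new_pos, _ = eg.update_agents(pos, vel, forces, np.ones(3), rng)
    assert new_pos.max() <= 1.0
    assert new_pos.min() >= 0.0


def test_dominant_mass_attracts_population():
    """On a static quadratic loss the swarm drifts toward the best agent."""
    rng = np.random.default_rng(3)
    target = np.full(4, 0.8)
    pos = rng.random((12, 4))
    vel = np.zeros_like(pos)
    dists = []
    for a in range(50):
        losses = np.sum((pos - target) ** 2, axis=1)
        m, q = eg.compute_masses(losses)
        best = pos[np.argmin(losses)]
        dists.append(np.mean(np.linalg.norm(pos - best, axis=1)))
        c = eg.gravitational_constant(100.0, 20.0, a, 50)
        forces = eg.total_forces(pos, q, c, rng)
        pos, vel = eg.update_agents(pos, vel, forces, m, rng)
    assert np.mean(dists[-10:]) < np.mean(dists[:10])


# ---------------------------------------------------------------------------
# forward pass


def test_zero_weights_score_half(rng):
    x, y = make_blobs(5)
    model = eg.EGNNN(x, y)
    params = {k: np.zeros(s) for k, s in model.topology.sizes.items()}
    scores = model.topology.forward(params, model.x)
    assert np.allclose(scores, 0.5)


def test_logistic_symmetry(rng):
    g = rng.normal(size=100)
    gamma = 1.0 / (1.0 + np.exp(-g))
    gamma_neg = 1.0 / (1.0 + np.exp(g))
    assert np.allclose(gamma + gamma_neg, 1.0)


def test_scores_in_open_unit_interval(rng):
    x, y = make_blobs(10)
    model = eg.EGNNN(x, y)
    params = model.topology.decode(rng.random(model.topology.n_params))
    scores = model.topology.forward(params, model.x)
    assert np.all((scores > 0) & (scores < 1))


def test_feature_length_mismatch_rejected():
    x, y = make_blobs(5)
    model = eg.EGNNN(x, y)
    params = model.topology.decode(np.full(model.topology.n_params, 0.5))
    with pytest.raises(ValueError, match="does not match"):
        model.topology.forward(params, np.zeros((1, 7)))


# ---------------------------------------------------------------------------
# training


def test_training_separates_blobs():
    x, y = make_blobs(50, seed=0)
    model = eg.EGNNN(x, y)
    fit = model.fit(eg.GravConfig(seed=0, iterations=30, polish_epochs=30))
    assert fit.accuracy(x, y) >= 0.95


def test_best_loss_trace_is_monotone():
    x, y = make_blobs(20, seed=1)
    model = eg.EGNNN(x, y)
    fit = model.fit(eg.GravConfig(seed=1, iterations=40, polish_epochs=0))
    assert all(b <= a + 1e-12 for a, b in zip(fit.trace, fit.trace[1:]))


def test_same_seed_identical_weights():
    x, y = make_blobs(15, seed=2)
    cfg = eg.GravConfig(seed=5, iterations=10, polish_epochs=5)
    f1 = eg.EGNNN(x, y).fit(cfg)
    f2 = eg.EGNNN(x, y).fit(cfg)
    for k in f1.params:
        assert np.array_equal(f1.params[k], f2.params[k])


def test_single_class_rejected():
    with pytest.raises(ValueError, match="2 classes"):
        eg.EGNNN(np.zeros((5, 2)), ["a"] * 5)


def test_zero_weight_ties_predict_first_class():
    x, y = make_blobs(5)
    model = eg.EGNNN(x, y)
    zeros = {k: np.zeros(s) for k, s in model.topology.sizes.items()}
    res = eg.EGNNNResults(model=model, params=zeros, best_loss=1.0)
    assert set(res.predict(x)) == {"a"}


def test_prediction_consistency_with_training_accuracy():
    x, y = make_blobs(20, seed=4)
    model = eg.EGNNN(x, y)
    fit = model.fit(eg.GravConfig(seed=2, iterations=10, polish_epochs=10))
    assert fit.accuracy(x, y) == np.mean(fit.predict(x) == y)


def test_gravitational_search_beats_random_search():
    """Paired over 10 seeds with equal evaluation budgets, population-phase
    training should dominate unguided random sampling.

    Run on a compact topology with an exploration-heavy schedule: mutual
    attraction averages weight vectors, which is informative in a small
    search space but washes out under the hidden-unit permutation symmetry
    of very wide layers.
    """
    diffs = []
    for seed in range(10):
        x, y = make_blobs(30, seed=seed, spread=1.0)
        iters = 30
        cfg = eg.GravConfig(
            seed=seed, population=10, iterations=iters, polish_epochs=0,
            c0=300.0, beta=10.0,
        )
        grav = eg.EGNNN(x, y, s_units=4).fit(cfg)
        rand = eg.random_search(
            x, y, n_evals=10 * (iters + 1), seed=seed, s_units=4
        )
        diffs.append(grav.accuracy(x, y) - rand.accuracy(x, y))
    assert np.mean(diffs) > 0.0
    assert sum(d >= 0 for d in diffs) >= 7


def test_summary_mentions_topology():
    x, y = make_blobs(10)
    fit = eg.EGNNN(x, y).fit(eg.GravConfig(seed=0, iterations=5, polish_epochs=2))
    text = fit.summary()
    assert "S-layer" in text and "classes" in text


def test_from_dataframe_roundtrip():
    import pandas as pd

    x, y = make_blobs(10)
    df = pd.DataFrame(x, columns=["f0", "f1"])
    df["label"] = y
    model = eg.EGNNN.from_dataframe(df)
    assert model.topology.d == 2
    assert model.class_names == ["a", "b", "c"]
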