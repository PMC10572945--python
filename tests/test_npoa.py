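"""Nomadic-people optimizer: dispersal geometry, Levy steps, convergence."""

import numpy as np
import pytest

from sonomass import npoa


def test_leader_initialization_respects_bounds_and_mean():
    rng = np.random.default_rng(0)
    lb, ub = np.zeros(1), np.ones(1)
    draws = npoa.init_leaders(10_000, lb, ub, rng)
    assert draws.min() >= 0.0 and draws.max() <= 1.0
    assert abs(draws.mean() - 0.5) < 0.02


def test_inverted_bounds_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="bounds"):
        npoa.init_leaders(3, np.ones(2), np.zeros(2), rng)


def test_zero_radius_families_sit_on_leader():
    rng = np.random.default_rng(1)
    leader = np.array([0.3, 0.7])
    fams = npoa.distribute_families(leader, 5, 0.0, np.zeros(2), np.ones(2), rng)
    assert np.allclose(fams, leader)


def test_families_within_clan_radius():
    rng = np.random.default_rng(2)
    leader = np.zeros(3)
    fams = npoa.distribute_families(
        leader, 200, 0.5, np.full(3, -10.0), np.full(3, 10.0), rng
    )
    assert np.max(np.abs(fams - leader)) <= 0.5 + 1e-12


def test_family_dispersal_is_seeded():
    leader = np.array([0.5])
    kw = dict(n_families=4, r_clan=0.2, lb=np.zeros(1), ub=np.ones(1))
    a = npoa.distribute_families(leader, rng=np.random.default_rng(7), **kw)
    b = npoa.distribute_families(leader, rng=np.random.default_rng(7), **kw)
    assert np.array_equal(a, b)


def test_levy_steps_are_heavy_tailed():
    from scipy import stats

    rng = np.random.default_rng(3)
    draws = npoa.mantegna_levy(rng, (10_000,), alpha=1.5)
    assert stats.kurtosis(draws) > 3.0  # far beyond the Gaussian's 0


def test_levy_explore_fixed_points():
    rng = np.random.default_rng(4)
    fam = np.array([[0.2, 0.4]])
    lb, ub = np.zeros(2), np.ones(2)
    same = npoa.levy_explore(fam, fam[0], 1.0, lb, ub, rng)
    assert np.allclose(same, fam)
    frozen = npoa.levy_explore(fam, np.array([0.9, 0.9]), 0.0, lb, ub, rng)
    assert np.allclose(frozen, fam)


def test_sphere_minimization_ten_seeds():
    for seed in range(10):
        res = npoa.optimize(
            lambda x: float(np.sum(x**2)),
            [(-5.0, 5.0)] * 2,
            budget=2000,
            seed=seed,
        )
        assert res.best_value < 1e-2
        assert all(
            b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:])
        )


def test_constant_objective_returns_in_bounds_point():
    res = npoa.optimize(lambda x: 1.0, [(2.0, 3.0)] * 2, budget=200, seed=0)
    assert res.best_value == 1.0
    assert np.all((res.best_position >= 2.0) & (res.best_position <= 3.0))


def test_budget_below_one_generation_rejected():
    with pytest.raises(ValueError, match="budget"):
        npoa.optimize(lambda x: 0.0, [(0.0, 1.0)], n_clans=5, n_families=10,
                      budget=10, seed=0)


def test_optimizer_is_deterministic():
    f = lambda x: float(np.sum((x - 0.3) ** 2))
    r1 = npoa.optimize(f, [(0.0, 1.0)] * 3, budget=500, seed=11)
    r2 = npoa.optimize(f, [(0.0, 1.0)] * 3, budget=500, seed=11)
    assert np.array_equal(r1.best_position, r2.best_position)
    assert r1.trace == r2.trace


# ---------------------------------------------------------------------------
# hyperparameter tuning


def _blobs(seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
    x = np.vstack([rng.normal(c, 0.8, size=(20, 2)) for c in centers])
    y = np.repeat(["a", "b", "c"], 20)
    return x, y


def test_degenerate_search_space_returns_that_point():
    x, y = _blobs()
    space = {"c0": (100.0, 100.0 + 1e-9, False)}
    hp, _ = npoa.tune_egnnn(
        x[::2], y[::2], x[1::2], y[1::2], search_space=space, budget=12, seed=0,
        inner_iterations=3, inner_polish_epochs=2,
    )
    assert hp["c0"] == pytest.approx(100.0, abs=1e-6)


def test_empty_search_space_rejected():
    x, y = _blobs()
    with pytest.raises(ValueError, match="empty"):
        npoa.tune_egnnn(x, y, x, y, search_space={}, budget=12, seed=0)


def test_tuning_is_seeded():
    x, y = _blobs(1)
    kw = dict(budget=12, seed=3, inner_iterations=3, inner_polish_epochs=2)
    hp1, _ = npoa.tune_egnnn(x[::2], y[::2], x[1::2], y[1::2], **kw)
    hp2, _ = npoa.tune_egnnn(x[::2], y[::2], x[1::2], y[1::2], **kw)
    assert hp1 == hp2


def test_tuned_config_no_worse_than_random_median():
    from sonomass.egnnn import EGNNN, GravConfig

    x, y = _blobs(2)
    xtr, ytr, xv, yv = x[::2], y[::2], x[1::2], y[1::2]
    hp, res = npoa.tune_egnnn(
        xtr, ytr, xv, yv, budget=36, seed=4,
        inner_iterations=4, inner_polish_epochs=3,
    )
    rng = np.random.default_rng(99)
    rand_losses = []
    space = npoa.DEFAULT_SEARCH_SPACE
    for _ in range(10):
        cand = {
            n: (int(round(rng.uniform(lo, hi))) if is_int else rng.uniform(lo, hi))
            for n, (lo, hi, is_int) in space.items()
        }
        cfg = GravConfig(c0=cand["c0"], beta=cand["beta"],
                         population=cand["population"], iterations=4,
                         polish_epochs=3, seed=4 + 10_007)
        m = EGNNN(xtr, ytr, s_units=cand["s_units"] - cand["s_units"] % 2)
        rand_losses.append(m.fit(cfg).loss(xv, yv))
    assert res.best_value <= np.median(rand_losses) + 1e-9
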