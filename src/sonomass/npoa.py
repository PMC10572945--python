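"""Nomadic people optimizer (NPOA): a clan-structured metaheuristic.

Each clan has a leader and a set of families.  Families camp semicircularly
around their leader (local search); whenever a family finds a better
position than its leader, leadership transfers.  A clan that stagnates for
several generations sends its families on Levy flights toward the leader
(global search), whose heavy-tailed steps occasionally jump far outside the
current camp.  The optimizer is elitist: the best position ever evaluated is
tracked and returned.

All randomness flows from a single seed; positions are clipped to the
search box after every move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def init_leaders(
    n_clans: int, lb: np.ndarray, ub: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform leader initialization: position = (ub - lb) * RD + lb."""
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if np.any(ub <= lb):
        raise ValueError("bounds must satisfy lb < ub per dimension")
    rd = rng.uniform(0.0, 1.0, size=(n_clans, lb.size))
    return (ub - lb) * rd + lb


def distribute_families(
    leader: np.ndarray,
    n_families: int,
    r_clan: np.ndarray | float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
    literal: bool = False,
) -> np.ndarray:
    """Semicircular dispersal of families around the leader.

    Per dimension: Y_d = leader_d + r_clan * RD * cos(theta), with
    RD ~ U(0,1) and theta ~ U(0, 2*pi), clipped to the bounds.  The
    ``literal`` flag switches to the purely multiplicative form
    Y_d = leader_d * RD * cos(theta), which collapses families toward the
    origin when leader coordinates are near zero and is kept only for
    reference.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    d = leader.size
    rd = rng.uniform(0.0, 1.0, size=(n_families, d))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_families, d))
    if literal:
        pos = leader[None, :] * rd * np.cos(theta)
    else:
        pos = leader[None, :] + np.asarray(r_clan) * rd * np.cos(theta)
    return np.clip(pos, lb, ub)


def mantegna_levy(
    rng: np.random.Generator, size: tuple[int, ...], alpha: float = 1.5
) -> np.ndarray:
    """Levy-stable step sampler (Mantegna's algorithm, stability ``alpha``)."""
    from scipy.special import gamma

    sigma_u = (
        gamma(1.0 + alpha)
        * np.sin(np.pi * alpha / 2.0)
        / (gamma((1.0 + alpha) / 2.0) * alpha * 2.0 ** ((alpha - 1.0) / 2.0))
    ) ** (1.0 / alpha)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / alpha)


def levy_explore(
    family_old: np.ndarray,
    leader: np.ndarray,
    n_d: float,
    lb: np.ndarray,
    ub: np.ndarray,
    rng: np.random.Generator,
    alpha: float = 1.5,
) -> np.ndarray:
    """Levy-flight exploration step toward (and past) the leader.

    Y_new = Y_old + N_d * (leader - Y_old) (element-wise *) Levy, clipped.
    """
    step = mantegna_levy(rng, family_old.shape, alpha=alpha)
    pos = family_old + n_d * (leader - family_old) * step
    return np.clip(pos, lb, ub)


@dataclass
class OptimizeResult:
    """Outcome of one NPOA run."""

    best_position: np.ndarray
    best_value: float
    trace: list[float] = field(default_factory=list)  # best-so-far per generation
    n_evals: int = 0


def optimize(
    objective,
    bounds,
    n_clans: int = 5,
    n_families: int = 10,
    budget: int = 2000,
    seed: int = 0,
    r_clan_frac: float = 0.1,
    n_d: float = 1.0,
    stagnation: int = 3,
) -> OptimizeResult:
    """Minimize ``objective`` over a bounded box.

    Per generation each clan evaluates ``n_families`` candidate positions
    (semicircular dispersal, or Levy exploration after ``stagnation``
    generations without clan improvement) and promotes the best family to
    leader when it beats the leader.  Terminates once ``budget`` objective
    evaluations are spent; the best-so-far trace is monotone non-increasing.
    """
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    if np.any(ub <= lb):
        raise ValueError("bounds must satisfy lb < ub per dimension")
    if budget < n_clans * n_families:
        raise ValueError("budget must allow at least one generation")
    rng = np.random.default_rng(seed)
    r_clan = r_clan_frac * (ub - lb)

    leaders = init_leaders(n_clans, lb, ub, rng)
    leader_fit = np.array([objective(p) for p in leaders])
    n_evals = n_clans
    best_idx = int(np.argmin(leader_fit))
    best_pos = leaders[best_idx].copy()
    best_val = float(leader_fit[best_idx])
    stagnant = np.zeros(n_clans, dtype=int)
    families = [
        distribute_families(leaders[c], n_families, r_clan, lb, ub, rng)
        for c in range(n_clans)
    ]

    trace: list[float] = []
    while n_evals + n_families <= budget:
        for c in range(n_clans):
            if n_evals + n_families > budget:
                break
            if stagnant[c] >= stagnation:
                cand = levy_explore(families[c], leaders[c], n_d, lb, ub, rng)
            else:
                cand = distribute_families(
                    leaders[c], n_families, r_clan, lb, ub, rng
                )
            fit = np.array([objective(p) for p in cand])
            n_evals += n_families
            families[c] = cand
            j = int(np.argmin(fit))
            if fit[j] < leader_fit[c]:
                leaders[c] = cand[j].copy()
                leader_fit[c] = float(fit[j])
                stagnant[c] = 0
            else:
                stagnant[c] += 1
            if fit[j] < best_val:
                best_val = float(fit[j])
                best_pos = cand[j].copy()
        trace.append(best_val)
    return OptimizeResult(
        best_position=best_pos, best_value=best_val, trace=trace, n_evals=n_evals
    )


# ---------------------------------------------------------------------------
# hyperparameter tuning of the gravitational neocognitron


#: search-space box: (low, high, integer?) per tunable hyperparameter
DEFAULT_SEARCH_SPACE = {
    "c0": (10.0, 300.0, False),
    "beta": (5.0, 40.0, False),
    "population": (8.0, 32.0, True),
    "s_units": (8.0, 64.0, True),
}


def tune_egnnn(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    val_features: np.ndarray,
    val_labels: np.ndarray,
    search_space: dict | None = None,
    budget: int = 60,
    seed: int = 0,
    inner_iterations: int = 30,
    inner_polish_epochs: int = 10,
) -> tuple[dict, OptimizeResult]:
    """Tune EGNNN hyperparameters by NPOA over a bounded box.

    The objective is the validation cross-entropy of a short training run
    under the candidate hyperparameters (inner seed fixed); integer-valued
    dimensions are decoded by rounding.  Returns the decoded best
    configuration and the raw optimizer result.
    """
    from .egnnn import EGNNN, GravConfig

    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACE
    if not space:
        raise ValueError("empty search space")
    names = list(space)
    bounds = [(space[n][0], space[n][1]) for n in names]

    def decode(x: np.ndarray) -> dict:
        out = {}
        for v, n in zip(x, names):
            lo, hi, is_int = space[n]
            v = min(max(float(v), lo), hi)
            out[n] = int(round(v)) if is_int else v
        return out

    def objective(x: np.ndarray) -> float:
        hp = decode(x)
        cfg = GravConfig(
            c0=hp.get("c0", 100.0),
            beta=hp.get("beta", 20.0),
            population=hp.get("population", 20),
            iterations=inner_iterations,
            polish_epochs=inner_polish_epochs,
            seed=seed + 10_007,
        )
        s_units = int(hp.get("s_units", 32))
        s_units = max(s_units - s_units % 2, 2)
        model = EGNNN(train_features, train_labels, s_units=s_units)
        res = model.fit(cfg)
        return float(res.loss(val_features, val_labels))

    res = optimize(
        objective,
        bounds,
        n_clans=3,
        n_families=4,
        budget=max(budget, 12),
        seed=seed,
    )
    return decode(res.best_position), res
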