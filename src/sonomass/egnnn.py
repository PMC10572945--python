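"""Evolutionary-gravitational neocognitron classifier (EGNNN).

A small neocognitron-style network — a feature-detecting S-layer (linear
units with rectification), a position-tolerant C-layer (max-pooling over
S-unit groups), and independent per-class logistic outputs — whose weights
are optimized by a gravitational population search: each candidate weight
vector is an agent whose mass derives from its training loss (best agent
mass 1, worst mass 0), and agents attract each other with forces
proportional to the product of their normalized masses and inversely
related to their distance.  A gradient "polish" phase (mini-batch SGD with
a step-decayed learning rate) optionally refines the best agent.

The public surface follows the model/results convention: build an
:class:`EGNNN` model from a feature matrix and labels, call :meth:`fit`,
and use the returned :class:`EGNNNResults` for prediction, scoring and the
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


# ---------------------------------------------------------------------------
# gravitational population mechanics


def compute_masses(losses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Agent masses from fitness (loss) values.

    M_q = (loss_q - poor) / (good - poor) with good = min loss and
    poor = max loss, so the best agent has mass 1 and the worst mass 0;
    Q_q normalizes the masses to sum 1.  If all losses are equal every
    agent receives M_q = 1/n.
    """
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("empty loss vector")
    good, poor = losses.min(), losses.max()
    if good == poor:
        m = np.full(losses.shape, 1.0 / losses.size)
    else:
        m = (losses - poor) / (good - poor)
    return m, m / m.sum()


def force_magnitude(
    q_q: float, q_i: float, distance: float, c: float,
    dist_exponent: float = 1.0, rho: float = 1e-6,
) -> float:
    """Pairwise attraction magnitude C * Q_q * Q_i / (L^b + rho)."""
    return c * q_q * q_i / (distance**dist_exponent + rho)


def total_forces(
    positions: np.ndarray,
    q: np.ndarray,
    c: float,
    rng: np.random.Generator,
    dist_exponent: float = 1.0,
    rho: float = 1e-6,
) -> np.ndarray:
    """Stochastic resultant force on every agent.

    Each pairwise contribution acts along the unit vector from agent q
    toward agent i and is scaled per dimension by a fresh uniform draw.
    """
    n, d = positions.shape
    forces = np.zeros((n, d))
    diff = positions[None, :, :] - positions[:, None, :]  # q -> i
    dist = np.linalg.norm(diff, axis=2)
    mag = c * (q[:, None] * q[None, :]) / (dist**dist_exponent + rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist[:, :, None] > 0, diff / np.maximum(dist, _EPS)[:, :, None], 0.0)
    rand = rng.uniform(0.0, 1.0, size=(n, n, d))
    contrib = rand * mag[:, :, None] * unit
    idx = np.arange(n)
    contrib[idx, idx, :] = 0.0
    forces = contrib.sum(axis=1)
    return forces


def update_agents(
    positions: np.ndarray,
    velocities: np.ndarray,
    forces: np.ndarray,
    m: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gravitational move: acceleration, stochastic inertia, clipping.

    acceleration = force / max(M_q, eps); velocity' = u * velocity +
    acceleration with u ~ U(0,1) per agent per dimension; positions are
    clipped back to the unit box.
    """
    accel = forces / np.maximum(m, _EPS)[:, None]
    u = rng.uniform(0.0, 1.0, size=velocities.shape)
    vel = u * velocities + accel
    pos = np.clip(positions + vel, 0.0, 1.0)
    return pos, vel


def gravitational_constant(c0: float, beta: float, a: int, a_max: int) -> float:
    """Decaying schedule C(a) = C0 * exp(-beta * a / a_max)."""
    return c0 * float(np.exp(-beta * a / max(a_max, 1)))


# ---------------------------------------------------------------------------
# network topology


@dataclass(frozen=True)
class GravConfig:
    """Training configuration.

    ``c0``/``beta`` parametrize the gravitational-constant schedule,
    ``dist_exponent``/``rho`` the force law.  ``batch_size`` and the
    learning-rate schedule (initial 1.32e-3, x0.1 every 10 epochs) govern
    the gradient polish phase that refines the best agent after the
    population phase; set ``polish_epochs=0`` to disable it.
    """

    c0: float = 100.0
    beta: float = 20.0
    dist_exponent: float = 1.0
    rho: float = 1e-6
    population: int = 20
    iterations: int = 100
    batch_size: int = 12
    learning_rate: float = 1.32e-3
    lr_decay: float = 0.1
    lr_step_epochs: int = 10
    polish_epochs: int = 30
    weight_decay: float = 1e-3
    validation_fraction: float = 0.0
    n_polish: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.rho <= 0:
            raise ValueError("c0 and rho must be positive")
        if self.population < 2:
            raise ValueError("population must be >= 2")


class _Topology:
    """Parameter layout of the S-layer / C-layer / logistic-output network."""

    def __init__(self, n_features: int, n_classes: int, s_units: int = 32,
                 pool: int = 2, output: str = "sigmoid"):
        if s_units % pool != 0:
            raise ValueError("s_units must be divisible by the pool size")
        if output not in ("sigmoid", "softmax"):
            raise ValueError("output must be 'sigmoid' or 'softmax'")
        self.d = n_features
        self.k = n_classes
        self.s_units = s_units
        self.pool = pool
        self.output = output
        self.c_units = s_units // pool
        self.sizes = {
            "w1": (s_units, n_features),
            "b1": (s_units,),
            "w2": (n_classes, self.c_units),
            "b2": (n_classes,),
        }
        self.n_params = sum(int(np.prod(s)) for s in self.sizes.values())

    def decode(self, position: np.ndarray) -> dict[str, np.ndarray]:
        """Unit-box agent position -> signed, fan-in-scaled weights."""
        w = 2.0 * np.asarray(position, dtype=float) - 1.0
        out = {}
        ofs = 0
        for name, shape in self.sizes.items():
            n = int(np.prod(shape))
            out[name] = w[ofs : ofs + n].reshape(shape)
            ofs += n
        out["w1"] = out["w1"] / np.sqrt(self.d)
        out["w2"] = out["w2"] / np.sqrt(self.c_units)
        return out

    def _logits(self, params, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.d:
            raise ValueError(
                f"feature length {x.shape[1]} does not match topology {self.d}"
            )
        pre = x @ params["w1"].T + params["b1"]
        s = np.maximum(pre, 0.0)
        c = s.reshape(x.shape[0], self.c_units, self.pool).max(axis=2)
        return c @ params["w2"].T + params["b2"]

    def forward(self, params: dict[str, np.ndarray], x: np.ndarray) -> np.ndarray:
        """Per-class scores in (0, 1) for standardized inputs.

        Independent logistic outputs by default; the softmax variant couples
        the classes through a shared normalizer.
        """
        logits = self._logits(params, x)
        if self.output == "softmax":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-logits))

    def loss(self, params, x, y_onehot) -> float:
        """Training loss: mean per-class binary cross-entropy of the
        logistic outputs, or mean categorical cross-entropy under softmax."""
        p = np.clip(self.forward(params, x), _EPS, 1.0 - _EPS)
        if self.output == "softmax":
            return float(-np.mean(np.sum(y_onehot * np.log(p), axis=1)))
        return float(
            -np.mean(y_onehot * np.log(p) + (1.0 - y_onehot) * np.log(1.0 - p))
        )

    def gradients(self, params, x, y_onehot) -> dict[str, np.ndarray]:
        """Analytic gradients of the training loss."""
        x = np.atleast_2d(x)
        n = x.shape[0]
        pre = x @ params["w1"].T + params["b1"]
        s = np.maximum(pre, 0.0)
        sg = s.reshape(n, self.c_units, self.pool)
        c = sg.max(axis=2)
        logits = c @ params["w2"].T + params["b2"]
        if self.output == "softmax":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            p = e / e.sum(axis=1, keepdims=True)
            dlogits = (p - y_onehot) / n
        else:
            p = 1.0 / (1.0 + np.exp(-logits))
            dlogits = (p - y_onehot) / (n * self.k)
        g = {
            "w2": dlogits.T @ c,
            "b2": dlogits.sum(axis=0),
        }
        dc = dlogits @ params["w2"]
        # route pooled gradient to the winning S-unit of each group
        winners = sg.argmax(axis=2)
        ds = np.zeros((n, self.s_units))
        rows = np.repeat(np.arange(n), self.c_units)
        groups = np.tile(np.arange(self.c_units), n)
        cols = groups * self.pool + winners.ravel()
        ds[rows, cols] = dc.ravel()
        dpre = ds * (pre > 0)
        g["w1"] = dpre.T @ x
        g["b1"] = dpre.sum(axis=0)
        return g


# ---------------------------------------------------------------------------
# model / results


class EGNNN:
    """Gravitational-neocognitron classifier model.

    Parameters
    ----------
    features : (n, d) array
        Feature matrix; standardized internally with train-set z-scores.
    labels : (n,) array of str or int
        Class labels; class order is taken from ``class_names`` when given,
        otherwise sorted unique labels.
    s_units, pool : int
        S-layer width and C-layer max-pool group size.
    """

    def __init__(self, features, labels, s_units: int = 32, pool: int = 2,
                 class_names=None, output: str = "sigmoid"):
        x = np.asarray(features, dtype=float)
        if x.ndim != 2:
            raise ValueError("features must be a 2D array")
        labels = np.asarray(labels)
        if class_names is None:
            class_names = [str(c) for c in np.unique(labels)]
        if len(class_names) < 2:
            raise ValueError("training set must contain at least 2 classes")
        self.class_names = list(class_names)
        index = {c: i for i, c in enumerate(self.class_names)}
        try:
            self.y = np.array([index[str(v)] for v in labels])
        except KeyError as e:
            raise ValueError(f"label {e} not in class_names") from None
        self.mu = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sigma = np.where(sd > 0, sd, 1.0)
        self.x = (x - self.mu) / self.sigma
        self.topology = _Topology(
            x.shape[1], len(self.class_names), s_units, pool, output
        )
        self.onehot = np.eye(len(self.class_names))[self.y]

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label", **kwargs) -> "EGNNN":
        feats = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(feats, df[label_col].to_numpy(), **kwargs)

    def _standardize(self, features) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mu) / self.sigma

    def fit(self, config: GravConfig | None = None) -> "EGNNNResults":
        """Run the gravitational population phase, then the gradient polish.

        Fitness is the full-training-set loss, which keeps the elitist
        best-loss trace exactly monotone; mini-batches enter only through
        the polish phase.  Fully deterministic for a fixed config seed.
        """
        cfg = config if config is not None else GravConfig()
        rng = np.random.default_rng(cfg.seed)
        topo = self.topology
        n_pop, m = cfg.population, topo.n_params

        positions = rng.uniform(0.0, 1.0, size=(n_pop, m))
        velocities = np.zeros((n_pop, m))
        losses = np.array(
            [topo.loss(topo.decode(p), self.x, self.onehot) for p in positions]
        )
        best_i = int(np.argmin(losses))
        best_pos = positions[best_i].copy()
        best_loss = float(losses[best_i])
        trace = [best_loss]

        for a in range(cfg.iterations):
            mass, q = compute_masses(losses)
            c = gravitational_constant(cfg.c0, cfg.beta, a, cfg.iterations)
            forces = total_forces(
                positions, q, c, rng, cfg.dist_exponent, cfg.rho
            )
            positions, velocities = update_agents(
                positions, velocities, forces, mass, rng
            )
            losses = np.array(
                [topo.loss(topo.decode(p), self.x, self.onehot) for p in positions]
            )
            it_best = int(np.argmin(losses))
            if losses[it_best] < best_loss:
                best_loss = float(losses[it_best])
                best_pos = positions[it_best].copy()
            trace.append(best_loss)

        # polish the elite agents: the population supplies several distinct
        # near-optima whose polished variants form a score-averaging ensemble
        order = np.argsort(losses)
        elite_pos = [best_pos] + [
            positions[i] for i in order if not np.array_equal(positions[i], best_pos)
        ]
        n_members = max(1, min(cfg.n_polish, len(elite_pos)))
        members: list[dict[str, np.ndarray]] = []
        polish_trace: list[float] = []
        if cfg.polish_epochs > 0:
            streams = np.random.SeedSequence(cfg.seed + 1).spawn(n_members)
            for pos, stream in zip(elite_pos[:n_members], streams):
                p, ptrace = self._polish(
                    topo.decode(pos), cfg, np.random.default_rng(stream)
                )
                members.append(p)
                if not polish_trace:
                    polish_trace = ptrace
        else:
            members = [topo.decode(best_pos)]

        member_losses = [topo.loss(p, self.x, self.onehot) for p in members]
        best_member = int(np.argmin(member_losses))
        best_loss = min(best_loss, member_losses[best_member])

        return EGNNNResults(
            model=self,
            params=members[best_member],
            members=members,
            best_loss=best_loss,
            trace=trace,
            polish_trace=polish_trace,
            config=cfg,
        )

    def _polish(self, params, cfg: GravConfig, rng) -> tuple[dict, list[float]]:
        """Mini-batch SGD refinement with the step-decayed learning rate.

        A held-out fraction of the training set selects the epoch to keep
        (early stopping), mirroring the validation-fold model selection of
        the cross-validation protocol; with ``validation_fraction=0`` the
        lowest-training-loss epoch wins instead.
        """
        topo = self.topology
        params = {k: v.copy() for k, v in params.items()}
        n = self.x.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        order0 = rng.permutation(n)
        val_idx, fit_idx = order0[:n_val], order0[n_val:]
        if fit_idx.size == 0:
            fit_idx, val_idx = order0, order0[:0]
        x_fit, y_fit = self.x[fit_idx], self.onehot[fit_idx]
        x_sel = self.x[val_idx] if val_idx.size else x_fit
        y_sel = self.onehot[val_idx] if val_idx.size else y_fit

        best = {k: v.copy() for k, v in params.items()}
        best_sel = topo.loss(params, x_sel, y_sel)
        trace = [topo.loss(params, self.x, self.onehot)]
        for epoch in range(cfg.polish_epochs):
            lr = cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)
            order = rng.permutation(fit_idx.size)
            for start in range(0, fit_idx.size, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                g = topo.gradients(params, x_fit[idx], y_fit[idx])
                # sum-over-batch-and-classes gradient convention, so the
                # small configured step size produces useful updates
                scale = len(idx) * topo.k
                for k in params:
                    params[k] -= lr * scale * (g[k] + cfg.weight_decay * params[k])
            trace.append(topo.loss(params, self.x, self.onehot))
            sel = topo.loss(params, x_sel, y_sel)
            if sel < best_sel:
                best_sel = sel
                best = {k: v.copy() for k, v in params.items()}
        return best, trace


@dataclass
class EGNNNResults:
    """Fitted classifier: estimates, diagnostics, prediction."""

    model: EGNNN
    params: dict[str, np.ndarray]
    best_loss: float
    members: list[dict] = field(default_factory=list)
    trace: list[float] = field(default_factory=list)
    polish_trace: list[float] = field(default_factory=list)
    config: GravConfig | None = None

    def scores(self, features) -> np.ndarray:
        """Per-class logistic scores in (0, 1).

        With an elite ensemble (several polished population agents) the
        member scores are averaged; otherwise the single best agent scores.
        """
        x = self.model._standardize(features)
        members = self.members if self.members else [self.params]
        return np.mean(
            [self.model.topology.forward(p, x) for p in members], axis=0
        )

    def predict(self, features) -> np.ndarray:
        """Class labels: argmax score, ties resolved to the lowest index."""
        idx = np.argmax(self.scores(features), axis=1)
        return np.array([self.model.class_names[i] for i in idx])

    def loss(self, features, labels) -> float:
        index = {c: i for i, c in enumerate(self.model.class_names)}
        y = np.array([index[str(v)] for v in np.asarray(labels)])
        onehot = np.eye(len(self.model.class_names))[y]
        return self.model.topology.loss(
            self.params, self.model._standardize(features), onehot
        )

    def accuracy(self, features, labels) -> float:
        pred = self.predict(features)
        return float(np.mean(pred == np.asarray(labels).astype(str)))

    def summary(self) -> str:
        topo = self.model.topology
        lines = [
            "EGNNN classification results",
            "=" * 44,
            f"classes:            {', '.join(self.model.class_names)}",
            f"n observations:     {self.model.x.shape[0]}",
            f"n features:         {topo.d}",
            f"S-layer units:      {topo.s_units} (pool {topo.pool} -> "
            f"{topo.c_units} C-units)",
            f"parameters:         {topo.n_params}",
            f"population phase:   {len(self.trace) - 1} iterations, "
            f"best loss {self.trace[-1]:.6f}" if self.trace else "",
            f"polish phase:       {max(len(self.polish_trace) - 1, 0)} epochs, "
            f"final loss {self.polish_trace[-1]:.6f}"
            if self.polish_trace
            else "polish phase:       disabled",
            f"training loss:      {self.best_loss:.6f}",
            f"training accuracy:  {self.accuracy(self.model.x * self.model.sigma + self.model.mu, np.array(self.model.class_names)[self.model.y]):.4f}",
            "=" * 44,
        ]
        return "\n".join(line for line in lines if line)


def random_search(
    features, labels, n_evals: int, seed: int = 0, s_units: int = 32,
    pool: int = 2, class_names=None,
) -> EGNNNResults:
    """Pure random-search baseline with the same evaluation budget.

    Samples agent positions uniformly in the unit box and keeps the best;
    used to benchmark the gravitational update against unguided search.
    """
    model = EGNNN(features, labels, s_units=s_units, pool=pool,
                  class_names=class_names)
    topo = model.topology
    rng = np.random.default_rng(seed)
    best_pos, best_loss = None, np.inf
    for _ in range(n_evals):
        p = rng.uniform(0.0, 1.0, size=topo.n_params)
        loss = topo.loss(topo.decode(p), model.x, model.onehot)
        if loss < best_loss:
            best_loss, best_pos = loss, p
    return EGNNNResults(
        model=model, params=topo.decode(best_pos), best_loss=float(best_loss)
    )
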