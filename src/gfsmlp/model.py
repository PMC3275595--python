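"""Group-feature-selecting multilayer perceptron (GFSMLP).

A three-layer perceptron whose input features are partitioned into
contiguous groups (here: the 20 positional values of one propensity
scale).  Every group ``i`` passes through a multiplicative attenuator gate

    G_i = sigmoid(lambda_i)  in  [0, 1]

before entering the network, so ``G_i = 0`` shuts the whole group out and
``G_i = 1`` lets it through unaltered.  The gate parameters ``lambda_i``
are trained jointly with the network weights by gradient descent on the
squared classification error — with their own learning rate ``mu`` — so
that gates of useful groups open and gates of useless groups stay shut.
Selecting whole groups this way is what ordinary per-feature selection
cannot do when a block of features only makes sense as a unit.

Training is per-pattern (online) gradient descent with a seeded shuffle
each sweep; a batch mode is available.  All runs are exactly reproducible
from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .preprocess import Dataset
from .scales import NormalizedScale

LAMBDA_CLAMP = 30.0  # |lambda| bound; sigmoid(30) is 1 to within 1e-13

# Per-group gate initialisation codes
GATE_NEARLY_CLOSED = "nearly_closed"  # trainable, G = g0
GATE_CLOSED = "closed"                # frozen at exactly G = 0
GATE_OPEN = "open"                    # frozen at exactly G = 1
GATE_OPEN_TRAINABLE = "open_trainable"  # trainable, G = 1 - g0


def gate_value(lam: float | np.ndarray) -> float | np.ndarray:
    """Logistic gate G(lambda) = 1/(1+exp(-lambda)); monotone, in [0, 1]."""
    from scipy.special import expit

    return expit(np.asarray(lam, dtype=float))


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of a GFSMLP training run.

    eta : learning rate for network weights and biases (dimensionless)
    mu : learning rate for the gate parameters lambda; mu = 0 freezes all
        gates exactly
    n_hidden : hidden-layer width
    iterations : number of full sweeps over the training data
    g0 : gate opening used for "nearly closed" initialisation
    mode : "online" (per-pattern updates, seeded shuffle per sweep) or
        "batch" (one accumulated update per sweep)
    """

    eta: float = 0.2
    mu: float = 0.1
    n_hidden: int = 15
    iterations: int = 2000
    g0: float = 0.05
    mode: str = "online"

    def __post_init__(self) -> None:
        if self.eta < 0 or self.mu < 0:
            raise ValueError("learning rates must be non-negative")
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not 0.0 < self.g0 < 1.0:
            raise ValueError("g0 must lie strictly inside (0, 1)")
        if self.mode not in ("online", "batch"):
            raise ValueError("mode must be 'online' or 'batch'")


def gate_plan(
    n_groups: int,
    open_clamped: Sequence[int] = (),
    closed: Sequence[int] = (),
    open_trainable: Sequence[int] = (),
) -> list[str]:
    """Build a per-group gate-initialisation list from 1-based group indices.

    Groups not named default to "nearly closed" (trainable, G = g0).
    """
    plan = [GATE_NEARLY_CLOSED] * n_groups
    for spec, code in (
        (open_clamped, GATE_OPEN),
        (closed, GATE_CLOSED),
        (open_trainable, GATE_OPEN_TRAINABLE),
    ):
        for g in spec:
            if not 1 <= g <= n_groups:
                raise ValueError(f"group index {g} outside 1..{n_groups}")
            plan[g - 1] = code
    return plan


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _init_gates(plan: Sequence[str], g0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """lambda, trainable mask and frozen gate values from an init plan."""
    n = len(plan)
    lam = np.zeros(n)
    trainable = np.zeros(n, dtype=np.bool_)
    gfix = np.zeros(n)
    for i, code in enumerate(plan):
        if code == GATE_NEARLY_CLOSED:
            lam[i], trainable[i] = _logit(g0), True
        elif code == GATE_OPEN_TRAINABLE:
            lam[i], trainable[i] = _logit(1.0 - g0), True
        elif code == GATE_CLOSED:
            gfix[i] = 0.0
        elif code == GATE_OPEN:
            gfix[i] = 1.0
        else:
            raise ValueError(f"unknown gate init {code!r}")
    return lam, trainable, gfix


@njit(cache=True)
def _gates_now(lam, trainable, gfix):
    n = lam.shape[0]
    G = np.empty(n)
    for i in range(n):
        if trainable[i]:
            G[i] = 1.0 / (1.0 + np.exp(-lam[i]))
        else:
            G[i] = gfix[i]
    return G


@njit(cache=True)
def _train_online(X, y, W1, b1, w2, b2, lam, trainable, gfix,
                  group_size, eta, mu, iterations, shuffle_seed):
    """Per-pattern backprop through the gated input layer. Mutates parameters."""
    n, d = X.shape
    H = b1.shape[0]
    n_groups = lam.shape[0]
    loss = np.zeros(iterations)
    np.random.seed(shuffle_seed)
    idx = np.arange(n)
    z = np.empty(d)
    h = np.empty(H)
    dh = np.empty(H)
    lam_grad = np.empty(n_groups)
    for it in range(iterations):
        for i in range(n - 1, 0, -1):  # Fisher-Yates shuffle
            j = np.random.randint(0, i + 1)
            tmp = idx[i]
            idx[i] = idx[j]
            idx[j] = tmp
        sse = 0.0
        for k in range(n):
            p = idx[k]
            G = _gates_now(lam, trainable, gfix)
            for l in range(d):
                z[l] = G[l // group_size] * X[p, l]
            for j in range(H):
                s = b1[j]
                for l in range(d):
                    s += W1[j, l] * z[l]
                h[j] = 1.0 / (1.0 + np.exp(-s))
            s = b2[0]
            for j in range(H):
                s += w2[j] * h[j]
            o = 1.0 / (1.0 + np.exp(-s))
            e = y[p] - o
            sse += e * e
            do = e * o * (1.0 - o)
            for j in range(H):
                dh[j] = do * w2[j] * h[j] * (1.0 - h[j])
            if mu > 0.0:
                for g in range(n_groups):
                    lam_grad[g] = 0.0
                for l in range(d):
                    g = l // group_size
                    if trainable[g]:
                        s = 0.0
                        for j in range(H):
                            s += dh[j] * W1[j, l]
                        lam_grad[g] += s * X[p, l]
            # weight updates (use pre-update activations and gates)
            b2[0] += eta * do
            for j in range(H):
                w2[j] += eta * do * h[j]
                b1[j] += eta * dh[j]
                for l in range(d):
                    W1[j, l] += eta * dh[j] * z[l]
            if mu > 0.0:
                for g in range(n_groups):
                    if trainable[g]:
                        lam[g] += mu * lam_grad[g] * G[g] * (1.0 - G[g])
                        if lam[g] > LAMBDA_CLAMP:
                            lam[g] = LAMBDA_CLAMP
                        elif lam[g] < -LAMBDA_CLAMP:
                            lam[g] = -LAMBDA_CLAMP
        loss[it] = sse / n
    return loss


@njit(cache=True)
def _train_batch(X, y, W1, b1, w2, b2, lam, trainable, gfix,
                 group_size, eta, mu, iterations):
    """Full-batch variant: gradients accumulated over all patterns per sweep."""
    n, d = X.shape
    H = b1.shape[0]
    n_groups = lam.shape[0]
    loss = np.zeros(iterations)
    z = np.empty(d)
    h = np.empty(H)
    dh = np.empty(H)
    for it in range(iterations):
        G = _gates_now(lam, trainable, gfix)
        gW1 = np.zeros((H, d))
        gb1 = np.zeros(H)
        gw2 = np.zeros(H)
        gb2 = 0.0
        glam = np.zeros(n_groups)
        sse = 0.0
        for p in range(n):
            for l in range(d):
                z[l] = G[l // group_size] * X[p, l]
            for j in range(H):
                s = b1[j]
                for l in range(d):
                    s += W1[j, l] * z[l]
                h[j] = 1.0 / (1.0 + np.exp(-s))
            s = b2[0]
            for j in range(H):
                s += w2[j] * h[j]
            o = 1.0 / (1.0 + np.exp(-s))
            e = y[p] - o
            sse += e * e
            do = e * o * (1.0 - o)
            gb2 += do
            for j in range(H):
                gw2[j] += do * h[j]
                dh[j] = do * w2[j] * h[j] * (1.0 - h[j])
                gb1[j] += dh[j]
                for l in range(d):
                    gW1[j, l] += dh[j] * z[l]
            if mu > 0.0:
                for l in range(d):
                    g = l // group_size
                    if trainable[g]:
                        s = 0.0
                        for j in range(H):
                            s += dh[j] * W1[j, l]
                        glam[g] += s * X[p, l]
        b2[0] += eta * gb2
        for j in range(H):
            w2[j] += eta * gw2[j]
            b1[j] += eta * gb1[j]
            for l in range(d):
                W1[j, l] += eta * gW1[j, l]
        if mu > 0.0:
            for g in range(n_groups):
                if trainable[g]:
                    lam[g] += mu * glam[g] * G[g] * (1.0 - G[g])
                    if lam[g] > LAMBDA_CLAMP:
                        lam[g] = LAMBDA_CLAMP
                    elif lam[g] < -LAMBDA_CLAMP:
                        lam[g] = -LAMBDA_CLAMP
        loss[it] = sse / n
    return loss


class GFSMLP:
    """Gated group-selecting MLP classifier over grouped feature vectors.

    Parameters
    ----------
    endog : array of 0/1 class labels, length n
    exog : (n, n_groups*group_size) feature matrix, group-major layout
    group_size : features per group (20 for propensity-encoded 20-mers)
    group_names : optional labels for the groups (e.g. scale names)
    """

    def __init__(
        self,
        endog,
        exog,
        group_size: int = 20,
        group_names: Sequence[str] | None = None,
    ):
        self.endog = np.asarray(endog, dtype=np.float64).ravel()
        self.exog = np.ascontiguousarray(exog, dtype=np.float64)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-D with one row per label")
        if self.exog.shape[0] == 0:
            raise ValueError("empty dataset")
        if self.exog.shape[1] % group_size:
            raise ValueError(
                f"feature count {self.exog.shape[1]} is not a multiple of "
                f"group_size {group_size}"
            )
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        self.group_size = int(group_size)
        self.n_groups = self.exog.shape[1] // self.group_size
        if group_names is not None and len(group_names) != self.n_groups:
            raise ValueError("group_names length must equal the number of groups")
        self.group_names = list(group_names) if group_names is not None else [
            f"group_{i + 1}" for i in range(self.n_groups)
        ]

    @classmethod
    def from_dataset(
        cls, dataset: Dataset, scales: Sequence[NormalizedScale] | None = None
    ) -> "GFSMLP":
        """Propensity-encode a labelled peptide dataset and wrap it as a model."""
        from .encoding import encode_dataset
        from .scales import builtin_normalized_scales

        if scales is None:
            scales = builtin_normalized_scales()
        X, y = encode_dataset(dataset, scales)
        return cls(y, X, group_size=len(dataset.sequences[0]),
                   group_names=[s.name for s in scales])

    def fit(
        self,
        config: TrainingConfig | None = None,
        gate_init: Sequence[str] | None = None,
        seed: int | None = None,
        **overrides,
    ) -> "GFSMLPResults":
        """Train weights and gates; returns a :class:`GFSMLPResults`.

        ``gate_init`` is a per-group list of codes ("nearly_closed",
        "closed", "open", "open_trainable"); default all nearly closed.
        Keyword overrides (eta, mu, n_hidden, iterations, g0, mode) update
        ``config``.
        """
        config = replace(config or TrainingConfig(), **overrides)
        plan = list(gate_init) if gate_init is not None else gate_plan(self.n_groups)
        if len(plan) != self.n_groups:
            raise ValueError("gate_init length must equal the number of groups")
        lam, trainable, gfix = _init_gates(plan, config.g0)

        rng = np.random.default_rng(seed)
        H, d = config.n_hidden, self.exog.shape[1]
        W1 = rng.uniform(-0.3, 0.3, size=(H, d))
        b1 = rng.uniform(-0.3, 0.3, size=H)
        w2 = rng.uniform(-0.3, 0.3, size=H)
        b2 = rng.uniform(-0.3, 0.3, size=1)
        shuffle_seed = int(rng.integers(0, 2**31 - 1))

        if config.iterations == 0:
            loss = np.zeros(0)
        elif config.mode == "online":
            loss = _train_online(
                self.exog, self.endog, W1, b1, w2, b2, lam, trainable, gfix,
                self.group_size, config.eta, config.mu, config.iterations,
                shuffle_seed,
            )
        else:
            loss = _train_batch(
                self.exog, self.endog, W1, b1, w2, b2, lam, trainable, gfix,
                self.group_size, config.eta, config.mu, config.iterations,
            )
        return GFSMLPResults(
            model=self, config=config, gate_plan_=plan, seed=seed,
            W1=W1, b1=b1, w2=w2, b2=b2,
            lam=lam, trainable=trainable, gfix=gfix,
            loss_trace=loss,
        )


@dataclass
class GFSMLPResults:
    """Fitted GFSMLP: terminal weights, gate states and the loss trace."""

    model: GFSMLP
    config: TrainingConfig
    gate_plan_: list[str]
    seed: int | None
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    lam: np.ndarray
    trainable: np.ndarray
    gfix: np.ndarray
    loss_trace: np.ndarray = field(repr=False, default=None)

    @property
    def gates(self) -> np.ndarray:
        """Terminal gate openings G_i in [0, 1], one per group."""
        G = gate_value(self.lam)
        return np.where(self.trainable, G, self.gfix)

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Network output scores in (0, 1) for each row of ``exog``."""
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, float))
        G = self.gates
        mask = np.repeat(G, self.model.group_size)
        hidden = 1.0 / (1.0 + np.exp(-((X * mask) @ self.W1.T + self.b1)))
        return 1.0 / (1.0 + np.exp(-(hidden @ self.w2 + self.b2[0])))

    def predict_class(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Hard 0/1 decisions: score thresholded at 0.5."""
        return (self.predict(exog) >= 0.5).astype(np.int64)

    def selected_groups(self, threshold: float = 0.5) -> set[int]:
        """1-based indices of groups whose terminal gate is >= ``threshold``."""
        return {i + 1 for i, g in enumerate(self.gates) if g >= threshold}

    def misclassification_rate(
        self, exog: np.ndarray | None = None, endog: np.ndarray | None = None
    ) -> float:
        """Percentage of wrong decisions (0..100); training data by default."""
        y = self.model.endog if endog is None else np.asarray(endog).ravel()
        if y.size == 0:
            raise ValueError("empty evaluation set")
        pred = self.predict_class(exog)
        return 100.0 * float(np.mean(pred != y))

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "GFSMLP fit summary",
            "==================",
            f"observations: {self.model.endog.size}   features: {self.model.exog.shape[1]} "
            f"({self.model.n_groups} groups x {self.model.group_size})",
            f"eta={cfg.eta} mu={cfg.mu} n_hidden={cfg.n_hidden} "
            f"iterations={cfg.iterations} mode={cfg.mode} seed={self.seed}",
            "",
            f"{'group':<28}{'init':<16}{'gate':>8}  selected",
            "-" * 62,
        ]
        sel = self.selected_groups()
        for i, (name, code, g) in enumerate(
            zip(self.model.group_names, self.gate_plan_, self.gates), start=1
        ):
            lines.append(f"{i}. {name:<25}{code:<16}{g:>8.4f}  {'yes' if i in sel else 'no'}")
        if self.loss_trace is not None and self.loss_trace.size:
            lines += [
                "",
                f"mean squared error: first sweep {self.loss_trace[0]:.4f}, "
                f"last sweep {self.loss_trace[-1]:.4f}",
                f"training misclassification: {self.misclassification_rate():.2f}%",
            ]
        return "\n".join(lines)

    # -- checkpointing -----------------------------------------------------

    def to_json(self, path) -> None:
        """Write a flat JSON checkpoint (gates, weights, config, seed)."""
        import json

        doc = {
            "config": {
                "eta": self.config.eta, "mu": self.config.mu,
                "n_hidden": self.config.n_hidden,
                "iterations": self.config.iterations,
                "g0": self.config.g0, "mode": self.config.mode,
            },
            "seed": self.seed,
            "gate_plan": self.gate_plan_,
            "group_size": self.model.group_size,
            "group_names": self.model.group_names,
            "lam": self.lam.tolist(),
            "trainable": self.trainable.astype(int).tolist(),
            "gfix": self.gfix.tolist(),
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path, model: GFSMLP) -> "GFSMLPResults":
        """Reload a checkpoint written by :meth:`to_json` onto a model."""
        import json

        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            model=model,
            config=TrainingConfig(**doc["config"]),
            gate_plan_=list(doc["gate_plan"]),
            seed=doc["seed"],
            W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
            w2=np.array(doc["w2"]), b2=np.array(doc["b2"]),
            lam=np.array(doc["lam"]),
            trainable=np.array(doc["trainable"], dtype=bool),
            gfix=np.array(doc["gfix"]),
            loss_trace=np.zeros(0),
        )
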