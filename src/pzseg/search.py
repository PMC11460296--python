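"""Sequential Bayesian optimisation of the 12-component hyperparameter vector.

The search minimises the validation Dice loss of partially trained candidate
networks.  Surrogate: Gaussian process with a Matern-5/2 kernel (categoricals
one-hot encoded, integers rounded); acquisition: expected improvement
maximised over a random candidate pool.  Warm-up proposals are uniform draws
from the search space.  Each iteration proposes a vector, trains the network
for a small epoch budget, records ``(lambda_t, L_t)`` in the trial history,
and refits the surrogate; the output is the history's argmin.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .metrics import LossConfig
from .network import HyperparamVector, build_network
from .training import TrainSchedule, TrainingDivergedError, fit_network, evaluate_loss

__all__ = ["IntRange", "RealRange", "Categorical", "SearchSpace",
           "default_search_space", "TrialHistory", "SearchConfig", "propose",
           "fit_surrogate", "evaluate_candidate", "run_search",
           "BayesianDiceSearch"]


@dataclass(frozen=True)
class IntRange:
    lo: int
    hi: int  # inclusive

    def sample(self, rng):
        return int(rng.integers(self.lo, self.hi + 1))

    def encode(self, v):
        span = max(1, self.hi - self.lo)
        return [(float(v) - self.lo) / span]

    def width(self):
        return 1


@dataclass(frozen=True)
class RealRange:
    lo: float
    hi: float

    def sample(self, rng):
        return float(rng.uniform(self.lo, self.hi))

    def encode(self, v):
        span = max(1e-12, self.hi - self.lo)
        return [(float(v) - self.lo) / span]

    def width(self):
        return 1


@dataclass(frozen=True)
class Categorical:
    options: tuple

    def sample(self, rng):
        return self.options[int(rng.integers(len(self.options)))]

    def encode(self, v):
        return [1.0 if v == o else 0.0 for o in self.options]

    def width(self):
        return len(self.options)


class SearchSpace:
    """Cross-product of per-component domains for the 12-vector."""

    def __init__(self, components: Dict[str, object]):
        if len(components) == 0:
            raise ValueError("search space must be nonempty")
        unknown = set(components) - set(HyperparamVector.ARCH_COMPONENTS
                                        + HyperparamVector.AUG_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown hyperparameter components: {sorted(unknown)}")
        self.components = dict(components)

    def __len__(self):
        return len(self.components)

    def sample(self, rng: np.random.Generator) -> HyperparamVector:
        return HyperparamVector(**{k: d.sample(rng)
                                   for k, d in self.components.items()})

    def contains(self, hp: HyperparamVector) -> bool:
        for k, d in self.components.items():
            v = getattr(hp, k)
            if isinstance(d, Categorical):
                if v not in d.options:
                    return False
            elif not (d.lo <= v <= d.hi):
                return False
        return True

    def encode(self, hp: HyperparamVector) -> np.ndarray:
        feats: List[float] = []
        for k, d in self.components.items():
            feats.extend(d.encode(getattr(hp, k)))
        return np.asarray(feats)


def default_search_space() -> SearchSpace:
    """The default 12-component space used for both the 2D and 3D searches."""
    return SearchSpace({
        "n_blocks": Categorical((2, 3, 4)),
        "base_filters": Categorical((8, 16, 32)),
        "activation": Categorical(("relu", "elu", "leaky_relu")),
        "kernel_1": Categorical((3, 5)),
        "kernel_2": Categorical((3, 5)),
        "kernel_3": Categorical((3, 5)),
        "dropout_p": RealRange(0.0, 0.5),
        "aug_rotation_deg": RealRange(0.0, 30.0),
        "aug_width_shift": RealRange(0.0, 0.2),
        "aug_height_shift": RealRange(0.0, 0.2),
        "aug_zoom": RealRange(0.0, 0.3),
        "aug_hflip": Categorical((False, True)),
    })


@dataclass
class TrialHistory:
    """The sequence D_t of (lambda_t, L_t) pairs accumulated by the search."""

    lambdas: List[HyperparamVector] = field(default_factory=list)
    losses: List[float] = field(default_factory=list)
    wall_times: List[float] = field(default_factory=list)

    def append(self, hp: HyperparamVector, loss: float, wall: float = 0.0):
        if not np.isfinite(loss):
            raise ValueError("trial losses must be finite")
        self.lambdas.append(hp)
        self.losses.append(float(loss))
        self.wall_times.append(float(wall))

    def __len__(self):
        return len(self.lambdas)

    def best(self) -> Tuple[HyperparamVector, float]:
        i = int(np.argmin(self.losses))
        return self.lambdas[i], self.losses[i]

    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate(self.losses)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(hp.as_dict(), loss=l, wall_time_s=w)
                for hp, l, w in zip(self.lambdas, self.losses, self.wall_times)]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SearchConfig:
    """Budget and machinery of one search run.

    ``objective`` is a test seam: when given, it is called as
    ``objective(hp) -> loss`` in place of network training.
    """

    T: int = 30
    n_init: int = 5
    acquisition: str = "expected_improvement"
    surrogate: str = "gaussian_process"
    partial_epochs: int = 5
    seed: int = 0
    mode: str = "2d"
    candidate_pool: int = 1000
    schedule: TrainSchedule = field(default_factory=TrainSchedule)
    objective: Optional[Callable[[HyperparamVector], float]] = None

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (1 <= self.n_init <= self.T):
            raise ValueError("need 1 <= n_init <= T")
        if self.partial_epochs < 1:
            raise ValueError("partial_epochs must be >= 1")
        if self.acquisition != "expected_improvement":
            raise ValueError("only expected_improvement acquisition is available")
        if self.surrogate != "gaussian_process":
            raise ValueError("only the gaussian_process surrogate is available")


def fit_surrogate(history: TrialHistory, space: SearchSpace, seed: int = 0):
    """Fit the Gaussian-process surrogate to an encoded trial history."""
    X = np.stack([space.encode(h) for h in history.lambdas])
    return _fit_surrogate(X, np.asarray(history.losses), seed)


def _fit_surrogate(X: np.ndarray, y: np.ndarray, seed: int):
    # encoded features live in [0, 1]; bound the length scales accordingly
    kernel = 1.0 * Matern(length_scale=np.full(X.shape[1], 0.2),
                          length_scale_bounds=(1e-2, 1e1), nu=2.5)
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6, normalize_y=True,
                                  n_restarts_optimizer=3, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return gp


def propose(surrogate, history: TrialHistory, space: SearchSpace,
            rng: np.random.Generator, n_candidates: int = 1000) -> HyperparamVector:
    """Expected-improvement proposal over a random candidate pool.

    With an empty history (or no fitted surrogate) this is a uniform draw from
    the space -- the warm-up policy.
    """
    if len(space) == 0:
        raise ValueError("empty search space")
    if surrogate is None or len(history) == 0:
        return space.sample(rng)
    candidates = [space.sample(rng) for _ in range(n_candidates)]
    # avoid re-proposing an already evaluated point (the objective is
    # deterministic given the seed); for continuous components exact
    # collisions essentially never occur and the filter is a no-op
    seen = {tuple(space.encode(h)) for h in history.lambdas}
    fresh = [c for c in candidates if tuple(space.encode(c)) not in seen]
    if fresh:
        candidates = fresh
    X = np.stack([space.encode(c) for c in candidates])
    mu, sd = surrogate.predict(X, return_std=True)
    best = float(np.min(history.losses))
    xi = 0.01
    imp = best - mu - xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, imp / sd, 0.0)
        ei = np.where(sd > 0, imp * norm.cdf(z) + sd * norm.pdf(z),
                      np.maximum(imp, 0.0))
    return candidates[int(np.argmax(ei))]


def evaluate_candidate(hp: HyperparamVector, train_set, valid_set,
                       cfg: SearchConfig) -> float:
    """Partial-train a candidate network and return its validation loss.

    The loss is the combined Dice loss (gland + alpha * PZ) on the validation
    set, so it lies in [0, 1 + alpha].  Seeded and deterministic.  Training
    divergence is recorded as the worst loss with a warning; the search
    continues.
    """
    if cfg.objective is not None:
        return float(cfg.objective(hp))
    images = train_set[0]
    if images.shape[0] == 0 or valid_set[0].shape[0] == 0:
        raise ValueError("train and validation sets must be nonempty")
    input_shape = images.shape[1:]
    net, _ = build_network(hp, cfg.mode, input_shape, seed=cfg.seed)
    worst = 1.0 + cfg.schedule.loss.alpha
    try:
        fit_network(net, train_set, valid_set, cfg.schedule,
                    epochs=cfg.partial_epochs, seed=cfg.seed, keep_best=True)
    except TrainingDivergedError as e:
        warnings.warn(f"candidate diverged ({e}); recording worst loss")
        return worst
    loss = evaluate_loss(net, valid_set, cfg.schedule.loss)
    if not np.isfinite(loss):
        warnings.warn("non-finite validation loss; recording worst loss")
        return worst
    return float(min(loss, worst))


def run_search(space: SearchSpace, data, cfg: SearchConfig
               ) -> Tuple[HyperparamVector, TrialHistory]:
    """Sequential search: n_init random warm-up trials, then surrogate-guided
    proposals; returns the argmin of the trial history.

    ``data`` is a (train_set, valid_set) pair (ignored when ``cfg.objective``
    is injected).
    """
    rng = np.random.default_rng(cfg.seed)
    history = TrialHistory()
    surrogate = None
    train_set, valid_set = (data if data is not None else (None, None))
    for t in range(cfg.T):
        t0 = time.perf_counter()
        if t < cfg.n_init:
            hp = space.sample(rng)
        else:
            hp = propose(surrogate, history, space, rng, cfg.candidate_pool)
        loss = evaluate_candidate(hp, train_set, valid_set, cfg)
        history.append(hp, loss, time.perf_counter() - t0)
        if t + 1 >= cfg.n_init and t + 1 < cfg.T:
            X = np.stack([space.encode(h) for h in history.lambdas])
            surrogate = _fit_surrogate(X, np.asarray(history.losses), cfg.seed)
    best_hp, _ = history.best()
    return best_hp, history


class BayesianDiceSearch:
    """sklearn-style wrapper: ``fit(train_set, valid_set)`` runs the search.

    Fitted attributes: ``best_params_`` (HyperparamVector), ``history_``
    (TrialHistory), ``best_loss_``.
    """

    def __init__(self, space: Optional[SearchSpace] = None,
                 config: Optional[SearchConfig] = None):
        self.space = space
        self.config = config

    def get_params(self, deep=True):
        return {"space": self.space, "config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, train_set=None, valid_set=None):
        space = self.space if self.space is not None else default_search_space()
        cfg = self.config if self.config is not None else SearchConfig()
        best, history = run_search(space, (train_set, valid_set), cfg)
        self.best_params_ = best
        self.history_ = history
        self.best_loss_ = history.best()[1]
        return self
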