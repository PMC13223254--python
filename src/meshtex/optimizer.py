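"""Grey Wolf Optimization over mixed hyperparameter search spaces.

The pack's three best agents (alpha, beta, delta) steer every wolf; the
exploration coefficient ``a`` decays linearly from 2 to 0 over the run, so
early iterations explore and late iterations converge on the leaders.
Positions live in a continuous box; integer and categorical dimensions are
decoded by rounding, which keeps the update rule dimension-agnostic.

The canonical three-leader averaged update is the default.  ``alpha_only``
switches to the literal single-leader rule P(t+1) = P_alpha(t) - B.E for
fidelity experiments; it converges, but loses the diversity the beta and
delta leaders provide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

__all__ = ["Dimension", "SearchSpace", "GWOConfig", "OptResult",
           "initialize_pack", "update_positions", "decode_position", "optimize"]


@dataclass(frozen=True)
class Dimension:
    """One search dimension: continuous, integer, or categorical."""

    name: str
    kind: str  # "continuous" | "integer" | "categorical"
    lower: float = 0.0
    upper: float = 1.0
    categories: tuple[Any, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "categorical"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "categorical":
            if len(self.categories) < 2:
                raise ValueError("categorical dimension needs >= 2 categories")
            object.__setattr__(self, "lower", 0.0)
            object.__setattr__(self, "upper", float(len(self.categories) - 1))
        elif self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dimensions])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dimensions])

    def __len__(self) -> int:
        return len(self.dimensions)


@dataclass(frozen=True)
class GWOConfig:
    n_wolves: int = 10
    n_iters: int = 20
    seed: int = 0
    alpha_only: bool = False

    def __post_init__(self) -> None:
        if self.n_wolves < 3:
            raise ValueError("need at least 3 wolves (alpha, beta, delta)")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")


@dataclass
class OptResult:
    """Best decoded assignment, its fitness, and the per-iteration best-so-far."""

    best_params: dict[str, Any]
    best_fitness: float
    history: list[float] = field(default_factory=list)


def initialize_pack(space: SearchSpace, cfg: GWOConfig,
                    rng: np.random.Generator | None = None,
                    initial_positions: Sequence[np.ndarray] = ()) -> np.ndarray:
    """Uniform random pack within bounds; optional seeded starting positions.

    ``initial_positions`` (e.g. the encoding of a classifier's default
    hyperparameters) replace the first rows, so the best-so-far trajectory
    can never fall below the fitness of those seeds.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = space.lower, space.upper
    pack = rng.uniform(lo, hi, size=(cfg.n_wolves, len(space)))
    for k, pos in enumerate(initial_positions):
        if k >= cfg.n_wolves:
            break
        pack[k] = np.clip(np.asarray(pos, dtype=float), lo, hi)
    return pack


def _leaders(fitnesses: np.ndarray, k: int = 3) -> np.ndarray:
    """Indices of the k fittest wolves; ties broken by lowest wolf index."""
    order = np.lexsort((np.arange(len(fitnesses)), -fitnesses))
    return order[:k]


def update_positions(positions: np.ndarray, fitnesses: np.ndarray, t: int,
                     cfg: GWOConfig, space: SearchSpace,
                     rng: np.random.Generator) -> np.ndarray:
    """One GWO step: move every wolf toward the leaders and clip to bounds."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(fitnesses) != len(positions) or len(positions) < 3:
        raise ValueError("need one fitness per wolf and at least 3 wolves")
    a = 2.0 * (1.0 - t / cfg.n_iters)
    n_leaders = 1 if cfg.alpha_only else 3
    leaders = positions[_leaders(fitnesses, n_leaders)]
    n, d = positions.shape
    candidates = np.empty((n_leaders, n, d))
    for k, lead in enumerate(leaders):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        B = 2.0 * a * r1 - a            # convergence coefficient
        E = np.abs(2.0 * r2 * lead - positions)  # distance to the leader
        candidates[k] = lead - B * E
    return np.clip(candidates.mean(axis=0), space.lower, space.upper)


def decode_position(position: np.ndarray, space: SearchSpace) -> dict[str, Any]:
    """Map a continuous position to a concrete hyperparameter assignment."""
    out: dict[str, Any] = {}
    for val, dim in zip(position, space.dimensions):
        if dim.kind == "continuous":
            out[dim.name] = float(np.clip(val, dim.lower, dim.upper))
        elif dim.kind == "integer":
            out[dim.name] = int(np.clip(round(float(val)), dim.lower, dim.upper))
        else:
            idx = int(np.clip(round(float(val)), 0, len(dim.categories) - 1))
            out[dim.name] = dim.categories[idx]
    return out


def optimize(fitness: Callable[[dict[str, Any]], float], space: SearchSpace,
             cfg: GWOConfig = GWOConfig(),
             initial_positions: Sequence[np.ndarray] = ()) -> OptResult:
    """Maximise ``fitness`` over the search space with Grey Wolf Optimization.

    Total fitness evaluations: n_wolves * (n_iters + 1).  Reproducible
    under ``cfg.seed``; the returned history (best-so-far per iteration,
    including the initial pack) is non-decreasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = initialize_pack(space, cfg, rng, initial_positions)

    def evaluate(pack: np.ndarray) -> np.ndarray:
        vals = np.empty(len(pack))
        for i, pos in enumerate(pack):
            params = decode_position(pos, space)
            try:
                vals[i] = float(fitness(params))
            except Exception as exc:
                raise RuntimeError(f"fitness failed on assignment {params}") from exc
        return vals

    fitnesses = evaluate(positions)
    best_i = int(_leaders(fitnesses, 1)[0])
    best_fit = float(fitnesses[best_i])
    best_pos = positions[best_i].copy()
    history = [best_fit]

    for t in range(cfg.n_iters):
        positions = update_positions(positions, fitnesses, t, cfg, space, rng)
        fitnesses = evaluate(positions)
        it_best = int(_leaders(fitnesses, 1)[0])
        if fitnesses[it_best] > best_fit:
            best_fit = float(fitnesses[it_best])
            best_pos = positions[it_best].copy()
        history.append(best_fit)

    return OptResult(best_params=decode_position(best_pos, space),
                     best_fitness=best_fit, history=history)
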