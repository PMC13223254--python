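"""Grey Wolf Optimization on a known landscape and on a mixed space.

First maximises the negated 3-D sphere function (optimum 0 at the origin) —
the best-so-far trace is non-decreasing and closes in on the optimum.
Then tunes a mixed integer/categorical/continuous space, showing how
positions decode to concrete hyperparameter assignments.
"""

from meshtex.optimizer import Dimension, GWOConfig, SearchSpace, optimize

space = SearchSpace(tuple(
    Dimension(f"x{i}", "continuous", -5.0, 5.0) for i in range(3)))
res = optimize(lambda p: -sum(v * v for v in p.values()), space,
               GWOConfig(n_wolves=20, n_iters=100, seed=0))
print(f"sphere: best fitness {res.best_fitness:.2e} "
      f"(0 is optimal) after {20 * 101} evaluations")
print(f"best-so-far at iterations 0/10/50/100: "
      f"{[round(res.history[t], 4) for t in (0, 10, 50, 100)]}")

mixed = SearchSpace((
    Dimension("n_neighbors", "integer", 1, 15),
    Dimension("metric", "categorical", categories=("euclidean", "manhattan")),
    Dimension("weight", "continuous", 0.0, 1.0),
))
res = optimize(lambda p: -abs(p["n_neighbors"] - 7) + p["weight"], mixed,
               GWOConfig(n_wolves=8, n_iters=30, seed=1))
print(f"mixed space: best assignment {res.best_params}")
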