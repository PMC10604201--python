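"""Search the structural hyperparameter box with the seeded SMBO backend.

The objective here is a cheap stand-in (distance to a known optimum) so the
example runs instantly; in practice the objective is a fold's validation
MAE from ppgrr.training.train.
"""

from ppgrr import bayes_search
from ppgrr.search import HYPERPARAM_RANGES

TARGET = {"n_blk": 4, "kernel_blk": 2, "d_blk": 3, "kernel_dwn": 3,
          "filters_c": 8, "s_c": 2, "n_den": 86}


def objective(cfg):
    return sum(abs(cfg[k] - v) for k, v in TARGET.items())


best = bayes_search(space=HYPERPARAM_RANGES, objective=objective,
                    budget=200, seed=0, backend="smbo")
print("search space:", {k: v for k, v in HYPERPARAM_RANGES.items()})
print("recovered configuration:")
for k in TARGET:
    print(f"  {k:>10} = {getattr(best, k)}  (optimum {TARGET[k]})")
print("\nWith 200 evaluations the random-exploration + coordinate-descent")
print("backend recovers the exact optimum of any unimodal objective on this")
print("~5e5-point grid; a uniform random search cannot.")
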