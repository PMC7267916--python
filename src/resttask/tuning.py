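"""Sequential one-parameter-at-a-time hyperparameter search.

Tuning uses dedicated hyperparameter-optimisation subjects whose rows are
pooled without any parcellation: one whole-domain model is fit per
candidate value and scored by RMSE on a held-out test subset (20% of
rows; a further 20% acts as the NN validation split).  Parameters are
swept in a fixed order, each being frozen at its RMSE-minimising value
before the next sweep — equivalent to a full grid search only when the
objective is separable, which is exactly the regime the procedure
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import RpropNet
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "Hyperparams",
    "coordinate_sweep",
    "tune_nn",
    "tune_rfbag",
    "NN_DEFAULTS",
    "RFBAG_DEFAULTS",
]

#: defaults adopted after tuning on the real data: one hidden layer and a
#: learning rate of 0.001 (layer count and learning rate had little or
#: erratic effect on RMSE; hidden size is task dependent).
NN_DEFAULTS = {"hidden_size": 10, "n_layers": 1, "learning_rate": 0.001}

#: tuned real-data forest configuration: 100 trees, a third of the
#: features sampled per split, minimum leaf size 5.
RFBAG_DEFAULTS = {"n_trees": 100, "n_predictors_per_split": 33, "min_leaf": 5}


@dataclass
class Hyperparams:
    values: dict
    rmse: float
    trace: pd.DataFrame = field(repr=False, default=None)


def coordinate_sweep(
    objective: Callable[[dict], float],
    grids: dict[str, Sequence],
    defaults: dict,
) -> Hyperparams:
    """Minimise ``objective`` one parameter at a time.

    Parameters are swept in ``grids`` insertion order starting from
    ``defaults``; after each sweep the parameter is fixed at its
    minimising value.  Returns the chosen values, their objective value
    and the full (parameter, candidate, objective) trace.
    """
    if not grids or any(len(g) == 0 for g in grids.values()):
        raise ValueError("all grids must be non-empty")
    current = dict(defaults)
    rows = []
    for name, grid in grids.items():
        scores = []
        for value in grid:
            candidate = dict(current)
            candidate[name] = value
            score = objective(candidate)
            scores.append(score)
            rows.append({"parameter": name, "value": value, "rmse": score})
        scores = np.asarray(scores, dtype=float)
        if np.all(np.isnan(scores)):
            raise RuntimeError(f"all candidates for {name!r} scored NaN")
        current[name] = grid[int(np.nanargmin(scores))]
    trace = pd.DataFrame(rows)
    best = float(
        trace[trace.parameter == list(grids)[-1]].rmse.min()
        if rows
        else np.nan
    )
    return Hyperparams(values=current, rmse=best, trace=trace)


def _split_rows(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """80/20 train/test row split (the NN carves its own validation split
    out of the training portion)."""
    order = rng.permutation(n)
    n_te = max(1, int(round(0.2 * n)))
    return order[n_te:], order[:n_te]


def _subsample(x, y, max_rows, rng):
    if max_rows is not None and x.shape[0] > max_rows:
        idx = rng.choice(x.shape[0], size=max_rows, replace=False)
        return x[idx], y[idx]
    return x, y


def tune_nn(
    x: np.ndarray,
    y: np.ndarray,
    grids: dict[str, Sequence] | None = None,
    seed: int = 0,
    *,
    max_rows: int | None = 5000,
    max_epochs: int = 200,
) -> Hyperparams:
    """Tune hidden size, layer count and learning rate, in that order.

    ``x``/``y`` are the pooled rows of the hyperparameter-optimisation
    subjects.  Rows may be subsampled (seeded) to bound cost.
    """
    if grids is None:
        grids = {
            "hidden_size": list(range(1, 51)),
            "n_layers": [1, 2, 3],
            "learning_rate": list(np.arange(0.001, 0.1 + 1e-12, 0.002)),
        }
    rng = np.random.default_rng(seed)
    x, y = _subsample(x, y, max_rows, rng)
    train, test = _split_rows(x.shape[0], rng)
    net_seed = int(rng.integers(2**31))

    def objective(params: dict) -> float:
        net = RpropNet(
            hidden_size=int(params["hidden_size"]),
            n_layers=int(params["n_layers"]),
            learning_rate=float(params["learning_rate"]),
            max_epochs=max_epochs,
            seed=net_seed,
        )
        net.fit(x[train], y[train])
        pred = net.predict(x[test])
        return float(np.sqrt(np.mean((pred - y[test]) ** 2)))

    return coordinate_sweep(objective, grids, NN_DEFAULTS)


def tune_rfbag(
    x: np.ndarray,
    y: np.ndarray,
    grids: dict[str, Sequence] | None = None,
    seed: int = 0,
    *,
    max_rows: int | None = 5000,
) -> Hyperparams:
    """Tune tree count, predictors per split and minimum leaf size, in
    that order."""
    n_feat = x.shape[1]
    if grids is None:
        grids = {
            "n_trees": list(range(1, 201)),
            "n_predictors_per_split": list(range(1, n_feat)),
            "min_leaf": list(range(1, 31)),
        }
    rng = np.random.default_rng(seed)
    x, y = _subsample(x, y, max_rows, rng)
    train, test = _split_rows(x.shape[0], rng)
    forest_seed = int(rng.integers(2**31))
    defaults = dict(RFBAG_DEFAULTS)
    defaults["n_predictors_per_split"] = min(defaults["n_predictors_per_split"], n_feat)

    def objective(params: dict) -> float:
        forest = RandomForestRegressor(
            n_estimators=int(params["n_trees"]),
            max_features=min(int(params["n_predictors_per_split"]), n_feat),
            min_samples_leaf=int(params["min_leaf"]),
            bootstrap=True,
            random_state=forest_seed,
            n_jobs=1,
        )
        forest.fit(x[train], y[train])
        pred = forest.predict(x[test])
        return float(np.sqrt(np.mean((pred - y[test]) ** 2)))

    return coordinate_sweep(objective, grids, defaults)
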