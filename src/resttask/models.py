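"""Per-parcel regression models mapping connectivity features to task z-scores.

Three model families share one interface: the closed-form GLM
(``beta = pinv(X) @ y`` per parcel), a small feed-forward neural network
(tanh hidden layer(s), linear output, trained full-batch with resilient
backpropagation and early stopping on a held-out validation split), and
random-forest bootstrap aggregation (bagged regression trees with feature
subsampling at each split).

Training data is built by row-stacking the training subjects' vertices;
one predictor is fit per parcel and predictions are reassembled into a
full vertex map.  ``train_ensemble`` fits M models differing only in
their random splits/initialisations/bootstraps; ensemble prediction is
the arithmetic mean of the member maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .parcellation import Parcellation

__all__ = [
    "ParcelModel",
    "ParcelEnsemble",
    "RpropNet",
    "stack_subjects",
    "fit_glm",
    "predict_glm",
    "fit_nn",
    "fit_rfbag",
    "predict_parcel_model",
    "train_ensemble",
    "predict_ensemble",
]


@dataclass
class ParcelModel:
    """One fitted predictor per parcel."""

    kind: str  # "glm" | "nn" | "rfbag"
    predictors: dict[int, Any]  # parcel -> fitted object
    n_features: int
    hyperparams: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_parcels(self) -> int:
        return len(self.predictors)

    @property
    def beta(self) -> np.ndarray:
        """GLM coefficients as a (features x parcels) matrix."""
        if self.kind != "glm":
            raise AttributeError("beta matrix is defined for GLM models only")
        out = np.empty((self.n_features, self.n_parcels))
        for p, (b, _c) in self.predictors.items():
            out[:, p] = b
        return out


@dataclass
class ParcelEnsemble:
    """M same-kind parcel models combined by averaging predicted maps."""

    members: list[ParcelModel]

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def kind(self) -> str:
        return self.members[0].kind


def stack_subjects(
    features: list[np.ndarray], targets: list[np.ndarray], parcellation: Parcellation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-stack subjects' (vertices x F) features and vertex targets.

    Returns stacked X (N x F), y (N,), and the tiled parcel label of every
    row, aligning rows across subjects by vertex.
    """
    if len(features) != len(targets) or not features:
        raise ValueError("features and targets must be non-empty and aligned")
    x = np.vstack(features)
    y = np.concatenate(targets)
    labels = np.tile(parcellation.labels, len(features))
    if x.shape[0] != y.shape[0] or x.shape[0] != labels.shape[0]:
        raise ValueError("row mismatch between features, targets and parcellation")
    return x, y, labels


# ---------------------------------------------------------------------------
# GLM


def fit_glm(
    x: np.ndarray,
    y: np.ndarray,
    parcel_ids: np.ndarray,
    n_parcels: int,
    *,
    fit_intercept: bool = True,
) -> ParcelModel:
    """Closed-form per-parcel least squares, ``beta = pinv(X_p) @ y_p``.

    The minimum-norm solution is used when a parcel's design is rank
    deficient.  An optional per-parcel intercept absorbs the constant
    offset that z-scoring the target maps introduces (the coefficient
    matrix keeps its features x parcels shape; intercepts are stored
    separately).
    """
    predictors: dict[int, Any] = {}
    for p in range(n_parcels):
        rows = parcel_ids == p
        if not rows.any():
            raise ValueError(f"parcel {p} has no training rows")
        xp, yp = x[rows], y[rows]
        if fit_intercept:
            design = np.column_stack([xp, np.ones(xp.shape[0])])
            coef = np.linalg.lstsq(design, yp, rcond=None)[0]
            predictors[p] = (coef[:-1], float(coef[-1]))
        else:
            coef = np.linalg.lstsq(xp, yp, rcond=None)[0]
            predictors[p] = (coef, 0.0)
    return ParcelModel(
        kind="glm",
        predictors=predictors,
        n_features=x.shape[1],
        hyperparams={"fit_intercept": fit_intercept},
        meta={"n_rows": int(x.shape[0])},
    )


def predict_glm(model: ParcelModel, x: np.ndarray, parcel_ids: np.ndarray) -> np.ndarray:
    """Per-parcel linear prediction assembled into a full vertex map."""
    return predict_parcel_model(model, x, parcel_ids)


# ---------------------------------------------------------------------------
# feed-forward network with resilient backpropagation


class RpropNet:
    """Small feed-forward regression net trained with iRprop-.

    Architecture: input F -> one to three tanh hidden layers -> linear
    output.  Training is full batch; resilient backpropagation adapts a
    per-weight step size from the sign of the gradient (increase by 1.2
    when the sign persists, halve and skip the update when it flips),
    which makes training insensitive to gradient magnitude.  Rows are
    split 60/20/20 into train/validation/test; the epoch with minimum
    validation MSE is kept (patience-limited early stopping, hard epoch
    cap) and the held-out test MSE of the training data is recorded.
    """

    ETA_PLUS = 1.2
    ETA_MINUS = 0.5
    STEP_MAX = 1.0
    STEP_MIN = 1e-9

    def __init__(
        self,
        hidden_size: int = 10,
        n_layers: int = 1,
        learning_rate: float = 0.001,
        max_epochs: int = 1000,
        patience: int = 6,
        seed: int = 0,
    ):
        if not 1 <= n_layers <= 3:
            raise ValueError("n_layers must be 1..3")
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.history_: dict[str, Any] = {}

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features] + [self.hidden_size] * self.n_layers + [1]
        ws, bs = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            ws.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            bs.append(np.zeros(fan_out))
        return ws, bs

    def _forward(self, x, ws, bs):
        acts = [x]
        h = x
        for w, b in zip(ws[:-1], bs[:-1]):
            h = np.tanh(h @ w + b)
            acts.append(h)
        acts.append(h @ ws[-1] + bs[-1])
        return acts

    def _gradients(self, x, y, ws, bs):
        n = x.shape[0]
        acts = self._forward(x, ws, bs)
        delta = 2.0 * (acts[-1] - y[:, None]) / n
        gw, gb = [None] * len(ws), [None] * len(ws)
        for layer in range(len(ws) - 1, -1, -1):
            gw[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ ws[layer].T) * (1.0 - acts[layer] ** 2)
        mse = float(np.mean((acts[-1][:, 0] - y) ** 2))
        return gw, gb, mse

    def _mse(self, x, y, ws, bs):
        pred = self._forward(x, ws, bs)[-1][:, 0]
        return float(np.mean((pred - y) ** 2))

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RpropNet":
        rng = np.random.default_rng(self.seed)
        n = x.shape[0]
        order = rng.permutation(n)
        n_tr = max(1, int(round(0.6 * n)))
        n_val = max(1, int(round(0.2 * n)))
        tr, val, te = (
            order[:n_tr],
            order[n_tr : n_tr + n_val],
            order[n_tr + n_val :],
        )
        if te.size == 0:
            te = val
        ws, bs = self._init_params(x.shape[1], rng)
        steps_w = [np.full_like(w, self.learning_rate) for w in ws]
        steps_b = [np.full_like(b, self.learning_rate) for b in bs]
        prev_gw = [np.zeros_like(w) for w in ws]
        prev_gb = [np.zeros_like(b) for b in bs]
        best = (np.inf, [w.copy() for w in ws], [b.copy() for b in bs], 0)
        val_trace = []
        stall = 0
        for epoch in range(1, self.max_epochs + 1):
            gw, gb, train_mse = self._gradients(x[tr], y[tr], ws, bs)
            if not np.isfinite(train_mse):
                raise FloatingPointError("non-finite training loss")
            for i in range(len(ws)):
                for g, pg, step, param in (
                    (gw[i], prev_gw[i], steps_w[i], ws[i]),
                    (gb[i], prev_gb[i], steps_b[i], bs[i]),
                ):
                    sign = np.sign(g * pg)
                    step[sign > 0] = np.minimum(step[sign > 0] * self.ETA_PLUS, self.STEP_MAX)
                    step[sign < 0] = np.maximum(step[sign < 0] * self.ETA_MINUS, self.STEP_MIN)
                    g[sign < 0] = 0.0  # iRprop-: forget flipped gradients
                    param -= np.sign(g) * step
                    pg[...] = g
            val_mse = self._mse(x[val], y[val], ws, bs)
            val_trace.append(val_mse)
            if val_mse < best[0]:
                best = (val_mse, [w.copy() for w in ws], [b.copy() for b in bs], epoch)
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.weights_, self.biases_ = best[1], best[2]
        self.history_ = {
            "val_mse": np.array(val_trace),
            "best_epoch": best[3],
            "best_val_mse": best[0],
            "final_val_mse": val_trace[-1],
            "test_mse": self._mse(x[te], y[te], self.weights_, self.biases_),
            "n_epochs": len(val_trace),
        }
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("net is not fitted")
        return self._forward(x, self.weights_, self.biases_)[-1][:, 0]


def fit_nn(
    x: np.ndarray,
    y: np.ndarray,
    parcel_ids: np.ndarray,
    n_parcels: int,
    *,
    hidden_size: int = 10,
    n_layers: int = 1,
    learning_rate: float = 0.001,
    max_epochs: int = 1000,
    patience: int = 6,
    seed: int = 0,
) -> ParcelModel:
    """Fit one early-stopped Rprop network per parcel."""
    rng = np.random.default_rng(seed)
    predictors: dict[int, Any] = {}
    for p in range(n_parcels):
        rows = parcel_ids == p
        if not rows.any():
            raise ValueError(f"parcel {p} has no training rows")
        net = RpropNet(
            hidden_size=hidden_size,
            n_layers=n_layers,
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            patience=patience,
            seed=int(rng.integers(2**31)),
        )
        predictors[p] = net.fit(x[rows], y[rows])
    return ParcelModel(
        kind="nn",
        predictors=predictors,
        n_features=x.shape[1],
        hyperparams={
            "hidden_size": hidden_size,
            "n_layers": n_layers,
            "learning_rate": learning_rate,
            "max_epochs": max_epochs,
            "patience": patience,
        },
        meta={"seed": seed, "init": "uniform-glorot", "n_rows": int(x.shape[0])},
    )


# ---------------------------------------------------------------------------
# random-forest bagging


def fit_rfbag(
    x: np.ndarray,
    y: np.ndarray,
    parcel_ids: np.ndarray,
    n_parcels: int,
    *,
    n_trees: int = 100,
    n_predictors_per_split: int | None = None,
    min_leaf: int = 5,
    bootstrap: bool = True,
    seed: int = 0,
) -> ParcelModel:
    """Bagged regression trees with feature subsampling per split.

    Defaults follow the tuned real-data configuration: 100 trees, a third
    of the features sampled per split, minimum leaf size 5.
    """
    n_feat = x.shape[1]
    if n_predictors_per_split is None:
        n_predictors_per_split = max(1, n_feat // 3)
    if not 1 <= n_predictors_per_split <= n_feat:
        raise ValueError("n_predictors_per_split must be in [1, n_features]")
    rng = np.random.default_rng(seed)
    predictors: dict[int, Any] = {}
    for p in range(n_parcels):
        rows = parcel_ids == p
        if not rows.any():
            raise ValueError(f"parcel {p} has no training rows")
        if min_leaf > rows.sum():
            raise ValueError(f"min_leaf={min_leaf} exceeds rows of parcel {p}")
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=n_predictors_per_split,
            min_samples_leaf=min_leaf,
            bootstrap=bootstrap,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        predictors[p] = forest.fit(x[rows], y[rows])
    return ParcelModel(
        kind="rfbag",
        predictors=predictors,
        n_features=n_feat,
        hyperparams={
            "n_trees": n_trees,
            "n_predictors_per_split": n_predictors_per_split,
            "min_leaf": min_leaf,
            "bootstrap": bootstrap,
        },
        meta={"seed": seed, "n_rows": int(x.shape[0])},
    )


# ---------------------------------------------------------------------------
# prediction and ensembling


def predict_parcel_model(model: ParcelModel, x: np.ndarray, parcel_ids: np.ndarray) -> np.ndarray:
    """Predict a full vertex map, each vertex written once by its parcel."""
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match training ({model.n_features})"
        )
    if x.shape[0] != parcel_ids.shape[0]:
        raise ValueError("x rows and parcel_ids must align")
    out = np.zeros(x.shape[0])
    for p, pred in model.predictors.items():
        rows = parcel_ids == p
        if not rows.any():
            continue
        if model.kind == "glm":
            beta, intercept = pred
            out[rows] = x[rows] @ beta + intercept
        else:
            out[rows] = pred.predict(x[rows])
    return out


_FITTERS = {"glm": fit_glm, "nn": fit_nn, "rfbag": fit_rfbag}


def train_ensemble(
    kind: str,
    features: list[np.ndarray],
    targets: list[np.ndarray],
    parcellation: Parcellation,
    hyperparams: dict | None = None,
    m: int = 1,
    seed: int = 0,
    *,
    max_retries: int = 3,
) -> ParcelEnsemble:
    """Train M independent models of one kind on stacked training data.

    Members differ only in their random seeds (splits, initialisations,
    bootstraps); a failed member is retrained with the next derived seed,
    a bounded number of times.
    """
    if kind not in _FITTERS:
        raise ValueError(f"unknown model kind {kind!r}")
    if m < 1:
        raise ValueError("m must be >= 1")
    hyperparams = dict(hyperparams or {})
    x, y, labels = stack_subjects(features, targets, parcellation)
    fitter = _FITTERS[kind]
    ss = np.random.SeedSequence(seed)
    member_seeds = ss.generate_state(m * (max_retries + 1)) % (2**31)
    members = []
    for i in range(m):
        last_err: Exception | None = None
        for r in range(max_retries + 1):
            s = int(member_seeds[i * (max_retries + 1) + r])
            try:
                if kind == "glm":
                    member = fitter(x, y, labels, parcellation.n_parcels, **hyperparams)
                else:
                    member = fitter(x, y, labels, parcellation.n_parcels, seed=s, **hyperparams)
                break
            except FloatingPointError as err:  # pragma: no cover - rare
                last_err = err
        else:  # pragma: no cover
            raise RuntimeError(f"member {i} failed after {max_retries} retries") from last_err
        members.append(member)
    return ParcelEnsemble(members=members)


def predict_ensemble(
    ensemble: ParcelEnsemble, x: np.ndarray, parcellation: Parcellation
) -> np.ndarray:
    """Arithmetic mean of the member-predicted maps."""
    preds = [predict_parcel_model(m, x, parcellation.labels) for m in ensemble.members]
    return np.mean(preds, axis=0)
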