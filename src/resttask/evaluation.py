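"""Prediction-quality evaluation.

Accuracy is the Pearson correlation between a test subject's actual and
predicted task maps.  Correlating every predicted map with every actual
map gives an S x S matrix whose diagonal dominance indicates
individual-specific (not merely group-average) prediction; the matrix can
be row/column normalised to equalise map variances.

For overlap-based evaluation each z-map is modelled as a three-component
mixture — a central Gaussian (null) plus one positive and one mirrored
negative gamma (activations) — fit by expectation-maximisation.  The map
is thresholded at the median of the upper (positive) gamma and thresholded
masks are compared with the Dice coefficient 2|A1 n A2| / (|A1| + |A2|).
Models are compared with a one-way repeated-measures ANOVA and one-sided
Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.anova import AnovaRM

from .models import ParcelEnsemble, predict_ensemble, train_ensemble
from .parcellation import Parcellation

__all__ = [
    "PredictionMatrix",
    "MixtureFit",
    "prediction_matrix",
    "normalize_matrix",
    "prediction_accuracy",
    "diagonal_dominance",
    "fit_mixture",
    "threshold_map",
    "dice",
    "compare_models",
    "learning_curve",
]


@dataclass
class PredictionMatrix:
    values: np.ndarray  # (S, S): row i = predicted_i vs actual_j
    subject_ids: list[str]
    task: str = ""
    model_kind: str = ""
    meta: dict = field(default_factory=dict)


def _zscore_rows(maps: np.ndarray, who: list[str], what: str) -> np.ndarray:
    sd = maps.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance {what} map for subject {who[bad[0]]}")
    return (maps - maps.mean(axis=1, keepdims=True)) / sd[:, None]


def prediction_matrix(
    predicted: np.ndarray,
    actual: np.ndarray,
    subject_ids: list[str] | None = None,
    task: str = "",
    model_kind: str = "",
) -> PredictionMatrix:
    """Cross-subject correlation matrix of predicted vs actual maps.

    ``predicted`` and ``actual`` are (subjects x vertices) arrays over the
    same subjects and vertex set; entry (i, j) is the Pearson correlation
    of subject i's predicted map with subject j's actual map.
    """
    predicted = np.atleast_2d(predicted)
    actual = np.atleast_2d(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have identical shape")
    ids = subject_ids if subject_ids is not None else [str(i) for i in range(len(predicted))]
    pz = _zscore_rows(predicted, ids, "predicted")
    az = _zscore_rows(actual, ids, "actual")
    values = pz @ az.T / predicted.shape[1]
    return PredictionMatrix(values=values, subject_ids=ids, task=task, model_kind=model_kind)


def normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Standardise rows then columns of a square matrix (z-score form).

    The second (column) pass is exact — columns end with mean 0, SD 1;
    rows remain approximately standardised.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or not np.isfinite(m).all():
        raise ValueError("matrix must be square and finite")
    for axis in (1, 0):
        sd = m.std(axis=axis, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero-variance row or column")
        m = (m - m.mean(axis=axis, keepdims=True)) / sd
    return m


def prediction_accuracy(matrix: PredictionMatrix | np.ndarray) -> float:
    """Mean diagonal correlation of the raw (non-normalised) matrix."""
    values = matrix.values if isinstance(matrix, PredictionMatrix) else np.asarray(matrix)
    return float(np.mean(np.diag(values)))


def diagonal_dominance(
    matrix: PredictionMatrix | np.ndarray,
    n_permutations: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of mean(diagonal) - mean(off-diagonal).

    The null permutes the predicted-to-actual subject pairing (rows of the
    matrix); the returned p-value is (1 + #{perm >= observed}) / (1 + B).
    """
    values = matrix.values if isinstance(matrix, PredictionMatrix) else np.asarray(matrix)
    s = values.shape[0]
    off_mask = ~np.eye(s, dtype=bool)

    def stat(m):
        return float(np.mean(np.diag(m)) - np.mean(m[off_mask]))

    observed = stat(values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(s)
        if stat(values[perm]) >= observed:
            count += 1
    return observed, (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# Gaussian + two-gamma mixture model


@dataclass
class MixtureFit:
    """Gaussian (null) + positive/negative gamma (activation) mixture."""

    weights: np.ndarray  # (3,): gaussian, positive gamma, negative gamma
    mu: float
    sigma: float
    pos_shape: float
    pos_scale: float
    pos_loc: float
    neg_shape: float
    neg_scale: float
    neg_loc: float
    loglik_trace: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def threshold(self) -> float:
        """Median of the upper (positive) gamma component."""
        if self.weights[1] <= 0:
            return np.inf
        return self.pos_loc + stats.gamma.ppf(0.5, self.pos_shape, scale=self.pos_scale)


def _weighted_gamma_mle(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted max-likelihood gamma shape/scale for positive data ``y``."""
    wsum = w.sum()
    mean = float((w * y).sum() / wsum)
    meanlog = float((w * np.log(y)).sum() / wsum)
    s = np.log(mean) - meanlog
    s = max(s, 1e-8)
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        f = np.log(a) - special.digamma(a) - s
        fp = 1.0 / a - special.polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-10 * a:
            a = a_new
            break
        a = a_new
    return float(a), mean / float(a)


def _em(
    x: np.ndarray,
    loc: float,
    init: dict,
    max_iter: int,
    tol: float,
    flags: list[str],
) -> dict:
    """Fixed-location EM for the Gaussian + two-gamma mixture."""
    eps = 1e-300
    w = np.array(init["weights"], dtype=float)
    mu, sigma = init["mu"], init["sigma"]
    pos = [init["pos_shape"], init["pos_scale"]]
    neg = [init["neg_shape"], init["neg_scale"]]
    ypos = x - loc
    yneg = loc - x
    pos_ok = ypos > 1e-12
    neg_ok = yneg > 1e-12
    trace = []
    converged = False
    for _ in range(max_iter):
        dens = np.zeros((3, x.size))
        dens[0] = stats.norm.pdf(x, mu, sigma)
        if w[1] > 0:
            dens[1, pos_ok] = stats.gamma.pdf(ypos[pos_ok], pos[0], scale=pos[1])
        if w[2] > 0:
            dens[2, neg_ok] = stats.gamma.pdf(yneg[neg_ok], neg[0], scale=neg[1])
        mix = (w[:, None] * dens).sum(axis=0)
        ll = float(np.log(mix + eps).sum())
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        resp = w[:, None] * dens / (mix + eps)[None, :]
        nk = resp.sum(axis=1)
        # drop a component whose support collapses
        for comp, name in ((1, "positive gamma"), (2, "negative gamma")):
            if w[comp] > 0 and nk[comp] / x.size < 1e-4:
                flags.append(f"degenerate {name} dropped; refit as two-component")
                w[comp] = 0.0
                resp[comp] = 0.0
                nk = resp.sum(axis=1)
        w = nk / nk.sum()
        mu = float((resp[0] * x).sum() / max(nk[0], eps))
        sigma = float(np.sqrt((resp[0] * (x - mu) ** 2).sum() / max(nk[0], eps)))
        sigma = max(sigma, 1e-6)
        if w[1] > 0 and resp[1, pos_ok].sum() > 0:
            pos = list(_weighted_gamma_mle(ypos[pos_ok], resp[1, pos_ok]))
        if w[2] > 0 and resp[2, neg_ok].sum() > 0:
            neg = list(_weighted_gamma_mle(yneg[neg_ok], resp[2, neg_ok]))
    return {
        "weights": w,
        "mu": mu,
        "sigma": sigma,
        "pos_shape": pos[0],
        "pos_scale": pos[1],
        "neg_shape": neg[0],
        "neg_scale": neg[1],
        "trace": np.array(trace),
        "converged": converged,
    }


def fit_mixture(
    z: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    *,
    refine_location: bool = True,
) -> MixtureFit:
    """Fit the Gaussian + two-gamma mixture to a z-map's values by EM.

    The gamma components are anchored at a robust centre estimate (the
    data median) and model the excess above/below it; holding the anchor
    fixed keeps each EM stage's log-likelihood monotone.  With
    ``refine_location`` the anchor is moved once to the fitted Gaussian
    mean and the EM re-run (the recorded trace is the final stage's).
    Fewer than 1000 values triggers a warning flag, not an error.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    flags: list[str] = []
    if z.size < 1000:
        import warnings

        warnings.warn("fewer than 1000 values; mixture fit may be unstable", stacklevel=2)
        flags.append("small sample")
    loc = float(np.median(z))
    spread = float(np.median(np.abs(z - loc)) * 1.4826) or float(z.std()) or 1.0
    init = {
        "weights": (0.8, 0.1, 0.1),
        "mu": loc,
        "sigma": spread,
        "pos_shape": 2.0,
        "pos_scale": max((np.quantile(z, 0.99) - loc) / 2.0, spread / 2.0),
        "neg_shape": 2.0,
        "neg_scale": max((loc - np.quantile(z, 0.01)) / 2.0, spread / 2.0),
    }
    res = _em(z, loc, init, max_iter, tol, flags)
    if refine_location and abs(res["mu"] - loc) > 1e-12:
        loc = float(res["mu"])
        init2 = {
            "weights": np.maximum(res["weights"], 1e-3),
            "mu": res["mu"],
            "sigma": res["sigma"],
            "pos_shape": res["pos_shape"],
            "pos_scale": res["pos_scale"],
            "neg_shape": res["neg_shape"],
            "neg_scale": res["neg_scale"],
        }
        init2["weights"] = init2["weights"] / init2["weights"].sum()
        zero = res["weights"] == 0
        if zero.any():
            init2["weights"][zero] = 0.0
            init2["weights"] /= init2["weights"].sum()
        res = _em(z, loc, init2, max_iter, tol, flags)
    return MixtureFit(
        weights=res["weights"],
        mu=res["mu"],
        sigma=res["sigma"],
        pos_shape=res["pos_shape"],
        pos_scale=res["pos_scale"],
        pos_loc=loc,
        neg_shape=res["neg_shape"],
        neg_scale=res["neg_scale"],
        neg_loc=loc,
        loglik_trace=res["trace"],
        converged=res["converged"],
        flags=flags,
    )


def threshold_map(z: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Binary activation mask: vertices with z >= the upper gamma's median."""
    thr = fit.threshold
    if not np.isfinite(thr):
        return np.zeros_like(np.asarray(z), dtype=bool)
    return np.asarray(z) >= thr


def dice(a1: np.ndarray, a2: np.ndarray) -> float:
    """Dice coefficient 2|A1 n A2| / (|A1| + |A2|); two empty masks -> 0."""
    a1 = np.asarray(a1, dtype=bool)
    a2 = np.asarray(a2, dtype=bool)
    if a1.shape != a2.shape:
        raise ValueError("masks must have identical shape")
    denom = a1.sum() + a2.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a1, a2).sum() / denom)


# ---------------------------------------------------------------------------
# model comparison


def compare_models(scores: dict[str, np.ndarray]) -> dict:
    """Repeated-measures ANOVA plus one-sided pairwise comparisons.

    ``scores`` maps model name to a per-subject score vector (all models
    over the same subjects, in a fixed canonical order).  Pairwise tests
    are one-sided paired t-tests for every ordered contrast
    "later model > earlier model" in dict order, Bonferroni-corrected by
    the number of pairwise tests.
    """
    names = list(scores)
    if len(names) < 2:
        raise ValueError("need at least two models")
    lengths = {len(v) for v in scores.values()}
    if len(lengths) != 1:
        raise ValueError("all models must score the same subjects")
    n_subj = lengths.pop()
    if n_subj < 3:
        raise ValueError("need at least three subjects")

    table = np.column_stack([np.asarray(scores[n], dtype=float) for n in names])
    grand = table.mean()
    ss_model = n_subj * ((table.mean(axis=0) - grand) ** 2).sum()
    if ss_model < 1e-14 * max(1.0, abs(grand)):
        f_stat, p_value = 0.0, 1.0
    else:
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n_subj), len(names)),
                "model": np.tile(names, n_subj),
                "score": table.ravel(),
            }
        )
        res = AnovaRM(long, depvar="score", subject="subject", within=["model"]).fit()
        f_stat = float(res.anova_table["F Value"].iloc[0])
        p_value = float(res.anova_table["Pr > F"].iloc[0])

    pairwise = {}
    contrasts = [
        (names[j], names[i]) for i in range(len(names)) for j in range(i + 1, len(names))
    ]
    for hi, lo in contrasts:
        diff = table[:, names.index(hi)] - table[:, names.index(lo)]
        if np.allclose(diff.std(), 0):
            p = 1.0 if np.allclose(diff.mean(), 0) else (0.0 if diff.mean() > 0 else 1.0)
        else:
            p = float(stats.ttest_rel(table[:, names.index(hi)], table[:, names.index(lo)], alternative="greater").pvalue)
        pairwise[f"{hi} > {lo}"] = min(1.0, p * len(contrasts))
    return {
        "F": f_stat,
        "p": p_value,
        "pairwise": pairwise,
        "bonferroni_factor": len(contrasts),
    }


# ---------------------------------------------------------------------------
# learning / averaging curves


def learning_curve(
    train_features: list[np.ndarray],
    train_targets: list[np.ndarray],
    test_features: list[np.ndarray],
    test_targets: list[np.ndarray],
    parcellation: Parcellation,
    kind: str,
    hyperparams: dict | None = None,
    n_train_grid: tuple[int, ...] = (5, 10, 20, 40),
    m_grid: tuple[int, ...] = (1,),
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy vs number of training subjects and number of averages.

    The n_train sweep uses M = min(m_grid) models; the M sweep re-uses the
    full training set.  The same test subjects are scored throughout.
    Returns a tidy frame with columns (sweep, value, mean_cc).
    """
    n_avail = len(train_features)
    if max(n_train_grid) > n_avail:
        raise ValueError("n_train grid exceeds available training subjects")
    rng = np.random.default_rng(seed)
    actual = np.vstack(test_targets)
    rows = []

    def run(n_train: int, m: int, sub_seed: int) -> float:
        idx = rng.permutation(n_avail)[:n_train]
        ens = train_ensemble(
            kind,
            [train_features[i] for i in idx],
            [train_targets[i] for i in idx],
            parcellation,
            hyperparams,
            m=m,
            seed=sub_seed,
        )
        predicted = np.vstack([predict_ensemble(ens, x, parcellation) for x in test_features])
        return prediction_accuracy(prediction_matrix(predicted, actual))

    base_m = min(m_grid)
    for n_train in n_train_grid:
        rows.append(
            {"sweep": "n_train", "value": n_train, "mean_cc": run(n_train, base_m, int(rng.integers(2**31)))}
        )
    for m in m_grid:
        rows.append(
            {"sweep": "m", "value": m, "mean_cc": run(n_avail, m, int(rng.integers(2**31)))}
        )
    return pd.DataFrame(rows)
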