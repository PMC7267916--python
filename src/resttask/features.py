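"""Connectivity feature extraction from multi-run resting-state time series.

The stages follow the classic dual-regression recipe for individualised
network features:

1. per-vertex normalisation of each run (zero mean, unit SD);
2. group dimensionality reduction (PCA over the temporally concatenated
   cohort data);
3. spatial ICA per hemisphere on the reduced data;
4. left/right symmetry filtering — only components with a mirrored
   counterpart in the other hemisphere are kept;
5. dual regression of each subject's runs on the retained group maps,
   giving subject-specific network maps;
6. per-structure subcortical mean signals;
7. final feature maps: one time course per feature (regression of the
   subject's data on the stacked individual maps plus subcortical
   indicator maps), correlated with every grayordinate's time series,
   then column-normalised.

The feature count is ``2 x retained_components + n_subcortical`` (the
real-data configuration yields 2x34+32 = 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .space import BrainSpace

__all__ = [
    "GroupComponentSet",
    "FeatureMaps",
    "normalize_timeseries",
    "concat_normalized",
    "group_reduce",
    "group_ica",
    "filter_symmetric",
    "dual_regression",
    "subcortical_signals",
    "feature_maps",
    "extract_cohort_features",
]


@dataclass
class GroupComponentSet:
    """Per-hemisphere group ICA maps with their retained symmetric pairs."""

    left_maps: np.ndarray  # (k_left, n_per_hemisphere)
    right_maps: np.ndarray  # (k_right, n_per_hemisphere)
    pairs: list[tuple[int, int, float]]  # (left idx, right idx, |corr| score)

    @property
    def n_retained(self) -> int:
        return len(self.pairs)

    def retained_full_maps(self, space: BrainSpace) -> np.ndarray:
        """(2 x retained, n_vertices) full-space regressor maps.

        Order: retained left maps (zero elsewhere), then the paired right
        maps, both sorted by descending symmetry score.
        """
        n_h = space.n_per_hemisphere
        out = np.zeros((2 * self.n_retained, space.n_vertices))
        for r, (li, ri, _score) in enumerate(self.pairs):
            out[r, :n_h] = self.left_maps[li]
            out[self.n_retained + r, n_h : 2 * n_h] = self.right_maps[ri]
        return out


@dataclass
class FeatureMaps:
    subject_id: str
    values: np.ndarray  # (n_vertices, F)
    normalized: bool = True
    meta: dict = field(default_factory=dict)


def normalize_timeseries(run: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each vertex's time series; constant series become zeros.

    Returns the normalised (vertices x time) matrix and a boolean flag
    vector marking degenerate (zero-variance) vertices.
    """
    run = np.asarray(run, dtype=float)
    if run.ndim != 2 or run.shape[1] < 2:
        raise ValueError("run must be (vertices, time) with >= 2 timepoints")
    mean = run.mean(axis=1, keepdims=True)
    sd = run.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    out = (run - mean) / sd
    out[flat] = 0.0
    return out, flat


def concat_normalized(runs: list[np.ndarray]) -> np.ndarray:
    """Normalise each run per vertex and concatenate along time."""
    return np.concatenate([normalize_timeseries(r)[0] for r in runs], axis=1)


def group_reduce(data: np.ndarray, target_dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Group PCA of temporally concatenated data.

    Parameters
    ----------
    data : (total_timepoints, n_vertices) array
        All subjects' normalised runs stacked along time.
    target_dim : int
        Number of retained components (<= total timepoints).

    Returns
    -------
    reduced : (target_dim, n_vertices)
        Principal spatial modes scaled by their singular values, i.e. a
        reduced pseudo-time-series representation of the group data.
    explained : (target_dim,)
        Fraction of total variance carried by each component
        (non-increasing).
    """
    data = np.asarray(data, dtype=float)
    if not 1 <= target_dim <= min(data.shape):
        raise ValueError(f"target_dim must be in [1, {min(data.shape)}]")
    mean = data.mean(axis=0, keepdims=True)
    _u, s, vt = np.linalg.svd(data - mean, full_matrices=False)
    total = np.sum(s**2)
    reduced = s[:target_dim, None] * vt[:target_dim]
    explained = s[:target_dim] ** 2 / total if total > 0 else np.zeros(target_dim)
    return reduced, explained


def group_ica(
    reduced: np.ndarray,
    k: int,
    seed: int = 0,
    *,
    fun: str = "cube",
    max_attempts: int = 5,
) -> np.ndarray:
    """Spatial ICA on one hemisphere's reduced data.

    ``reduced`` is (dims, hemisphere vertices); vertices act as samples so
    the extracted sources are spatial maps with independent, non-Gaussian
    value distributions.  Maps are sign-fixed to non-negative skewness,
    scaled to unit SD and ordered by the explained-variance of their
    mixing column.  Non-convergence triggers seeded retries.  The default
    kurtosis contrast (``fun="cube"``) suits sparse, localised sources.
    """
    reduced = np.asarray(reduced, dtype=float)
    if not 1 <= k <= reduced.shape[0]:
        raise ValueError("k must be in [1, reduced dimension]")
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        # retries loosen the unmixing tolerance: the sources are coarse
        # spatial maps, so 1e-2 precision is ample when 1e-3 cycles
        ica = FastICA(
            n_components=k,
            random_state=seed + attempt,
            whiten="unit-variance",
            fun=fun,
            max_iter=2000,
            tol=1e-3 * 10 ** (attempt / 2),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(reduced.T)  # (vertices, k)
            except ConvergenceWarning as err:  # pragma: no cover - rare
                last_err = err
                continue
        maps = sources.T
        sign = np.where(stats.skew(maps, axis=1) < 0, -1.0, 1.0)
        maps = maps * sign[:, None]
        sd = maps.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        maps = maps / sd
        order = np.argsort(-np.linalg.norm(ica.mixing_, axis=0))
        return maps[order]
    raise RuntimeError(f"FastICA failed to converge after {max_attempts} attempts") from last_err


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix between two (n, V) / (m, V) arrays."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / a.shape[1]


def filter_symmetric(
    left_maps: np.ndarray,
    right_maps: np.ndarray,
    space: BrainSpace,
    threshold: float = 0.5,
) -> GroupComponentSet:
    """Keep components with a left/right mirror-symmetric counterpart.

    Right maps are brought into left-vertex order through the mirror map
    and matched one-to-one to left maps greedily by descending absolute
    spatial correlation; pairs scoring >= ``threshold`` are retained,
    ordered by score.
    """
    n_h = space.n_per_hemisphere
    right_in_left_order = right_maps[:, space.mirror - n_h]
    corr = np.abs(_corr_rows(left_maps, right_in_left_order))
    pairs: list[tuple[int, int, float]] = []
    c = corr.copy()
    while np.isfinite(c).any() and c.size:
        li, ri = np.unravel_index(np.nanargmax(c), c.shape)
        score = c[li, ri]
        if not np.isfinite(score) or score < threshold:
            break
        pairs.append((int(li), int(ri), float(score)))
        c[li, :] = -np.inf
        c[:, ri] = -np.inf
        if len(pairs) == min(left_maps.shape[0], right_maps.shape[0]):
            break
    if not pairs:
        warnings.warn("no symmetric component pairs retained", stacklevel=2)
        raise ValueError("symmetry filtering retained no components")
    return GroupComponentSet(left_maps=left_maps, right_maps=right_maps, pairs=pairs)


def _lstsq(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares, warning on rank deficiency."""
    coef, _res, rank, _sv = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient design; minimum-norm solution used", stacklevel=3)
    return coef


def dual_regression(runs: list[np.ndarray], group_maps: np.ndarray) -> np.ndarray:
    """Estimate subject-specific spatial maps from group maps.

    Stage 1 regresses each timepoint of the (normalised, concatenated)
    data onto the group spatial maps, giving one time course per
    component; stage 2 regresses each vertex's time series onto those
    courses, giving the subject's component maps.

    Parameters
    ----------
    runs : list of (n_vertices, T) arrays
    group_maps : (n_components, n_vertices) array

    Returns
    -------
    (n_components, n_vertices) subject spatial maps.
    """
    group_maps = np.atleast_2d(np.asarray(group_maps, dtype=float))
    data = concat_normalized(runs)
    courses = _lstsq(group_maps.T, data)  # (C, T_total)
    maps = _lstsq(courses.T, data.T)  # (C, V)
    return maps


def subcortical_signals(runs: list[np.ndarray], space: BrainSpace) -> np.ndarray:
    """Mean normalised time course per subcortical structure.

    Returns an (n_structures, total timepoints) array.
    """
    data = concat_normalized(runs)
    out = np.empty((space.n_structures, data.shape[1]))
    for s in range(1, space.n_structures + 1):
        members = space.structure_members(s)
        if members.size == 0:
            raise ValueError(f"subcortical structure {s} has no member nodes")
        out[s - 1] = data[members].mean(axis=0)
    return out


def feature_maps(
    runs: list[np.ndarray],
    subject_maps: np.ndarray,
    space: BrainSpace,
    subject_id: str = "",
    *,
    normalize: bool = True,
) -> FeatureMaps:
    """Build the final (vertices x features) connectivity feature matrix.

    The subject's component maps and the binary subcortical structure maps
    are stacked into one spatial design; regressing the subject's
    concatenated time series on it yields one time course per feature,
    and each course is Pearson-correlated with every grayordinate's
    series.  Degenerate (zero-variance) vertices get feature value 0.
    Columns are finally normalised to zero mean, unit SD.
    """
    subject_maps = np.atleast_2d(subject_maps)
    indicators = space.structure_indicators()
    design = np.vstack([subject_maps, indicators]) if indicators.size else subject_maps
    if design.shape[0] == 0:
        raise ValueError("no features: empty spatial design")
    data = concat_normalized(runs)
    courses = _lstsq(design.T, data)  # (F, T)
    t = data.shape[1]
    cz = courses - courses.mean(axis=1, keepdims=True)
    csd = cz.std(axis=1, keepdims=True)
    csd[csd == 0] = 1.0
    cz /= csd
    vz = data - data.mean(axis=1, keepdims=True)
    vsd = vz.std(axis=1, keepdims=True)
    dead = vsd[:, 0] == 0
    vsd[dead] = 1.0
    vz /= vsd
    feats = vz @ cz.T / t  # (V, F) Pearson correlations
    feats[dead] = 0.0
    meta = {"n_features": feats.shape[1], "degenerate_vertices": int(dead.sum())}
    if normalize:
        feats = feats - feats.mean(axis=0, keepdims=True)
        sd = feats.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        feats = feats / sd
    return FeatureMaps(subject_id=subject_id, values=feats, normalized=normalize, meta=meta)


def extract_cohort_features(
    subjects: list,
    space: BrainSpace,
    *,
    target_dim: int = 100,
    k_ica: int = 12,
    symmetry_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, FeatureMaps], GroupComponentSet]:
    """Run the full group + per-subject feature pipeline on a cohort.

    Group PCA and per-hemisphere ICA run on all subjects' concatenated
    runs; symmetric components are retained and dual-regressed into each
    subject, whose final feature maps are returned keyed by subject id.
    """
    n_h = space.n_per_hemisphere
    stacked = np.concatenate(
        [concat_normalized(s.runs).T for s in subjects], axis=0
    )  # (T_total, V)
    target = min(target_dim, *stacked.shape)
    reduced, _explained = group_reduce(stacked, target)
    k = min(k_ica, target)
    left = group_ica(reduced[:, :n_h], k, seed=seed)
    right = group_ica(reduced[:, n_h : 2 * n_h], k, seed=seed + 1)
    comp = filter_symmetric(left, right, space, threshold=symmetry_threshold)
    regressors = comp.retained_full_maps(space)
    out: dict[str, FeatureMaps] = {}
    for s in subjects:
        maps = dual_regression(s.runs, regressors)
        out[s.subject_id] = feature_maps(s.runs, maps, space, subject_id=s.subject_id)
    return out, comp
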