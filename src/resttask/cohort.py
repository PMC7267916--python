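"""Synthetic multi-subject resting-state / task cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes about real multi-run resting-state fMRI:

* a set of K smooth, approximately non-overlapping group network maps per
  hemisphere, mirrored exactly across the midline;
* per-subject network maps = group maps plus a smooth subject-specific
  perturbation (additive Gaussian random field), so subjects differ in
  specific, reproducible ways;
* multi-run time series = (subject maps) x (AR(1) network time courses)
  plus white noise; subcortical structures carry their own latent courses;
* task z-score maps generated per parcel from the subject's *true* feature
  matrix through a known linear or saturating-nonlinear link, plus noise.

Because every subject's generating maps, courses and feature matrices are
retained, each downstream stage (dual regression, feature maps, the
regression models) can be tested against ground truth that real data never
exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .parcellation import Parcellation, voronoi_parcellate
from .space import BrainSpace, make_space

__all__ = [
    "CohortTruth",
    "SubjectTruth",
    "SubjectData",
    "smooth_field",
    "make_group_networks",
    "make_link_weights",
    "make_subject",
    "make_task_maps",
    "make_cohort",
    "load_cohort",
    "regenerate_cohort",
]

#: gain of the saturating (tanh) nonlinear link; a documented constant so
#: nonlinear cohorts are reproducible.
NONLINEAR_GAIN = 2.0

#: AR(1) coefficient of the network time courses (mild temporal
#: autocorrelation, as in fMRI, without modelling hemodynamics).
AR1_RHO = 0.3


@dataclass
class SubjectTruth:
    """Ground truth behind one generated subject."""

    subject_id: str
    left_maps: np.ndarray  # (K, n_per_hemisphere) subject network maps
    right_maps: np.ndarray  # (K, n_per_hemisphere), right-vertex order
    courses: np.ndarray  # (n_runs, 2K + n_structures, T) latent time courses
    features: np.ndarray  # (n_vertices, F_true) z-scored true feature matrix


@dataclass
class SubjectData:
    """One subject's observable data: resting runs and task maps."""

    subject_id: str
    runs: list[np.ndarray]  # each (n_vertices, T)
    task_maps: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class CohortTruth:
    """Group-level ground truth plus generation parameters."""

    group_left: np.ndarray  # (K, n_per_hemisphere)
    group_right: np.ndarray  # (K, n_per_hemisphere), right-vertex order
    link_weights: dict[str, np.ndarray]  # contrast -> (n_parcels, F_true)
    link_types: dict[str, str]  # contrast -> "linear" | "nonlinear"
    ts_noise_sd: float
    task_noise_sd: float
    subject_variability: float
    subjects: dict[str, SubjectTruth] = field(default_factory=dict)

    @property
    def k_networks(self) -> int:
        return int(self.group_left.shape[0])

    def network_loadings(self, space: BrainSpace, subject: str | None = None) -> np.ndarray:
        """Full-space (2K + n_structures, n_vertices) loading matrix.

        Rows: K left networks, K right networks, then the binary
        subcortical structure maps.  With ``subject`` the subject's
        perturbed maps are used, otherwise the group maps.
        """
        if subject is None:
            left, right = self.group_left, self.group_right
        else:
            st = self.subjects[subject]
            left, right = st.left_maps, st.right_maps
        k = left.shape[0]
        n_h = space.n_per_hemisphere
        loads = np.zeros((2 * k + space.n_structures, space.n_vertices))
        loads[:k, :n_h] = left
        loads[k : 2 * k, n_h : 2 * n_h] = right
        loads[2 * k :] = space.structure_indicators()
        return loads


def _angular_kernel(coords: np.ndarray, sigma: float) -> np.ndarray:
    """Row-normalised Gaussian kernel on angular distance between unit vectors."""
    cosang = np.clip(coords @ coords.T, -1.0, 1.0)
    theta = np.arccos(cosang)
    w = np.exp(-0.5 * (theta / sigma) ** 2)
    return w / w.sum(axis=1, keepdims=True)


def _typical_spacing(n_per_hemisphere: int) -> float:
    # mean angular distance to the nearest neighbour of n uniform points
    # on the sphere scales like sqrt(4*pi/n)/2
    return 0.5 * np.sqrt(4.0 * np.pi / n_per_hemisphere)


def smooth_field(
    space: BrainSpace,
    smoothness: float,
    rng: np.random.Generator,
    n_fields: int = 1,
    hemi: int = 0,
) -> np.ndarray:
    """Draw smooth Gaussian random fields on one hemisphere.

    ``smoothness`` is expressed in units of the typical nearest-neighbour
    spacing, so values of a few units give maps that vary over many
    vertices while ``smoothness -> 0`` degenerates to white noise.  Fields
    are z-scored over vertices.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    verts = space.hemisphere_vertices(hemi)
    noise = rng.standard_normal((n_fields, len(verts)))
    if smoothness > 0:
        sigma = smoothness * _typical_spacing(space.n_per_hemisphere)
        kernel = _angular_kernel(space.coords[verts], sigma)
        noise = noise @ kernel.T
    noise -= noise.mean(axis=1, keepdims=True)
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def make_group_networks(
    space: BrainSpace,
    k_per_hemisphere: int = 10,
    smoothness: float = 5.0,
    seed: int = 0,
    *,
    sparsity_quantile: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate K mirrored group network maps.

    Each network is a contiguous binary patch: K smooth random fields are
    drawn and every vertex joins the field with the largest value there,
    provided that value exceeds the field's own ``sparsity_quantile``.
    The winner-take-all rule makes the supports disjoint (maximally
    non-overlapping) and the constant in-network height means per-vertex
    variance normalisation of noiseless mixed time series rescales every
    network uniformly, so dual regression can invert the model exactly.
    Graded inter-subject structure is added later by the subject
    perturbation.  Right-hemisphere maps equal the mirrored left maps.

    Returns
    -------
    (group_left, group_right) : each (K, n_per_hemisphere), unit SD.
    """
    if not 1 <= k_per_hemisphere <= space.n_per_hemisphere:
        raise ValueError("k_per_hemisphere must be in [1, n_per_hemisphere]")
    rng = np.random.default_rng(seed)
    fields = smooth_field(space, smoothness, rng, n_fields=k_per_hemisphere, hemi=0)
    thr = np.quantile(fields, sparsity_quantile, axis=1, keepdims=True)
    winner = np.argmax(fields, axis=0)
    maps = np.zeros_like(fields)
    for k in range(k_per_hemisphere):
        support = (winner == k) & (fields[k] > thr[k, 0])
        if not support.any():  # beaten everywhere: fall back to own top values
            support = fields[k] > thr[k, 0]
        maps[k, support] = 1.0
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    left = maps / sd
    # right vertex mirror[i]-n_h is homologous to left vertex i
    n_h = space.n_per_hemisphere
    right = np.zeros_like(left)
    right[:, space.mirror - n_h] = left
    return left, right


def make_link_weights(
    n_parcels: int,
    n_features: int,
    seed: int,
    *,
    n_active: int = 3,
) -> np.ndarray:
    """Sparse per-parcel feature->activation weights.

    Each parcel's activation is driven by ``n_active`` randomly chosen
    features with standard-normal weights; the remaining entries are zero.
    """
    rng = np.random.default_rng(seed)
    w = np.zeros((n_parcels, n_features))
    for p in range(n_parcels):
        idx = rng.choice(n_features, size=min(n_active, n_features), replace=False)
        w[p, idx] = rng.standard_normal(len(idx))
    return w


def _ar1_courses(rng: np.random.Generator, n: int, t: int, rho: float = AR1_RHO) -> np.ndarray:
    eps = rng.standard_normal((n, t))
    out = np.empty((n, t))
    out[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for i in range(1, t):
        out[:, i] = rho * out[:, i - 1] + scale * eps[:, i]
    return out


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_subject(
    space: BrainSpace,
    truth: CohortTruth,
    subject_variability: float = 0.5,
    ts_noise_sd: float = 0.5,
    n_runs: int = 4,
    n_timepoints: int = 200,
    seed: int = 0,
    *,
    subject_id: str | None = None,
    smoothness: float = 5.0,
) -> tuple[SubjectData, SubjectTruth]:
    """Generate one subject's resting-state runs and ground truth.

    Subject maps are the group maps plus an independent smooth perturbation
    per network and hemisphere, scaled by ``subject_variability``.  Each
    run is (subject loadings) x (fresh AR(1) latent courses) + white noise.
    """
    if subject_variability < 0 or ts_noise_sd < 0:
        raise ValueError("subject_variability and ts_noise_sd must be >= 0")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = np.random.default_rng(seed)
    k = truth.k_networks
    sid = subject_id if subject_id is not None else f"sub-{seed:06d}"

    left = truth.group_left.copy()
    right = truth.group_right.copy()
    if subject_variability > 0:
        left = left + subject_variability * smooth_field(space, smoothness, rng, k, hemi=0)
        pert_r = smooth_field(space, smoothness, rng, k, hemi=1)
        right = right + subject_variability * pert_r

    n_lat = 2 * k + space.n_structures
    st = SubjectTruth(
        subject_id=sid,
        left_maps=left,
        right_maps=right,
        courses=np.empty((n_runs, n_lat, n_timepoints)),
        features=np.empty(0),
    )
    truth.subjects[sid] = st
    loads = truth.network_loadings(space, subject=sid)

    runs = []
    for r in range(n_runs):
        courses = _ar1_courses(rng, n_lat, n_timepoints)
        st.courses[r] = courses
        data = loads.T @ courses
        if ts_noise_sd > 0:
            data = data + ts_noise_sd * rng.standard_normal(data.shape)
        runs.append(data)

    st.features = _zscore_columns(loads.T.copy())
    return SubjectData(subject_id=sid, runs=runs), st


def make_task_maps(
    subject_truth: SubjectTruth,
    parcellation: Parcellation,
    link_weights: np.ndarray,
    link_type: str = "linear",
    task_noise_sd: float = 0.3,
    seed: int = 0,
    *,
    zscore: bool = True,
) -> np.ndarray:
    """Generate one task z-score map from a subject's true features.

    Per parcel ``p``: ``y = g(X_true) @ w[p] + noise`` over the parcel's
    vertices, where ``g`` is the identity (linear link) or an elementwise
    ``tanh(NONLINEAR_GAIN * x)`` saturation (nonlinear link).  The full map
    is z-scored over vertices afterwards, matching the use of z-score maps
    as prediction targets.
    """
    x = subject_truth.features
    if link_weights.shape != (parcellation.n_parcels, x.shape[1]):
        raise ValueError(
            f"link_weights must have shape {(parcellation.n_parcels, x.shape[1])}, "
            f"got {link_weights.shape}"
        )
    if link_type == "linear":
        g = x
    elif link_type == "nonlinear":
        g = np.tanh(NONLINEAR_GAIN * x)
    else:
        raise ValueError(f"unknown link_type {link_type!r}")
    rng = np.random.default_rng(seed)
    y = np.empty(x.shape[0])
    for p in range(parcellation.n_parcels):
        idx = parcellation.members(p)
        y[idx] = g[idx] @ link_weights[p]
    if task_noise_sd > 0:
        y = y + task_noise_sd * rng.standard_normal(y.shape)
    if zscore:
        y = (y - y.mean()) / y.std()
    return y


def make_cohort(
    n_subjects: int = 60,
    seed: int = 7,
    *,
    n_vertices_per_hemisphere: int = 1000,
    n_subcortical_structures: int = 32,
    k_networks: int = 10,
    smoothness: float = 5.0,
    subject_variability: float = 0.5,
    ts_noise_sd: float = 0.5,
    task_noise_sd: float = 0.3,
    n_runs: int = 4,
    n_timepoints: int = 200,
    n_parcels_per_hemisphere: int = 50,
    contrasts: dict[str, str] | None = None,
    n_active_weights: int = 3,
    sparsity_quantile: float = 0.9,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectData], CohortTruth, BrainSpace, Parcellation]:
    """Generate (and optionally serialise) a full synthetic cohort.

    ``contrasts`` maps contrast names to link types; the default provides
    one linear and one nonlinear task.  All randomness derives from
    ``seed`` via independent spawned streams, so identical calls produce
    bitwise-identical cohorts.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    if contrasts is None:
        contrasts = {"linear": "linear", "nonlinear": "nonlinear"}
    params = {
        "n_subjects": n_subjects,
        "seed": seed,
        "n_vertices_per_hemisphere": n_vertices_per_hemisphere,
        "n_subcortical_structures": n_subcortical_structures,
        "k_networks": k_networks,
        "smoothness": smoothness,
        "subject_variability": subject_variability,
        "ts_noise_sd": ts_noise_sd,
        "task_noise_sd": task_noise_sd,
        "n_runs": n_runs,
        "n_timepoints": n_timepoints,
        "n_parcels_per_hemisphere": n_parcels_per_hemisphere,
        "contrasts": dict(contrasts),
        "n_active_weights": n_active_weights,
        "sparsity_quantile": sparsity_quantile,
    }
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(4 + 2 * n_subjects + len(contrasts)) % (2**31)
    space = make_space(n_vertices_per_hemisphere, n_subcortical_structures, seed=int(seeds[0]))
    gl, gr = make_group_networks(
        space, k_networks, smoothness, seed=int(seeds[1]), sparsity_quantile=sparsity_quantile
    )
    parc = voronoi_parcellate(space, n_parcels_per_hemisphere, seed=int(seeds[2]))
    f_true = 2 * k_networks + n_subcortical_structures
    truth = CohortTruth(
        group_left=gl,
        group_right=gr,
        link_weights={},
        link_types=dict(contrasts),
        ts_noise_sd=ts_noise_sd,
        task_noise_sd=task_noise_sd,
        subject_variability=subject_variability,
    )
    for i, name in enumerate(contrasts):
        truth.link_weights[name] = make_link_weights(
            parc.n_parcels, f_true, seed=int(seeds[3 + i]), n_active=n_active_weights
        )
    base = 3 + len(contrasts)
    subjects = []
    for s in range(n_subjects):
        data, st = make_subject(
            space,
            truth,
            subject_variability,
            ts_noise_sd,
            n_runs,
            n_timepoints,
            seed=int(seeds[base + 2 * s]),
            subject_id=f"sub-{s:03d}",
            smoothness=smoothness,
        )
        for name, link in contrasts.items():
            data.task_maps[name] = make_task_maps(
                st,
                parc,
                truth.link_weights[name],
                link_type=link,
                task_noise_sd=task_noise_sd,
                seed=int(seeds[base + 2 * s + 1]),
            )
        subjects.append(data)
    if out_dir is not None:
        save_cohort(Path(out_dir), subjects, truth, space, parc, params)
    return subjects, truth, space, parc


# ---------------------------------------------------------------------------
# serialisation


def save_cohort(
    out_dir: Path,
    subjects: list[SubjectData],
    truth: CohortTruth,
    space: BrainSpace,
    parc: Parcellation,
    params: dict,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    edges = np.array(
        [(i, int(j)) for i, nb in enumerate(space.neighbors) for j in nb if i < j],
        dtype=np.int64,
    )
    with h5py.File(out_dir / "truth.h5", "w") as f:
        g = f.create_group("space")
        g.create_dataset("coords", data=space.coords)
        g.create_dataset("hemisphere", data=space.hemisphere)
        g.create_dataset("edges", data=edges)
        g.create_dataset("subcortical_labels", data=space.subcortical_labels)
        g.create_dataset("mirror", data=space.mirror)
        g = f.create_group("group")
        g.create_dataset("left", data=truth.group_left)
        g.create_dataset("right", data=truth.group_right)
        g = f.create_group("parcellation")
        g.create_dataset("labels", data=parc.labels)
        g.create_dataset("seed_vertices", data=parc.seed_vertices)
        g.attrs["n_per_hemisphere"] = parc.n_per_hemisphere
        g = f.create_group("links")
        for name, w in truth.link_weights.items():
            d = g.create_dataset(name, data=w)
            d.attrs["link_type"] = truth.link_types[name]
        f.attrs["ts_noise_sd"] = truth.ts_noise_sd
        f.attrs["task_noise_sd"] = truth.task_noise_sd
        f.attrs["subject_variability"] = truth.subject_variability
    sub_dir = out_dir / "subjects"
    sub_dir.mkdir(exist_ok=True)
    for data in subjects:
        st = truth.subjects[data.subject_id]
        with h5py.File(sub_dir / f"{data.subject_id}.h5", "w") as f:
            g = f.create_group("runs")
            for r, run in enumerate(data.runs):
                g.create_dataset(f"run{r:02d}", data=run)
            g = f.create_group("tasks")
            for name, y in data.task_maps.items():
                g.create_dataset(name, data=y)
            g = f.create_group("truth")
            g.create_dataset("left_maps", data=st.left_maps)
            g.create_dataset("right_maps", data=st.right_maps)
            g.create_dataset("courses", data=st.courses)
            g.create_dataset("features", data=st.features)


def load_cohort(
    in_dir: str | Path,
) -> tuple[list[SubjectData], CohortTruth, BrainSpace, Parcellation]:
    in_dir = Path(in_dir)
    with h5py.File(in_dir / "truth.h5", "r") as f:
        coords = f["space/coords"][()]
        hemisphere = f["space/hemisphere"][()]
        edges = f["space/edges"][()]
        sub_labels = f["space/subcortical_labels"][()]
        mirror = f["space/mirror"][()]
        neighbors: list[list[int]] = [[] for _ in range(coords.shape[0])]
        for a, b in edges:
            neighbors[a].append(int(b))
            neighbors[b].append(int(a))
        space = BrainSpace(
            coords=coords,
            hemisphere=hemisphere,
            neighbors=[np.array(sorted(nb), dtype=np.int64) for nb in neighbors],
            subcortical_labels=sub_labels,
            mirror=mirror,
        )
        truth = CohortTruth(
            group_left=f["group/left"][()],
            group_right=f["group/right"][()],
            link_weights={name: f["links"][name][()] for name in f["links"]},
            link_types={name: f["links"][name].attrs["link_type"] for name in f["links"]},
            ts_noise_sd=float(f.attrs["ts_noise_sd"]),
            task_noise_sd=float(f.attrs["task_noise_sd"]),
            subject_variability=float(f.attrs["subject_variability"]),
        )
        labels = f["parcellation/labels"][()]
        parc = Parcellation(
            labels=labels,
            n_per_hemisphere=int(f["parcellation"].attrs["n_per_hemisphere"]),
            seed_vertices=f["parcellation/seed_vertices"][()],
            n_cortical_parcels=2 * int(f["parcellation"].attrs["n_per_hemisphere"]),
            n_parcels=int(labels.max()) + 1,
        )
    subjects = []
    for path in sorted((in_dir / "subjects").glob("*.h5")):
        with h5py.File(path, "r") as f:
            sid = path.stem
            runs = [f["runs"][k][()] for k in sorted(f["runs"])]
            tasks = {name: f["tasks"][name][()] for name in f["tasks"]}
            truth.subjects[sid] = SubjectTruth(
                subject_id=sid,
                left_maps=f["truth/left_maps"][()],
                right_maps=f["truth/right_maps"][()],
                courses=f["truth/courses"][()],
                features=f["truth/features"][()],
            )
            subjects.append(SubjectData(subject_id=sid, runs=runs, task_maps=tasks))
    return subjects, truth, space, parc


def regenerate_cohort(manifest: str | Path | dict, out_dir: str | Path | None = None):
    """Replay a cohort from its manifest; identical parameters give a
    bitwise-identical cohort."""
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = yaml.safe_load(fh)
    params = dict(manifest)
    n_subjects = params.pop("n_subjects")
    seed = params.pop("seed")
    return make_cohort(n_subjects, seed, out_dir=out_dir, **params)
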