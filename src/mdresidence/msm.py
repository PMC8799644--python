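"""Markov state modelling: from feature trajectories to metastable states.

The stack mirrors standard MSM practice: backbone-torsion featurization
(cos/sin encoded), VAMP-2 scoring of the featurization, TICA projection
onto the slowest linear subspace (default lag 40 ns, 2 dimensions),
k-means microstates with k = round(sqrt(n_frames)), reversible
maximum-likelihood transition-matrix estimation on the largest strongly
connected set, implied timescales, the Chapman-Kolmogorov consistency
test, and PCCA++ coarse-graining into metastable states (default 3) with
equilibrium probabilities pi_i and representative frames (3 per state).

All stochastic steps take explicit seeds; the default k-means seed is
2022.  The full stack is reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .core import Trajectory

__all__ = [
    "FeatureMatrix",
    "TICAModel",
    "MSMModel",
    "MetastablePartition",
    "CKResult",
    "featurize_backbone_torsions",
    "vamp2_score",
    "fit_tica",
    "cluster_microstates",
    "estimate_msm",
    "implied_timescales",
    "its_over_lags",
    "ck_test",
    "pcca_coarse_grain",
    "select_representatives",
    "msm_pipeline",
]

DEFAULT_KMEANS_SEED = 2022


@dataclass
class FeatureMatrix:
    data: np.ndarray              # (n_frames, n_features)
    labels: list                  # one label per feature column
    stride_ns: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count must match feature count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _dihedrals(xyz: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Dihedral angles (radians) for index quadruplets over all frames."""
    p = xyz[:, quads, :]  # (F, Q, 4, 3)
    b0 = p[:, :, 0] - p[:, :, 1]
    b1 = p[:, :, 2] - p[:, :, 1]
    b2 = p[:, :, 3] - p[:, :, 2]
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - (b0 * b1n).sum(-1, keepdims=True) * b1n
    w = b2 - (b2 * b1n).sum(-1, keepdims=True) * b1n
    x = (v * w).sum(-1)
    y = (np.cross(b1n, v) * w).sum(-1)
    return np.arctan2(y, x)


def featurize_backbone_torsions(trajectory: Trajectory,
                                residue_exclusions: Sequence = ()
                                ) -> FeatureMatrix:
    """phi/psi backbone torsions encoded as (cos, sin) pairs.

    ``residue_exclusions`` lists (chain, residue_number) pairs whose
    torsions are omitted.  Torsions across chain breaks (C-N > 1.8 A in
    frame 0) are dropped with a warning.
    """
    top = trajectory.topology
    excl = {tuple(e) for e in residue_exclusions}
    backbone: dict[tuple, dict] = {}
    order: list[tuple] = []
    for i, a in enumerate(top.atoms):
        if a.name in ("N", "CA", "C") and a.residue_name not in ("HOH", "WAT"):
            key = (a.chain, a.residue_number)
            if key not in backbone:
                backbone[key] = {}
                order.append(key)
            backbone[key][a.name] = i
    order = [k for k in order if set(backbone[k]) >= {"N", "CA", "C"}]
    if len(order) < 3:
        raise ValueError("need a protein chain of >= 3 residues")

    xyz0 = trajectory.xyz[0]
    quads, labels = [], []
    for j, key in enumerate(order):
        chain, resnum = key
        res = backbone[key]
        # phi: C(i-1) - N - CA - C
        if j > 0 and order[j - 1][0] == chain:
            prev = backbone[order[j - 1]]
            if np.linalg.norm(xyz0[prev["C"]] - xyz0[res["N"]]) > 1.8:
                warnings.warn(f"chain break before residue {key}; phi dropped",
                              stacklevel=2)
            elif key not in excl:
                quads.append([prev["C"], res["N"], res["CA"], res["C"]])
                labels.append((chain, resnum, "phi"))
        # psi: N - CA - C - N(i+1)
        if j + 1 < len(order) and order[j + 1][0] == chain:
            nxt = backbone[order[j + 1]]
            if np.linalg.norm(xyz0[res["C"]] - xyz0[nxt["N"]]) > 1.8:
                warnings.warn(f"chain break after residue {key}; psi dropped",
                              stacklevel=2)
            elif key not in excl:
                quads.append([res["N"], res["CA"], res["C"], nxt["N"]])
                labels.append((chain, resnum, "psi"))
    if not quads:
        raise ValueError("no backbone torsions could be built")
    ang = _dihedrals(trajectory.xyz, np.array(quads))
    data = np.empty((trajectory.n_frames, 2 * ang.shape[1]))
    data[:, 0::2] = np.cos(ang)
    data[:, 1::2] = np.sin(ang)
    out_labels = []
    for lab in labels:
        out_labels.extend([(*lab, "cos"), (*lab, "sin")])
    return FeatureMatrix(data, out_labels, stride_ns=trajectory.stride_ns)


# ---------------------------------------------------------------------------
# VAMP-2 and TICA
# ---------------------------------------------------------------------------

def _lagged_pairs(data, lag):
    data = np.asarray(data, dtype=float)
    if data.shape[0] <= lag:
        raise ValueError("n_frames must exceed the lag")
    return data[:-lag], data[lag:]


def _inv_sqrt(mat: np.ndarray, ridge: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    floor = max(ridge, vals.max() * 1e-12)
    keep = vals > floor
    return vecs[:, keep] @ np.diag(vals[keep] ** -0.5) @ vecs[:, keep].T


def vamp2_score(features, lag: int, n_components: int = 10,
                ridge: float = 1e-10) -> float:
    """VAMP-2 score of the feature space at the given lag (frames).

    Sum of squared singular values of the half-weighted time-lagged
    covariance operator, truncated at ``n_components`` (the constant
    function counts as one component, so the score is >= 1 and
    ``n_components = 1`` returns exactly 1).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components == 1:
        return 1.0
    data = features.data if isinstance(features, FeatureMatrix) else features
    x0, xt = _lagged_pairs(data, lag)
    m0, mt = x0.mean(axis=0), xt.mean(axis=0)
    a = x0 - m0
    b = xt - mt
    n = a.shape[0]
    c00 = a.T @ a / n
    ctt = b.T @ b / n
    c0t = a.T @ b / n
    k = _inv_sqrt(c00, ridge) @ c0t @ _inv_sqrt(ctt, ridge)
    s = np.linalg.svd(k, compute_uv=False)
    s = np.clip(s, 0.0, 1.0)
    return float(1.0 + np.sum(s[: n_components - 1] ** 2))


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ct: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray  # columns are independent components
    n_dims: int

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        return (data - self.mean) @ self.loadings[:, : self.n_dims]


def fit_tica(features, lag: int, n_dims: int = 2, ridge: float = 1e-10):
    """Symmetrized (reversible) TICA.

    Solves the generalized eigenproblem C_tau v = lambda C_0 v with
    symmetrized covariances; returns (TICAModel, projected coordinates).
    Rank deficiency is handled with a logged ridge.
    """
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    data = features.data if isinstance(features, FeatureMatrix) else features
    x0, xt = _lagged_pairs(data, lag)
    mean = 0.5 * (x0.mean(axis=0) + xt.mean(axis=0))
    a = x0 - mean
    b = xt - mean
    n = a.shape[0]
    c0 = 0.5 * (a.T @ a + b.T @ b) / n
    ct = 0.5 * (a.T @ b + b.T @ a) / n
    scale = np.trace(c0) / c0.shape[0]
    reg = ridge * max(scale, 1.0)
    try:
        vals, vecs = scipy.linalg.eigh(ct, c0 + reg * np.eye(c0.shape[0]))
    except scipy.linalg.LinAlgError:
        reg = 1e-6 * max(scale, 1.0)
        warnings.warn(f"rank-deficient covariance; ridge raised to {reg:g}",
                      stacklevel=2)
        vals, vecs = scipy.linalg.eigh(ct, c0 + reg * np.eye(c0.shape[0]))
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], -1.0, 1.0)
    vecs = vecs[:, order]
    model = TICAModel(lag=lag, mean=mean, c0=c0, ct=ct, eigenvalues=vals,
                      loadings=vecs, n_dims=min(n_dims, vecs.shape[1]))
    return model, model.transform(data)


# ---------------------------------------------------------------------------
# Microstates and transition-matrix estimation
# ---------------------------------------------------------------------------

def cluster_microstates(projected: np.ndarray, k_override: int | None = None,
                        seed: int = DEFAULT_KMEANS_SEED, n_init: int = 2):
    """k-means microstates on the projected coordinates.

    k defaults to round(sqrt(n_frames)); k-means++ initialization with a
    fixed seed.  Empty clusters (possible with degenerate data) are pruned
    and labels compacted.
    """
    projected = np.asarray(projected, dtype=float)
    if projected.ndim == 1:
        projected = projected[:, None]
    n = projected.shape[0]
    k = int(round(np.sqrt(n))) if k_override is None else int(k_override)
    if k > n:
        raise ValueError(f"k = {k} exceeds n_frames = {n}")
    n_distinct = np.unique(projected, axis=0).shape[0]
    k = min(k, n_distinct)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                random_state=seed)
    labels = km.fit_predict(projected)
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    labels = np.array([remap[v] for v in labels])
    centers = km.cluster_centers_[used]
    return centers, labels


@dataclass
class MSMModel:
    counts: np.ndarray            # (k, k) counts on the active set
    transition_matrix: np.ndarray
    stationary: np.ndarray
    lag_frames: int
    active_set: np.ndarray        # original microstate labels of active states
    mode: str = "mle_reversible"
    lag_ns: float | None = None
    pi_samples: np.ndarray | None = None  # bayesian mode: posterior pi draws

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        vals = np.linalg.eigvals(self.transition_matrix)
        vals = np.real(vals[np.argsort(-np.real(vals))])
        return vals if k is None else vals[:k]

    def pi_std(self) -> np.ndarray | None:
        if self.pi_samples is None:
            return None
        return self.pi_samples.std(axis=0)


def _count_matrix(assignments, lag: int, n_states: int) -> np.ndarray:
    c = np.zeros((n_states, n_states))
    for traj in assignments:
        traj = np.asarray(traj)
        if traj.shape[0] > lag:
            np.add.at(c, (traj[:-lag], traj[lag:]), 1.0)  # sliding window
    return c


def _largest_scc(c: np.ndarray) -> np.ndarray:
    strong = csr_matrix(c > 0)
    n_comp, labels = connected_components(strong, directed=True,
                                          connection="strong")
    sizes = np.bincount(labels, weights=c.sum(axis=1))
    return np.where(labels == np.argmax(sizes))[0]


def _reversible_mle(c: np.ndarray, tol: float = 1e-13, max_iter: int = 10000):
    """Reversible maximum-likelihood transition matrix by fixed-point
    iteration on the symmetric flux variables."""
    csym = c + c.T
    ci = c.sum(axis=1)
    x = csym.copy()
    xi = x.sum(axis=1)
    for _ in range(max_iter):
        denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            x_new = np.where(csym > 0, csym / denom, 0.0)
        xi_new = x_new.sum(axis=1)
        if np.max(np.abs(xi_new / xi_new.sum() - xi / xi.sum())) < tol:
            x, xi = x_new, xi_new
            break
        x, xi = x_new, xi_new
    t = x / xi[:, None]
    mu = xi / xi.sum()
    return t, mu


def transition_matrix_from_counts(c: np.ndarray, mode: str = "mle_reversible"):
    """(T, stationary) from a connected count matrix.

    ``mle_reversible`` enforces detailed balance via fixed-point
    iteration; ``nonreversible`` row-normalizes and takes the leading
    left eigenvector.
    """
    c = np.asarray(c, dtype=float)
    if mode == "nonreversible":
        t = c / c.sum(axis=1, keepdims=True)
        return t, _stationary_from_t(t)
    if mode in ("mle_reversible", "bayesian"):
        return _reversible_mle(c)
    raise ValueError(f"unknown mode {mode!r}")


def _stationary_from_t(t: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(t.T)
    i = np.argmin(np.abs(vals - 1.0))
    mu = np.real(vecs[:, i])
    mu = np.abs(mu)
    return mu / mu.sum()


def estimate_msm(assignments, lag_frames: int, mode: str = "mle_reversible",
                 n_samples: int = 100, seed: int = 0,
                 stride_ns: float | None = None) -> MSMModel:
    """Estimate an MSM from microstate assignments.

    ``assignments`` is one integer array or a list of them (one per
    trajectory).  Counts use a sliding window at ``lag_frames``; the
    estimate is restricted to the largest strongly connected set.
    Modes: ``mle_reversible`` (detailed balance enforced),
    ``nonreversible`` (row-normalized counts), ``bayesian``
    (reversible MLE point estimate plus reversible-count-resampling
    posterior draws of pi for error bars).
    """
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    if isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        assignments = [assignments]
    assignments = [np.asarray(a, dtype=int) for a in assignments]
    n_states = int(max(a.max() for a in assignments)) + 1
    c_full = _count_matrix(assignments, lag_frames, n_states)
    active = _largest_scc(c_full)
    if active.size == 0 or c_full[np.ix_(active, active)].sum() == 0:
        raise ValueError("no connected transitions at this lag")
    if active.size < n_states:
        warnings.warn(f"restricting to largest connected set: {active.size} of "
                      f"{n_states} microstates", stacklevel=2)
    c = c_full[np.ix_(active, active)]

    t, mu = transition_matrix_from_counts(c, mode)
    pi_samples = None
    if mode == "bayesian":
        rng = np.random.default_rng(seed)
        draws = []
        row_tot = c.sum(axis=1)
        probs = c / row_tot[:, None]
        for _ in range(n_samples):
            c_s = np.vstack([rng.multinomial(int(round(row_tot[i])), probs[i])
                             for i in range(c.shape[0])]).astype(float)
            c_s = np.where(c_s + c_s.T > 0, c_s, 0.0)
            try:
                _, mu_s = _reversible_mle(c_s, tol=1e-10, max_iter=2000)
                draws.append(mu_s)
            except Exception:
                continue
        pi_samples = np.array(draws) if draws else None
    lag_ns = lag_frames * stride_ns if stride_ns else None
    return MSMModel(counts=c, transition_matrix=t, stationary=mu,
                    lag_frames=lag_frames, active_set=active, mode=mode,
                    lag_ns=lag_ns, pi_samples=pi_samples)


# ---------------------------------------------------------------------------
# Implied timescales and Chapman-Kolmogorov
# ---------------------------------------------------------------------------

def implied_timescales(models: Sequence[MSMModel], n_timescales: int = 3,
                       frame_ns: float = 1.0) -> pd.DataFrame:
    """t_i(tau) = -tau / ln(lambda_i(tau)) for each model; non-decaying or
    non-positive eigenvalues yield NaN (reported absent)."""
    rows = []
    for model in models:
        vals = model.eigenvalues(n_timescales + 1)[1:]
        tau = model.lag_frames * frame_ns
        for i, lam in enumerate(vals, start=2):
            if lam >= 1.0 or lam <= 0.0:
                ts = np.nan
            else:
                ts = -tau / np.log(lam)
            rows.append({"lag": tau, "index": i, "eigenvalue": float(lam),
                         "timescale": ts})
    return pd.DataFrame(rows)


def its_over_lags(assignments, lags: Sequence[int], n_timescales: int = 3,
                  frame_ns: float = 1.0, mode: str = "mle_reversible",
                  rel_tol: float = 0.10):
    """Implied-timescale table over lags plus a convergence flag (relative
    change of the slowest timescale across the last two lags < rel_tol)."""
    if len(lags) < 2:
        raise ValueError("need at least two lags")
    models = [estimate_msm(assignments, lag, mode=mode) for lag in lags]
    table = implied_timescales(models, n_timescales, frame_ns)
    slow = table[table["index"] == 2].sort_values("lag")["timescale"].to_numpy()
    converged = bool(np.isfinite(slow[-2:]).all() and
                     abs(slow[-1] - slow[-2]) / abs(slow[-2]) < rel_tol)
    return table, converged


def _coarse_grain_matrix(t: np.ndarray, mu: np.ndarray,
                         sets: Sequence[np.ndarray]) -> np.ndarray:
    m = len(sets)
    out = np.zeros((m, m))
    for a, sa in enumerate(sets):
        wa = mu[sa]
        for b, sb in enumerate(sets):
            out[a, b] = wa @ t[np.ix_(sa, sb)].sum(axis=1) / wa.sum()
    return out


@dataclass
class CKResult:
    factors: list
    predicted: np.ndarray   # (n_factors, m, m)
    estimated: np.ndarray
    lower: np.ndarray       # bootstrap band on diagonal occupations
    upper: np.ndarray
    max_deviation: float
    passed: bool


def ck_test(model: MSMModel, assignments, n_metastable: int = 3,
            factors: Sequence[int] = (2, 3, 4, 5), n_bootstrap: int = 30,
            seed: int = 0, n_blocks: int = 50) -> CKResult:
    """Chapman-Kolmogorov test: T(tau)^k vs re-estimated T(k tau), both
    projected onto the PCCA++ metastable sets of ``model``.

    The comparison uses the per-state occupation curves (diagonal of the
    coarse matrices); the band is a bootstrap (resampled trajectory
    blocks) 95% interval around the estimates.  ``passed`` is true when
    every predicted occupation lies inside its band.
    """
    if min(factors) < 2:
        raise ValueError("factors must be >= 2")
    if isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        assignments = [assignments]
    assignments = [np.asarray(a, dtype=int) for a in assignments]

    part = pcca_coarse_grain(model, n_metastable)
    sets = [np.where(part.assignments == s)[0] for s in range(n_metastable)]
    label_of = {orig: i for i, orig in enumerate(model.active_set)}

    def coarse_at(k_lag, trajs):
        m_k = estimate_msm(trajs, k_lag)
        # map this model's active set onto the reference partition
        sets_k, ok = [], True
        for s in sets:
            orig = model.active_set[s]
            local = [np.where(m_k.active_set == o)[0] for o in orig]
            local = np.array([v[0] for v in local if v.size])
            if local.size == 0:
                ok = False
                local = np.array([0])
            sets_k.append(local)
        if not ok:
            warnings.warn("metastable set lost at long lag; truncated",
                          stacklevel=2)
        return _coarse_grain_matrix(m_k.transition_matrix, m_k.stationary, sets_k)

    pred = np.empty((len(factors), n_metastable, n_metastable))
    est = np.empty_like(pred)
    t1 = _coarse_grain_matrix(model.transition_matrix, model.stationary, sets)
    for fi, k in enumerate(factors):
        pred[fi] = np.linalg.matrix_power(
            _coarse_grain_matrix(np.linalg.matrix_power(model.transition_matrix, k),
                                 model.stationary, sets), 1)
        est[fi] = coarse_at(k * model.lag_frames, assignments)

    # bootstrap band on the estimated diagonals
    rng = np.random.default_rng(seed)
    blocks = []
    for traj in assignments:
        size = max(len(traj) // n_blocks, max(factors) * model.lag_frames + 1)
        blocks.extend(traj[i:i + size] for i in range(0, len(traj), size))
    boot = np.full((n_bootstrap, len(factors), n_metastable), np.nan)
    for bi in range(n_bootstrap):
        pick = [blocks[j] for j in rng.integers(0, len(blocks), len(blocks))]
        try:
            for fi, k in enumerate(factors):
                boot[bi, fi] = np.diag(coarse_at(k * model.lag_frames, pick))
        except ValueError:
            continue
    lower = np.nanpercentile(boot, 2.5, axis=0)
    upper = np.nanpercentile(boot, 97.5, axis=0)
    diag_pred = np.array([np.diag(pred[fi]) for fi in range(len(factors))])
    diag_est = np.array([np.diag(est[fi]) for fi in range(len(factors))])
    max_dev = float(np.max(np.abs(diag_pred - diag_est)))
    passed = bool(np.all((diag_pred >= lower - 1e-12) &
                         (diag_pred <= upper + 1e-12)))
    return CKResult(list(factors), pred, est, lower, upper, max_dev, passed)


# ---------------------------------------------------------------------------
# PCCA++ coarse-graining
# ---------------------------------------------------------------------------

@dataclass
class MetastablePartition:
    n_states: int
    memberships: np.ndarray      # (n_micro, n_states), rows sum to 1
    assignments: np.ndarray      # crisp argmax per microstate
    pi: np.ndarray               # equilibrium probability per metastable state
    microstate_mu: np.ndarray
    representative_frames: list = field(default_factory=list)


def _pcca_vertices(x: np.ndarray) -> np.ndarray:
    """Inner-simplex vertex search on the eigenvector rows."""
    n, m = x.shape
    ortho = x - x.mean(axis=0)
    idx = np.empty(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = x - x[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        v = ortho[idx[j]] / norms[idx[j]]
        ortho = ortho - np.outer(ortho @ v, v)
    return idx


def pcca_coarse_grain(model: MSMModel, n_states: int = 3) -> MetastablePartition:
    """PCCA++ memberships from the top right-eigenvector simplex.

    Requires a reversible transition matrix; pi_i sums the stationary mass
    of the crisp members of each metastable state.
    """
    t = model.transition_matrix
    mu = model.stationary
    k = t.shape[0]
    if n_states > k:
        raise ValueError("more metastable states than microstates")
    if n_states == k:
        memberships = np.eye(k)
        assignments = np.arange(k)
        return MetastablePartition(n_states, memberships, assignments,
                                   mu.copy(), mu.copy())
    d = np.sqrt(mu)
    sym = (t * d[:, None]) / d[None, :]
    sym = 0.5 * (sym + sym.T)
    vals, vecs = np.linalg.eigh(sym)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    if vals[n_states - 1] <= 0:
        raise ValueError("not enough positive leading eigenvalues for the "
                         "requested number of metastable states")
    if n_states < k and vals[n_states - 1] - vals[n_states] < 1e-10:
        warnings.warn("nearly degenerate eigenvalues at the metastable cut",
                      stacklevel=2)
    psi = vecs[:, order[:n_states]] / d[:, None]
    psi[:, 0] = 1.0  # the stationary eigenvector is constant
    verts = _pcca_vertices(psi)
    a = np.linalg.inv(psi[verts])
    chi = psi @ a
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    assignments = chi.argmax(axis=1)
    pi = np.array([mu[assignments == s].sum() for s in range(n_states)])
    return MetastablePartition(n_states, chi, assignments, pi, mu.copy())


def select_representatives(partition: MetastablePartition, projected: np.ndarray,
                           assignments: np.ndarray,
                           centers: np.ndarray | None = None,
                           n_per_state: int = 3) -> list:
    """Deterministic representative frame ids: per metastable state, the
    ``n_per_state`` most populated member microstates contribute the frame
    nearest their center each (ties -> lowest frame index)."""
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    projected = np.asarray(projected, dtype=float)
    if projected.ndim == 1:
        projected = projected[:, None]
    assignments = np.asarray(assignments, dtype=int)
    reps = []
    for s in range(partition.n_states):
        micro = np.where(partition.assignments == s)[0]
        order = micro[np.argsort(-partition.microstate_mu[micro], kind="stable")]
        chosen = order[:n_per_state]
        if chosen.size < n_per_state:
            warnings.warn(f"metastable state {s} has only {chosen.size} "
                          f"microstates", stacklevel=2)
        state_reps = []
        for m in chosen:
            frames = np.where(assignments == m)[0]
            if frames.size == 0:
                continue
            if centers is not None:
                c = centers[m]
            else:
                c = projected[frames].mean(axis=0)
            d = np.linalg.norm(projected[frames] - c, axis=1)
            state_reps.append(int(frames[np.argmin(d)]))
        reps.append(state_reps)
    partition.representative_frames = reps
    return reps


def msm_pipeline(features, tica_lag: int, msm_lag: int, n_states: int = 3,
                 k_override: int | None = None, n_dims: int = 2,
                 seed: int = DEFAULT_KMEANS_SEED, mode: str = "mle_reversible"):
    """Convenience driver: TICA -> k-means -> MSM -> PCCA++ -> representatives.

    Returns a dict with keys tica, projected, centers, assignments, model,
    partition, representatives.
    """
    tica, projected = fit_tica(features, tica_lag, n_dims=n_dims)
    centers, assignments = cluster_microstates(projected, k_override, seed=seed)
    model = estimate_msm(assignments, msm_lag, mode=mode, seed=seed)
    # microstates outside the active set: map their frames out of the MSM
    active_map = {orig: i for i, orig in enumerate(model.active_set)}
    frame_mask = np.isin(assignments, model.active_set)
    active_assign = np.array([active_map[a] for a in assignments[frame_mask]])
    partition = pcca_coarse_grain(model, n_states)
    reps_local = select_representatives(partition, projected[frame_mask],
                                        active_assign,
                                        centers[model.active_set])
    frame_ids = np.where(frame_mask)[0]
    reps = [[int(frame_ids[r]) for r in state] for state in reps_local]
    partition.representative_frames = reps
    return {"tica": tica, "projected": projected, "centers": centers,
            "assignments": assignments, "model": model, "partition": partition,
            "representatives": reps}
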