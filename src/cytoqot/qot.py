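"""Quantized optimal transport between cytometry samples.

Each sample's cell cloud is quantized as a Gaussian mixture
``w = sum_h alpha_h N(mu_h, Sigma_h)``; the distance between two samples is
the optimal-transport cost between their mixtures, where moving unit mass
from component p to component q costs the squared 2-Wasserstein distance
between the two Gaussians (or, in the scalable variant, the cosine distance
between their means).  The transport problem is the exact linear program

    min_T sum_pq T_pq C_pq   s.t.  T 1 = alpha_i,  T' 1 = alpha_j,  T >= 0,

solved without entropic smoothing.  With the Gaussian-W2 cost the square
root of the optimal objective is a metric on mixture space (the mixture
Wasserstein distance, MW2); the raw objective is kept alongside.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linprog
from sklearn.mixture import GaussianMixture

from .io import CytometrySample, StudyCollection, ValidationError

__all__ = [
    "QotConfig", "GmmSummary", "CostMatrix", "TransportPlan",
    "DistanceMatrix", "FitError", "SolverError", "fit_gmm",
    "gaussian_w2_sq", "cosine_cost", "build_cost_matrix", "solve_transport",
    "qot_distance", "pairwise_distances", "GmmCache", "mixture_distance",
]


class FitError(RuntimeError):
    """EM did not converge; carries the best iterate as ``.summary``."""

    def __init__(self, message, summary=None):
        super().__init__(message)
        self.summary = summary


class SolverError(RuntimeError):
    """The transport LP solver failed; carries the solver status."""


@dataclass(frozen=True)
class QotConfig:
    """Quantization and distance settings.

    selection: "bic" chooses the component count by the Bayesian
        information criterion over ``bic_range`` (sweep stops early after
        ``bic_patience`` consecutive increases; set None to disable);
        "fixed" uses ``n_components`` as given.
    covariance_type: "full" or "diag" (diagonal is steadier at high marker
        counts).  ``reg_covar`` is the diagonal jitter guarding the matrix
        square root.
    cost_mode: "gaussian_w2" (closed-form Gaussian W2^2 ground cost) or
        "cosine" (1 - cosine similarity of component means).
    sqrt_distance: report sqrt of the LP objective in gaussian_w2 mode so
        the result is a metric; cosine mode always reports the raw
        objective.
    """

    selection: str = "bic"
    n_components: int = 3
    bic_range: tuple[int, int] = (1, 10)
    bic_patience: int | None = 2
    covariance_type: str = "full"
    reg_covar: float = 1e-6
    max_iter: int = 200
    cost_mode: str = "gaussian_w2"
    sqrt_distance: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.selection not in {"bic", "fixed"}:
            raise ValidationError(f"unknown selection {self.selection!r}")
        if self.covariance_type not in {"full", "diag"}:
            raise ValidationError(
                f"unknown covariance_type {self.covariance_type!r}")
        if self.cost_mode not in {"gaussian_w2", "cosine"}:
            raise ValidationError(f"unknown cost_mode {self.cost_mode!r}")
        object.__setattr__(self, "bic_range", tuple(self.bic_range))

    def fit_key(self) -> tuple:
        return (self.selection, self.n_components, self.bic_range,
                self.bic_patience, self.covariance_type, self.reg_covar,
                self.max_iter, self.seed)


@dataclass
class GmmSummary:
    """A fitted mixture: weights, means and (full) covariance stack."""

    weights: np.ndarray          # (H,)
    means: np.ndarray            # (H, m)
    covariances: np.ndarray      # (H, m, m)
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        self.validate()

    def validate(self):
        H, m = self.means.shape
        if self.weights.shape != (H,) or self.covariances.shape != (H, m, m):
            raise ValidationError("inconsistent GMM component shapes")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("mixture weights must be a simplex vector")
        for k, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValidationError(f"covariance {k} not symmetric")
            lo = np.linalg.eigvalsh(cov).min()
            if lo < -1e-8 * max(1.0, abs(cov).max()):
                raise ValidationError(f"covariance {k} not PSD (min eig {lo})")

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def n_markers(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        doc = {"weights": self.weights.tolist(), "means": self.means.tolist(),
               "covariances": self.covariances.tolist(),
               "fit_metadata": self.fit_metadata}
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "GmmSummary":
        doc = json.loads(text)
        return cls(weights=np.array(doc["weights"]),
                   means=np.array(doc["means"]),
                   covariances=np.array(doc["covariances"]),
                   fit_metadata=doc.get("fit_metadata", {}))


@dataclass
class CostMatrix:
    values: np.ndarray
    mode: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise ValidationError("cost matrix has negative entries")
        self.values = np.clip(self.values, 0.0, None)
        if self.mode == "cosine" and (self.values > 2 + 1e-9).any():
            raise ValidationError("cosine costs must lie in [0, 2]")


@dataclass
class TransportPlan:
    """An optimal coupling between two mixtures and its objective value."""

    coupling: np.ndarray
    objective: float
    source_weights: np.ndarray
    target_weights: np.ndarray

    def validate(self, cost: np.ndarray | None = None):
        T = self.coupling
        if (T < -1e-12).any():
            raise ValidationError("coupling has negative mass")
        if not np.allclose(T.sum(axis=1), self.source_weights, atol=1e-7):
            raise ValidationError("row sums do not match source weights")
        if not np.allclose(T.sum(axis=0), self.target_weights, atol=1e-7):
            raise ValidationError("column sums do not match target weights")
        if cost is not None:
            val = float((T * cost).sum())
            if abs(val - self.objective) > 1e-9 * max(1.0, abs(val)):
                raise ValidationError("objective inconsistent with coupling")


# --- quantization ---------------------------------------------------------

def _canonical_rows(X: np.ndarray) -> np.ndarray:
    # Lexicographic row order makes the fit independent of cell order in
    # the input file (k-means++ seeding is otherwise row-order sensitive).
    order = np.lexsort(X.T[::-1])
    return X[order]


def _fit_one(X, H, config: QotConfig):
    gm = GaussianMixture(n_components=H,
                         covariance_type=config.covariance_type,
                         reg_covar=config.reg_covar,
                         max_iter=config.max_iter,
                         random_state=config.seed)
    gm.fit(X)
    return gm


def _summarize(gm, config: QotConfig, score=None) -> GmmSummary:
    weights = gm.weights_.copy()
    means = gm.means_.copy()
    if config.covariance_type == "diag":
        covs = np.array([np.diag(c) for c in gm.covariances_])
    else:
        covs = gm.covariances_.copy()
        covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    order = np.lexsort((means[:, 0], -weights))
    meta = {"seed": config.seed, "covariance_type": config.covariance_type,
            "selection_score": score, "converged": bool(gm.converged_),
            "n_components": int(weights.shape[0])}
    weights = weights[order] / weights.sum()
    return GmmSummary(weights=weights, means=means[order],
                      covariances=covs[order], fit_metadata=meta)


def fit_gmm(sample: CytometrySample | np.ndarray,
            config: QotConfig = QotConfig()) -> GmmSummary:
    """Quantize a sample as a Gaussian mixture.

    Component count is either fixed or BIC-selected; components are
    returned sorted by descending weight (ties by first mean coordinate)
    and the result is deterministic given the data, the settings and the
    seed.
    """
    X = sample.matrix if isinstance(sample, CytometrySample) else np.asarray(sample, float)
    n = X.shape[0]
    X = _canonical_rows(X)
    if config.selection == "fixed":
        if config.n_components > n:
            raise ValidationError(
                f"n_components={config.n_components} exceeds {n} cells")
        gm = _fit_one(X, config.n_components, config)
        summary = _summarize(gm, config)
        if not gm.converged_:
            raise FitError(
                f"EM did not converge in {config.max_iter} iterations",
                summary=summary)
        return summary

    lo, hi = config.bic_range
    if hi > n:
        raise ValidationError(f"BIC range upper bound {hi} exceeds {n} cells")
    best = None
    best_bic = np.inf
    rising = 0
    for H in range(lo, hi + 1):
        gm = _fit_one(X, H, config)
        bic = gm.bic(X)
        if bic < best_bic:
            best, best_bic, rising = gm, bic, 0
        else:
            rising += 1
            if config.bic_patience is not None and rising >= config.bic_patience:
                break
    summary = _summarize(best, config, score=float(best_bic))
    if not best.converged_:
        raise FitError(
            f"EM did not converge in {config.max_iter} iterations "
            f"(selected H={best.n_components})", summary=summary)
    return summary


# --- ground costs ---------------------------------------------------------

def _check_psd(cov: np.ndarray, name: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        cov = cov.reshape(1, 1)
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValidationError(f"{name}: covariance not symmetric")
    scale = max(1.0, abs(cov).max())
    vals = np.linalg.eigvalsh(cov)
    if vals.min() < -1e-8 * scale:
        raise ValidationError(f"{name}: covariance not PSD (min eig {vals.min()})")
    return cov


def _psd_sqrt(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def gaussian_w2_sq(mean_a, cov_a, mean_b, cov_b) -> float:
    """Squared 2-Wasserstein distance between two Gaussians.

    ``||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a^{1/2} S_b S_a^{1/2})^{1/2})``
    (the Bures term).  Matrix square roots use symmetric eigendecomposition
    with negative eigenvalues clamped to zero.
    """
    mean_a = np.atleast_1d(np.asarray(mean_a, float))
    mean_b = np.atleast_1d(np.asarray(mean_b, float))
    cov_a = _check_psd(cov_a, "cov_a")
    cov_b = _check_psd(cov_b, "cov_b")
    if mean_a.shape != mean_b.shape or cov_a.shape != cov_b.shape:
        raise ValidationError("mean/covariance dimension mismatch")
    gap = float(np.sum((mean_a - mean_b) ** 2))
    root_a = _psd_sqrt(cov_a)
    inner = root_a @ cov_b @ root_a
    # trace of the PSD square root = sum of sqrt eigenvalues
    cross = float(np.sqrt(np.clip(np.linalg.eigvalsh(0.5 * (inner + inner.T)),
                                  0.0, None)).sum())
    bures = float(np.trace(cov_a) + np.trace(cov_b)) - 2.0 * cross
    val = gap + bures
    scale = max(1.0, gap + abs(np.trace(cov_a)) + abs(np.trace(cov_b)))
    if val < -1e-8 * scale:
        raise ValidationError(f"negative W2^2 beyond tolerance: {val}")
    # floor: eigendecomposition noise is ~1e-15 * scale; anything smaller
    # than 1e-12 * scale is numerically indistinguishable from zero
    if val < 1e-12 * scale:
        return 0.0
    return val


def cosine_cost(mean_a, mean_b) -> float:
    """Cosine distance ``1 - cos(mu_a, mu_b)`` between component means."""
    a = np.asarray(mean_a, float).ravel()
    b = np.asarray(mean_b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 1e-12 or nb <= 1e-12:
        raise ValidationError("cosine cost undefined for zero-norm mean")
    val = 1.0 - float(a @ b) / (na * nb)
    return float(np.clip(val, 0.0, 2.0))


def build_cost_matrix(gmm_a: GmmSummary, gmm_b: GmmSummary,
                      mode: str = "gaussian_w2") -> CostMatrix:
    """Pairwise component-to-component ground costs between two mixtures."""
    if gmm_a.n_markers != gmm_b.n_markers:
        raise ValidationError(
            f"marker dimension mismatch: {gmm_a.n_markers} vs {gmm_b.n_markers}")
    Ha, Hb = gmm_a.n_components, gmm_b.n_components
    C = np.empty((Ha, Hb))
    for p in range(Ha):
        for q in range(Hb):
            if mode == "gaussian_w2":
                C[p, q] = gaussian_w2_sq(gmm_a.means[p], gmm_a.covariances[p],
                                         gmm_b.means[q], gmm_b.covariances[q])
            elif mode == "cosine":
                C[p, q] = cosine_cost(gmm_a.means[p], gmm_b.means[q])
            else:
                raise ValidationError(f"unknown cost mode {mode!r}")
    return CostMatrix(values=C, mode=mode)


# --- exact transport LP ---------------------------------------------------

def solve_transport(source_weights, target_weights,
                    cost: CostMatrix | np.ndarray) -> TransportPlan:
    """Solve the discrete transport LP exactly (no entropic smoothing).

    Minimizes ``sum_pq T_pq C_pq`` over couplings whose row sums equal the
    source weights and column sums the target weights.
    """
    a = np.asarray(source_weights, dtype=float).ravel()
    b = np.asarray(target_weights, dtype=float).ravel()
    C = cost.values if isinstance(cost, CostMatrix) else np.asarray(cost, float)
    if C.shape != (a.size, b.size):
        raise ValidationError(f"cost shape {C.shape} vs marginals "
                              f"({a.size}, {b.size})")
    for name, w in (("source", a), ("target", b)):
        if (w < -1e-12).any():
            raise ValidationError(f"{name} weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"{name} weights sum to {w.sum()}, expected 1")
    Ha, Hb = C.shape
    # equality constraints: Ha row sums then Hb column sums (one is
    # redundant; HiGHS copes with the dependent row)
    A = np.zeros((Ha + Hb, Ha * Hb))
    for p in range(Ha):
        A[p, p * Hb:(p + 1) * Hb] = 1.0
    for q in range(Hb):
        A[Ha + q, q::Hb] = 1.0
    rhs = np.concatenate([a, b])
    res = linprog(C.ravel(), A_eq=A, b_eq=rhs, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise SolverError(f"transport LP failed: {res.status} {res.message}")
    T = np.clip(res.x.reshape(Ha, Hb), 0.0, None)
    plan = TransportPlan(coupling=T, objective=float((T * C).sum()),
                         source_weights=a, target_weights=b)
    plan.validate(cost=C)
    return plan


# --- sample-level distances -----------------------------------------------

class GmmCache(dict):
    """Memoizes GMM fits keyed by (matrix content, markers, fit settings).

    With a ``directory`` the cache also persists fits as JSON documents so
    repeated runs (e.g., the leave-one-out sweep) can reuse them.
    """

    def __init__(self, directory=None):
        super().__init__()
        self.hits = 0
        self.misses = 0
        self.directory = None
        if directory is not None:
            from pathlib import Path
            self.directory = Path(directory)
            self.directory.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def key(sample: CytometrySample, config: QotConfig) -> tuple:
        digest = hashlib.sha1(
            np.ascontiguousarray(sample.matrix).tobytes()).hexdigest()
        return (digest, sample.marker_names, config.fit_key())

    def _path(self, k: tuple):
        digest = hashlib.sha1(repr(k).encode()).hexdigest()
        return self.directory / f"gmm_{digest}.json"

    def fit(self, sample: CytometrySample, config: QotConfig) -> GmmSummary:
        k = self.key(sample, config)
        if k in self:
            self.hits += 1
            return self[k]
        if self.directory is not None:
            path = self._path(k)
            if path.exists():
                self.hits += 1
                summary = GmmSummary.from_json(path.read_text())
                self[k] = summary
                return summary
        self.misses += 1
        summary = fit_gmm(sample, config)
        self[k] = summary
        if self.directory is not None:
            self._path(k).write_text(summary.to_json())
        return summary


def _fit(sample, config, cache):
    if cache is not None:
        return cache.fit(sample, config)
    return fit_gmm(sample, config)


def mixture_distance(gmm_a: GmmSummary, gmm_b: GmmSummary,
                     mode: str = "gaussian_w2",
                     sqrt_distance: bool = True) -> float:
    """Transport distance between two already-fitted mixtures."""
    C = build_cost_matrix(gmm_a, gmm_b, mode=mode)
    plan = solve_transport(gmm_a.weights, gmm_b.weights, C)
    if mode == "gaussian_w2" and sqrt_distance:
        return float(np.sqrt(max(plan.objective, 0.0)))
    return float(plan.objective)


def qot_transport(sample_a: CytometrySample, sample_b: CytometrySample,
                  config: QotConfig = QotConfig(),
                  cache: GmmCache | None = None):
    """Full QOT pipeline for one pair: returns (distance, plan, gmm_a, gmm_b).

    ``distance`` follows the configured convention: sqrt of the LP
    objective for the gaussian_w2 cost (a metric on mixtures), raw
    objective for the cosine cost.  The raw objective is always available
    as ``plan.objective``.
    """
    if sample_a.marker_names != sample_b.marker_names:
        raise ValidationError("samples must share marker set and order")
    gmm_a = _fit(sample_a, config, cache)
    gmm_b = _fit(sample_b, config, cache)
    C = build_cost_matrix(gmm_a, gmm_b, mode=config.cost_mode)
    plan = solve_transport(gmm_a.weights, gmm_b.weights, C)
    if config.cost_mode == "gaussian_w2" and config.sqrt_distance:
        dist = float(np.sqrt(max(plan.objective, 0.0)))
    else:
        dist = float(plan.objective)
    return dist, plan, gmm_a, gmm_b


def qot_distance(sample_a: CytometrySample, sample_b: CytometrySample,
                 config: QotConfig = QotConfig(),
                 cache: GmmCache | None = None) -> float:
    """QOT distance between two samples (see :func:`qot_transport`)."""
    return qot_transport(sample_a, sample_b, config, cache)[0]


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of sample-level QOT distances."""

    values: np.ndarray
    sample_ids: list[str]
    subject_ids: list[str]
    timepoints: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        P = len(self.sample_ids)
        if self.values.shape != (P, P):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("distance matrix not symmetric")
        if (self.values < 0).any():
            raise ValidationError("negative distances")
        np.fill_diagonal(self.values, 0.0)
        self.values = 0.5 * (self.values + self.values.T)

    def to_tsv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.sample_ids)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "timepoint", self.timepoints)
        df.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col="sample_id",
                         float_precision="round_trip")
        subject_ids = df.pop("subject_id").astype(str).tolist()
        timepoints = df.pop("timepoint").astype(str).tolist()
        return cls(values=df.to_numpy(dtype=float),
                   sample_ids=[str(i) for i in df.index],
                   subject_ids=subject_ids, timepoints=timepoints)


def pairwise_distances(collection: StudyCollection,
                       markers=None,
                       config: QotConfig = QotConfig(),
                       cache: GmmCache | None = None) -> DistanceMatrix:
    """All-pairs QOT distance matrix over a (possibly restricted) panel."""
    if len(collection) < 2:
        raise ValidationError("need at least 2 samples")
    if markers is None:
        markers = collection.shared_markers
    markers = tuple(markers)
    if not markers:
        raise ValidationError("marker subset must be non-empty")
    unknown = [m for m in markers if m not in collection.shared_markers]
    if unknown:
        raise ValidationError(f"markers not in shared panel: {unknown}")
    samples = [s.select_markers(markers) for s in collection.samples]
    P = len(samples)
    D = np.zeros((P, P))
    for i, j in combinations(range(P), 2):
        D[i, j] = D[j, i] = qot_distance(samples[i], samples[j], config, cache)
    return DistanceMatrix(values=D,
                          sample_ids=[s.sample_id for s in samples],
                          subject_ids=[s.subject_id for s in samples],
                          timepoints=[s.timepoint for s in samples])
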