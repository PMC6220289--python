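"""Network-structured synthetic expression data.

The generator emulates the statistical structure of sparse, correlated
predictors in an ``n << p`` expression matrix:

1. a scale-free feature network is grown by preferential attachment
   (each node is a gene; hubs model highly connected genes);
2. pairwise shortest-path distances ``D`` over the network are turned
   into a correlation matrix ``Sigma_ij = decay ** D_ij`` (default decay
   0.7), so close features are strongly correlated and distant ones
   nearly independent;
3. samples are drawn i.i.d. from ``N(0, Sigma)``;
4. a small set of "true predictor" features is chosen — either
   clustered around high-degree cores, or half-scattered uniformly over
   the network — and a logistic model on those columns is thresholded
   to produce the binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.special import expit

from .data import ExpressionDataset

__all__ = [
    "FeatureNetwork",
    "OutcomeModel",
    "SimulationConfig",
    "generate_scale_free_network",
    "shortest_path_distances",
    "distance_to_covariance",
    "sample_gaussian",
    "select_true_predictors",
    "sample_coefficients",
    "generate_labels",
    "generate_dataset",
]


@dataclass
class FeatureNetwork:
    """Scale-free feature graph with optional distance / covariance matrices."""

    num_features: int
    graph: nx.Graph
    distances: np.ndarray | None = None
    covariance: np.ndarray | None = None
    covariance_repaired: bool = False

    @property
    def edges(self) -> list[tuple[int, int]]:
        return list(self.graph.edges())

    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree(i) for i in range(self.num_features)])


@dataclass
class OutcomeModel:
    """Sparse logistic outcome model over a subset of features."""

    true_predictor_indices: np.ndarray
    coefficients: np.ndarray
    intercept: float
    threshold: float
    case: Literal["clustered", "scattered"]

    def __post_init__(self) -> None:
        self.true_predictor_indices = np.asarray(self.true_predictor_indices, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.true_predictor_indices.shape != self.coefficients.shape:
            raise ValueError("indices and coefficients must have the same length")


def generate_scale_free_network(p: int, attach_m: int = 1, seed=None) -> FeatureNetwork:
    """Grow a scale-free graph on ``p`` feature nodes by preferential attachment.

    ``attach_m`` is the number of edges each new node attaches with;
    ``attach_m=1`` yields a tree, which maximizes the hub/leaf contrast.
    """
    if p < 2:
        raise ValueError(f"need at least 2 features, got p={p}")
    if attach_m < 1:
        raise ValueError(f"attach_m must be >= 1, got {attach_m}")
    if p < attach_m + 1:
        raise ValueError(f"p={p} too small for attach_m={attach_m} (need p >= attach_m+1)")
    rng = _as_rng(seed)
    graph = nx.barabasi_albert_graph(p, attach_m, seed=_nx_seed(rng))
    if not nx.is_connected(graph):  # pragma: no cover - BA graphs are connected
        raise RuntimeError("generated graph is unexpectedly disconnected")
    return FeatureNetwork(num_features=p, graph=graph)


def shortest_path_distances(network: FeatureNetwork) -> np.ndarray:
    """All-pairs shortest-path hop counts as a symmetric integer matrix."""
    p = network.num_features
    adj = nx.to_scipy_sparse_array(network.graph, nodelist=range(p), format="csr")
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if n_comp > 1:
        isolated = np.flatnonzero(labels != labels[0])
        raise ValueError(
            f"graph is disconnected: nodes {isolated[:10].tolist()} are not reachable "
            "from node 0"
        )
    D = shortest_path(csr_matrix(adj), method="D", directed=False, unweighted=True)
    D = np.asarray(D)
    network.distances = D
    return D


def distance_to_covariance(D: np.ndarray, decay: float = 0.7) -> tuple[np.ndarray, bool]:
    """Map hop distances to correlations, ``Sigma_ij = decay ** D_ij``.

    Returns ``(Sigma, repaired)``.  For tree graphs the result is the exact
    correlation matrix of a Gaussian tree model and hence positive definite;
    for denser graphs it may not be, in which case negative eigenvalues are
    clipped at a small floor and the diagonal re-unitized (``repaired=True``).
    """
    if not 0 < decay < 1:
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square matrix")
    if np.any(np.diag(D) != 0) or not np.allclose(D, D.T):
        raise ValueError("D must be symmetric with zero diagonal")
    sigma = decay ** D
    np.fill_diagonal(sigma, 1.0)
    repaired = False
    if not _is_positive_definite(sigma):
        repaired = True
        sigma = _clip_eigenvalues(sigma, floor=1e-8)
    return sigma, repaired


def sample_gaussian(sigma: np.ndarray, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. rows from ``N(0, sigma)`` via Cholesky."""
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got n={n}")
    sigma = np.asarray(sigma, dtype=float)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    rng = _as_rng(seed)
    Z = rng.standard_normal(size=(n, sigma.shape[0]))
    return Z @ L.T


def select_true_predictors(
    network: FeatureNetwork,
    num_cores: int,
    target_p0: int,
    case: Literal["clustered", "scattered"] = "clustered",
    degree_quantile: float = 0.99,
    seed=None,
) -> np.ndarray:
    """Pick the indices of the true predictors.

    Clustered case: ``num_cores`` cores are drawn from the top
    ``(1 - degree_quantile)`` fraction of nodes by degree, then the set is
    filled from the union of the cores' 1-hop neighborhoods (extended to
    2 hops if needed).  Scattered case: ``ceil(p0/2)`` indices are chosen
    the clustered way and the remaining ``floor(p0/2)`` uniformly from the
    whole network.
    """
    if num_cores < 1:
        raise ValueError("num_cores must be >= 1")
    if target_p0 < num_cores:
        raise ValueError(f"target_p0={target_p0} must be >= num_cores={num_cores}")
    rng = _as_rng(seed)
    p = network.num_features

    if case == "scattered":
        n_clustered = -(-target_p0 // 2)  # ceil
        clustered = _clustered_indices(network, num_cores, n_clustered, degree_quantile, rng)
        remaining = np.setdiff1d(np.arange(p), clustered)
        n_uniform = target_p0 - n_clustered
        uniform = rng.choice(remaining, size=n_uniform, replace=False)
        return np.sort(np.concatenate([clustered, uniform]))
    if case != "clustered":
        raise ValueError(f"unknown case {case!r}; expected 'clustered' or 'scattered'")
    return np.sort(_clustered_indices(network, num_cores, target_p0, degree_quantile, rng))


def _clustered_indices(
    network: FeatureNetwork,
    num_cores: int,
    count: int,
    degree_quantile: float,
    rng: np.random.Generator,
) -> np.ndarray:
    degrees = network.degrees()
    cutoff = np.quantile(degrees, degree_quantile)
    hubs = np.flatnonzero(degrees >= cutoff)
    if len(hubs) < num_cores:
        hubs = np.argsort(degrees)[::-1][:num_cores]
    cores = rng.choice(hubs, size=num_cores, replace=False)
    selected = set(cores.tolist())
    for radius in (1, 2):
        pool = set()
        for c in cores:
            pool.update(
                nx.single_source_shortest_path_length(network.graph, int(c), cutoff=radius)
            )
        pool -= selected
        need = count - len(selected)
        if need <= 0:
            break
        take = min(need, len(pool))
        picked = rng.choice(sorted(pool), size=take, replace=False)
        selected.update(int(i) for i in picked)
    if len(selected) < count:
        raise ValueError(
            f"cores' 2-hop neighborhoods hold only {len(selected)} features, "
            f"need {count}; increase num_cores"
        )
    return np.array(sorted(selected))


def sample_coefficients(
    p0: int,
    magnitude_range: tuple[float, float] = (0.05, 0.1),
    negative_fraction: float = 0.5,
    intercept: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, float]:
    """Draw effect sizes uniformly from ``magnitude_range`` with random sign flips."""
    low, high = magnitude_range
    if not 0 < low < high:
        raise ValueError(f"magnitude range must satisfy 0 < low < high, got {magnitude_range}")
    if not 0 <= negative_fraction <= 1:
        raise ValueError("negative_fraction must lie in [0, 1]")
    rng = _as_rng(seed)
    beta = rng.uniform(low, high, size=p0)
    flips = rng.random(p0) < negative_fraction
    beta[flips] *= -1.0
    return beta, float(intercept)


def generate_labels(X: np.ndarray, model: OutcomeModel) -> np.ndarray:
    """Deterministic hard-threshold labels from the logistic model.

    ``y_i = 1`` iff ``logit^{-1}(x_i' beta + beta0) > t`` (strict).
    """
    idx = model.true_predictor_indices
    if idx.size and idx.max() >= X.shape[1]:
        raise IndexError(
            f"predictor index {idx.max()} out of range for {X.shape[1]} features"
        )
    probs = expit(X[:, idx] @ model.coefficients + model.intercept)
    return (probs > model.threshold).astype(int)


@dataclass
class SimulationConfig:
    """All knobs of the generator, bundled.

    Defaults reproduce the benchmark design: 5,000 features, 400 samples,
    tree-shaped scale-free network, ``Sigma = 0.7^D``, effect sizes in
    (0.05, 0.1) with half the signs flipped, and a probability threshold at
    the sample median (balanced classes).  One core contributes roughly ten
    true predictors, so ``num_cores = p0 // 10`` when not given.
    """

    p: int = 5000
    n: int = 400
    attach_m: int = 1
    decay: float = 0.7
    p0: int = 50
    num_cores: int | None = None
    case: Literal["clustered", "scattered"] = "clustered"
    degree_quantile: float = 0.99
    magnitude_range: tuple[float, float] = (0.05, 0.1)
    negative_fraction: float = 0.5
    intercept: float = 0.0
    threshold: float | None = None  # None -> median of fitted probabilities
    max_redraws: int = 10

    def resolved_num_cores(self) -> int:
        if self.num_cores is not None:
            return self.num_cores
        return max(1, self.p0 // 10)


def generate_dataset(
    config: SimulationConfig, seed=None
) -> tuple[ExpressionDataset, OutcomeModel, FeatureNetwork]:
    """Compose the full pipeline: network -> Sigma -> X -> predictors -> y.

    All randomness flows from ``seed`` through named sub-streams so each
    stage is independently reproducible.  If the thresholded labels come
    out single-class, the coefficients are re-drawn up to
    ``config.max_redraws`` times before raising.
    """
    streams = _substreams(seed, ["network", "sampling", "selection", "coefficients"])
    network = generate_scale_free_network(config.p, config.attach_m, seed=streams["network"])
    D = shortest_path_distances(network)
    sigma, repaired = distance_to_covariance(D, config.decay)
    network.covariance = sigma
    network.covariance_repaired = repaired
    X = sample_gaussian(sigma, config.n, seed=streams["sampling"])
    indices = select_true_predictors(
        network,
        num_cores=config.resolved_num_cores(),
        target_p0=config.p0,
        case=config.case,
        degree_quantile=config.degree_quantile,
        seed=streams["selection"],
    )

    coef_rng = _as_rng(streams["coefficients"])
    model = None
    y = None
    for _ in range(config.max_redraws + 1):
        beta, beta0 = sample_coefficients(
            config.p0,
            config.magnitude_range,
            config.negative_fraction,
            config.intercept,
            seed=coef_rng,
        )
        probs = expit(X[:, indices] @ beta + beta0)
        t = float(np.median(probs)) if config.threshold is None else config.threshold
        candidate = OutcomeModel(indices, beta, beta0, t, config.case)
        y = generate_labels(X, candidate)
        if 0 in y and 1 in y:
            model = candidate
            break
    if model is None:
        raise RuntimeError(
            f"labels degenerate after {config.max_redraws} coefficient re-draws"
        )

    provenance = {
        "generator": "fdnn.synthetic.generate_dataset",
        "seed": _seed_repr(seed),
        "covariance_repaired": repaired,
        **asdict(config),
    }
    dataset = ExpressionDataset(X=X, y=y, provenance=provenance)
    return dataset, model, network


# ---------------------------------------------------------------------------
# helpers

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _nx_seed(rng: np.random.Generator) -> int:
    # networkx wants an int or RandomState; draw a stable int from the stream
    return int(rng.integers(0, 2**31 - 1))


def _substreams(seed, names: list[str]) -> dict:
    if isinstance(seed, np.random.Generator):
        # split an existing generator by drawing child seeds
        return {name: np.random.default_rng(seed.integers(0, 2**31 - 1)) for name in names}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _seed_repr(seed):
    if isinstance(seed, np.random.Generator):
        return "generator"
    return seed


def _is_positive_definite(mat: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(mat)
        return True
    except np.linalg.LinAlgError:
        return False


def _clip_eigenvalues(mat: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, floor, None)
    repaired = (vecs * vals) @ vecs.T
    # re-unitize the diagonal so the matrix remains a correlation matrix
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired
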