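"""Extended fuzzy c-means (EFCM) clustering with circular volume prototypes.

Classical fuzzy c-means represents each cluster by a point center; EFCM
represents it by a hypersphere (here, a circle on the map plane): a center
``v_i`` plus a radius ``r_i`` derived from the cluster's fuzzy covariance.
The point-to-prototype distance is ``max(0, ||x_j - v_i|| - r_i)``, so every
point inside the circle is at distance zero, and the objective

    J(U, V, r) = sum_i sum_j u_ij^m * delta_ij^2

is minimized by alternating estimation of centers, covariances, radii and
memberships.  Unlike plain FCM the number of clusters is not fixed: the run
starts from a deliberately large ``C0`` and, at each iteration, the two most
similar clusters (inclusion index) are merged whenever the maximum similarity
has stabilized and exceeds the adaptive threshold ``alpha = 1/(C-1)``.  An
integer schedule parameter ``beta`` (growing from 1 toward ``C``) scales the
radii by ``beta/C`` so that prototype volume is released gradually, which
keeps early iterations close to point-prototype FCM and promotes separation
before merging.

The module is deliberately restricted to two spatial features (planar map
coordinates in meters); the mathematics generalizes but the artifact does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("fuzzyhotspots")

#: Numerical tolerance on partition-matrix column sums.
COLUMN_SUM_ATOL = 1e-9

RADIUS_MODES = ("as-printed", "half")
BETA_MODES = ("pseudocode", "equation9")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class EFCMError(Exception):
    """Base class for clustering errors."""


class ConfigError(EFCMError, ValueError):
    """Invalid configuration (bad fuzzifier, tolerances, cluster count...)."""


class DegenerateClusterError(EFCMError):
    """A cluster captured no membership mass; its statistics are undefined."""


class InvalidCovarianceError(EFCMError):
    """Covariance determinant negative beyond numerical tolerance."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSet:
    """N spatial events as planar coordinates in meters.

    Parameters
    ----------
    points
        ``(N, 2)`` array of projected planar coordinates.
    crs_tag
        Identifier of the projection used (e.g. ``"utm:33N"``); ``"planar"``
        marks coordinates that were supplied already projected.
    """

    points: np.ndarray
    crs_tag: str = "planar"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ConfigError(f"points must be (N, 2), got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise ConfigError("an event set needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ConfigError("event coordinates must all be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class PartitionMatrix:
    """C x N fuzzy partition: u[i, j] is the membership of point j in cluster i.

    Every entry lies in [0, 1] and every column sums to 1.
    """

    u: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 2:
            raise ConfigError("partition matrix must be 2-D (C x N)")
        if np.any(u < -COLUMN_SUM_ATOL) or np.any(u > 1 + COLUMN_SUM_ATOL):
            raise ConfigError("membership degrees must lie in [0, 1]")
        colsums = u.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=COLUMN_SUM_ATOL):
            raise ConfigError("every partition column must sum to 1")
        object.__setattr__(self, "u", u)

    @property
    def n_clusters(self) -> int:
        return self.u.shape[0]

    @property
    def n_points(self) -> int:
        return self.u.shape[1]


@dataclass(frozen=True)
class ClusterPrototype:
    """A detected circular hotspot: center, radius and fuzzy covariance."""

    center: np.ndarray
    radius: float
    covariance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "covariance",
                           np.asarray(self.covariance, dtype=float))
        if self.radius < 0:
            raise ConfigError("radius must be non-negative")


@dataclass(frozen=True)
class EFCMConfig:
    """Tunable parameters of an EFCM run.

    Attributes
    ----------
    m
        Fuzzifier exponent, > 1.  ``m -> 1`` approaches hard clustering.
    epsilon
        Convergence tolerance on the maximum absolute change of the
        partition matrix between iterations.
    eta
        Merge-stability tolerance: a merge (or a ``beta`` increment) is only
        considered when the maximum inter-cluster similarity has changed by
        less than ``eta`` since the previous iteration.
    c0
        Initial number of clusters (the run merges downward from here).
    max_iterations
        Iteration cap; a run that hits it is flagged unconverged.
    rng_seed
        Seed for the random partition initialization.
    radius_exponent_mode
        ``"as-printed"`` uses r = det(P)^(1/n) (n = 2); ``"half"`` uses
        det(P)^(1/(2n)), which has length units for planar data.
    beta_update_mode
        ``"pseudocode"`` increments beta only when the similarity has
        stabilized but falls below the merge threshold; ``"equation9"``
        increments it whenever the pair was not merged yet exceeds the
        threshold.
    """

    m: float = 2.0
    epsilon: float = 1e-4
    eta: float = 0.01
    c0: int = 30
    max_iterations: int = 200
    rng_seed: int | None = None
    radius_exponent_mode: str = "as-printed"
    beta_update_mode: str = "pseudocode"

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ConfigError("fuzzifier m must be > 1")
        if self.epsilon <= 0 or self.eta <= 0:
            raise ConfigError("tolerances epsilon and eta must be > 0")
        if self.c0 < 2:
            raise ConfigError("initial cluster count c0 must be >= 2")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.radius_exponent_mode not in RADIUS_MODES:
            raise ConfigError(
                f"radius_exponent_mode must be one of {RADIUS_MODES}")
        if self.beta_update_mode not in BETA_MODES:
            raise ConfigError(f"beta_update_mode must be one of {BETA_MODES}")


@dataclass
class EFCMState:
    """Mutable per-iteration state of the alternating optimization."""

    partition: PartitionMatrix
    prototypes: list[ClusterPrototype]
    beta: int = 1
    iteration: int = 0
    s_star_prev: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.beta <= max(self.partition.n_clusters, 1):
            raise ConfigError("beta must satisfy 1 <= beta <= C")


@dataclass(frozen=True)
class IterationRecord:
    """One row of the machine-readable convergence trace."""

    iteration: int
    n_clusters: int
    beta: int
    s_star: float        # max inter-cluster similarity (NaN when C < 2)
    max_delta_u: float   # max |U(t) - U(t-1)| (NaN when shapes differ)
    merged: bool
    dropped: int         # degenerate clusters removed this iteration


@dataclass(frozen=True)
class EFCMResult:
    """Converged partition, volume prototypes and the run trace."""

    partition: PartitionMatrix
    prototypes: list[ClusterPrototype]
    trace: list[IterationRecord]
    converged: bool
    config: EFCMConfig

    @property
    def n_clusters(self) -> int:
        return self.partition.n_clusters


# ---------------------------------------------------------------------------
# prototype estimation
# ---------------------------------------------------------------------------

def compute_center(partition: PartitionMatrix, events: EventSet,
                   m: float, i: int) -> np.ndarray:
    """Weighted mean of the events under memberships raised to the fuzzifier.

    v_i = sum_j u_ij^m x_j / sum_j u_ij^m
    """
    w = partition.u[i] ** m
    total = w.sum()
    if total <= 0.0:
        raise DegenerateClusterError(f"cluster {i} has zero membership mass")
    return (w @ events.points) / total


def compute_covariance(partition: PartitionMatrix, events: EventSet,
                       center: np.ndarray, m: float, i: int) -> np.ndarray:
    """Fuzzy covariance of cluster i about its center.

    P_i = sum_j u_ij^m (x_j - v_i)(x_j - v_i)^T / sum_j u_ij^m
    """
    w = partition.u[i] ** m
    total = w.sum()
    if total <= 0.0:
        raise DegenerateClusterError(f"cluster {i} has zero membership mass")
    d = events.points - np.asarray(center, dtype=float)
    return (d.T * w) @ d / total


def compute_radius(covariance: np.ndarray, mode: str = "as-printed") -> float:
    """Prototype radius from the covariance determinant.

    ``as-printed`` returns det(P)^(1/n) with n = 2 (which has units of area
    for planar data); ``half`` returns det(P)^(1/(2n)), a length.  For an
    isotropic spread sigma^2 * I these give sigma^2 and sigma respectively.
    """
    if mode not in RADIUS_MODES:
        raise ConfigError(f"unknown radius mode {mode!r}")
    cov = np.asarray(covariance, dtype=float)
    det = float(np.linalg.det(cov))
    scale = max(float(np.abs(cov).max()), 1.0)
    if det < -1e-9 * scale * scale:
        raise InvalidCovarianceError(f"negative determinant {det}")
    det = max(det, 0.0)
    n = 2
    exponent = 1.0 / n if mode == "as-printed" else 1.0 / (2 * n)
    return det ** exponent


def enlarge_radius(radius: float, beta: int, n_clusters: int) -> float:
    """Scale a radius by beta / C (the volume-release schedule)."""
    if n_clusters < 1:
        raise ConfigError("n_clusters must be >= 1")
    beta = min(max(int(beta), 1), n_clusters)
    return radius * beta / n_clusters


def prototype_distance(point: np.ndarray, prototype: ClusterPrototype) -> float:
    """Distance from a point to a circular prototype: max(0, d - r).

    Zero if and only if the point lies inside or on the circle.
    """
    d = float(np.linalg.norm(np.asarray(point, dtype=float) - prototype.center))
    return max(0.0, d - prototype.radius)


def _distance_matrix(points: np.ndarray, centers: np.ndarray,
                     radii: np.ndarray) -> np.ndarray:
    """(C, N) matrix of max(0, ||x_j - v_i|| - r_i)."""
    d = np.linalg.norm(points[None, :, :] - centers[:, None, :], axis=2)
    return np.maximum(0.0, d - radii[:, None])


# ---------------------------------------------------------------------------
# membership update
# ---------------------------------------------------------------------------

def update_memberships(distances: np.ndarray, m: float) -> PartitionMatrix:
    """Optimal partition for fixed prototypes.

    For a point j with no zero distances the standard FCM update applies,

        u_ij = 1 / sum_k (delta_ij / delta_kj)^(2/(m-1)),

    while a point lying inside phi_j >= 1 prototype circles (zero distance)
    splits its membership equally among those clusters and gives 0 to the
    rest.  Either branch makes every column sum to 1.
    """
    delta = np.asarray(distances, dtype=float)
    if np.any(delta < 0):
        raise ConfigError("distances must be non-negative")
    n_clusters, n_points = delta.shape
    inside = delta == 0.0
    phi = inside.sum(axis=0)

    u = np.empty_like(delta)
    p = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        w = delta ** (-p)
        u_upper = w / w.sum(axis=0, keepdims=True)

    # Columns where tiny-but-positive distances overflowed to inf weights:
    # the limit allocates all mass to the overflowing entries, equally.
    bad = ~np.isfinite(u_upper).all(axis=0)
    if np.any(bad):
        winf = np.isinf(w[:, bad])
        u_upper[:, bad] = winf / winf.sum(axis=0, keepdims=True)

    outside = phi == 0
    u[:, outside] = u_upper[:, outside]
    if np.any(~outside):
        cols = ~outside
        u[:, cols] = inside[:, cols] / phi[cols]
    return PartitionMatrix(u)


# ---------------------------------------------------------------------------
# similarity and merging
# ---------------------------------------------------------------------------

def similarity_matrix(partition: PartitionMatrix) -> np.ndarray:
    """Pairwise cluster similarity by the inclusion index.

    S_ik = sum_j min(u_ij, u_kj) / min(sum_j u_ij, sum_j u_kj)

    equals 1 when one cluster's membership profile is contained in the
    other's, 0 when their supports are disjoint.  The diagonal is zeroed so
    the matrix can be searched directly for the most similar *pair*.
    """
    u = partition.u
    if partition.n_clusters < 2:
        raise ConfigError("similarity needs at least 2 clusters")
    row_sums = u.sum(axis=1)
    if np.any(row_sums <= 0.0):
        raise DegenerateClusterError("cluster with zero total membership")
    overlap = np.minimum(u[:, None, :], u[None, :, :]).sum(axis=2)
    s = overlap / np.minimum.outer(row_sums, row_sums)
    np.fill_diagonal(s, 0.0)
    return s


def most_similar_pair(similarity: np.ndarray) -> tuple[int, int, float]:
    """Indices (i < k) and value of the largest off-diagonal similarity.

    Ties break to the lexicographically lowest (i, k).
    """
    c = similarity.shape[0]
    iu, ku = np.triu_indices(c, k=1)
    vals = similarity[iu, ku]
    best = int(np.argmax(vals))  # argmax returns the first max: lexicographic
    return int(iu[best]), int(ku[best]), float(vals[best])


def merge_step(state: EFCMState, similarity: np.ndarray, eta: float,
               beta_update_mode: str = "pseudocode") -> tuple[EFCMState, bool]:
    """One adaptive merge decision.

    Finds the most similar pair (i*, k*) with similarity S*.  If S* has
    stabilized (|S* - S*_prev| < eta) and exceeds the adaptive threshold
    alpha = 1/(C-1), row k* is added into row i* (which preserves column
    sums) and C drops by one with beta unchanged.  Otherwise beta may be
    incremented, where depends on the mode: ``pseudocode`` increments when
    the similarity stabilized below the threshold, ``equation9`` whenever an
    unmerged S* exceeds it.  Returns the new state and whether a merge
    happened.
    """
    u = state.partition.u
    c = u.shape[0]
    if c < 2:
        raise ConfigError("merge step needs at least 2 clusters")
    i_star, k_star, s_star = most_similar_pair(similarity)
    alpha = 1.0 / (c - 1)
    stable = abs(s_star - state.s_star_prev) < eta

    merged = False
    beta = state.beta
    if stable and s_star > alpha:
        new_u = np.delete(u, k_star, axis=0)
        new_u[i_star] = u[i_star] + u[k_star]
        u = new_u
        c -= 1
        merged = True
    elif beta_update_mode == "pseudocode":
        if stable:
            beta = min(c, beta + 1)
    elif beta_update_mode == "equation9":
        if s_star > alpha:
            beta = min(c, beta + 1)

    new_state = EFCMState(
        partition=PartitionMatrix(u),
        prototypes=state.prototypes if not merged else [],
        beta=min(beta, c),
        iteration=state.iteration,
        s_star_prev=s_star,
    )
    return new_state, merged


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def _estimate_prototypes(u: np.ndarray, points: np.ndarray, m: float,
                         mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized centers, covariances and raw radii for every cluster."""
    w = u ** m
    totals = w.sum(axis=1)
    centers = (w @ points) / totals[:, None]
    c = u.shape[0]
    covs = np.empty((c, 2, 2))
    radii = np.empty(c)
    for i in range(c):
        d = points - centers[i]
        covs[i] = (d.T * w[i]) @ d / totals[i]
        radii[i] = compute_radius(covs[i], mode)
    return centers, covs, radii


def run_efcm(events: EventSet, config: EFCMConfig | None = None) -> EFCMResult:
    """Run the full EFCM iteration on an event set.

    Alternates prototype estimation (centers, covariances, radii scaled by
    beta/C), the membership update, and the adaptive merge step, until the
    partition matrix changes by at most ``config.epsilon`` (max absolute
    entry) or the iteration cap is reached.  Degenerate clusters (zero
    membership mass, possible only after pathological collapses) are dropped
    and logged rather than aborting the run.

    Returns
    -------
    EFCMResult
        Final partition, volume prototypes recomputed from the final
        partition (radii scaled by the final beta/C), per-iteration trace,
        and a convergence flag.
    """
    config = config or EFCMConfig()
    points = events.points
    n = events.n_points
    c = config.c0
    if n < c:
        raise ConfigError(f"need at least c0={c} points, got {n}")

    rng = np.random.default_rng(config.rng_seed)
    u = rng.random((c, n))
    u /= u.sum(axis=0, keepdims=True)

    beta = 1
    s_star_prev = 1.0
    trace: list[IterationRecord] = []
    converged = False

    for iteration in range(1, config.max_iterations + 1):
        # Drop clusters that captured no mass before estimating prototypes.
        masses = u.sum(axis=1)
        dropped = int(np.sum(masses <= 0.0))
        if dropped:
            logger.warning("iteration %d: dropping %d degenerate cluster(s)",
                           iteration, dropped)
            u = u[masses > 0.0]
            c = u.shape[0]
            beta = min(beta, c)

        centers, _covs, radii = _estimate_prototypes(
            u, points, config.m, config.radius_exponent_mode)
        r_eff = radii * beta / c
        delta = _distance_matrix(points, centers, r_eff)
        new_partition = update_memberships(delta, config.m)

        if new_partition.u.shape == u.shape:
            max_delta_u = float(np.max(np.abs(new_partition.u - u)))
        else:
            max_delta_u = float("nan")

        s_star = float("nan")
        merged = False
        state = EFCMState(partition=new_partition, prototypes=[], beta=beta,
                          iteration=iteration, s_star_prev=s_star_prev)
        if new_partition.n_clusters >= 2:
            sim = similarity_matrix(new_partition)
            state, merged = merge_step(state, sim, config.eta,
                                       config.beta_update_mode)
            _, _, s_star = most_similar_pair(sim)

        u = state.partition.u
        c = u.shape[0]
        beta = state.beta
        s_star_prev = state.s_star_prev

        trace.append(IterationRecord(iteration=iteration, n_clusters=c,
                                     beta=beta, s_star=s_star,
                                     max_delta_u=max_delta_u, merged=merged,
                                     dropped=dropped))
        logger.debug("iter %d: C=%d beta=%d S*=%.4f max|dU|=%.2e merged=%s",
                     iteration, c, beta, s_star, max_delta_u, merged)

        # a merge or drop is itself a change of U, so it blocks convergence
        if (not merged and dropped == 0
                and np.isfinite(max_delta_u)
                and max_delta_u <= config.epsilon):
            converged = True
            break

    if not converged:
        logger.warning("EFCM did not converge within %d iterations",
                       config.max_iterations)

    partition = PartitionMatrix(u)
    centers, covs, radii = _estimate_prototypes(
        u, points, config.m, config.radius_exponent_mode)
    prototypes = [
        ClusterPrototype(center=centers[i],
                         radius=enlarge_radius(radii[i], beta, c),
                         covariance=covs[i])
        for i in range(c)
    ]
    return EFCMResult(partition=partition, prototypes=prototypes,
                      trace=trace, converged=converged, config=config)
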