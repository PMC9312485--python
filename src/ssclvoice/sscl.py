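"""Semi-supervised competitive learning core: density-based prototype seeding
and seeded K-means.

Given N feature vectors, each pattern's density is the number of patterns
(itself included) within a proximity range eta of it.  Patterns whose density
reaches the threshold gamma become candidate seeds; winning seeds are chosen
from the candidates by greedy non-maximum suppression (take the densest
remaining candidate, drop every candidate within eta of it), which guarantees
winners are pairwise separated by more than eta and every candidate lies
within eta of some winner.  The winners fix both the prototype count K and the
initial centroids of a K-means refinement that runs until the centroids stop
moving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import ConfigError, RunConfig

KMEANS_TOL = 1e-9
KMEANS_MAX_ITER = 300


class SeedingError(RuntimeError):
    """No candidate seeds; eta is too small or gamma too large."""


def euclidean(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return float(np.linalg.norm(a - b))


def indicator(a: np.ndarray, b: np.ndarray, eta: float) -> int:
    """1 iff the Euclidean distance between a and b is not larger than eta."""
    if eta <= 0:
        raise ConfigError("eta must be positive")
    return int(euclidean(a, b) <= eta)


@dataclass
class DensityProfile:
    eta: float
    densities: np.ndarray  # int, 1 <= D <= N (self always counted)
    gamma: float | None = None
    candidate_mask: np.ndarray | None = None


def resolve_eta(data: np.ndarray, config: RunConfig) -> float:
    """Absolute eta from config, or the configured percentile of pairwise
    distances (bumped to the smallest positive distance if the percentile
    hits duplicated points)."""
    if config.eta is not None:
        return float(config.eta)
    d = pdist(np.asarray(data, dtype=float))
    if d.size == 0:
        raise ConfigError("cannot resolve eta from a single record; set it explicitly")
    eta = float(np.percentile(d, config.eta_quantile))
    if eta <= 0:
        positive = d[d > 0]
        if positive.size == 0:
            raise ConfigError("all points coincide; eta cannot be resolved")
        eta = float(positive.min())
    return eta


def compute_densities(data: np.ndarray, eta: float) -> DensityProfile:
    """Per-pattern neighbor counts within eta (boundary inclusive, self in)."""
    data = np.asarray(data, dtype=float)
    if eta <= 0:
        raise ConfigError("eta must be positive")
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("data must be a nonempty 2-D matrix")
    dmat = squareform(pdist(data)) if data.shape[0] > 1 else np.zeros((1, 1))
    densities = (dmat <= eta).sum(axis=1).astype(int)
    return DensityProfile(eta=eta, densities=densities)


def resolve_gamma(profile: DensityProfile, config: RunConfig) -> float:
    """Absolute gamma from config, or the configured percentile of the density
    distribution, clamped into the valid range (1, N]."""
    n = len(profile.densities)
    if config.gamma is not None:
        gamma = float(config.gamma)
    else:
        gamma = float(np.percentile(profile.densities, config.gamma_quantile))
        gamma = min(max(gamma, 2.0), float(max(n, 2)))
    return gamma


def select_candidates(profile: DensityProfile, gamma: float) -> np.ndarray:
    """Indices of candidate seeds: patterns with density >= gamma."""
    n = len(profile.densities)
    if not 1 < gamma <= n:
        raise ConfigError(f"gamma must satisfy 1 < gamma <= N={n}, got {gamma}")
    mask = profile.densities >= gamma
    profile.gamma = float(gamma)
    profile.candidate_mask = mask
    return np.flatnonzero(mask)


def select_winning_seeds(
    data: np.ndarray, profile: DensityProfile, gamma: float | None = None
) -> np.ndarray:
    """Greedy competitive selection of winning seeds from the candidates.

    Repeatedly promote the highest-density remaining candidate (ties broken
    by lowest record index) and suppress all candidates within eta of it.
    Returns winner indices in order of promotion.
    """
    data = np.asarray(data, dtype=float)
    if gamma is None:
        if profile.candidate_mask is None:
            raise ValueError("gamma not given and candidates not yet selected")
        candidates = np.flatnonzero(profile.candidate_mask)
    else:
        candidates = select_candidates(profile, gamma)
    if candidates.size == 0:
        raise SeedingError(
            "no candidate seeds: increase eta or decrease gamma"
        )
    dens = profile.densities[candidates]
    # sort by (-density, index): stable deterministic promotion order
    order = np.lexsort((candidates, -dens))
    pool = candidates[order]
    alive = np.ones(len(pool), dtype=bool)
    dists = cdist(data[pool], data[pool])
    winners = []
    for i in range(len(pool)):
        if not alive[i]:
            continue
        winners.append(int(pool[i]))
        alive &= dists[i] > profile.eta
        alive[i] = False
    return np.array(winners, dtype=int)


@dataclass
class SSCLModel:
    """Fitted prototype model: seeds, refined centroids and assignments."""

    seed_indices: np.ndarray
    seeds: np.ndarray  # (K, L) initial centroids
    centroids: np.ndarray  # (K, L) after K-means
    assignments: np.ndarray  # (N,) prototype index per record
    n_iterations: int
    sse_trace: list[float]
    eta: float | None = None
    gamma: float | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed_indices": self.seed_indices.tolist(),
            "seeds": self.seeds.tolist(),
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "n_iterations": self.n_iterations,
            "sse_trace": self.sse_trace,
            "eta": self.eta,
            "gamma": self.gamma,
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SSCLModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            seed_indices=np.array(raw["seed_indices"], dtype=int),
            seeds=np.array(raw["seeds"], dtype=float),
            centroids=np.array(raw["centroids"], dtype=float),
            assignments=np.array(raw["assignments"], dtype=int),
            n_iterations=int(raw["n_iterations"]),
            sse_trace=list(raw["sse_trace"]),
            eta=raw.get("eta"),
            gamma=raw.get("gamma"),
        )


def seeded_kmeans(data: np.ndarray, seed_indices: np.ndarray) -> SSCLModel:
    """Lloyd iterations from the winning seeds; K is fixed at |S|.

    Each iteration assigns every record to its nearest centroid (minimum
    sum-of-squared-error partition) and moves each centroid to the mean of its
    members; a centroid that loses all members keeps its position and competes
    again.  Stops when the maximal centroid displacement falls below 1e-9 or
    assignments repeat.
    """
    data = np.asarray(data, dtype=float)
    seed_indices = np.asarray(seed_indices, dtype=int)
    if seed_indices.size < 1:
        raise ValueError("need at least one seed")
    centroids = data[seed_indices].copy()
    k = len(seed_indices)
    prev_assign = None
    sse_trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, KMEANS_MAX_ITER + 1):
        d2 = cdist(data, centroids, metric="sqeuclidean")
        assign = np.argmin(d2, axis=1)
        sse_trace.append(float(d2[np.arange(len(data)), assign].sum()))
        new_centroids = centroids.copy()
        for j in range(k):
            members = assign == j
            if np.any(members):
                new_centroids[j] = data[members].mean(axis=0)
        shift = np.max(np.linalg.norm(new_centroids - centroids, axis=1))
        centroids = new_centroids
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        if shift <= KMEANS_TOL:
            break
    return SSCLModel(
        seed_indices=seed_indices,
        seeds=data[seed_indices].copy(),
        centroids=centroids,
        assignments=prev_assign if prev_assign is not None else assign,
        n_iterations=n_iter,
        sse_trace=sse_trace,
    )


def fit_sscl(data: np.ndarray, config: RunConfig | None = None) -> SSCLModel:
    """Full unsupervised stage: resolve eta/gamma, seed competitively, refine."""
    config = config or RunConfig()
    data = np.asarray(data, dtype=float)
    eta = resolve_eta(data, config)
    profile = compute_densities(data, eta)
    gamma = resolve_gamma(profile, config)
    select_candidates(profile, gamma)
    winners = select_winning_seeds(data, profile)
    model = seeded_kmeans(data, winners)
    model.eta = eta
    model.gamma = gamma
    return model
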