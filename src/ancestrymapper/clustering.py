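"""Partitioning Around Medoids (PAM) on AMid vectors.

PAM is k-medoids clustering in the classic Kaufman–Rousseeuw form:

* BUILD — greedy initialization.  The first medoid is the point with the
  smallest total distance to everything; each further medoid is the
  point whose addition most reduces the total cost.
* SWAP — local search.  While some exchange of one medoid for one
  non-medoid lowers the total cost, perform the best such exchange.

The cost of a solution is the sum over points of the distance to their
nearest medoid.  BUILD is deterministic, so the default PAM run needs no
seed and is reproducible given the input order; a random-initialization
mode is available behind ``init="random"``.

Points are AMid vectors — normalized barcodes by default, since all
coordinates then live on the same 0-100 scale — compared with the
Euclidean metric.  Sweeping K from small to large retraces population
structure at increasing resolution: at K=2 the deepest split in the data
(for worldwide human panels, Africa vs. non-Africa) emerges first, and
further K peel off progressively finer groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .amid_core import AMidProfile, profiles_to_frame
from .errors import InvalidKError, TooFewSamplesError


@dataclass
class ClusterSolution:
    """One PAM solution: K medoids, assignments and total dissimilarity.

    Cluster indices are ordered by descending cluster size, ties by
    medoid sample id, so reports are stable across runs.
    """

    K: int
    sample_ids: list[str]
    medoid_ids: list[str]
    medoid_indices: np.ndarray
    assignment: np.ndarray  # cluster index per sample
    total_cost: float

    def members(self, cluster: int) -> list[str]:
        return [s for s, a in zip(self.sample_ids, self.assignment) if a == cluster]

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "cluster": self.assignment}
        )


@dataclass
class CompositionTable:
    """Cluster composition counts and AMid-derived labels for one K."""

    K: int
    counts: pd.DataFrame | None  # clusters x metadata populations, or None
    labels: dict[int, list[str]] = field(default_factory=dict)


def _build_init(dist: np.ndarray, K: int) -> list[int]:
    """Greedy cost-minimizing BUILD phase; ties to the lowest index."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < K:
        # gain of adding candidate c: sum over j of max(nearest_j - d_cj, 0)
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        np.minimum(nearest, dist[c], out=nearest)
    return medoids


def _swap_phase(dist: np.ndarray, medoids: list[int]) -> list[int]:
    """Best-improvement SWAP until no single exchange lowers the cost."""
    n = dist.shape[0]
    medoids = list(medoids)
    while True:
        med = np.array(medoids)
        d_med = dist[med]                      # (K, n)
        order = np.argsort(d_med, axis=0, kind="stable")
        nearest_k = order[0]                   # index into med, per point
        d1 = d_med[nearest_k, np.arange(n)]    # nearest-medoid distance
        d2 = d_med[order[1], np.arange(n)] if len(medoids) > 1 else np.full(n, np.inf)

        best_delta, best_swap = -1e-12, None
        non_medoids = [h for h in range(n) if h not in set(medoids)]
        for ki, m in enumerate(medoids):
            served = nearest_k == ki
            for h in non_medoids:
                d_h = dist[h]
                # points served by m: re-served by h or by their 2nd choice
                delta = np.minimum(d_h[served], d2[served]).sum() - d1[served].sum()
                # other points: may defect to h if it is closer
                delta += np.minimum(d_h[~served] - d1[~served], 0.0).sum()
                if delta < best_delta:
                    best_delta, best_swap = delta, (ki, h)
        if best_swap is None:
            return medoids
        ki, h = best_swap
        medoids[ki] = h


def _assign(dist: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    d_med = dist[np.array(medoids)]
    assignment = np.argmin(d_med, axis=0)  # argmin → lowest index on ties
    cost = float(d_med[assignment, np.arange(dist.shape[0])].sum())
    return assignment, cost


def pam(
    points: np.ndarray,
    K: int,
    sample_ids: list[str] | None = None,
    init: str = "build",
    seed: int | None = None,
) -> ClusterSolution:
    """Cluster fixed-length vectors into K groups around medoids.

    ``init="build"`` (default) is deterministic; ``init="random"`` draws
    the initial medoids with ``seed``.  After convergence no single
    (medoid, non-medoid) exchange lowers the total cost.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if not 1 <= K <= n:
        raise InvalidKError(f"K={K} outside 1..{n}")
    dist = cdist(points, points)

    if init == "build":
        medoids = _build_init(dist, K)
    elif init == "random":
        rng = np.random.default_rng(seed)
        medoids = list(rng.choice(n, size=K, replace=False))
    else:
        raise ValueError(f"unknown init {init!r}")
    medoids = _swap_phase(dist, medoids)
    assignment, cost = _assign(dist, medoids)

    # stable cluster numbering: by descending size, then medoid sample id
    sizes = np.bincount(assignment, minlength=K)
    order = sorted(range(K), key=lambda k: (-sizes[k], sample_ids[medoids[k]]))
    relabel = {old: new for new, old in enumerate(order)}
    medoids = [medoids[k] for k in order]
    assignment = np.array([relabel[a] for a in assignment])
    return ClusterSolution(
        K=K,
        sample_ids=list(sample_ids),
        medoid_ids=[sample_ids[m] for m in medoids],
        medoid_indices=np.array(medoids),
        assignment=assignment,
        total_cost=cost,
    )


def sweep_k(
    points: np.ndarray,
    k_min: int = 2,
    k_max: int = 40,
    sample_ids: list[str] | None = None,
) -> list[ClusterSolution]:
    """PAM solutions for every K in ``k_min..k_max`` inclusive."""
    n = np.asarray(points).shape[0]
    if k_max > n:
        raise InvalidKError(f"k_max={k_max} exceeds n={n}")
    return [pam(points, K, sample_ids=sample_ids) for K in range(k_min, k_max + 1)]


def label_clusters(
    solution: ClusterSolution,
    profiles: list[AMidProfile],
    metadata: pd.DataFrame | None = None,
    top_m: int = 3,
) -> CompositionTable:
    """Label clusters by their members' highest median AMids.

    Per cluster, the label is the ``top_m`` panel populations ranked by
    the median normalized AMid of the cluster's members — no individuals
    of known ancestry are required.  When metadata is available, the
    cluster x population count table is also produced.
    """
    norm = profiles_to_frame(profiles, "normalized")
    missing = set(solution.sample_ids) - set(norm.index)
    if missing:
        raise ValueError(f"profiles missing for samples: {sorted(missing)[:5]}")
    labels: dict[int, list[str]] = {}
    for k in range(solution.K):
        members = solution.members(k)
        medians = norm.loc[members].median(axis=0)
        labels[k] = medians.sort_values(ascending=False, kind="stable").index[:top_m].tolist()
    counts = None
    if metadata is not None and "population" in metadata.columns:
        pops = metadata.loc[solution.sample_ids, "population"].to_numpy()
        counts = (
            pd.crosstab(pd.Series(solution.assignment, name="cluster"),
                        pd.Series(pops, name="population"))
            .reindex(range(solution.K), fill_value=0)
        )
    return CompositionTable(K=solution.K, counts=counts, labels=labels)


def subset_cluster(
    profiles: list[AMidProfile],
    metadata: pd.DataFrame,
    population_filter: list[str],
    K: int,
    space: str = "normalized",
) -> ClusterSolution:
    """PAM restricted to samples whose population is in the filter.

    Useful for dissecting heterogeneous or admixed groups on their own
    (e.g. clustering only an admixed cohort to expose its internal
    ancestry gradient).
    """
    wanted = set(population_filter)
    ids = [p.sample_id for p in profiles
           if metadata.loc[p.sample_id, "population"] in wanted]
    if len(ids) < K:
        raise TooFewSamplesError(
            f"filter selected {len(ids)} samples but K={K}"
        )
    frame = profiles_to_frame(profiles, space).loc[ids]
    return pam(frame.to_numpy(), K, sample_ids=ids)
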