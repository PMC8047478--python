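"""Nonparametric cluster-based permutation tests.

Implements the two-step procedure standard in M/EEG group analysis:

1. a per-sample paired (dependent-samples) t statistic across subjects —
   for activation-vs-baseline contrasts each activation sample is paired
   with the subject's time-averaged baseline;
2. supra-threshold samples (t beyond the 2.5th / 97.5th percentiles of the
   t distribution with N-1 degrees of freedom) are clustered by adjacency
   — neighbouring channels at the same time/frequency bin, adjacent time
   bins on the same channel, and (for time-frequency data) adjacent
   frequency bins — keeping positive and negative clusters separate; each
   cluster's summed t is compared to a Monte-Carlo null distribution of the
   maximum absolute cluster sum under per-subject condition swaps
   (equivalently, random sign flips of the subject difference maps).

The Monte-Carlo p-value uses the ``(1 + count) / (1 + B)`` estimator, so it
is never exactly zero. For small N an exhaustive enumeration of all ``2^N``
sign assignments replaces sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .preprocess import EpochSet

__all__ = [
    "AdjacencyGraph",
    "ClusterConfig",
    "Cluster",
    "ClusterResult",
    "build_adjacency",
    "actvsbl_subject_maps",
    "dependent_t",
    "find_clusters",
    "permutation_test",
    "equalize_trials",
]


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, irreflexive channel neighbourhood relation."""

    neighbors: tuple[frozenset, ...]  # per-channel neighbour index sets

    def __post_init__(self):
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("adjacency must be irreflexive")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)

    def edge_array(self) -> np.ndarray:
        """Edges as an (n_edges, 2) array with i < j."""
        edges = [
            (i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j
        ]
        return np.asarray(edges, int).reshape(-1, 2)


def build_adjacency(positions: np.ndarray, threshold: float = 0.55) -> AdjacencyGraph:
    """Channels are neighbours iff their 3D distance is at most ``threshold``.

    Positions are unit-head coordinates; the default chord distance of
    0.55 (about a 32 degree arc) gives a mean neighbour count of roughly 6
    on a 64-channel 10-10 layout.
    """
    positions = np.asarray(positions, float)
    if positions.shape[0] < 2:
        raise ValueError("need at least 2 positioned channels")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    adj = (d <= threshold) & ~np.eye(positions.shape[0], dtype=bool)
    graph = AdjacencyGraph(
        tuple(frozenset(np.nonzero(row)[0].tolist()) for row in adj)
    )
    if any(len(nb) == 0 for nb in graph.neighbors):
        import warnings

        warnings.warn("adjacency threshold leaves isolated channels", stacklevel=2)
    return graph


@dataclass(frozen=True)
class ClusterConfig:
    """Test configuration (defaults follow the analysis settings)."""

    cluster_quantiles: tuple[float, float] = (2.5, 97.5)
    n_permutations: int = 1000
    final_alpha: float = 0.05
    seed: int = 0
    exhaustive: bool | None = None  # None = auto when 2^N <= n_permutations

    def __post_init__(self):
        if not 0 < self.cluster_quantiles[0] < self.cluster_quantiles[1] < 100:
            raise ValueError("quantiles must lie strictly inside (0, 100)")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class Cluster:
    members: np.ndarray  # flat sample indices into the map
    sign: int  # +1 or -1
    t_sum: float
    p_value: float = np.nan


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max: np.ndarray  # null distribution of max |cluster sum|
    map_shape: tuple[int, ...]
    config: ClusterConfig
    t_map: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.config.final_alpha]


def actvsbl_subject_maps(
    subject_epochs: list[EpochSet],
    activation: tuple[float, float],
    baseline: tuple[float, float],
) -> np.ndarray:
    """Per-subject activation-minus-baseline difference maps.

    For each subject, the trial-averaged activation samples are paired with
    that subject's time-averaged baseline per channel; returns the
    difference maps, shape ``(n_subjects, n_channels, n_activation_times)``.
    """
    maps = []
    for ep in subject_epochs:
        times = ep.times
        act = (times >= activation[0] - 1e-12) & (times <= activation[1] + 1e-12)
        base = (times >= baseline[0] - 1e-12) & (times <= baseline[1] + 1e-12)
        if not act.any() or not base.any():
            raise ValueError("activation or baseline window outside the epoch")
        avg = ep.data.mean(axis=0)  # channels x time
        maps.append(avg[:, act] - avg[:, base].mean(axis=1, keepdims=True))
    return np.stack(maps)


def dependent_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic across the first (subject) axis, N-1 df.

    Zero-variance samples with a nonzero mean map to +/- inf; zero mean and
    zero variance map to 0.
    """
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def _cluster_one_map(
    t_map: np.ndarray,
    t_crit: tuple[float, float],
    edges: np.ndarray,
) -> list[tuple[np.ndarray, int, float]]:
    """Connected signed clusters of supra-threshold samples.

    ``t_map`` is (channels, [freqs,] times); ``edges`` lists neighbouring
    channel pairs. Returns (flat member indices, sign, summed t) triples.
    """
    lo, hi = t_crit
    shape = t_map.shape
    flat_t = t_map.ravel()
    out = []
    for sign, supra in ((1, t_map > hi), (-1, t_map < lo)):
        idx = np.nonzero(supra.ravel())[0]
        if idx.size == 0:
            continue
        pos = np.full(flat_t.size, -1, dtype=int)
        pos[idx] = np.arange(idx.size)
        rows, cols = [], []

        def _link(a: np.ndarray, b: np.ndarray):
            ok = (pos[a] >= 0) & (pos[b] >= 0)
            rows.append(pos[a[ok]])
            cols.append(pos[b[ok]])

        grid = np.unravel_index(idx, shape)
        flat = np.arange(flat_t.size).reshape(shape)
        # adjacent bins along every non-channel axis
        for ax in range(1, t_map.ndim):
            sel_a = [slice(None)] * t_map.ndim
            sel_b = [slice(None)] * t_map.ndim
            sel_a[ax] = slice(0, shape[ax] - 1)
            sel_b[ax] = slice(1, None)
            _link(flat[tuple(sel_a)].ravel(), flat[tuple(sel_b)].ravel())
        # neighbouring channels at identical remaining coordinates
        if edges.size:
            for ci, cj in edges:
                _link(flat[ci].ravel(), flat[cj].ravel())
        if rows:
            r = np.concatenate(rows)
            c = np.concatenate(cols)
        else:
            r = c = np.empty(0, int)
        graph = coo_matrix(
            (np.ones(r.size), (r, c)), shape=(idx.size, idx.size)
        )
        n_comp, labels = connected_components(graph, directed=False)
        for k in range(n_comp):
            members = idx[labels == k]
            out.append((members, sign, float(flat_t[members].sum())))
    return out


def find_clusters(
    t_map: np.ndarray,
    n_subjects: int,
    adjacency: AdjacencyGraph | None = None,
    config: ClusterConfig | None = None,
) -> list[Cluster]:
    """Signed clusters of supra-threshold t values with their summed t."""
    config = config or ClusterConfig()
    qlo, qhi = config.cluster_quantiles
    t_crit = (
        float(t_dist.ppf(qlo / 100.0, n_subjects - 1)),
        float(t_dist.ppf(qhi / 100.0, n_subjects - 1)),
    )
    edges = adjacency.edge_array() if adjacency is not None else np.empty((0, 2), int)
    t_map = np.where(np.isfinite(t_map), t_map, np.sign(t_map) * 1e12)
    triples = _cluster_one_map(t_map, t_crit, edges)
    return [Cluster(members=m, sign=s, t_sum=ts) for m, s, ts in triples]


def permutation_test(
    diffs: np.ndarray,
    adjacency: AdjacencyGraph | None = None,
    config: ClusterConfig | None = None,
) -> ClusterResult:
    """Cluster-based permutation test on subject difference maps.

    ``diffs`` has shape ``(n_subjects, n_channels, [n_freqs,] n_times)``
    and holds condition-A-minus-condition-B (or activation-minus-baseline)
    maps. The permutation unit is a per-subject swap of the two conditions,
    i.e. a random sign flip of that subject's difference map. Every
    observed cluster is tested against the same null distribution of the
    maximum absolute cluster sum.
    """
    config = config or ClusterConfig()
    n = diffs.shape[0]
    observed_t = dependent_t(diffs)
    clusters = find_clusters(observed_t, n, adjacency, config)

    exhaustive = config.exhaustive
    if exhaustive is None:
        exhaustive = 2**n <= config.n_permutations
    if exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(config.seed)
        signs = rng.choice((1.0, -1.0), size=(config.n_permutations, n))

    flat = diffs.reshape(n, -1)
    sumsq = np.sum(flat**2, axis=0)  # invariant under sign flips
    qlo, qhi = config.cluster_quantiles
    t_crit = (
        float(t_dist.ppf(qlo / 100.0, n - 1)),
        float(t_dist.ppf(qhi / 100.0, n - 1)),
    )
    edges = adjacency.edge_array() if adjacency is not None else np.empty((0, 2), int)
    map_shape = diffs.shape[1:]

    null_max = np.empty(signs.shape[0])
    for b, s in enumerate(signs):
        mean = (s @ flat) / n
        var = (sumsq / n - mean**2) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        t = np.where(var <= 0, np.where(mean == 0, 0.0, np.sign(mean) * 1e12), t)
        triples = _cluster_one_map(t.reshape(map_shape), t_crit, edges)
        null_max[b] = max((abs(ts) for _, _, ts in triples), default=0.0)

    for c in clusters:
        if exhaustive:
            c.p_value = float(np.mean(null_max >= abs(c.t_sum)))
        else:
            c.p_value = float(
                (1 + np.sum(null_max >= abs(c.t_sum))) / (1 + null_max.size)
            )
    clusters.sort(key=lambda c: -abs(c.t_sum))
    return ClusterResult(
        clusters=clusters,
        null_max=null_max,
        map_shape=map_shape,
        config=config,
        t_map=observed_t,
    )


def equalize_trials(
    epochs_a: EpochSet, epochs_b: EpochSet, seed: int = 0
) -> tuple[EpochSet, EpochSet]:
    """Subsample the larger side to the smaller side's trial count.

    Uniform without replacement, keeping the original trial order; the
    smaller side is returned untouched.
    """
    from dataclasses import replace

    na, nb = epochs_a.n_trials, epochs_b.n_trials
    if na == 0 or nb == 0:
        raise ValueError("cannot equalize with an empty trial set")
    if na == nb:
        return epochs_a, epochs_b
    rng = np.random.default_rng(seed)
    m = min(na, nb)
    if na > nb:
        keep = np.sort(rng.choice(na, size=m, replace=False))
        return replace(epochs_a, data=epochs_a.data[keep]), epochs_b
    keep = np.sort(rng.choice(nb, size=m, replace=False))
    return epochs_a, replace(epochs_b, data=epochs_b.data[keep])
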