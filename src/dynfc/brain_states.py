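"""Group-level latent brain states and dwell-time statistics.

Windows (6-dim Fisher-z vectors) pooled across the subjects of one group
are clustered with a subsampled consensus k-means scheme; the number of
states is chosen by a majority vote of cluster-validity indices. Per-state
dwell times are run-length statistics of each subject's window label
sequence.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

DEFAULT_K_RANGE = (2, 6)

#: Validity indices available to :func:`select_k`.
DEFAULT_INDEX_SET = (
    "calinski_harabasz",
    "silhouette",
    "davies_bouldin",
    "dunn",
    "gap",
    "hartigan",
    "krzanowski_lai",
    "ball_hall",
)


class ClusteringError(RuntimeError):
    """Clustering failed after bounded retries, or all indices failed."""


@dataclass
class StatePartition:
    """Result of clustering one group's pooled windows at a fixed k.

    ``labels`` holds one 1-based label array per subject, in the order the
    subjects' windows were pooled. ``centroids`` are per-cluster means of
    the raw (unstandardized) Fisher-z vectors.
    """

    group_name: str
    k_selected: int
    centroids: np.ndarray  # (k, 6)
    labels: list[np.ndarray]
    index_votes: dict[str, int]
    consensus_matrix: np.ndarray | None = None

    def pooled_labels(self) -> np.ndarray:
        return np.concatenate(self.labels)


@dataclass
class SelectKResult:
    k: int
    votes: dict[str, int]
    vote_dispersion: float  # 1 - modal share; high values flag instability


@dataclass
class DwellStats:
    """Run-length dwell statistics for one subject's label sequence."""

    state_mean_windows: dict[int, float]
    state_run_counts: dict[int, int]
    mean_dwell_windows: float  # unweighted mean over visited states
    mean_dwell_seconds: float
    tr: float
    step: int

    @property
    def state_mean_seconds(self) -> dict[int, float]:
        return {
            s: m * self.step * self.tr for s, m in self.state_mean_windows.items()
        }


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label sequence -> (run_values, run_lengths)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    values = labels[bounds[:-1]]
    lengths = np.diff(bounds)
    return values, lengths


def dwell_times(labels: np.ndarray, tr: float, step: int = 1) -> DwellStats:
    """Per-state mean run lengths and the subject's mean dwell time.

    The subject mean is the unweighted mean of per-state mean run lengths
    over the states the subject actually visits; seconds are windows x
    step x TR.
    """
    values, lengths = run_lengths(labels)
    state_means: dict[int, float] = {}
    state_counts: dict[int, int] = {}
    for s in np.unique(values):
        mask = values == s
        state_means[int(s)] = float(lengths[mask].mean())
        state_counts[int(s)] = int(mask.sum())
    mean_windows = float(np.mean(list(state_means.values())))
    return DwellStats(
        state_mean_windows=state_means,
        state_run_counts=state_counts,
        mean_dwell_windows=mean_windows,
        mean_dwell_seconds=mean_windows * step * tr,
        tr=tr,
        step=step,
    )


def _kmeans_labels(x: np.ndarray, k: int, seed, n_init: int = 4) -> KMeans:
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        random_state=np.random.default_rng(seed).integers(2**31),
    )
    km.fit(x)
    return km


def consensus_kmeans(
    x: np.ndarray,
    k: int,
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    seed=None,
    max_retries: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subsampled consensus k-means at a fixed k.

    ``n_resamples`` k-means runs on random ``subsample_frac`` subsets are
    aggregated into a co-assignment frequency matrix (entries normalized by
    co-sampling counts, diagonal 1); final 1-based labels come from an
    average-linkage cut of ``1 - consensus`` at k, and centroids are the
    per-cluster means of ``x``.

    Returns ``(labels, centroids, consensus_matrix)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_windows, got k={k}, n={n}")
    if not 0 < subsample_frac <= 1:
        raise ValueError("subsample_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = max(k + 1, int(round(subsample_frac * n)))

    for attempt in range(max_retries):
        hits = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            lab = _kmeans_labels(x[idx], k, rng, n_init=1).labels_
            co = (lab[:, None] == lab[None, :]).astype(float)
            hits[np.ix_(idx, idx)] += co
            both[np.ix_(idx, idx)] += 1.0
        consensus = np.divide(hits, both, out=np.zeros_like(hits), where=both > 0)
        np.fill_diagonal(consensus, 1.0)

        dist = 1.0 - consensus
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method="average")
        labels = fcluster(z, k, criterion="maxclust")
        if len(np.unique(labels)) == k:
            centroids = np.vstack(
                [x[labels == c].mean(axis=0) for c in range(1, k + 1)]
            )
            return labels, centroids, consensus
    raise ClusteringError(
        f"consensus clustering produced fewer than k={k} clusters "
        f"after {max_retries} attempts"
    )


def _dunn_index(x: np.ndarray, labels: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform as _sqf

    d = _sqf(pdist(x))
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    diam = 0.0
    for c in uniq:
        mask = labels == c
        if mask.sum() > 1:
            diam = max(diam, d[np.ix_(mask, mask)].max())
    if diam == 0:
        return np.nan
    sep = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            sep = min(sep, d[np.ix_(labels == a, labels == b)].min())
    return sep / diam


def select_k(
    x: np.ndarray,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    index_set: tuple[str, ...] = DEFAULT_INDEX_SET,
    seed=None,
    max_pairwise: int = 1500,
    gap_b: int = 5,
) -> SelectKResult:
    """Choose the number of states by majority vote of validity indices.

    Each configured index votes for its optimal k over ``k_range``; the
    modal k wins, with ties broken toward smaller k. ``max_pairwise`` caps
    the number of points used by O(n^2) indices (silhouette, Dunn).
    Indices that fail on the given data abstain; if all fail a
    :class:`ClusteringError` lists the failures.
    """
    x = np.asarray(x, dtype=float)
    if len(index_set) < 3:
        raise ValueError("at least 3 validity indices are required")
    rng = np.random.default_rng(seed)
    n, d = x.shape
    kmin, kmax = int(k_range[0]), int(k_range[1])
    if not 2 <= kmin <= kmax:
        raise ValueError(f"invalid k_range {k_range}")
    kmax = min(kmax, n - 1)
    ks = list(range(kmin, kmax + 1))

    # one k-means sweep over 1 .. kmax+1 (inertia for sweep-based indices,
    # labels for the per-partition indices)
    wss: dict[int, float] = {1: float(((x - x.mean(axis=0)) ** 2).sum())}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(2, kmax + 2):
        km = _kmeans_labels(x, k, rng)
        wss[k] = float(km.inertia_)
        if k <= kmax:
            labels_by_k[k] = km.labels_

    sub = (
        rng.choice(n, size=max_pairwise, replace=False)
        if n > max_pairwise
        else np.arange(n)
    )

    votes: dict[str, int] = {}
    failures: dict[str, str] = {}

    def _vote(name, fn):
        if name not in index_set:
            return
        try:
            k = fn()
            if k is None or not kmin <= k <= kmax:
                raise ValueError(f"index voted outside k_range: {k}")
            votes[name] = int(k)
        except Exception as exc:  # noqa: BLE001 - abstain, report at end
            failures[name] = str(exc)

    _vote(
        "calinski_harabasz",
        lambda: max(ks, key=lambda k: calinski_harabasz_score(x, labels_by_k[k])),
    )
    _vote(
        "silhouette",
        lambda: max(
            ks, key=lambda k: silhouette_score(x[sub], labels_by_k[k][sub])
        ),
    )
    _vote(
        "davies_bouldin",
        lambda: min(ks, key=lambda k: davies_bouldin_score(x, labels_by_k[k])),
    )
    _vote(
        "dunn",
        lambda: max(ks, key=lambda k: _dunn_index(x[sub], labels_by_k[k][sub])),
    )

    def _gap_vote():
        lo, hi = x.min(axis=0), x.max(axis=0)
        gap: dict[int, float] = {}
        sk: dict[int, float] = {}
        for k in range(kmin, kmax + 2):
            ref_log = np.empty(gap_b)
            for b in range(gap_b):
                ref = rng.uniform(lo, hi, size=(n, d))
                ref_log[b] = np.log(_kmeans_labels(ref, k, rng, n_init=1).inertia_)
            gap[k] = float(ref_log.mean() - np.log(wss[k]))
            sk[k] = float(ref_log.std(ddof=1) * np.sqrt(1 + 1 / gap_b))
        for k in ks:
            if gap[k] >= gap[k + 1] - sk[k + 1]:
                return k
        return max(ks, key=lambda k: gap[k])

    _vote("gap", _gap_vote)

    def _hartigan_vote():
        for k in range(1, kmax + 1):
            h = (wss[k] / wss[k + 1] - 1.0) * (n - k - 1)
            if h <= 10.0:
                return max(k, kmin)
        return kmax

    _vote("hartigan", _hartigan_vote)

    def _kl_vote():
        def diff(k):
            return (k - 1) ** (2 / d) * wss[k - 1] - k ** (2 / d) * wss[k]

        kl = {}
        for k in ks:
            denom = diff(k + 1)
            if denom == 0:
                continue
            kl[k] = abs(diff(k) / denom)
        if not kl:
            raise ValueError("degenerate within-cluster sums")
        return max(kl, key=kl.get)

    _vote("krzanowski_lai", _kl_vote)

    def _ball_hall_vote():
        bh = {k: wss[k] / k for k in range(1, kmax + 1)}
        drops = {k: bh[k - 1] - bh[k] for k in range(max(2, kmin), kmax + 1)}
        return max(drops, key=drops.get)

    _vote("ball_hall", _ball_hall_vote)

    if not votes:
        raise ClusteringError(f"all validity indices failed: {failures}")

    counts = Counter(votes.values())
    top = max(counts.values())
    k_sel = min(k for k, c in counts.items() if c == top)
    dispersion = 1.0 - top / len(votes)
    if dispersion >= 0.5:
        warnings.warn(
            f"validity-index votes are dispersed ({votes}); "
            "the data may not support a clear number of states",
            stacklevel=2,
        )
    return SelectKResult(k=k_sel, votes=votes, vote_dispersion=dispersion)


def partition_group(
    subject_z6: list[np.ndarray],
    group_name: str = "",
    k: int | None = None,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    n_resamples: int = 100,
    subsample_frac: float = 0.8,
    index_set: tuple[str, ...] = DEFAULT_INDEX_SET,
    seed=None,
    standardize: bool = True,
    keep_consensus: bool = False,
    method: str = "consensus",
) -> StatePartition:
    """Cluster one group's subjects into latent states.

    Pools all subjects' Fisher-z window vectors, standardizes the pooled
    features (per column), selects k by index vote unless ``k`` is given,
    then runs consensus k-means and splits the 1-based labels back per
    subject. Centroids are reported in raw Fisher-z units.

    ``method="kmeans"`` replaces the consensus step with a single k-means
    fit — an O(n) shortcut for large pooled window sets (the consensus
    co-assignment matrix is quadratic in the window count).
    """
    if not subject_z6:
        raise ValueError("no subjects provided")
    pooled = np.vstack(subject_z6)
    counts = [z.shape[0] for z in subject_z6]
    feat = pooled
    if standardize:
        sd = pooled.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        feat = (pooled - pooled.mean(axis=0)) / sd

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_select, s_cluster = ss.spawn(2)

    if k is None:
        res = select_k(feat, k_range=k_range, index_set=index_set, seed=s_select)
        k_sel, votes = res.k, res.votes
    else:
        k_sel, votes = int(k), {"fixed": int(k)}

    if method == "consensus":
        labels, _, consensus = consensus_kmeans(
            feat,
            k_sel,
            n_resamples=n_resamples,
            subsample_frac=subsample_frac,
            seed=s_cluster,
        )
    elif method == "kmeans":
        labels = _kmeans_labels(feat, k_sel, s_cluster, n_init=10).labels_ + 1
        consensus = None
    else:
        raise ValueError(f"unknown method {method!r}")
    centroids = np.vstack(
        [pooled[labels == c].mean(axis=0) for c in range(1, k_sel + 1)]
    )
    split = np.split(labels, np.cumsum(counts)[:-1])
    return StatePartition(
        group_name=group_name,
        k_selected=k_sel,
        centroids=centroids,
        labels=[np.asarray(s) for s in split],
        index_votes=votes,
        consensus_matrix=consensus if keep_consensus else None,
    )
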