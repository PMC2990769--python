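"""Consensus clustering of pathway activity profiles.

The pipeline keeps only PALs that change over time (one-way ANOVA with time
point as factor, replicates as the error term), aligns their arbitrary signs
against the ensemble's first principal direction, and then clusters the
replicate-averaged profiles with an ensemble of methods — agglomerative and
divisive hierarchical clustering, k-means, k-medoids (PAM), a 1-D
self-organizing map and a Gaussian mixture — under Euclidean, Manhattan and
correlation (1 - r) geometry where each method admits it.  Every run votes;
the agreement matrix records how often two pathways land in the same
cluster.  Pathways with ambiguous agreements (strictly between 1 - delta and
delta for any partner) are removed greedily, and the consistent remainder is
partitioned by average-linkage clustering of 1 - agreement, with the cluster
count picked by mean silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .data_io import TimeDesign
from .rhythm import SinusoidFit, TimeProfile, fit_sinusoid

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.65
DEFAULT_K_RANGE = (2, 8)

_EUCLIDEAN_ONLY = ("kmeans", "som", "gmm")
_ALL_METRIC = ("hclust", "diana", "pam")
DEFAULT_METHODS = _ALL_METRIC + _EUCLIDEAN_ONLY
DEFAULT_METRICS = ("euclidean", "manhattan", "correlation")


@dataclass
class AgreementMatrix:
    """Pairwise co-clustering frequency over an ensemble of runs."""

    items: list[str]
    values: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValueError("agreement matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("agreement matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("agreement diagonal must be 1")

    def restrict(self, names: list[str]) -> "AgreementMatrix":
        idx = [self.items.index(n) for n in names]
        return AgreementMatrix(
            list(names), self.values[np.ix_(idx, idx)], self.n_runs
        )


@dataclass
class ClusterResult:
    retained: list[str]
    labels: np.ndarray
    k_clusters: int
    centroids: list[TimeProfile]
    centroid_fits: list[SinusoidFit]
    delta: float
    silhouette: float


# ---------------------------------------------------------------------------
# Stage 1: ANOVA time-dependence filter
# ---------------------------------------------------------------------------

def anova_filter(
    pal_by_sample: np.ndarray,
    design: TimeDesign,
    alpha: float = 0.01,
) -> tuple[bool, float]:
    """One-way fixed-effects ANOVA of a per-sample PAL on the time factor.

    Returns ``(keep, p)``; keep is true when p < alpha, i.e. the activity
    changes across time points beyond replicate scatter.  A profile with no
    variation at all gets p = 1 and is dropped.
    """
    v = np.asarray(pal_by_sample, dtype=float)
    idx = design.time_index()
    if len(design.time_points) < 2 or design.replicates_per_time < 2:
        raise ValueError("ANOVA needs >= 2 time points and >= 2 replicates")
    groups = [v[idx == i] for i in range(len(design.time_points))]
    if np.ptp(v) == 0:
        return False, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.f_oneway(*groups)
    if not np.isfinite(p):
        # no within-group scatter: any between-group difference is exact
        between = np.ptp([g.mean() for g in groups])
        p = 0.0 if between > 0 else 1.0
    return bool(p < alpha), float(p)


# ---------------------------------------------------------------------------
# Stage 2: sign alignment
# ---------------------------------------------------------------------------

def sign_align(profiles: list[TimeProfile]) -> list[TimeProfile]:
    """Resolve per-profile sign ambiguity against the ensemble.

    The reference is the first principal direction of the (row-centered)
    profile matrix; a profile anticorrelated with it is negated.  Profiles
    essentially uncorrelated with the reference are left as-is (logged).
    """
    if not profiles:
        raise ValueError("no profiles to align")
    X = np.stack([p.values for p in profiles]).astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    ref = Vt[0]
    norms = np.linalg.norm(Xc, axis=1) * np.linalg.norm(ref)
    with np.errstate(invalid="ignore"):
        corrs = np.where(norms > 0, Xc @ ref / np.where(norms > 0, norms, 1.0),
                         0.0)
    if corrs.sum() < 0:
        # the principal direction's sign is arbitrary; orient it with the
        # majority so an already-consistent set is left untouched
        ref, corrs = -ref, -corrs
    out: list[TimeProfile] = []
    for p, corr in zip(profiles, corrs):
        if abs(corr) < 1e-12:
            logger.info("profile %s uncorrelated with reference; sign kept",
                        p.label)
            out.append(p)
        elif corr < 0:
            out.append(TimeProfile(p.times, -p.values, p.label))
        else:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Clustering algorithm families
# ---------------------------------------------------------------------------

def _distance(X: np.ndarray, metric: str) -> np.ndarray:
    name = {"euclidean": "euclidean", "manhattan": "cityblock",
            "correlation": "correlation"}[metric]
    return squareform(pdist(X, metric=name))


def _labels_hclust(D: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def _labels_diana(D: np.ndarray, k: int) -> np.ndarray:
    """Divisive analysis: repeatedly split the widest cluster by growing a
    splinter group seeded with the most dissimilar member."""
    n = D.shape[0]
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < k:
        diam = [D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters]
        j = int(np.argmax(diam))
        if diam[j] == 0.0:
            break  # all remaining clusters are singletons/identical
        cluster = clusters.pop(j)
        sub = D[np.ix_(cluster, cluster)]
        avg = sub.sum(axis=1) / (len(cluster) - 1)
        splinter = [int(np.argmax(avg))]
        rest = [i for i in range(len(cluster)) if i not in splinter]
        moved = True
        while moved and len(rest) > 1:
            moved = False
            d_rest = np.array([
                sub[i, rest].sum() / (len(rest) - 1) if len(rest) > 1 else 0.0
                for i in rest
            ])
            d_spl = np.array([sub[i, splinter].mean() for i in rest])
            gain = d_rest - d_spl
            i_best = int(np.argmax(gain))
            if gain[i_best] > 0:
                splinter.append(rest.pop(i_best))
                moved = True
        clusters.insert(j, [cluster[i] for i in rest])
        clusters.append([cluster[i] for i in splinter])
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(clusters, start=1):
        labels[c] = lab
    return labels


def _labels_pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """k-medoids with the deterministic BUILD initialization and greedy swap."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(d_near - D[:, c], 0.0).sum() if c not in medoids else -1
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = list(medoids)
        for j in range(k):
            members = np.where(labels == j)[0]
            if members.size:
                costs = D[np.ix_(members, members)].sum(axis=1)
                new[j] = int(members[np.argmin(costs)])
        if new == medoids:
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1) + 1


def _labels_som(X: np.ndarray, k: int, seed: int, epochs: int = 40) -> np.ndarray:
    """Batch SOM on a 1 x k grid; codebook initialized along the first PC."""
    n, d = X.shape
    Xc = X - X.mean(axis=0)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    span = s[0] / np.sqrt(max(n - 1, 1))
    pos = np.linspace(-1, 1, k)[:, None]
    codebook = X.mean(axis=0) + pos * span * Vt[0]
    grid = np.arange(k, dtype=float)
    for epoch in range(epochs):
        sigma = max(k / 2.0 * (1 - epoch / epochs), 0.4)
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2, axis=1)
        h = np.exp(-((grid[:, None] - grid[bmu][None, :]) ** 2)
                   / (2 * sigma ** 2))          # (k, n) neighborhood weights
        wsum = h.sum(axis=1, keepdims=True)
        nonzero = wsum[:, 0] > 1e-12
        codebook[nonzero] = (h @ X)[nonzero] / wsum[nonzero]
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1


def _labels_kmeans(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X) + 1


def _labels_gmm(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    gm = GaussianMixture(
        n_components=k, covariance_type="diag", reg_covar=1e-6,
        random_state=seed, n_init=1, max_iter=200,
    )
    labels = gm.fit_predict(X)
    if not gm.converged_:
        raise RuntimeError("Gaussian mixture did not converge")
    return labels + 1


# ---------------------------------------------------------------------------
# Stage 3: the ensemble and its agreement matrix
# ---------------------------------------------------------------------------

def run_ensemble(
    profiles: list[TimeProfile],
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    seed: int = 0,
) -> AgreementMatrix:
    """Vote every (method, metric, k) combination into an agreement matrix.

    Distance-based families (hclust, diana, pam) run under every metric;
    centroid/model-based families (kmeans, som, gmm) are Euclidean-only.
    A failed run is logged and excluded from the denominator; more than half
    failing is an error.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError("need at least 3 profiles to cluster")
    k_lo, k_hi = max(2, k_range[0]), min(k_range[1], n - 1)
    if k_lo > k_hi:
        raise ValueError(f"k_range {k_range} is empty for {n} profiles")
    X = np.stack([p.values for p in profiles]).astype(float)
    dists = {m: _distance(X, m) for m in metrics}

    same = np.zeros((n, n))
    n_runs = n_failed = 0
    for k in range(k_lo, k_hi + 1):
        runs: list[tuple[str, str]] = []
        for method in methods:
            if method in _ALL_METRIC:
                runs += [(method, m) for m in metrics]
            else:
                runs.append((method, "euclidean"))
        for method, metric in runs:
            try:
                if method == "hclust":
                    labels = _labels_hclust(dists[metric], k)
                elif method == "diana":
                    labels = _labels_diana(dists[metric], k)
                elif method == "pam":
                    labels = _labels_pam(dists[metric], k)
                elif method == "kmeans":
                    labels = _labels_kmeans(X, k, seed)
                elif method == "som":
                    labels = _labels_som(X, k, seed)
                elif method == "gmm":
                    labels = _labels_gmm(X, k, seed)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception as exc:
                n_failed += 1
                logger.warning("run (%s, %s, k=%d) failed: %s",
                               method, metric, k, exc)
                continue
            same += labels[:, None] == labels[None, :]
            n_runs += 1
    if n_runs == 0 or n_failed > n_runs:
        raise RuntimeError(
            f"too many ensemble failures ({n_failed} failed, {n_runs} ok)"
        )
    values = same / n_runs
    np.fill_diagonal(values, 1.0)
    return AgreementMatrix([p.label for p in profiles], values, n_runs)


# ---------------------------------------------------------------------------
# Stage 4: ambiguity removal and final partition
# ---------------------------------------------------------------------------

def select_consistent_subset(
    agreement: AgreementMatrix, delta: float = DEFAULT_DELTA
) -> list[str]:
    """Greedily drop items until no pairwise agreement is ambiguous.

    An agreement a is ambiguous when 1 - delta < a < delta: the pair is
    neither consistently together (>= delta) nor consistently apart
    (<= 1 - delta).  The item with the most ambiguous partners is removed
    first (ties: lower mean agreement, then name).
    """
    if not 0.5 < delta <= 1.0:
        raise ValueError("delta must be in (0.5, 1]")
    names = list(agreement.items)
    A = agreement.values.copy()
    while True:
        n = len(names)
        if n == 0:
            raise RuntimeError(f"no consistent subset at delta={delta}")
        off = ~np.eye(n, dtype=bool)
        ambiguous = (A > 1 - delta) & (A < delta) & off
        counts = ambiguous.sum(axis=1)
        if counts.max(initial=0) == 0:
            return names
        worst = np.flatnonzero(counts == counts.max())
        if worst.size > 1:
            mean_agree = np.array([
                A[i, np.arange(n) != i].mean() for i in worst
            ])
            order = sorted(
                range(worst.size),
                key=lambda j: (mean_agree[j], names[worst[j]]),
            )
            drop = int(worst[order[0]])
        else:
            drop = int(worst[0])
        logger.info("removing ambiguous pathway %s (%d ambiguous pairs)",
                    names[drop], counts[drop])
        del names[drop]
        A = np.delete(np.delete(A, drop, axis=0), drop, axis=1)


def final_clusters(
    agreement: AgreementMatrix,
    profiles: list[TimeProfile],
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    delta: float = DEFAULT_DELTA,
    corr_threshold: float = 0.8,
    band: tuple[float, float] = (0.24, 0.28),
) -> ClusterResult:
    """Partition the retained items by their consensus distances.

    Average-linkage hierarchical clustering on 1 - agreement; the number of
    clusters is the k in ``k_range`` maximizing the mean silhouette on that
    distance (ties to the smaller k).  Cluster centroids are mean profiles,
    each fitted with the circadian sinusoid.
    """
    names = agreement.items
    if not names:
        raise ValueError("empty agreement matrix")
    by_label = {p.label: p for p in profiles}
    missing = [n for n in names if n not in by_label]
    if missing:
        raise ValueError(f"profiles missing for {missing}")
    D = 1.0 - agreement.values
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    n = len(names)
    Z = linkage(squareform(D, checks=False), method="average")

    best: tuple[float, int, np.ndarray] | None = None
    for k in range(max(2, k_range[0]), min(k_range[1], n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        try:
            score = silhouette_score(D, labels, metric="precomputed")
        except ValueError:
            continue
        if best is None or score > best[0] + 1e-12:
            best = (float(score), k, labels)
    if best is None:
        raise RuntimeError("no valid partition in k_range (silhouette undefined)")
    score, k, labels = best

    centroids: list[TimeProfile] = []
    fits: list[SinusoidFit] = []
    for lab in range(1, labels.max() + 1):
        members = [by_label[names[i]] for i in np.flatnonzero(labels == lab)]
        mean = np.mean([m.values for m in members], axis=0)
        centroid = TimeProfile(members[0].times, mean, f"cluster_{lab}")
        centroids.append(centroid)
        fits.append(fit_sinusoid(centroid, corr_threshold, band))
    return ClusterResult(
        retained=list(names),
        labels=labels,
        k_clusters=int(labels.max()),
        centroids=centroids,
        centroid_fits=fits,
        delta=delta,
        silhouette=score,
    )
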