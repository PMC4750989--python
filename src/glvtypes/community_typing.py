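"""Community-type detection on ensembles of steady states.

Steady states of many local communities, embedded in the common
metacommunity frame and normalized to relative abundances, play the role of
microbiome samples.  Community types are then the clusters found by
k-medoids (PAM) under the Jensen-Shannon distance, with the cluster number
chosen by the mean silhouette index (or the variance-ratio criterion), and
visualized by principal coordinates analysis.  A winning silhouette below
0.1 is read as absence of cluster structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from ._seeding import substream
from .dynamics import GLVSystem, integrate_to_steady
from .metacommunity import LocalCommunity, Metacommunity

__all__ = [
    "SteadyStateEnsemble",
    "ClusteringResult",
    "ClusterProfile",
    "simulate_ensemble",
    "relative_abundance",
    "jsd_distance",
    "jsd_matrix",
    "kmedoids",
    "silhouette",
    "variance_ratio",
    "select_k",
    "pcoa",
    "cluster_ensemble",
    "characterize_clusters",
]

NO_CLUSTERING_SILHOUETTE = 0.1


@dataclass
class SteadyStateEnsemble:
    """q steady-state samples in the n-species metacommunity frame.

    ``samples`` holds absolute abundances (absent species are zero) for the
    stable runs only; unstable local communities are excluded up front and
    counted in ``n_unstable``.
    """

    samples: np.ndarray
    membership: list[np.ndarray]
    meta: Metacommunity | None = None
    n_unstable: int = 0
    unstable_reasons: dict = field(default_factory=dict)

    @property
    def q(self) -> int:
        return self.samples.shape[0]

    @property
    def relative(self) -> np.ndarray:
        return relative_abundance(self.samples)

    def to_tsv(self, path) -> None:
        """Samples-by-species table of absolute abundances."""
        import pandas as pd
        n = self.samples.shape[1]
        pd.DataFrame(self.samples, columns=[f"sp{j}" for j in range(n)]
                     ).to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "SteadyStateEnsemble":
        """Load a samples-by-species table; membership = positive entries."""
        import pandas as pd
        samples = pd.read_csv(path, sep="\t", index_col=0).to_numpy()
        membership = [np.flatnonzero(row > 0) for row in samples]
        return cls(samples=samples, membership=membership)


@dataclass
class ClusteringResult:
    distance: np.ndarray
    metric: str
    abundance: str
    per_k: dict  # k -> dict(labels, medoids, silhouette, vrc, cost)
    k_opt: int
    criterion: str
    best_score: float
    no_clustering: bool
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    negative_eigenvalue_mass: float
    states: np.ndarray = field(default=None, repr=False)

    @property
    def labels(self) -> np.ndarray:
        return self.per_k[self.k_opt]["labels"]

    @property
    def medoids(self) -> np.ndarray:
        return self.per_k[self.k_opt]["medoids"]

    def save(self, outdir) -> None:
        """Write labels, the per-k score table, coordinates and a summary."""
        import json
        from pathlib import Path
        import pandas as pd
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"label": self.labels}).to_csv(
            outdir / "labels.tsv", sep="\t", index_label="sample")
        pd.DataFrame([
            {"k": k, "silhouette": self.per_k[k]["silhouette"],
             "vrc": self.per_k[k]["vrc"], "cost": self.per_k[k]["cost"]}
            for k in self.per_k]).to_csv(outdir / "scores.tsv", sep="\t",
                                         index=False)
        pd.DataFrame(self.coordinates).to_csv(
            outdir / "coordinates.tsv", sep="\t", index_label="sample")
        (outdir / "summary.json").write_text(json.dumps({
            "metric": self.metric, "abundance": self.abundance,
            "criterion": self.criterion, "k_opt": int(self.k_opt),
            "best_score": float(self.best_score),
            "no_clustering": bool(self.no_clustering),
            "negative_eigenvalue_mass": float(self.negative_eigenvalue_mass),
        }, indent=1))


@dataclass
class ClusterProfile:
    cluster: int
    size: int
    top_species: list  # (species index, mean relative abundance), descending
    sis_presence: dict  # SIS index -> fraction of member LCs containing it


def simulate_ensemble(meta: Metacommunity, lcs: list[LocalCommunity],
                      seed: int | None = None, horizon: float = 100.0,
                      x0_low: float = 0.0, x0_high: float = 1.0,
                      ) -> SteadyStateEnsemble:
    """Integrate every local community from U(x0_low, x0_high) initial abundances.

    Initial conditions use the per-community substream ("x0", nu).  Unstable
    runs (solver failure, terminal discrete derivative above 0.01, or
    non-finite states) are dropped, mirroring the exclusion rule of the
    simulation protocol.
    """
    seed = meta.config.seed if seed is None else seed
    rows, membership, reasons = [], [], {}
    n_unstable = 0
    for lc in lcs:
        rng = substream(seed, "x0", lc.nu)
        x0 = rng.uniform(x0_low, x0_high, lc.p)
        res = integrate_to_steady(GLVSystem.from_local(lc), x0, horizon=horizon)
        if res.stable:
            rows.append(lc.embed(res.x_star))
            membership.append(lc.members)
        else:
            n_unstable += 1
            reasons[lc.nu] = res.reason
    samples = np.array(rows) if rows else np.empty((0, meta.n))
    return SteadyStateEnsemble(samples=samples, membership=membership, meta=meta,
                               n_unstable=n_unstable, unstable_reasons=reasons)


def relative_abundance(samples: np.ndarray) -> np.ndarray:
    """Row-normalize nonnegative abundance rows to sum to one.

    Raises on negative entries or on all-zero rows (a community with no
    biomass has no composition).
    """
    samples = np.asarray(samples, dtype=float)
    if np.any(samples < 0):
        raise ValueError("abundances must be nonnegative")
    totals = samples.sum(axis=-1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("cannot normalize an all-zero abundance row")
    return samples / totals


def jsd_distance(p: np.ndarray, q: np.ndarray, tol: float = 1e-8) -> float:
    """Jensen-Shannon distance between two relative-abundance profiles.

    Square root of the Jensen-Shannon divergence with base-2 logarithms
    (0 log 0 := 0), hence a metric bounded by 1, attained on disjoint
    supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for v in (p, q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > tol:
            raise ValueError("inputs must be probability vectors")
    return float(jsd_matrix(np.vstack([p, q]))[0, 1])


def _entropy2(M: np.ndarray) -> np.ndarray:
    """Row-wise base-2 Shannon entropy with 0 log 0 = 0."""
    safe = np.where(M > 0, M, 1.0)
    return -(M * np.log2(safe)).sum(axis=-1)


def jsd_matrix(rel: np.ndarray) -> np.ndarray:
    """Pairwise Jensen-Shannon distance matrix for row-stochastic input."""
    rel = np.asarray(rel, dtype=float)
    m = rel.shape[0]
    h = _entropy2(rel)
    D = np.zeros((m, m))
    for i in range(m):
        mix = 0.5 * (rel[i] + rel[i:])
        div = _entropy2(mix) - 0.5 * (h[i] + h[i:])
        D[i, i:] = np.sqrt(np.clip(div, 0.0, None))
    D = D + D.T
    np.fill_diagonal(D, 0.0)
    return D


def _pam_swap(D: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy best-improvement swap phase of PAM.

    Repeatedly evaluates every (medoid, candidate) exchange from the current
    assignment (vectorized over candidates) and applies the best strictly
    improving one until none remains.
    """
    q = len(D)
    medoids = np.array(sorted(medoids))
    while True:
        dm = D[:, medoids]
        order = np.argsort(dm, axis=1)
        d1 = dm[np.arange(q), order[:, 0]]
        nearest = order[:, 0]
        d2 = dm[np.arange(q), order[:, 1]] if len(medoids) > 1 else np.full(q, np.inf)
        cand = np.setdiff1d(np.arange(q), medoids, assume_unique=False)
        if len(cand) == 0:
            break
        Dc = D[:, cand]
        best_delta, best_swap = -1e-12, None
        for jpos, m in enumerate(medoids):
            owned = nearest == jpos
            # points owned by m: cost becomes min(d(i,h), d2_i)
            delta_owned = (np.minimum(Dc[owned], d2[owned, None]) - d1[owned, None]).sum(0)
            # other points: can only improve, to d(i,h) if closer than d1
            delta_other = np.minimum(Dc[~owned] - d1[~owned, None], 0.0).sum(0)
            delta = delta_owned + delta_other
            idx = int(np.argmin(delta))
            if delta[idx] < best_delta:
                best_delta, best_swap = float(delta[idx]), (jpos, cand[idx])
        if best_swap is None:
            break
        jpos, h = best_swap
        medoids[jpos] = h
        medoids = np.array(sorted(medoids))
    dm = D[:, medoids]
    labels = np.argmin(dm, axis=1)
    cost = float(dm[np.arange(q), labels].sum())
    return medoids, cost


def _pam_build(D: np.ndarray, k: int) -> np.ndarray:
    """Classic greedy BUILD initialization."""
    q = len(D)
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    d1 = D[:, first].copy()
    while len(medoids) < k:
        gains = np.maximum(d1[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        d1 = np.minimum(d1, D[:, nxt])
    return np.array(medoids)


def kmedoids(distance: np.ndarray, k: int, seed: int = 0, restarts: int = 10,
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM k-medoids on a precomputed distance matrix.

    One greedy BUILD start plus ``restarts - 1`` random seeded starts, each
    refined by best-improvement swaps; returns (labels, medoids, cost) of the
    lowest total distance-to-medoid cost.  Ties go to the lexicographically
    smallest sorted medoid set.
    """
    D = np.asarray(distance, dtype=float)
    q = len(D)
    if not 1 <= k <= q:
        raise ValueError("k must lie in [1, q]")
    starts = [_pam_build(D, k)]
    rng = np.random.default_rng(seed)
    for _ in range(max(restarts - 1, 0)):
        starts.append(rng.choice(q, size=k, replace=False))
    best = None
    for init in starts:
        medoids, cost = _pam_swap(D, init)
        key = (cost, tuple(medoids))
        if best is None or key < best[0]:
            best = (key, medoids)
    medoids = best[1]
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids, best[0][0]


def silhouette(distance: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette index on a precomputed distance matrix.

    s(i) = (b - a) / max(a, b) with a the mean within-cluster distance and b
    the smallest mean distance to another cluster; samples in singleton
    clusters score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(silhouette_score(np.asarray(distance), labels, metric="precomputed"))


def variance_ratio(coordinates: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz statistic on an (embedding) coordinate matrix.

    Between/within dispersion ratio scaled by (q - k)/(k - 1); degenerate
    zero within-dispersion returns +inf.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("variance ratio is undefined for a single cluster")
    X = np.asarray(coordinates, dtype=float)
    within = sum(
        ((X[labels == c] - X[labels == c].mean(0)) ** 2).sum()
        for c in np.unique(labels)
    )
    if within == 0:
        return np.inf
    return float(calinski_harabasz_score(X, labels))


def select_k(scores: dict[int, float]) -> tuple[int, float]:
    """Argmax of the criterion over k; ties go to the smallest k."""
    if not scores:
        raise ValueError("no candidate cluster numbers were scored")
    k_opt = min(scores, key=lambda k: (-scores[k], k))
    return k_opt, scores[k_opt]


def pcoa(distance: np.ndarray, dims: int | None = None,
         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Classical scaling (principal coordinates analysis).

    Double-centers -D^2/2, eigendecomposes, and keeps the positive
    eigenvalues; coordinates are eigenvectors scaled by sqrt(eigenvalue),
    axes ordered by decreasing eigenvalue.  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive.  Returns
    (coordinates, eigenvalues, negative_eigenvalue_mass) where the last is
    sum(|negative|)/sum(|all|) -- nonzero for non-Euclidean distances such
    as JSD.
    """
    D = np.asarray(distance, dtype=float)
    q = len(D)
    J = np.eye(q) - np.ones((q, q)) / q
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(q, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    neg_mass = float(np.abs(eigval[eigval < -tol]).sum() / max(np.abs(eigval).sum(), tol))
    keep = eigval > tol
    eigval_pos, vec = eigval[keep], eigvec[:, keep]
    coords = vec * np.sqrt(eigval_pos)
    for j in range(coords.shape[1]):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    if dims is not None:
        coords = coords[:, :dims]
        eigval_pos = eigval_pos[:dims]
    return coords, eigval_pos, neg_mass


def _distance_matrix(states: np.ndarray, metric: str) -> np.ndarray:
    if metric == "jsd":
        return jsd_matrix(states)
    if metric == "euclidean":
        diff = states[:, None, :] - states[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))
    raise ValueError(f"unknown metric {metric!r}")


def cluster_ensemble(ensemble: SteadyStateEnsemble | np.ndarray,
                     metric: str = "jsd", abundance: str = "relative",
                     criterion: str = "silhouette",
                     krange=range(2, 11), seed: int = 0, restarts: int = 10,
                     ) -> ClusteringResult:
    """Full community-typing pipeline on a steady-state ensemble.

    Normalizes (if ``abundance="relative"``), builds the distance matrix,
    runs PAM for each k in ``krange``, scores each partition by silhouette
    and by the variance-ratio criterion on the full PCoA embedding, selects
    the optimal k by the chosen criterion (ties to smaller k), and flags
    ``no_clustering`` when the winning mean silhouette falls below 0.1.
    """
    if isinstance(ensemble, SteadyStateEnsemble):
        samples = ensemble.samples
    else:
        samples = np.asarray(ensemble, dtype=float)
    states = relative_abundance(samples) if abundance == "relative" else samples
    D = _distance_matrix(states, metric)
    coords, eigval, neg_mass = pcoa(D)
    per_k = {}
    for k in krange:
        labels, medoids, cost = kmedoids(D, k, seed=seed, restarts=restarts)
        entry = {"labels": labels, "medoids": medoids, "cost": cost}
        if len(np.unique(labels)) >= 2:
            entry["silhouette"] = silhouette(D, labels)
            entry["vrc"] = variance_ratio(coords, labels)
        else:  # collapsed partition: worst possible scores
            entry["silhouette"], entry["vrc"] = -1.0, 0.0
        per_k[k] = entry
    scores = {k: per_k[k][criterion] for k in per_k}
    k_opt, best = select_k(scores)
    sil_win = per_k[k_opt]["silhouette"]
    return ClusteringResult(
        distance=D, metric=metric, abundance=abundance, per_k=per_k,
        k_opt=k_opt, criterion=criterion, best_score=best,
        no_clustering=bool(sil_win < NO_CLUSTERING_SILHOUETTE),
        coordinates=coords, eigenvalues=eigval,
        negative_eigenvalue_mass=neg_mass, states=states,
    )


def characterize_clusters(ensemble: SteadyStateEnsemble, labels: np.ndarray,
                          sis_ids, top_m: int = 6) -> list[ClusterProfile]:
    """Dominating species and SIS occupancy per cluster.

    For each cluster: the ``top_m`` species by mean relative abundance over
    member samples, and for each listed SIS the fraction of member local
    communities whose species set contains it.  In heterogeneous
    metacommunities the SISs are typically *not* among the dominating
    species even though their presence defines the cluster.
    """
    labels = np.asarray(labels)
    sis_ids = np.asarray(sis_ids, dtype=int)
    n = ensemble.samples.shape[1]
    if np.any(sis_ids < 0) or np.any(sis_ids >= n):
        raise ValueError("unknown species id in sis_ids")
    rel = ensemble.relative
    profiles = []
    for c in np.unique(labels):
        rows = np.where(labels == c)[0]
        mean_rel = rel[rows].mean(axis=0)
        ranked = np.argsort(-mean_rel, kind="stable")[:top_m]
        presence = {
            int(sid): float(np.mean([sid in ensemble.membership[i] for i in rows]))
            for sid in sis_ids
        }
        profiles.append(ClusterProfile(
            cluster=int(c), size=len(rows),
            top_species=[(int(sp), float(mean_rel[sp])) for sp in ranked],
            sis_presence=presence,
        ))
    return profiles
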