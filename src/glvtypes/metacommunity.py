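"""Random metacommunities with heterogeneous interaction strengths.

A metacommunity is a universal species pool S = {0, ..., n-1} together with
an interaction matrix A and growth-rate vector r.  A is built from four
components,

    A = N H ∘ G s,       off-diagonal;  A_ii = -1,

where N holds nominal interaction strengths (i.i.d. normal), the diagonal
matrix H scales each species' outgoing interactions (its column of A), G is
the binary adjacency matrix of the ecological network, ∘ is the Hadamard
product, and s in (0, 1] is a global scaling that keeps the dynamics stable.
Heterogeneity of the diagonal of H -- a few species with outsized columns,
the strongly interacting species (SISs) -- is the object of study.

Local communities are random p-subsets of the pool; their dynamics use the
corresponding submatrix of A and subvector of r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import substream

__all__ = [
    "MetacommunityConfig",
    "Metacommunity",
    "LocalCommunity",
    "sample_powerlaw",
    "build_heterogeneity",
    "build_topology",
    "assemble_interaction_matrix",
    "generate_metacommunity",
    "sample_local_communities",
]

TOPOLOGIES = ("complete", "erdos_renyi", "powerlaw_out")


@dataclass
class MetacommunityConfig:
    """Generative parameters for one universal triple (S, A, r).

    Parameters
    ----------
    n : species count.
    sigma : s.d. of the nominal normal interaction strengths.
    alpha : power-law exponent of the heterogeneity distribution; smaller
        alpha (down toward 1) means heavier tails, i.e. stronger SISs.
    topology : "complete", "erdos_renyi" or "powerlaw_out".
    edge_prob : link probability for the Erdős–Rényi digraph.
    mean_out_degree : target mean out-degree for the power-law digraph.
    s : global interaction scaling in (0, 1].
    heterogeneity : if False, H is the identity matrix.
    seed : master seed for this metacommunity.
    """

    n: int = 100
    sigma: float = 1.0
    alpha: float = 2.0
    topology: str = "complete"
    edge_prob: float = 0.1
    mean_out_degree: float = 10.0
    s: float = 0.07
    heterogeneity: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if not 0 < self.s <= 1:
            raise ValueError("s must lie in (0, 1]")
        if not 0 < self.edge_prob <= 1:
            raise ValueError("edge_prob must lie in (0, 1]")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class Metacommunity:
    """A universal triple (S, A, r) plus its generative components."""

    config: MetacommunityConfig
    N: np.ndarray
    H: np.ndarray
    G: np.ndarray
    s: float
    A: np.ndarray
    r: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def species(self) -> np.ndarray:
        return np.arange(self.n)

    def sis_ranking(self) -> np.ndarray:
        """Species indices ranked by outgoing interaction scale H_jj, descending.

        The top entries are the strongly interacting species (SISs).  Ties
        broken by species index.
        """
        h = np.diag(self.H)
        return np.argsort(-h, kind="stable")

    def local(self, members, nu: int = 0, seed: int | None = None) -> "LocalCommunity":
        """Extract the local community on the given (sorted) member set."""
        members = np.asarray(members, dtype=int)
        if members.ndim != 1 or len(np.unique(members)) != len(members):
            raise ValueError("members must be a 1-d set of distinct indices")
        if members.min() < 0 or members.max() >= self.n:
            raise ValueError("member index out of range")
        members = np.sort(members)
        return LocalCommunity(
            nu=nu,
            members=members,
            A_local=self.A[np.ix_(members, members)],
            r_local=self.r[members],
            parent=self,
            seed=seed,
        )

    def to_dir(self, path) -> None:
        """Serialize components as TSV plus a JSON sidecar with the config."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        idx = pd.Index(self.species, name="species")
        for name, mat in (("N", self.N), ("H", self.H), ("G", self.G), ("A", self.A)):
            pd.DataFrame(mat, index=idx, columns=idx).to_csv(path / f"{name}.tsv", sep="\t")
        pd.Series(self.r, index=idx, name="r").to_csv(path / "r.tsv", sep="\t")
        sidecar = {"s": self.s, "config": {**self.config.__dict__}}
        (path / "metacommunity.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, path) -> "Metacommunity":
        path = Path(path)
        sidecar = json.loads((path / "metacommunity.json").read_text())
        mats = {
            name: pd.read_csv(path / f"{name}.tsv", sep="\t", index_col=0).to_numpy()
            for name in ("N", "H", "G", "A")
        }
        r = pd.read_csv(path / "r.tsv", sep="\t", index_col=0)["r"].to_numpy()
        cfg = MetacommunityConfig(**sidecar["config"])
        return cls(config=cfg, s=sidecar["s"], r=r, **mats)


@dataclass
class LocalCommunity:
    """A p-species subset of the pool with its extracted dynamics."""

    nu: int
    members: np.ndarray
    A_local: np.ndarray
    r_local: np.ndarray
    parent: Metacommunity | None = None
    seed: int | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.members)

    def embed(self, x_local: np.ndarray) -> np.ndarray:
        """Lift a p-vector of abundances into the n-species pool frame."""
        full = np.zeros(self.parent.n if self.parent is not None else self.members.max() + 1)
        full[self.members] = x_local
        return full


def sample_powerlaw(alpha: float, size: int, seed=None) -> np.ndarray:
    """Draw i.i.d. power-law (Pareto) samples on x >= 1.

    Inverse-CDF sampling ``x = U**(-1/alpha)``: survival function x**(-alpha),
    density proportional to x**(-(alpha+1)).  Heavier tails as alpha
    approaches 1 from above; at alpha slightly above 1 the largest draw
    dominates the sum, which is the single-SIS regime.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if size < 1:
        raise ValueError("size must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.exp(_log_powerlaw(alpha, size, rng))


def _log_powerlaw(alpha: float, size: int, rng: np.random.Generator) -> np.ndarray:
    # log x = E / alpha with E ~ Exp(1); kept in log space so that the
    # mean-normalization below stays finite for alpha near 1.
    return rng.exponential(1.0, size) / alpha


def _normalize_log(logh: np.ndarray) -> np.ndarray:
    # h / mean(h) computed via log-sum-exp to survive huge draws
    shift = logh.max()
    w = np.exp(logh - shift)
    return w * (len(w) / w.sum())


def build_heterogeneity(hbar: np.ndarray) -> np.ndarray:
    """Diagonal heterogeneity matrix H = diag(hbar / mean(hbar))."""
    hbar = np.asarray(hbar, dtype=float)
    if hbar.ndim != 1 or np.any(hbar <= 0) or not np.all(np.isfinite(hbar)):
        raise ValueError("hbar must be a positive finite vector")
    return np.diag(hbar / hbar.mean())


def build_topology(kind: str, n: int, *, edge_prob: float | None = None,
                   mean_out_degree: float | None = None,
                   hbar: np.ndarray | None = None,
                   seed=None) -> np.ndarray:
    """Binary adjacency matrix G with zero diagonal.

    G_ij = 1 means species i is affected by species j, so the out-edges of
    species j form column j of G (and of A).

    kind:
      - "complete": every off-diagonal entry is 1.
      - "erdos_renyi": each ordered pair is a link independently with
        probability ``edge_prob``.
      - "powerlaw_out": species j receives out-degree
        round(mean_out_degree * hbar_j / mean(hbar)), clipped to [0, n-1],
        with targets drawn uniformly without replacement; reusing the
        heterogeneity draws as ``hbar`` aligns high out-degree with high
        interaction scaling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "complete":
        G = np.ones((n, n))
    elif kind == "erdos_renyi":
        if edge_prob is None:
            raise ValueError("erdos_renyi topology needs edge_prob")
        G = (rng.random((n, n)) < edge_prob).astype(float)
    elif kind == "powerlaw_out":
        if hbar is None:
            raise ValueError("powerlaw_out topology needs an hbar degree profile")
        if mean_out_degree is None:
            raise ValueError("powerlaw_out topology needs mean_out_degree")
        hbar = np.asarray(hbar, dtype=float)
        degrees = np.clip(np.floor(mean_out_degree * hbar / hbar.mean() + 0.5), 0, n - 1)
        G = np.zeros((n, n))
        for j, d in enumerate(degrees.astype(int)):
            others = np.delete(np.arange(n), j)
            targets = rng.choice(others, size=d, replace=False)
            G[targets, j] = 1.0
    else:
        raise ValueError(f"unknown topology {kind!r}")
    np.fill_diagonal(G, 0.0)
    return G


def assemble_interaction_matrix(N: np.ndarray, H: np.ndarray, G: np.ndarray,
                                s: float) -> np.ndarray:
    """A = N H ∘ G s off-diagonal, with A_ii = -1.

    H being diagonal, N H scales column j of N by H_jj; the Hadamard product
    with G then masks absent links.
    """
    N, H, G = (np.asarray(m, dtype=float) for m in (N, H, G))
    if not (N.shape == H.shape == G.shape) or N.shape[0] != N.shape[1]:
        raise ValueError("N, H, G must be square matrices of equal shape")
    A = (N @ H) * G * s
    np.fill_diagonal(A, -1.0)
    return A


def generate_metacommunity(config: MetacommunityConfig) -> Metacommunity:
    """Draw all components with the config seed and assemble the triple.

    Substreams: "N" (nominal), "h" (heterogeneity), "G" (topology),
    "r" (growth rates).  Two calls with the same config are bitwise
    identical.
    """
    n = config.n
    N = substream(config.seed, "N").normal(0.0, config.sigma, (n, n))
    # the power-law draw also supplies the out-degree profile for the
    # powerlaw_out topology, even when H itself is switched off
    logh = _log_powerlaw(config.alpha, n, substream(config.seed, "h"))
    h_norm = _normalize_log(logh)
    if config.heterogeneity:
        H = np.diag(h_norm)
    else:
        H = np.eye(n)
    G = build_topology(
        config.topology, n,
        edge_prob=config.edge_prob,
        mean_out_degree=config.mean_out_degree,
        hbar=h_norm,
        seed=substream(config.seed, "G"),
    )
    r = substream(config.seed, "r").uniform(0.0, 1.0, n)
    A = assemble_interaction_matrix(N, H, G, config.s)
    return Metacommunity(config=config, N=N, H=H, G=G, s=config.s, A=A, r=r)


def sample_local_communities(meta: Metacommunity, q: int, p: int,
                             seed: int | None = None) -> list[LocalCommunity]:
    """Sample q local communities of p species uniformly without replacement.

    Each community stores its own substream seed ("lc", nu) so it can be
    regenerated in isolation.
    """
    if p > meta.n:
        raise ValueError("p cannot exceed the metacommunity size")
    if q < 1:
        raise ValueError("q must be positive")
    seed = meta.config.seed if seed is None else seed
    out = []
    for nu in range(q):
        rng = substream(seed, "lc", nu)
        members = np.sort(rng.choice(meta.n, size=p, replace=False))
        out.append(meta.local(members, nu=nu, seed=seed))
    return out
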