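"""Open-loop control of community types.

Three intervention scenarios steer a controlled local community (LC*)
toward a target community type, emulating clinical manipulation of a gut
microbiome:

* **SIS swap** -- remove the strongly interacting species that
  characterize LC*'s own cluster and introduce (at arbitrary small random
  abundance) the SISs characteristic of the target cluster;
* **dominant swap** -- replace the six most abundant species of LC* with
  the six most abundant species of a donor community, copied at exactly the
  donor's steady abundances;
* **FMT** -- remove LC*'s SISs plus its most abundant species (antibiotic
  stage), let the community settle into a depleted "CDI" state, then add a
  small fraction (default 1%) of every species of a donor community's
  steady state (the transplant) and let the dynamics run.

Success is membership of the target cluster at the integration endpoint,
judged by the nearest background sample (1-NN; the medoid rule is available
but brittle when clusters overlap).  The robust outcome -- SIS swaps
succeed, dominant swaps fail, FMT succeeds only when the donor's SISs are
transplanted -- shows that the strongly interacting species, not the
abundant ones, carry the community type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import substream
from .community_typing import ClusteringResult, SteadyStateEnsemble, jsd_matrix
from .dynamics import GLVSystem, integrate_to_steady
from .metacommunity import Metacommunity

__all__ = [
    "ControlContext",
    "ControlScenario",
    "ControlOutcome",
    "classify_endpoint",
    "sis_swap",
    "dominant_swap",
    "fmt_protocol",
    "plan_sis_swap",
    "project_trajectory",
]


@dataclass
class ControlContext:
    """Background against which interventions are run and judged.

    ``k`` selects which k-medoids partition of the background defines the
    community types (default: the optimal k).  The finer-than-optimal
    partition is sometimes the relevant one -- e.g. when the SIS-combination
    groups are resolved at k = 3 while the silhouette optimum is k = 2.
    """

    meta: Metacommunity
    ensemble: SteadyStateEnsemble
    clustering: ClusteringResult
    k: int | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.clustering.per_k[self.k or self.clustering.k_opt]["labels"]

    @property
    def medoids(self) -> np.ndarray:
        return self.clustering.per_k[self.k or self.clustering.k_opt]["medoids"]

    def steady_state(self, index: int) -> np.ndarray:
        return self.ensemble.samples[index]

    def members(self, index: int) -> np.ndarray:
        return self.ensemble.membership[index]


@dataclass
class ControlScenario:
    """One intervention on a controlled community.

    ``source_index`` / ``donor_index`` are rows of the background ensemble.
    ``horizon`` is the post-intervention integration time; interventions can
    trigger much slower transients than community assembly from random
    abundances, so the default is generous.
    ``remove_ids`` / ``add_ids`` are metacommunity species indices (used by
    the SIS swap; the other scenarios derive their sets from abundances and
    the SIS ranking).  ``dose`` is the transplanted fraction of the donor's
    steady abundances.
    """

    kind: str
    source_index: int
    target_cluster: int
    donor_index: int | None = None
    remove_ids: np.ndarray | None = None
    add_ids: np.ndarray | None = None
    add_init: str = "uniform01"
    dose: float = 0.01
    n_remove_abundant: int = 18
    n_sis: int = 2
    withhold_donor_sis: bool = False
    withhold_ids: np.ndarray | None = None
    horizon: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in {"sis_swap", "dominant_swap", "fmt", "custom"}:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "fmt" and not 0 <= self.dose <= 1:
            raise ValueError("dose must lie in [0, 1]")


@dataclass
class ControlOutcome:
    final_state: np.ndarray
    assigned_cluster: int
    distance: float
    success: bool
    checkpoints: dict = field(default_factory=dict)
    reason: str | None = None


def _metric_distances(state_abs: np.ndarray, clustering: ClusteringResult,
                      reference: np.ndarray) -> np.ndarray:
    """Distance from one pool-frame absolute state to reference states."""
    if clustering.abundance == "relative":
        total = state_abs.sum()
        if total <= 0:
            raise ValueError("cannot classify an empty community")
        state = state_abs / total
    else:
        state = state_abs
    if clustering.metric == "euclidean":
        return np.linalg.norm(reference - state, axis=1)
    stacked = np.vstack([state, reference])
    return jsd_matrix(stacked)[0, 1:]


def classify_endpoint(state_abs: np.ndarray, clustering: ClusteringResult,
                      medoids: np.ndarray | None = None,
                      labels: np.ndarray | None = None) -> tuple[int, float]:
    """Cluster id for a pool-frame state; ties to the lowest id.

    With ``labels`` given, assignment is nearest-sample (1-NN over the
    background ensemble), which is robust when clusters overlap and their
    medoids are poor prototypes of the boundary; otherwise assignment is
    nearest-medoid.  The reported distance is to the deciding reference
    state.
    """
    if labels is not None:
        d = _metric_distances(state_abs, clustering, clustering.states)
        i = int(np.argmin(d))
        return int(labels[i]), float(d[i])
    medoid_states = clustering.states[
        clustering.medoids if medoids is None else medoids]
    d = _metric_distances(state_abs, clustering, medoid_states)
    cid = int(np.argmin(d))  # argmin takes the lowest index on ties
    return cid, float(d[cid])


def _settle(ctx: ControlContext, members: np.ndarray, init_full: np.ndarray,
            horizon: float = 100.0):
    """Integrate the community on ``members`` from the pool-frame init."""
    lc = ctx.meta.local(np.sort(np.asarray(members, dtype=int)))
    res = integrate_to_steady(GLVSystem.from_local(lc), init_full[lc.members],
                              horizon=horizon)
    return lc, res


def _outcome(ctx: ControlContext, lc, res, target: int, checkpoints: dict,
             ) -> ControlOutcome:
    if not np.all(np.isfinite(res.x_star)):
        return ControlOutcome(final_state=np.full(ctx.meta.n, np.nan),
                              assigned_cluster=-1, distance=np.inf,
                              success=False, checkpoints=checkpoints,
                              reason=res.reason or "unstable")
    final = lc.embed(res.x_star)
    cid, dist = classify_endpoint(final, ctx.clustering, labels=ctx.labels)
    return ControlOutcome(final_state=final, assigned_cluster=cid, distance=dist,
                          success=bool(cid == target), checkpoints=checkpoints,
                          reason=None if res.stable else res.reason)


def sis_swap(ctx: ControlContext, scenario: ControlScenario) -> ControlOutcome:
    """Replace the source cluster's SISs with the target cluster's SISs.

    Removed species leave the community entirely; added species enter at
    initial abundances drawn from U(0, 1) (substream "add_init").  All other
    residents start at their current steady abundances.
    """
    if scenario.remove_ids is None or scenario.add_ids is None:
        raise ValueError("sis_swap needs explicit remove_ids and add_ids")
    members = ctx.members(scenario.source_index)
    remove = np.asarray(scenario.remove_ids, dtype=int)
    add = np.asarray(scenario.add_ids, dtype=int)
    if not np.all(np.isin(remove, members)):
        raise ValueError("remove_ids must be current members")
    kept = np.setdiff1d(members, remove)
    if np.any(np.isin(add, kept)):
        raise ValueError("add_ids overlap the retained residents")
    new_members = np.union1d(kept, add)
    init = ctx.steady_state(scenario.source_index).copy()
    init[remove] = 0.0
    if scenario.add_init == "uniform01":
        rng = substream(scenario.seed, "add_init", scenario.source_index)
        init[add] = rng.uniform(0.0, 1.0, len(add))
    elif scenario.add_init == "copy_donor" and scenario.donor_index is not None:
        init[add] = ctx.steady_state(scenario.donor_index)[add]
    else:
        raise ValueError(f"unsupported add_init {scenario.add_init!r}")
    checkpoints = {"post_swap": init.copy()}
    lc, res = _settle(ctx, new_members, init, horizon=scenario.horizon)
    return _outcome(ctx, lc, res, scenario.target_cluster, checkpoints)


def dominant_swap(ctx: ControlContext, scenario: ControlScenario,
                  m_dominant: int = 6) -> ControlOutcome:
    """Swap the most abundant species for the donor's most abundant ones.

    The donor's top species enter at exactly the donor's steady abundances;
    species present in both communities are overwritten to the donor level.
    """
    if scenario.donor_index is None:
        raise ValueError("dominant_swap needs a donor")
    members = ctx.members(scenario.source_index)
    state = ctx.steady_state(scenario.source_index).copy()
    remove = members[np.argsort(-state[members], kind="stable")[:m_dominant]]
    donor_members = ctx.members(scenario.donor_index)
    donor_state = ctx.steady_state(scenario.donor_index)
    add = donor_members[np.argsort(-donor_state[donor_members], kind="stable")[:m_dominant]]
    kept = np.setdiff1d(members, remove)
    new_members = np.union1d(kept, add)
    init = state
    init[remove] = 0.0
    init[add] = donor_state[add]
    checkpoints = {"post_swap": init.copy()}
    lc, res = _settle(ctx, new_members, init, horizon=scenario.horizon)
    return _outcome(ctx, lc, res, scenario.target_cluster, checkpoints)


def fmt_protocol(ctx: ControlContext, scenario: ControlScenario) -> ControlOutcome:
    """Antibiotic knockout followed by a fractional-dose transplant.

    Stage 1 removes the SISs of LC* -- ``remove_ids`` when given (e.g. the
    cluster-characteristic SISs from :func:`plan_sis_swap`), otherwise the
    ``n_sis`` members with the highest heterogeneity scale -- together with
    the ``n_remove_abundant`` most abundant of the remaining species, then
    integrates to the depleted CDI state.  Stage 2 adds ``dose`` times the
    donor's steady abundance of every donor species to the CDI state
    (incrementing residents, introducing absentees) and integrates to the
    final state.  With ``withhold_donor_sis`` the donor's SISs --
    ``withhold_ids`` when given, otherwise the donor's top-H members -- are
    left out of the transplant, the designed failure control.
    """
    if scenario.donor_index is None:
        raise ValueError("fmt needs a donor")
    meta = ctx.meta
    members = ctx.members(scenario.source_index)
    state = ctx.steady_state(scenario.source_index).copy()
    h = np.diag(meta.H)
    if scenario.remove_ids is not None:
        sis_members = np.asarray(scenario.remove_ids, dtype=int)
        if not np.all(np.isin(sis_members, members)):
            raise ValueError("remove_ids must be current members")
    else:
        sis_members = members[
            np.argsort(-h[members], kind="stable")[:scenario.n_sis]]
    rest = np.setdiff1d(members, sis_members)
    top_rest = rest[np.argsort(-state[rest], kind="stable")[:scenario.n_remove_abundant]]
    remove = np.union1d(sis_members, top_rest)
    kept = np.setdiff1d(members, remove)
    init = state
    init[remove] = 0.0
    checkpoints = {"post_antibiotic": init.copy()}
    lc_cdi, res_cdi = _settle(ctx, kept, init, horizon=scenario.horizon)
    if not (res_cdi.stable and np.all(np.isfinite(res_cdi.x_star))):
        return ControlOutcome(final_state=np.full(meta.n, np.nan),
                              assigned_cluster=-1, distance=np.inf, success=False,
                              checkpoints=checkpoints, reason="cdi_unstable")
    cdi = lc_cdi.embed(res_cdi.x_star)
    checkpoints["cdi"] = cdi.copy()

    donor_members = ctx.members(scenario.donor_index)
    donor_state = ctx.steady_state(scenario.donor_index)
    transplant = donor_members
    if scenario.withhold_donor_sis:
        if scenario.withhold_ids is not None:
            donor_sis = np.asarray(scenario.withhold_ids, dtype=int)
        else:
            donor_sis = donor_members[
                np.argsort(-h[donor_members], kind="stable")[:scenario.n_sis]]
        transplant = np.setdiff1d(donor_members, donor_sis)
    init2 = cdi.copy()
    init2[transplant] += scenario.dose * donor_state[transplant]
    checkpoints["post_fmt"] = init2.copy()
    new_members = np.union1d(kept, transplant) if scenario.dose > 0 else kept
    lc, res = _settle(ctx, new_members, init2, horizon=scenario.horizon)
    return _outcome(ctx, lc, res, scenario.target_cluster, checkpoints)


def plan_sis_swap(ctx: ControlContext, source_index: int, target_cluster: int,
                  n_top_sis: int = 6, present: float = 0.9, absent: float = 0.1,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Derive the (remove, add) SIS sets from the background clustering.

    Among the ``n_top_sis`` species with the largest heterogeneity scale,
    the removal set are those present in nearly every member of the source
    cluster and nearly no member of the target cluster; the addition set is
    the reverse.  Raises if either set is empty (the background then has no
    SIS-separated pair of clusters).
    """
    labels = ctx.labels
    source_cluster = int(labels[source_index])
    if source_cluster == target_cluster:
        raise ValueError("target must differ from the source cluster")
    sis = ctx.meta.sis_ranking()[:n_top_sis]
    frac = {}
    for c in (source_cluster, target_cluster):
        rows = np.where(labels == c)[0]
        frac[c] = {
            int(s): float(np.mean([s in ctx.ensemble.membership[i] for i in rows]))
            for s in sis
        }
    remove = [s for s in sis if frac[source_cluster][int(s)] >= present
              and frac[target_cluster][int(s)] <= absent]
    add = [s for s in sis if frac[target_cluster][int(s)] >= present
           and frac[source_cluster][int(s)] <= absent]
    members = ctx.members(source_index)
    remove = [s for s in remove if s in members]
    add = [s for s in add if s not in members]
    if not remove or not add:
        raise ValueError("clusters are not separated by disjoint SIS sets")
    return np.array(remove, dtype=int), np.array(add, dtype=int)


def project_trajectory(states: np.ndarray, ctx: ControlContext) -> np.ndarray:
    """Project pool-frame states onto the background's top-2 ordination axes.

    Only defined for a Euclidean background (classical scaling of Euclidean
    distances is principal component analysis, so an explicit projection
    matrix exists).  Background samples project exactly onto their stored
    ordination coordinates.
    """
    clustering = ctx.clustering
    if clustering.metric != "euclidean":
        raise ValueError("projection needs a Euclidean background; recluster "
                         "with metric='euclidean'")
    X = clustering.states
    mean = X.mean(axis=0)
    Xc = X - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    axes = Vt[:2].T
    ref = Xc @ axes
    for j in range(axes.shape[1]):  # align signs with the stored coordinates
        if ref[:, j] @ clustering.coordinates[:, j] < 0:
            axes[:, j] = -axes[:, j]
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if clustering.abundance == "relative":
        states = states / states.sum(axis=1, keepdims=True)
    return (states - mean) @ axes
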