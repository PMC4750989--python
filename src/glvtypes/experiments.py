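"""Config-driven computational experiments.

Each experiment regenerates everything from a master seed: metacommunity
draws, local-community sampling, initial conditions, clustering restarts.
Summaries are tidy pandas DataFrames (one row per topology x alpha x
replicate) so sweeps can be aggregated or serialized as TSV directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeding import substream
from .community_typing import (SteadyStateEnsemble, cluster_ensemble,
                               simulate_ensemble)
from .control import (ControlContext, ControlScenario, classify_endpoint,
                      dominant_swap, fmt_protocol, plan_sis_swap, sis_swap)
from .dynamics import (GLVSystem, MigrationConfig, StochasticConfig,
                       simulate_stochastic, simulate_with_migration)
from .metacommunity import (MetacommunityConfig, generate_metacommunity,
                            sample_local_communities)

__all__ = [
    "ALPHA_SWEEP",
    "default_scaling",
    "run_alpha_pipeline",
    "run_heterogeneity_sweep",
    "run_topology_comparison",
    "run_robustness",
    "find_control_background",
    "iter_control_backgrounds",
    "run_control_demo",
    "run_control_suite",
]

#: heterogeneity levels of the main sweep, from near-homogeneous to single-SIS
ALPHA_SWEEP = (7.0, 3.0, 2.0, 1.6, 1.01)

_DEFAULT_S = {"complete": 0.07, "erdos_renyi": 0.1, "powerlaw_out": 0.1}


def default_scaling(topology: str) -> float:
    """Interaction scaling s used for each topology (stability margin)."""
    return _DEFAULT_S[topology]


def _perturbed_ensemble(meta, lcs, seed, mode, noise_c, lambda_high,
                        horizon) -> SteadyStateEnsemble:
    """Terminal states under Itô noise or migration inflow.

    Persistent disturbances keep the terminal discrete derivative at the
    disturbance scale, so the deterministic residual filter does not apply;
    only non-finite (diverged) runs count as unstable here.
    """
    rows, membership, reasons = [], [], {}
    n_unstable = 0
    for lc in lcs:
        x0 = substream(seed, "x0", lc.nu).uniform(0.0, 1.0, lc.p)
        sub = int(substream(seed, "perturb", lc.nu).integers(0, 2**31 - 1))
        system = GLVSystem.from_local(lc)
        if mode == "stochastic":
            _, path = simulate_stochastic(
                system, x0, StochasticConfig(c=noise_c, seed=sub), horizon)
        elif mode == "migration":
            _, path = simulate_with_migration(
                system, x0, MigrationConfig(lambda_high=lambda_high, seed=sub), horizon)
        else:
            raise ValueError(f"unknown dynamics mode {mode!r}")
        terminal = path[-1]
        if np.all(np.isfinite(terminal)):
            rows.append(lc.embed(terminal))
            membership.append(lc.members)
        else:
            n_unstable += 1
            reasons[lc.nu] = "nonfinite"
    samples = np.array(rows) if rows else np.empty((0, meta.n))
    return SteadyStateEnsemble(samples=samples, membership=membership, meta=meta,
                               n_unstable=n_unstable, unstable_reasons=reasons)


def run_alpha_pipeline(alpha: float, topology: str = "complete", *,
                       n: int = 100, q: int = 500, p: int = 80,
                       sigma: float = 1.0, s: float | None = None,
                       heterogeneity: bool = True, seed: int = 0,
                       metric: str = "jsd", abundance: str = "relative",
                       criterion: str = "silhouette", krange=range(2, 11),
                       dynamics: str = "deterministic", noise_c: float = 0.0,
                       lambda_high: float = 0.0, horizon: float = 100.0,
                       edge_prob: float = 0.1, mean_out_degree: float = 10.0,
                       restarts: int = 10, do_cluster: bool = True,
                       return_objects: bool = False):
    """Generate, simulate and cluster one metacommunity at one alpha.

    Returns a summary dict (plus the generated objects when
    ``return_objects``): counts of stable/unstable communities, optimal k,
    the winning score, and the per-k silhouette/VRC curves.
    """
    s = default_scaling(topology) if s is None else s
    cfg = MetacommunityConfig(n=n, sigma=sigma, alpha=alpha, topology=topology,
                              edge_prob=edge_prob, mean_out_degree=mean_out_degree,
                              s=s, heterogeneity=heterogeneity, seed=seed)
    meta = generate_metacommunity(cfg)
    lcs = sample_local_communities(meta, q, p, seed=seed)
    if dynamics == "deterministic":
        ensemble = simulate_ensemble(meta, lcs, seed=seed, horizon=horizon)
    else:
        ensemble = _perturbed_ensemble(meta, lcs, seed, dynamics, noise_c,
                                       lambda_high, horizon)
    row = {
        "topology": topology, "alpha": alpha, "seed": seed, "q": q, "p": p,
        "s": s, "dynamics": dynamics,
        "n_stable": ensemble.q, "n_unstable": ensemble.n_unstable,
        "unstable_pct": 100.0 * ensemble.n_unstable / q,
    }
    if do_cluster and ensemble.q >= max(krange) + 1 and ensemble.q >= 3:
        clustering = cluster_ensemble(ensemble, metric=metric, abundance=abundance,
                                      criterion=criterion, krange=krange,
                                      seed=seed, restarts=restarts)
        row.update({
            "k_opt": clustering.k_opt,
            "best_score": clustering.best_score,
            "silhouette_opt": clustering.per_k[clustering.k_opt]["silhouette"],
            "no_clustering": clustering.no_clustering,
            "scores": {k: clustering.per_k[k][criterion] for k in clustering.per_k},
        })
    else:  # too few stable samples to cluster
        clustering = None
        row.update({"k_opt": None, "best_score": np.nan,
                    "silhouette_opt": np.nan, "no_clustering": None, "scores": {}})
    if return_objects:
        return row, meta, lcs, ensemble, clustering
    return row


def run_heterogeneity_sweep(alphas=ALPHA_SWEEP, topology: str = "complete",
                            replicates: int = 1, master_seed: int = 0,
                            **kwargs) -> pd.DataFrame:
    """Cluster-structure summary over heterogeneity levels.

    Each replicate redraws the whole universal triple from a replicate
    substream of ``master_seed``; per-replicate rows are all retained.
    """
    rows = []
    for rep in range(replicates):
        seed = int(substream(master_seed, "replicate", rep).integers(0, 2**31 - 1))
        for alpha in alphas:
            row = run_alpha_pipeline(alpha, topology, seed=seed, **kwargs)
            row["replicate"] = rep
            rows.append(row)
    return pd.DataFrame(rows)


def run_topology_comparison(topologies=("complete", "erdos_renyi",
                                        "powerlaw_out", "powerlaw_out_homog"),
                            alphas=ALPHA_SWEEP, replicates: int = 1,
                            master_seed: int = 0, **kwargs) -> pd.DataFrame:
    """Heterogeneity sweep across network structures.

    ``powerlaw_out_homog`` is the structural-heterogeneity-only variant:
    power-law out-degree network with H = identity, the null showing that
    degree heterogeneity alone does not create community types.
    """
    frames = []
    for topo in topologies:
        homog = topo == "powerlaw_out_homog"
        real_topo = "powerlaw_out" if homog else topo
        df = run_heterogeneity_sweep(alphas, real_topo, replicates, master_seed,
                                     heterogeneity=not homog, **kwargs)
        df["topology"] = topo
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_robustness(mode: str, alphas=ALPHA_SWEEP, topology: str = "complete",
                   replicates: int = 1, master_seed: int = 0,
                   noise_c: float = 0.1, lambda_high: float = 0.1,
                   **kwargs) -> pd.DataFrame:
    """Heterogeneity sweep under Itô noise or migration disturbance."""
    return run_heterogeneity_sweep(alphas, topology, replicates, master_seed,
                                   dynamics=mode, noise_c=noise_c,
                                   lambda_high=lambda_high, **kwargs)


def _candidate_plans(ctx, min_cluster):
    """All SIS-swap plans a partition offers, with premise-quality scores.

    The source community LC* is the source-cluster member nearest its medoid
    (a typical community of that type) whose species set allows the swap.
    Candidates are scored a priori by partition coarseness, the smaller of
    the two cluster sizes, and the exclusivity margin of the chosen SIS sets
    -- never by scenario outcomes.
    """
    labels = ctx.labels
    D = ctx.clustering.distance
    out = []
    sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
    for a in sorted(sizes):
        if sizes[a] < min_cluster:
            continue
        rows_a = np.where(labels == a)[0]
        order = rows_a[np.argsort(D[rows_a, ctx.medoids[a]], kind="stable")]
        for b in sorted(sizes):
            if a == b or sizes[b] < min_cluster:
                continue
            for idx in order:
                try:
                    remove, add = plan_sis_swap(ctx, int(idx), int(b))
                except ValueError:
                    continue
                rows_b = np.where(labels == b)[0]
                margin = min(
                    min(np.mean([s in ctx.ensemble.membership[i] for i in rows_a])
                        - np.mean([s in ctx.ensemble.membership[i] for i in rows_b])
                        for s in remove),
                    min(np.mean([s in ctx.ensemble.membership[i] for i in rows_b])
                        - np.mean([s in ctx.ensemble.membership[i] for i in rows_a])
                        for s in add),
                )
                out.append({"source": int(idx), "target": int(b),
                            "remove": remove, "add": add,
                            "min_size": min(sizes[a], sizes[b]),
                            "margin": float(margin)})
                break
    return out


def _cdi_outside_target(ctx, plan) -> bool:
    """Premise check for the FMT failure control: the post-antibiotic (CDI)
    state must not already classify into the target cluster, otherwise the
    removal alone decides the outcome and withholding the donor SISs tests
    nothing."""
    fmt = fmt_protocol(ctx, ControlScenario(
        kind="fmt", source_index=plan["source"], target_cluster=plan["target"],
        donor_index=int(ctx.medoids[plan["target"]]), remove_ids=plan["remove"]))
    cid, _ = classify_endpoint(fmt.checkpoints["cdi"], ctx.clustering,
                               labels=ctx.labels)
    plan["_fmt_outcome"] = fmt  # reused by the suite; computed either way
    return cid != plan["target"]


def iter_control_backgrounds(alpha: float = 1.6, *, n: int = 100, q: int = 200,
                             p: int = 80, master_seed: int = 0,
                             max_tries: int = 60, metric: str = "euclidean",
                             min_cluster: int = 8,
                             partitions=(2, 3, 4, 5, 6, 7, 8),
                             validate_cdi: bool = True, **kwargs):
    """Yield SIS-separated control backgrounds, one per qualifying draw.

    The control scenarios presuppose a background with two community types
    distinguished by disjoint SIS sets -- a typical but not guaranteed
    outcome at alpha = 1.6, and often resolved only at a finer partition
    than the silhouette optimum.  Metacommunity draws are scanned in
    substream order; within a draw, candidate plans from all partitions in
    ``partitions`` are ranked by (coarsest partition, largest smaller
    cluster, widest exclusivity margin) and, when ``validate_cdi``, must
    additionally leave the post-antibiotic state outside the target
    cluster.  Yields (context, plan) pairs where plan has keys
    source/target/remove/add.
    """
    for trial in range(max_tries):
        seed = int(substream(master_seed, "control_bg", trial).integers(0, 2**31 - 1))
        row, meta, lcs, ensemble, clustering = run_alpha_pipeline(
            alpha, "complete", n=n, q=q, p=p, seed=seed, metric=metric,
            return_objects=True, **kwargs)
        if clustering is None:
            continue
        candidates = []
        for k in partitions:
            if k not in clustering.per_k:
                continue
            ctx = ControlContext(meta=meta, ensemble=ensemble,
                                 clustering=clustering, k=k)
            for plan in _candidate_plans(ctx, min_cluster):
                candidates.append((k, ctx, plan))
        candidates.sort(key=lambda t: (t[0], -t[2]["min_size"], -t[2]["margin"]))
        for k, ctx, plan in candidates:
            if validate_cdi and not _cdi_outside_target(ctx, plan):
                continue
            yield ctx, plan
            break  # one background per metacommunity draw


def find_control_background(alpha: float = 1.6, **kwargs):
    """First qualifying control background; see iter_control_backgrounds.

    Returns (context, source_index, target_cluster, remove_ids, add_ids).
    """
    for ctx, plan in iter_control_backgrounds(alpha, **kwargs):
        return ctx, plan["source"], plan["target"], plan["remove"], plan["add"]
    raise RuntimeError(
        f"no SIS-separated background found at alpha={alpha}; "
        "try more draws (max_tries) or a different master_seed")


def run_control_demo(alpha: float = 1.6, *, master_seed: int = 0, q: int = 200,
                     p: int = 80, n: int = 100, n_redraws: int = 10,
                     dose: float = 0.01, **kwargs) -> dict:
    """Execute the three control scenarios plus the withheld-SIS FMT control.

    Returns a bundle with the background context, the SIS swap repeated over
    ``n_redraws`` initial-abundance draws, one dominant-species swap, and
    the FMT protocol with and without the donor's SISs.
    """
    ctx, source, target, remove, add = find_control_background(
        alpha, n=n, q=q, p=p, master_seed=master_seed, **kwargs)
    labels = ctx.labels
    target_rows = np.where(labels == target)[0]
    # donor: the target cluster's medoid community (overridable by editing
    # the scenario objects directly)
    donor = int(ctx.medoids[target])
    if labels[donor] != target:  # guard against degenerate partitions
        donor = int(target_rows[0])
    bundle = {"context": ctx, "source_index": source, "target_cluster": target,
              "remove_ids": remove, "add_ids": add, "donor_index": donor}

    swaps = []
    for redraw in range(n_redraws):
        sc = ControlScenario(kind="sis_swap", source_index=source,
                             target_cluster=target, remove_ids=remove,
                             add_ids=add, seed=int(
                                 substream(master_seed, "swap_redraw", redraw)
                                 .integers(0, 2**31 - 1)))
        swaps.append(sis_swap(ctx, sc))
    bundle["sis_swap"] = swaps

    bundle["dominant_swap"] = dominant_swap(ctx, ControlScenario(
        kind="dominant_swap", source_index=source, target_cluster=target,
        donor_index=donor))
    # antibiotic stage removes the source cluster's characteristic SISs;
    # the failure control withholds the donor's SISs -- its strongest
    # interactors together with the target-characteristic species
    h = np.diag(ctx.meta.H)
    donor_members = ctx.members(donor)
    donor_top = donor_members[np.argsort(-h[donor_members], kind="stable")[:2]]
    bundle["fmt"] = fmt_protocol(ctx, ControlScenario(
        kind="fmt", source_index=source, target_cluster=target,
        donor_index=donor, dose=dose, remove_ids=remove))
    bundle["fmt_withheld"] = fmt_protocol(ctx, ControlScenario(
        kind="fmt", source_index=source, target_cluster=target,
        donor_index=donor, dose=dose, remove_ids=remove,
        withhold_donor_sis=True, withhold_ids=np.union1d(add, donor_top)))
    return bundle


def run_control_suite(alpha: float = 1.6, *, master_seed: int = 0,
                      n_backgrounds: int = 5, n_redraws: int = 10,
                      q: int = 200, p: int = 80, n: int = 100,
                      dose: float = 0.01, **kwargs) -> pd.DataFrame:
    """All four control scenarios on several qualifying backgrounds.

    Aggregating over metacommunity draws is the fair reading of the control
    claims: any single background is one realization.  Returns one row per
    background with the SIS-swap success count over ``n_redraws`` initial
    conditions and the success flags of the dominant swap, the FMT, and the
    SIS-withheld FMT.
    """
    rows = []
    backgrounds = iter_control_backgrounds(
        alpha, n=n, q=q, p=p, master_seed=master_seed, **kwargs)
    for bg_index, (ctx, plan) in enumerate(backgrounds):
        if bg_index >= n_backgrounds:
            break
        source, target = plan["source"], plan["target"]
        remove, add = plan["remove"], plan["add"]
        donor = int(ctx.medoids[target])
        swaps = sum(
            sis_swap(ctx, ControlScenario(
                kind="sis_swap", source_index=source, target_cluster=target,
                remove_ids=remove, add_ids=add,
                seed=int(substream(master_seed, "swap_redraw", bg_index, r)
                         .integers(0, 2**31 - 1)))).success
            for r in range(n_redraws))
        dom = dominant_swap(ctx, ControlScenario(
            kind="dominant_swap", source_index=source, target_cluster=target,
            donor_index=donor))
        fmt = plan.get("_fmt_outcome") or fmt_protocol(ctx, ControlScenario(
            kind="fmt", source_index=source, target_cluster=target,
            donor_index=donor, dose=dose, remove_ids=remove))
        # the donor's SISs: its strongest interactors together with the
        # target cluster's characteristic species (in the reference
        # experiment these coincide)
        h = np.diag(ctx.meta.H)
        donor_members = ctx.members(donor)
        donor_top = donor_members[np.argsort(-h[donor_members],
                                             kind="stable")[:2]]
        withheld = fmt_protocol(ctx, ControlScenario(
            kind="fmt", source_index=source, target_cluster=target,
            donor_index=donor, dose=dose, remove_ids=remove,
            withhold_donor_sis=True,
            withhold_ids=np.union1d(add, donor_top)))
        rows.append({
            "background": bg_index, "partition_k": ctx.k,
            "source": source, "target": target,
            "remove_ids": list(map(int, remove)), "add_ids": list(map(int, add)),
            "sis_swap_successes": int(swaps), "n_redraws": n_redraws,
            "dominant_swap_success": bool(dom.success),
            "fmt_success": bool(fmt.success),
            "fmt_withheld_success": bool(withheld.success),
        })
    if not rows:
        raise RuntimeError("no qualifying control backgrounds found")
    return pd.DataFrame(rows)
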