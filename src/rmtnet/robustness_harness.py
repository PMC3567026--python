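"""Perturbation experiment: rebuild networks from degraded inputs.

The harness emulates the robustness protocol: a global network is built from
the full expression matrix; then, for every requested (sample_fraction,
probe_fraction) cell and replicate, a random subset of samples/probe sets is
kept (uniformly without replacement, seeded as ``base_seed + replicate``),
the entire similarity -> RMT threshold -> edge-list pipeline is re-run with
identical parameters, and the perturbed network is compared with the global
one: shared nodes and edges, edges lost (present only globally) and new
(present only perturbed), topology metrics, module counts, and — when an
annotation table is supplied — the average best-match kappa of module
enrichment profiles. Replicates whose threshold scan fails to confirm are
recorded as failed rather than silently reseeded, so failure rates stay an
honest part of the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GlobalNetworkError,
    InsufficientData,
    NoComparableModules,
    ThresholdNotFound,
    TooSmall,
)
from .expression_io import ExpressionMatrix, subset
from .functional_similarity import (
    AnnotationSet,
    EnrichmentProfile,
    average_module_kappa,
    enrichment_profile,
)
from .link_communities import LinkCommunitySet, count_modules, detect_link_communities
from .network_topology import (
    Network,
    extract_network,
    shared_edges,
    shared_nodes,
    topology_summary,
)
from .similarity import DEFAULT_MIN_OBS, build_similarity_matrix
from .rmt_threshold import find_threshold

MODULE_MIN_NODES = 3


@dataclass
class PerturbationSpec:
    """One cell of the perturbation grid."""

    sample_fraction: float = 1.0
    probe_fraction: float = 1.0
    replicates: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.sample_fraction, self.probe_fraction):
            if not 0.0 < f <= 1.0:
                raise InsufficientData(f"fractions must lie in (0, 1], got {f}")


@dataclass
class RobustnessReport:
    """Per-replicate rows plus per-cell aggregates of the experiment."""

    global_threshold: float
    global_network: Network = field(repr=False)
    replicates: pd.DataFrame = field(repr=False)
    aggregates: pd.DataFrame = field(repr=False)
    global_module_count: int = 0


def perturb_expression(
    em: ExpressionMatrix,
    spec: PerturbationSpec,
    replicate: int,
    min_obs: int = DEFAULT_MIN_OBS,
) -> ExpressionMatrix:
    """Randomly keep ``round(fraction * count)`` samples and probes.

    Probe and sample draws are independent within a replicate; replicate r
    uses seed ``base_seed + r``, so the same spec and replicate always yield
    the same submatrix. Original row/column order is preserved.
    """
    rng = np.random.default_rng(spec.base_seed + replicate)
    n_probes = max(1, round(spec.probe_fraction * em.n_probes))
    n_samples = max(1, round(spec.sample_fraction * em.n_samples))
    if n_probes < 2 or n_samples < min_obs:
        raise InsufficientData(
            f"perturbation leaves {n_probes} probes / {n_samples} samples "
            f"(need >= 2 probes and >= {min_obs} samples)"
        )
    probe_idx = np.sort(rng.choice(em.n_probes, size=n_probes, replace=False))
    sample_idx = np.sort(rng.choice(em.n_samples, size=n_samples, replace=False))
    return subset(
        em,
        [em.probe_ids[i] for i in probe_idx],
        [em.sample_ids[j] for j in sample_idx],
    )


def _build(em: ExpressionMatrix, min_obs: int, rmt_params: dict):
    sm = build_similarity_matrix(em, min_obs=min_obs)
    result = find_threshold(sm, **rmt_params)
    net = extract_network(sm, result.final_threshold)
    return sm, result, net


def _modules_and_profile(
    net: Network, ann: AnnotationSet | None
) -> tuple[int, EnrichmentProfile | None]:
    try:
        lcs: LinkCommunitySet = detect_link_communities(net)
    except TooSmall:
        return 0, None
    n_modules = count_modules(lcs, MODULE_MIN_NODES)
    if ann is None:
        return n_modules, None
    modules = {
        c: g for c, g in lcs.community_genes().items()
        if len(g) >= MODULE_MIN_NODES
    }
    profile = enrichment_profile(modules, ann.restricted_to(net.nodes))
    return n_modules, profile


def run_robustness(
    em: ExpressionMatrix,
    ann: AnnotationSet | None = None,
    cells: Iterable[tuple[float, float]] = ((0.25, 1.0), (0.5, 1.0), (0.75, 1.0)),
    replicates: int = 10,
    base_seed: int = 0,
    min_obs: int = DEFAULT_MIN_OBS,
    rmt_params: dict | None = None,
) -> RobustnessReport:
    """Run the full perturbation grid against the global network.

    ``cells`` lists (sample_fraction, probe_fraction) combinations;
    ``rmt_params`` is forwarded to the threshold scan for every network.
    """
    rmt_params = dict(rmt_params or {})
    try:
        _, g_result, g_net = _build(em, min_obs, rmt_params)
    except (ThresholdNotFound, InsufficientData) as exc:
        raise GlobalNetworkError(f"global network not buildable: {exc}") from exc
    g_modules, g_profile = _modules_and_profile(g_net, ann)

    rows: list[dict] = []
    for sf, pf in cells:
        spec = PerturbationSpec(sf, pf, replicates, base_seed)
        for r in range(1, replicates + 1):
            row: dict = dict(
                sample_fraction=sf, probe_fraction=pf, replicate=r, status="ok"
            )
            try:
                sub = perturb_expression(em, spec, r, min_obs=min_obs)
                _, p_result, p_net = _build(sub, min_obs, rmt_params)
            except (ThresholdNotFound, InsufficientData) as exc:
                row["status"] = f"failed: {type(exc).__name__}"
                rows.append(row)
                continue
            summ = topology_summary(p_net)
            sn = shared_nodes(p_net, g_net)
            se = shared_edges(p_net, g_net)
            n_modules, p_profile = _modules_and_profile(p_net, ann)
            kappa = np.nan
            if p_profile is not None and g_profile is not None:
                try:
                    kappa = average_module_kappa(p_profile, g_profile).average_kappa
                except NoComparableModules:
                    pass
            row.update(
                rmt_threshold=p_result.final_threshold,
                n_nodes=summ.n_nodes,
                n_edges=summ.n_edges,
                avg_degree=summ.avg_degree,
                clustering=summ.clustering_coefficient,
                gamma=summ.gamma if summ.gamma is not None else np.nan,
                shared_nodes=sn,
                shared_edges=se,
                edges_lost=g_net.n_edges - se,
                edges_new=p_net.n_edges - se,
                shared_edge_fraction=se / g_net.n_edges if g_net.n_edges else np.nan,
                module_count=n_modules,
                avg_kappa=kappa,
            )
            rows.append(row)

    rep_df = pd.DataFrame(rows)
    ok = rep_df[rep_df["status"] == "ok"]
    if len(ok):
        num_cols = [
            c
            for c in ok.columns
            if c not in ("sample_fraction", "probe_fraction", "replicate", "status")
        ]
        agg = (
            ok.groupby(["sample_fraction", "probe_fraction"])[num_cols]
            .agg(["mean", "std"])
            .reset_index()
        )
    else:
        agg = pd.DataFrame()
    return RobustnessReport(
        global_threshold=g_result.final_threshold,
        global_network=g_net,
        replicates=rep_df,
        aggregates=agg,
        global_module_count=g_modules,
    )
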