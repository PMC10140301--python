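"""Progressive edge-threshold refinement of similarity networks.

The network is swept with an increasing percent-identity edge threshold.
At each step connected components are extracted and classified by source
composition; the sweep stops when metagenome and reference sequences have
separated (at least one non-singleton metagenome-only cluster exists and
persists one further step) or when the threshold exceeds a ceiling
(default 50% identity).  A family whose sweep hits the ceiling with no
metagenome-only cluster carries no novelty signal and is flagged
"not unique".

The cohesiveness of a network is summarized by its *fragmentation
percentage*: 100 x (number of connected components, singletons included) /
(number of nodes).  Both component count and fragmentation are
non-decreasing in the threshold (monotone filtration).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from ssnmine.ssn_builder import Network

logger = logging.getLogger(__name__)

CLUSTER_CLASSES = ("metagenome_only", "reference_only", "mixed", "singleton")


@dataclass(slots=True)
class Partition:
    """Connected components of the network at one edge threshold."""

    threshold: float
    components: list[frozenset[str]]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_of(self) -> dict[str, int]:
        return {
            node: idx for idx, comp in enumerate(self.components) for node in comp
        }


@dataclass(slots=True)
class ClusterComposition:
    """Source composition of one connected component."""

    members: frozenset[str]
    n_metagenome: int
    n_reference: int
    klass: str

    @property
    def size(self) -> int:
        return self.n_metagenome + self.n_reference

    @property
    def purity(self) -> float:
        return self.n_metagenome / self.size


@dataclass(slots=True)
class RefinementResult:
    """Outcome of a threshold sweep over one family's network."""

    final_threshold: float
    stop_reason: str  # 'separated' or 'ceiling'
    fragmentation: float  # percent, at the final threshold
    clusters: list[ClusterComposition]
    trace: list[tuple[float, int, int]]  # (threshold, n_components, n_mg_only)
    unique: bool  # any metagenome-only cluster at the final threshold

    def metagenome_only_clusters(self) -> list[ClusterComposition]:
        return [c for c in self.clusters if c.klass == "metagenome_only"]


@dataclass(slots=True)
class FamilySummary:
    """Per-family report row of the network statistics."""

    family_name: str
    length_threshold: int
    total_nodes: int
    n_metagenome: int
    n_reference: int
    pct_reference: float  # one decimal
    resolution_identity: float
    n_connected_components: int
    fragmentation_percent_int: int
    stop_reason: str
    unique: bool

    def __post_init__(self) -> None:
        assert self.total_nodes == self.n_metagenome + self.n_reference


def components_at(network: Network, threshold: float) -> Partition:
    """Connected components keeping edges with identity >= threshold.

    Singletons are included.  Components are ordered by their smallest
    member id, so the partition is deterministic for a given network.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    graph = network.subgraph_at(threshold)
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: min(c))
    return Partition(threshold=threshold, components=comps)


def fragmentation_percent(n_components: int, n_nodes: int) -> float:
    """Percentage fragmentation: 100 x components / nodes.

    Components include clusters and single nodes.  The value is kept at
    full precision here and integer-rounded only in reports.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    if not 1 <= n_components <= n_nodes:
        raise ValueError("need 1 <= n_components <= n_nodes")
    return 100.0 * n_components / n_nodes


def _round_half_away(x: float, ndigits: int = 0) -> float:
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def reference_percentage(n_reference: int, n_total: int) -> float:
    """Reference share of the network as a one-decimal percentage
    (rounded half away from zero)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_reference <= n_total:
        raise ValueError("need 0 <= n_reference <= n_total")
    return _round_half_away(100.0 * n_reference / n_total, 1)


def classify_cluster(
    component: frozenset[str] | set[str],
    node_sources: Mapping[str, str],
    purity_min: float = 0.95,
    size_min: int = 5,
) -> ClusterComposition:
    """Classify a component by its metagenome/reference composition.

    Components below ``size_min`` members are singletons (too small to
    call).  A cluster is metagenome-only when its metagenome purity
    reaches ``purity_min`` ("exclusively/primarily metagenome"),
    reference-only in the mirrored case, otherwise mixed.
    """
    if not 0.5 < purity_min <= 1.0:
        raise ValueError("purity_min must be in (0.5, 1]")
    if size_min < 2:
        raise ValueError("size_min must be at least 2")
    n_mg = sum(1 for node in component if node_sources[node] == "metagenome")
    n_ref = len(component) - n_mg
    size = n_mg + n_ref
    if size < size_min:
        klass = "singleton"
    else:
        purity = n_mg / size
        if purity >= purity_min:
            klass = "metagenome_only"
        elif purity <= 1.0 - purity_min:
            klass = "reference_only"
        else:
            klass = "mixed"
    return ClusterComposition(
        members=frozenset(component), n_metagenome=n_mg, n_reference=n_ref, klass=klass
    )


def _classify_partition(
    partition: Partition,
    node_sources: Mapping[str, str],
    purity_min: float,
    size_min: int,
) -> list[ClusterComposition]:
    return [
        classify_cluster(comp, node_sources, purity_min, size_min)
        for comp in partition.components
    ]


def refine(
    network: Network,
    t_start: float = 10.0,
    step: float = 1.0,
    ceiling: float = 50.0,
    purity_min: float = 0.95,
    size_min: int = 5,
) -> RefinementResult:
    """Sweep the edge threshold upward until the network separates.

    At each threshold ``t_start, t_start + step, ...`` the components are
    classified.  The sweep stops with reason ``"separated"`` at the first
    threshold where at least one metagenome-only cluster exists *and* each
    such cluster still contains a metagenome-only cluster one step higher
    (a hysteresis guard against transient splinters).  Otherwise it stops
    at the ceiling (default 50% identity) with reason ``"ceiling"``; if no
    metagenome-only cluster exists there either, the family is flagged not
    unique.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if t_start >= ceiling:
        raise ValueError("t_start must lie below the ceiling")
    if len(network.nodes) < size_min:
        raise ValueError("network smaller than the minimum cluster size")
    node_sources = network.nodes["source"].to_dict()

    thresholds = []
    t = t_start
    while t <= ceiling + 1e-9:
        thresholds.append(round(t, 9))
        t += step
    # one lookahead step past the ceiling for the hysteresis check
    thresholds.append(round(thresholds[-1] + step, 9))

    partitions: dict[float, Partition] = {}
    compositions: dict[float, list[ClusterComposition]] = {}

    def at(threshold: float) -> list[ClusterComposition]:
        if threshold not in compositions:
            part = components_at(network, min(threshold, 100.0))
            partitions[threshold] = part
            compositions[threshold] = _classify_partition(
                part, node_sources, purity_min, size_min
            )
        return compositions[threshold]

    trace: list[tuple[float, int, int]] = []
    final_t: float | None = None
    stop_reason = "ceiling"
    for i, t in enumerate(thresholds[:-1]):
        comps = at(t)
        mg_only = [c for c in comps if c.klass == "metagenome_only"]
        trace.append((t, len(comps), len(mg_only)))
        if mg_only:
            nxt = at(thresholds[i + 1])
            stable = all(
                any(
                    c.klass == "metagenome_only" and c.members <= cluster.members
                    for c in nxt
                )
                for cluster in mg_only
            )
            if stable:
                final_t = t
                stop_reason = "separated"
                break
    if final_t is None:
        final_t = thresholds[-2]  # the ceiling itself
        stop_reason = "ceiling"
    clusters = at(final_t)
    unique = any(c.klass == "metagenome_only" for c in clusters)
    if stop_reason == "ceiling" and not unique:
        logger.info(
            "no metagenome-only cluster resolved at the %.0f%% ceiling; "
            "family flagged not unique",
            ceiling,
        )
    return RefinementResult(
        final_threshold=final_t,
        stop_reason=stop_reason,
        fragmentation=fragmentation_percent(len(clusters), len(network.nodes)),
        clusters=clusters,
        trace=trace,
        unique=unique,
    )


def summarize_family(
    family_name: str,
    length_threshold: int,
    network: Network,
    result: RefinementResult,
) -> FamilySummary:
    """Fold a refinement outcome into the per-family report row."""
    sources = network.nodes["source"]
    n_ref = int((sources == "reference").sum())
    n_mg = int((sources == "metagenome").sum())
    total = len(network.nodes)
    return FamilySummary(
        family_name=family_name,
        length_threshold=length_threshold,
        total_nodes=total,
        n_metagenome=n_mg,
        n_reference=n_ref,
        pct_reference=reference_percentage(n_ref, total),
        resolution_identity=result.final_threshold,
        n_connected_components=len(result.clusters),
        fragmentation_percent_int=int(_round_half_away(result.fragmentation)),
        stop_reason=result.stop_reason,
        unique=result.unique,
    )


def summaries_to_frame(summaries: Sequence[FamilySummary]) -> pd.DataFrame:
    """Tabulate family summaries in the standard report layout."""
    rows = [
        {
            "family": s.family_name,
            "length_threshold_aa": s.length_threshold,
            "total_nodes": s.total_nodes,
            "n_metagenome": s.n_metagenome,
            "n_reference": s.n_reference,
            "pct_reference": s.pct_reference,
            "resolution_identity": s.resolution_identity,
            "n_connected_components": s.n_connected_components,
            "fragmentation_pct": s.fragmentation_percent_int,
            "stop_reason": s.stop_reason,
            "unique": s.unique,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def write_trace_tsv(result: RefinementResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# threshold\tn_components\tn_metagenome_only\n")
        for t, n_comp, n_mg in result.trace:
            fh.write(f"{t:g}\t{n_comp}\t{n_mg}\n")
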