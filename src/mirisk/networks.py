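"""Group-specific miRNA-miRNA correlation networks under subsampling.

For each group, fixed-size subsets of samples are drawn many times and
all pairwise Pearson correlations among a node set (typically the most
abundant miRNAs) computed per draw.  A pair becomes an edge when its
correlation exceeds an analytic critical value (the one-sided upper
quantile of the null correlation for that subset size) in more than a
stated number of draws.  The exceedance-frequency rule substitutes for
multiple-testing control: under an iid null with tail probability 0.001
and 1000 draws, no pair comes near the majority threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def critical_correlation(p_tail: float, n: int) -> float:
    """One-sided upper ``p_tail`` quantile of the null Pearson correlation.

    For two independent length-``n`` normal vectors, inverts the
    t-transform with ``n - 2`` degrees of freedom; mutually inverse with
    :func:`mirisk.preprocess.null_correlation_tail`.
    """
    if not 0 < p_tail < 0.5:
        raise ValueError(f"p_tail must be in (0, 0.5), got {p_tail}")
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    tq = stats.t.isf(p_tail, n - 2)
    return float(tq / math.sqrt(n - 2 + tq * tq))


def top_abundant_nodes(counts: pd.DataFrame, k: int = 40) -> list[str]:
    """The ``k`` miRNAs with the largest total read counts.

    Ties break deterministically by miRNA id (ascending).
    """
    if k > len(counts.index):
        raise ValueError(f"k={k} exceeds the number of miRNAs ({len(counts.index)})")
    totals = counts.sum(axis=1)
    order = sorted(counts.index, key=lambda m: (-totals[m], m))
    return order[:k]


def subsample_exceedance_counts(
    z: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    nodes: list[str],
    subset_size: int = 25,
    n_trials: int = 1000,
    r_threshold: float | None = None,
    p_tail: float = 0.001,
    seed: int | None = None,
) -> pd.DataFrame:
    """Count, per node pair, trials whose subset correlation exceeds a threshold.

    Per trial a uniform without-replacement subset of ``subset_size``
    samples is drawn from the group and the Pearson correlation of every
    node pair computed; the count records trials with ``r >
    r_threshold`` (strict).  When ``r_threshold`` is omitted it defaults
    to ``critical_correlation(p_tail, subset_size)``.  Undefined
    correlations (constant node within a subset) never count as
    exceedances.

    Returns a DataFrame with columns ``mirna_i``, ``mirna_j`` (canonical
    ``i < j`` in node order) and ``count``.
    """
    missing = [n_ for n_ in nodes if n_ not in z.index]
    if missing:
        raise ValueError(f"nodes absent from the expression matrix: {missing}")
    samples = metadata.loc[metadata["group"] == group, "sample_id"].tolist()
    samples = [s for s in samples if s in z.columns]
    if len(samples) < subset_size:
        raise ValueError(
            f"group {group!r} has {len(samples)} samples; need >= {subset_size}"
        )
    if r_threshold is None:
        r_threshold = critical_correlation(p_tail, subset_size)

    X = z.loc[nodes, samples].to_numpy(dtype=float)
    m = len(nodes)
    iu = np.triu_indices(m, k=1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(iu[0]), dtype=int)
    for _ in range(n_trials):
        idx = rng.choice(len(samples), size=subset_size, replace=False)
        sub = X[:, idx]
        sd = sub.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(sub)
        r = corr[iu]
        ok = np.isfinite(r) & (sd[iu[0]] > 0) & (sd[iu[1]] > 0)
        exceed += (ok & (r > r_threshold)).astype(int)
    return pd.DataFrame(
        {
            "mirna_i": [nodes[i] for i in iu[0]],
            "mirna_j": [nodes[j] for j in iu[1]],
            "count": exceed,
        }
    )


@dataclass
class CorrelationNetwork:
    """An exceedance network: nodes, full pair-count table, graph edges."""

    group: str
    nodes: list[str]
    pair_counts: pd.DataFrame  # mirna_i, mirna_j, count (all pairs)
    n_trials: int
    edge_min: int
    params: dict = field(default_factory=dict)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        """Pairs whose exceedance count strictly exceeds ``edge_min``."""
        sel = self.pair_counts[self.pair_counts["count"] > self.edge_min]
        return [
            (r.mirna_i, r.mirna_j, int(r.count))
            for r in sel.itertuples(index=False)
        ]

    def graph(self):
        """The thresholded network as a ``networkx.Graph`` (isolated nodes kept)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, c in self.edges:
            g.add_edge(a, b, weight=c)
        return g

    def connected_nodes(self) -> set[str]:
        return {a for a, _, _ in self.edges} | {b for _, b, _ in self.edges}


def build_network(
    pair_counts: pd.DataFrame,
    edge_min: int = 500,
    group: str = "",
    n_trials: int = 1000,
    nodes: list[str] | None = None,
    params: dict | None = None,
) -> CorrelationNetwork:
    """Threshold a pair-count table into a network (count strictly > edge_min).

    The node set is unchanged by thresholding, so miRNAs absent from a
    group's edge set remain representable as isolated nodes.
    """
    required = {"mirna_i", "mirna_j", "count"}
    if not required <= set(pair_counts.columns):
        raise ValueError(f"pair_counts must have columns {sorted(required)}")
    if nodes is None:
        nodes = sorted(set(pair_counts["mirna_i"]) | set(pair_counts["mirna_j"]))
    return CorrelationNetwork(
        group=group,
        nodes=list(nodes),
        pair_counts=pair_counts.reset_index(drop=True),
        n_trials=n_trials,
        edge_min=edge_min,
        params=params or {},
    )


def compare_networks(nets: list[CorrelationNetwork]) -> dict:
    """Edge counts, densities, shared edges and per-node presence.

    All networks must share one node universe.  A node is "present" in a
    network when it carries at least one edge; the presence table flags
    hub nodes that vanish from weakly-correlated groups.
    """
    if not nets:
        raise ValueError("need at least one network")
    universe = set(nets[0].nodes)
    for net in nets[1:]:
        if set(net.nodes) != universe:
            raise ValueError("networks have inconsistent node universes")
    edge_sets = {
        net.group: {(a, b) for a, b, _ in net.edges} for net in nets
    }
    n_nodes = len(universe)
    possible = n_nodes * (n_nodes - 1) // 2
    report: dict = {
        "groups": [net.group for net in nets],
        "n_nodes": n_nodes,
        "edge_counts": {g: len(e) for g, e in edge_sets.items()},
        "densities": {
            g: (len(e) / possible if possible else 0.0) for g, e in edge_sets.items()
        },
        "shared_edges": {},
        "node_presence": {},
    }
    groups = list(edge_sets)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            report["shared_edges"][f"{a}&{b}"] = sorted(edge_sets[a] & edge_sets[b])
    connected = {net.group: net.connected_nodes() for net in nets}
    for node in sorted(universe):
        report["node_presence"][node] = {
            g: (node in connected[g]) for g in groups
        }
    return report


def export_pajek(net: CorrelationNetwork, path) -> None:
    """Write a Pajek .net file: 1-based vertices with quoted labels, then edges.

    Edge weights carry the exceedance counts.  Round-trips through
    :func:`read_pajek`.
    """
    if not net.nodes:
        raise ValueError("cannot export a network with an empty node set")
    index = {n: i + 1 for i, n in enumerate(net.nodes)}
    lines = [f"*Vertices {len(net.nodes)}"]
    for n, i in index.items():
        lines.append(f'{i} "{n}"')
    lines.append("*Edges")
    for a, b, c in net.edges:
        lines.append(f"{index[a]} {index[b]} {c}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pajek(path) -> CorrelationNetwork:
    """Minimal Pajek reader for the dialect written by :func:`export_pajek`."""
    nodes: dict[int, str] = {}
    rows = []
    section = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "v"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                section = "e"
                continue
            if section == "v":
                idx, rest = line.split(None, 1)
                label = rest.strip()
                if label.startswith('"') and label.endswith('"'):
                    label = label[1:-1]
                nodes[int(idx)] = label
            elif section == "e":
                parts = line.split()
                i, j = int(parts[0]), int(parts[1])
                w = int(float(parts[2])) if len(parts) > 2 else 1
                rows.append((nodes[i], nodes[j], w))
    pair_counts = pd.DataFrame(rows, columns=["mirna_i", "mirna_j", "count"])
    ordered = [nodes[i] for i in sorted(nodes)]
    # Edge counts written to file are already above threshold; edge_min=-1
    # keeps them all when re-thresholding the reconstructed table.
    return CorrelationNetwork(
        group="",
        nodes=ordered,
        pair_counts=pair_counts,
        n_trials=0,
        edge_min=-1,
    )
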