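"""Comparison of condition-specific networks.

Set-level logic over two inferred networks (e.g. normal vs disease):
edge differentials with per-edge weight pairs, regulator-switch detection
(groups of targets whose regulator changes between conditions), TF hub
degrees, and edge-overlap validation between independently inferred
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import Edge, GeneNetwork, RegulatorSwitch


@dataclass
class ConditionPairResult:
    """Edge partition and annotations from a two-condition comparison."""

    specific_a: set[tuple[str, str]]
    specific_b: set[tuple[str, str]]
    shared: set[tuple[str, str]]
    weight_pairs: dict[tuple[str, str], tuple[float, float]]
    switches: list[RegulatorSwitch] = field(default_factory=list)
    multi_regulator_changes: list[tuple[str, frozenset, frozenset]] = \
        field(default_factory=list)
    hub_table: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.specific_a & self.specific_b) or \
                (self.specific_a & self.shared) or \
                (self.specific_b & self.shared):
            raise ValueError("edge partition blocks must be disjoint")


def dominant_regulator_network(scores, tfs: list[str]) -> GeneNetwork:
    """Assign every non-TF gene its best-scoring TF as sole regulator.

    Takes any score matrix (symmetric or directed) and returns the directed
    network in which each non-TF target receives one edge from the TF with
    the highest score toward it. This is the single-regulator reduction
    used for condition comparison and regulator-switch detection.
    """
    index = {g: i for i, g in enumerate(scores.gene_ids)}
    missing = set(tfs) - set(scores.gene_ids)
    if missing:
        raise ValueError(f"TFs missing from scores: {sorted(missing)}")
    tf_set = set(tfs)
    net = GeneNetwork(nodes=list(scores.gene_ids),
                      tf_flags={g: g in tf_set for g in scores.gene_ids})
    tf_rows = np.array([index[tf] for tf in tfs])
    for g in scores.gene_ids:
        if g in tf_set:
            continue
        j = index[g]
        col = scores.values[tf_rows, j]
        best = tfs[int(np.argmax(col))]
        net.add_edge(Edge(best, g, weight=float(col.max())))
    return net


def _positive_edges(net: GeneNetwork) -> dict[tuple[str, str], float]:
    return {k: e.weight for k, e in net.edges.items() if e.weight > 0}


def _check_universe(net_a: GeneNetwork, net_b: GeneNetwork) -> None:
    if set(net_a.nodes) != set(net_b.nodes):
        raise ValueError("networks must share the same gene universe")


def differential_edges(net_a: GeneNetwork,
                       net_b: GeneNetwork) -> ConditionPairResult:
    """Partition positive-weight edges into A-specific, B-specific, shared.

    ``weight_pairs`` maps every edge in the union to its (weight in A,
    weight in B) pair, with 0 where the edge is absent, for
    weight-versus-weight scatter comparisons.
    """
    _check_universe(net_a, net_b)
    ea = _positive_edges(net_a)
    eb = _positive_edges(net_b)
    shared = set(ea) & set(eb)
    weight_pairs = {k: (ea.get(k, 0.0), eb.get(k, 0.0))
                    for k in set(ea) | set(eb)}
    return ConditionPairResult(
        specific_a=set(ea) - shared,
        specific_b=set(eb) - shared,
        shared=shared,
        weight_pairs=weight_pairs,
        hub_table=hub_degrees(net_a),
    )


def regulator_switches(net_a: GeneNetwork, net_b: GeneNetwork,
                       min_group: int = 1
                       ) -> tuple[list[RegulatorSwitch],
                                  list[tuple[str, frozenset, frozenset]]]:
    """Detect target groups whose sole regulator changes between conditions.

    Targets regulated by exactly one TF in each condition, with different
    TFs, are grouped by the ordered (TF in A, TF in B) pair; groups with at
    least ``min_group`` targets are returned, largest first. Targets whose
    regulator *set* changes but is not single in both conditions are
    reported separately as (target, regulators in A, regulators in B).
    """
    _check_universe(net_a, net_b)
    ea = _positive_edges(net_a)
    eb = _positive_edges(net_b)
    regs_a: dict[str, set[str]] = {}
    regs_b: dict[str, set[str]] = {}
    for (r, t) in ea:
        regs_a.setdefault(t, set()).add(r)
    for (r, t) in eb:
        regs_b.setdefault(t, set()).add(r)

    groups: dict[tuple[str, str], set[str]] = {}
    multi: list[tuple[str, frozenset, frozenset]] = []
    for t in set(regs_a) | set(regs_b):
        ra = regs_a.get(t, set())
        rb = regs_b.get(t, set())
        if ra == rb:
            continue
        if len(ra) == 1 and len(rb) == 1:
            groups.setdefault((next(iter(ra)), next(iter(rb))), set()).add(t)
        else:
            multi.append((t, frozenset(ra), frozenset(rb)))
    switches = [RegulatorSwitch(old_tf=a, new_tf=b, targets=frozenset(ts))
                for (a, b), ts in groups.items() if len(ts) >= min_group]
    switches.sort(key=lambda s: (-s.size, s.old_tf, s.new_tf))
    multi.sort()
    return switches, multi


def hub_degrees(net: GeneNetwork) -> list[tuple[str, int]]:
    """Out-degree per TF over positive-weight edges, sorted descending."""
    counts = {tf: 0 for tf in net.tfs}
    for (r, _t), w in _positive_edges(net).items():
        counts[r] += 1
    table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return table


def edge_overlap(net_a: GeneNetwork, net_b: GeneNetwork,
                 top_k: int | None = None,
                 directed: bool = True,
                 jaccard: bool = False) -> float:
    """Percentage of the reference network's edges found in the second.

    ``net_a`` is the reference inference: overlap = |E_A inter E_B| / |E_A|
    as a percentage. With ``top_k`` set, E_A is first restricted to its k
    highest-weight edges. ``directed=False`` matches edges regardless of
    orientation; ``jaccard=True`` divides by the union instead of |E_A|.
    """
    _check_universe(net_a, net_b)
    ea = _positive_edges(net_a)
    eb = set(_positive_edges(net_b))
    if top_k is not None:
        ranked = sorted(ea.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        ea = dict(ranked)
    if not ea:
        raise ValueError("reference network has no positive-weight edges")
    if directed:
        hits = set(ea) & eb
        union = set(ea) | eb
    else:
        norm_a = {frozenset(k) for k in ea}
        norm_b = {frozenset(k) for k in eb}
        hits = norm_a & norm_b
        union = norm_a | norm_b
        ea = norm_a
    if jaccard:
        return 100.0 * len(hits) / len(union)
    return 100.0 * len(hits) / len(ea)
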