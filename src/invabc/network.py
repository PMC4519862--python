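"""Statistical parsimony haplotype networks with ancestral-root weights.

The connection limit is the largest number of mutational steps between two
haplotypes for which parsimony (no superimposed or parallel change) still
holds with a set confidence, conventionally 95%.  The probability model:
per-site mutation counts on the path joining two haplotypes are Poisson,
with Jukes–Cantor kinetics governing whether a hit is visible, so for two
sequences differing at j of m comparable sites the per-site expected number
of hits is estimated by the usual multiple-hit inversion
``lam = -(3/4) ln(1 - 4(j/m)/3)`` and

    P(parsimony) = P(exactly 1 hit | site differs)^j
                   * P(0 hits | site identical)^(m-j).

Pairs within the limit are connected level by level (1 step, 2 steps, ...),
adding every minimal connection between two previously separate
subnetworks; equal-length alternatives are all retained, so closed loops —
evidence of homoplasy — survive rather than being resolved arbitrarily.
Edges longer than one step pass through inferred (unsampled) intermediate
haplotypes.

Ancestral ("outgroup") weights per subnetwork follow the
frequency-plus-connectivity logic of neutral-coalescent root probability:
older haplotypes are both more frequent and more central.  The weight of an
observed haplotype is proportional to its count plus half the counts of its
directly connected observed neighbours, normalized within the component;
inferred intermediates carry zero frequency and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .seq_io import HaplotypeTable


@dataclass
class ParsimonyNetwork:
    graph: nx.Graph                       # expanded graph incl. inferred nodes
    hap_graph: nx.Graph                   # observed haplotypes only
    components: list[list[str]]           # observed haplotype ids per component
    outgroup_weights: dict[str, float]
    has_loop: dict[int, bool]             # component index -> loop present
    limit: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    def ancestral_haplotype(self, component: int) -> str:
        comp = self.components[component]
        return max(comp, key=lambda h: (self.outgroup_weights[h], -comp.index(h)))


def parsimony_probability(L: int, j: int) -> float:
    """Probability that j observed differences over L sites are parsimonious."""
    if j <= 0:
        return 1.0
    p = j / L
    if p >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    # visible-difference probability after Poisson(lam) JC hits
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_same = 1.0 - p_diff
    p_one_given_diff = lam * math.exp(-lam) / p_diff
    p_zero_given_same = math.exp(-lam) / p_same
    return p_one_given_diff**j * p_zero_given_same ** (L - j)


def connection_limit(L: int, alpha: float = 0.95) -> int:
    """Largest step count j with parsimony probability >= alpha.

    Always at least 1: a single observed difference is parsimonious with
    probability well above 95% at realistic sequence lengths.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    j = 1
    while j + 1 < 0.75 * L and parsimony_probability(L, j + 1) >= alpha:
        j += 1
    return j


def _step_distances(haps: HaplotypeTable) -> np.ndarray:
    """Pairwise mutational steps, ignoring sites gapped/N in either sequence."""
    mats = [
        np.frombuffer(seq.encode(), dtype=np.uint8) for seq in haps.haplotypes
    ]
    h = len(mats)
    bad = [
        (m == ord("-")) | (m == ord("N")) for m in mats
    ]
    d = np.zeros((h, h), dtype=int)
    for i in range(h):
        for j in range(i + 1, h):
            ok = ~(bad[i] | bad[j])
            d[i, j] = d[j, i] = int(np.sum((mats[i] != mats[j]) & ok))
    return d


def build_networks(haps: HaplotypeTable, limit: int) -> ParsimonyNetwork:
    """Connect haplotypes into parsimony networks at the given step limit.

    Level-by-level agglomeration: at step distance d = 1, 2, ..., limit,
    every pair whose subnetworks were still separate at the start of level d
    is connected; all ties are kept (loops allowed).  Pairs farther apart
    than the limit stay in different components.
    """
    ids = haps.ids
    counts = {h: int(c) for h, c in zip(ids, haps.total_counts())}
    d = _step_distances(haps)
    hap_graph = nx.Graph()
    for h in ids:
        hap_graph.add_node(h, count=counts[h])

    comp_of = {h: i for i, h in enumerate(ids)}

    def find(h: str) -> int:
        return comp_of[h]

    h_n = len(ids)
    for level in range(1, limit + 1):
        at_level = [
            (i, j) for i in range(h_n) for j in range(i + 1, h_n)
            if d[i, j] == level
        ]
        snapshot = dict(comp_of)
        added = []
        for i, j in at_level:
            if snapshot[ids[i]] != snapshot[ids[j]]:
                hap_graph.add_edge(ids[i], ids[j], steps=level)
                added.append((ids[i], ids[j]))
        for a, b in added:       # merge after the level so ties all connect
            ca, cb = comp_of[a], comp_of[b]
            if ca != cb:
                for h, c in comp_of.items():
                    if c == cb:
                        comp_of[h] = ca

    # expand multi-step edges through inferred intermediate nodes
    graph = nx.Graph()
    for h in ids:
        graph.add_node(h, haplotype_id=h, count=counts[h], is_inferred=False)
    mv = 0
    for a, b, data in hap_graph.edges(data=True):
        steps = data["steps"]
        chain = [a]
        for _ in range(steps - 1):
            mv += 1
            node = f"mv_{mv}"
            graph.add_node(node, haplotype_id=node, count=0, is_inferred=True)
            chain.append(node)
        chain.append(b)
        for u, v in zip(chain, chain[1:]):
            graph.add_edge(u, v, step=1)

    components = [
        sorted(c, key=ids.index) for c in nx.connected_components(hap_graph)
    ]
    components.sort(key=lambda c: ids.index(c[0]))
    has_loop = {
        idx: len(nx.cycle_basis(hap_graph.subgraph(comp))) > 0
        for idx, comp in enumerate(components)
    }
    net = ParsimonyNetwork(
        graph=graph, hap_graph=hap_graph, components=components,
        outgroup_weights={}, has_loop=has_loop, limit=limit,
    )
    net.outgroup_weights = outgroup_weights(net, haps)
    for h, w in net.outgroup_weights.items():
        graph.nodes[h]["outgroup_weight"] = w
        hap_graph.nodes[h]["outgroup_weight"] = w
    return net


def outgroup_weights(
    net: ParsimonyNetwork, haps: HaplotypeTable, neighbour_bonus: float = 0.5
) -> dict[str, float]:
    """Per-component root weights from frequency and connectivity.

    ``raw(h) = count(h) + neighbour_bonus * sum(count of observed
    neighbours)``, normalized to sum to 1 within each component.  A
    singleton component trivially gets weight 1.  The weight is strictly
    increasing in a haplotype's own count with topology held fixed, and the
    centre of a star receives the maximum weight.
    """
    counts = {h: int(c) for h, c in zip(haps.ids, haps.total_counts())}
    weights: dict[str, float] = {}
    for comp in net.components:
        raw = {}
        for h in comp:
            bonus = sum(counts[nb] for nb in net.hap_graph.neighbors(h))
            raw[h] = counts[h] + neighbour_bonus * bonus
        total = sum(raw.values())
        for h in comp:
            weights[h] = raw[h] / total if total > 0 else 1.0 / len(comp)
    return weights


def network_summary(net: ParsimonyNetwork) -> pd.DataFrame:
    rows = []
    for idx, comp in enumerate(net.components):
        anc = net.ancestral_haplotype(idx)
        rows.append({
            "component": idx + 1,
            "size": len(comp),
            "ancestral_haplotype": anc,
            "max_outgroup_weight": net.outgroup_weights[anc],
            "has_loop": net.has_loop[idx],
        })
    return pd.DataFrame(rows)


def write_graphml(
    net: ParsimonyNetwork,
    haps: HaplotypeTable,
    path: str | Path,
    regions: dict[str, str] | None = None,
) -> None:
    """GraphML export with per-region counts on observed haplotype nodes."""
    g = net.graph.copy()
    if regions:
        by_region: dict[str, dict[str, int]] = {}
        for hap_id in haps.ids:
            row = haps.counts.loc[hap_id]
            agg: dict[str, int] = {}
            for pop, cnt in row.items():
                reg = regions.get(pop, pop)
                agg[reg] = agg.get(reg, 0) + int(cnt)
            by_region[hap_id] = agg
        for node, data in g.nodes(data=True):
            if not data.get("is_inferred"):
                for reg, cnt in by_region[node].items():
                    data[f"count_{reg}"] = cnt
    nx.write_graphml(g, str(path))
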