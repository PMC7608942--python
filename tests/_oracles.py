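"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementations they check:
clique percolation is done by exhaustive k-subset enumeration and pairwise
intersection; chaining by exhaustive search over all monotone anchor
subsequences.
"""

from __future__ import annotations

import itertools

import networkx as nx


def cpm_oracle(graph: nx.Graph, k: int) -> set[frozenset]:
    """Clique percolation by brute force: enumerate every k-subset of nodes
    that is a clique, connect cliques sharing exactly k-1 nodes, and take
    the node-union of each connected component."""
    nodes = sorted(graph.nodes)
    cliques = [
        frozenset(sub)
        for sub in itertools.combinations(nodes, k)
        if all(graph.has_edge(a, b) for a, b in itertools.combinations(sub, 2))
    ]
    meta = nx.Graph()
    meta.add_nodes_from(range(len(cliques)))
    for x, y in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[x] & cliques[y]) == k - 1:
            meta.add_edge(x, y)
    return {
        frozenset(itertools.chain.from_iterable(cliques[i] for i in comp))
        for comp in nx.connected_components(meta)
    }


def best_chain_oracle(anchors, params) -> float:
    """Best chain score over all monotone subsequences of the anchor list
    (both orientations), honoring the max_gaps constraint."""
    best = 0.0
    n = len(anchors)
    order = sorted(range(n), key=lambda idx: (anchors[idx].i, anchors[idx].j))
    for r in range(1, n + 1):
        for combo in itertools.combinations(order, r):
            for sign in (1, -1):
                ok = True
                for p, c in zip(combo, combo[1:]):
                    ap, ac = anchors[p], anchors[c]
                    di = ac.i - ap.i
                    dj = sign * (ac.j - ap.j)
                    if di <= 0 or dj <= 0:
                        ok = False
                        break
                    if di - 1 > params.max_gaps or dj - 1 > params.max_gaps:
                        ok = False
                        break
                if not ok:
                    continue
                gaps = sum(
                    (anchors[c].i - anchors[p].i - 1)
                    + (abs(anchors[c].j - anchors[p].j) - 1)
                    for p, c in zip(combo, combo[1:])
                )
                score = r * params.match_score + params.gap_penalty * gaps
                best = max(best, score)
    return best
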