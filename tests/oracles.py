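"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive implementations, kept free of any import from the
package's algorithmic code paths.
"""

from __future__ import annotations


def jaccard_oracle(a, b) -> float:
    """Set overlap by explicit element enumeration (no set operators)."""
    union = []
    for x in list(a) + list(b):
        if x not in union:
            union.append(x)
    if not union:
        return 0.0
    inter = [x for x in union if x in a and x in b]
    return len(inter) / len(union)


def scc_oracle(nodes, edges) -> set[frozenset]:
    """SCC partition via transitive-closure mutual reachability."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for a, b in edges:
        reach[idx[a]][idx[b]] = True
    for k in range(n):  # Floyd–Warshall closure
        for i in range(n):
            if reach[i][k]:
                for j in range(n):
                    if reach[k][j]:
                        reach[i][j] = True
    comps: dict[int, set] = {}
    assigned = [None] * n
    for i in range(n):
        if assigned[i] is None:
            comp = {nodes[i]}
            assigned[i] = i
            for j in range(i + 1, n):
                if assigned[j] is None and reach[i][j] and reach[j][i]:
                    comp.add(nodes[j])
                    assigned[j] = i
            comps[i] = comp
    return {frozenset(c) for c in comps.values()}
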