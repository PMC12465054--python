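"""Within-map reaction graphs, strongly connected components, and cross-map
similarity groups.

The reaction graph has one node per interaction; a directed edge A→B exists
when some canonical identifier among A's targets occurs among B's sources or
modifiers.  Identity is the canonical identifier, not the element id, so
cascades spanning diagrams of one map connect.  SCC pairs linked by at least
``min_similar_reactions`` retained matches form a similarity group; a
weakly-connected-component fallback mode exists for maps without feedback
cycles and is always recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .matching import ComparisonConfig, InteractionMatch
from .model import CanonicalId, DiseaseMap, canonical_identifier


@dataclass(frozen=True)
class SCC:
    scc_id: str
    map_id: str
    members: frozenset[str]


@dataclass(frozen=True)
class SimilarityGroup:
    group_id: str
    scc_a: SCC
    scc_b: SCC
    matches: tuple[InteractionMatch, ...]

    @property
    def n_similar(self) -> int:
        return len({(m.interaction_a, m.interaction_b) for m in self.matches})

    def element_ids_a(self) -> frozenset[CanonicalId]:
        return self._side_elements("a")

    def element_ids_b(self) -> frozenset[CanonicalId]:
        return self._side_elements("b")

    def _side_elements(self, side: str) -> frozenset[CanonicalId]:
        # populated by pair_components via object.__setattr__
        return getattr(self, f"_elements_{side}", frozenset())


def build_reaction_graph(
    m: DiseaseMap, restrict_to: Optional[Sequence[str]] = None,
    include_modifiers: bool = True,
) -> nx.DiGraph:
    """Directed interaction-adjacency graph of *m*.

    Nodes are interaction ids (restricted to *restrict_to* when given);
    edge A→B iff canonical ids of targets(A) intersect those of
    sources(B) ∪ modifiers(B), evaluated across all diagrams of the map.
    """
    keep = set(restrict_to) if restrict_to is not None else None
    interactions = [
        i for i in m.interactions if keep is None or i.interaction_id in keep
    ]

    def cids(eids: Sequence[str]) -> frozenset[CanonicalId]:
        return frozenset(
            c for eid in eids
            if (c := canonical_identifier(m.element(eid))) is not None
        )

    g = nx.DiGraph(map_id=m.map_id)
    out_ids = {}
    in_index: dict[CanonicalId, list[str]] = {}
    for i in interactions:
        g.add_node(i.interaction_id)
        out_ids[i.interaction_id] = cids(i.targets)
        incoming = cids(i.sources) | (cids(i.modifiers) if include_modifiers else frozenset())
        for c in incoming:
            in_index.setdefault(c, []).append(i.interaction_id)
    for a, outs in out_ids.items():
        for c in outs:
            for b in in_index.get(c, ()):
                g.add_edge(a, b)
    return g


def strongly_connected_components(
    g: nx.DiGraph, mode: str = "scc"
) -> list[SCC]:
    """Component partition of *g* with deterministic ids and ordering.

    ``mode="weak"`` substitutes weakly connected components (fallback for
    cascade-style maps without feedback).  Singleton components are included.
    """
    map_id = g.graph.get("map_id", "")
    if mode == "scc":
        comps = nx.strongly_connected_components(g)
    elif mode == "weak":
        comps = nx.weakly_connected_components(g)
    else:
        raise ValueError(f"unknown component mode {mode!r}")
    ordered = sorted((tuple(sorted(c)) for c in comps), key=lambda c: (-len(c), c))
    return [
        SCC(scc_id=f"{map_id}.c{i}", map_id=map_id, members=frozenset(c))
        for i, c in enumerate(ordered)
    ]


def _group_elements(
    scc: SCC, m: DiseaseMap
) -> frozenset[CanonicalId]:
    ids: set[CanonicalId] = set()
    for i in m.interactions:
        if i.interaction_id in scc.members:
            for eid in i.participants():
                cid = canonical_identifier(m.element(eid))
                if cid is not None:
                    ids.add(cid)
    return frozenset(ids)


def pair_components(
    sccs_a: Sequence[SCC],
    sccs_b: Sequence[SCC],
    matches: Sequence[InteractionMatch],
    cfg: Optional[ComparisonConfig] = None,
    map_a: Optional[DiseaseMap] = None,
    map_b: Optional[DiseaseMap] = None,
) -> list[SimilarityGroup]:
    """SCC pairs linked by at least ``cfg.min_similar_reactions`` matches.

    One SCC may appear in several groups (against different opposite-side
    SCCs).  Groups are ordered by n_similar descending, ties broken by
    (scc_a, scc_b) ids; group ids are assigned in that order.
    """
    cfg = cfg or ComparisonConfig()
    loc_a = {iid: s for s in sccs_a for iid in s.members}
    loc_b = {iid: s for s in sccs_b for iid in s.members}

    bucket: dict[tuple[str, str], list[InteractionMatch]] = {}
    scc_by_id = {s.scc_id: s for s in list(sccs_a) + list(sccs_b)}
    for m in matches:
        sa = loc_a.get(m.interaction_a)
        sb = loc_b.get(m.interaction_b)
        if sa is None or sb is None:
            continue
        bucket.setdefault((sa.scc_id, sb.scc_id), []).append(m)

    qualifying = []
    for (said, sbid), ms in bucket.items():
        n = len({(m.interaction_a, m.interaction_b) for m in ms})
        if n >= cfg.min_similar_reactions:
            qualifying.append((n, said, sbid, ms))
    qualifying.sort(key=lambda q: (-q[0], q[1], q[2]))

    groups = []
    for gi, (n, said, sbid, ms) in enumerate(qualifying):
        ms_sorted = tuple(
            sorted(ms, key=lambda m: (-m.similarity, m.interaction_a, m.interaction_b))
        )
        grp = SimilarityGroup(
            group_id=f"G{gi:03d}",
            scc_a=scc_by_id[said],
            scc_b=scc_by_id[sbid],
            matches=ms_sorted,
        )
        if map_a is not None:
            object.__setattr__(grp, "_elements_a", _group_elements(grp.scc_a, map_a))
        if map_b is not None:
            object.__setattr__(grp, "_elements_b", _group_elements(grp.scc_b, map_b))
        groups.append(grp)
    return groups


def find_similarity_groups(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    matches: Sequence[InteractionMatch],
    cfg: Optional[ComparisonConfig] = None,
) -> list[SimilarityGroup]:
    """Convenience wrapper: graphs on matched interactions → components → groups."""
    cfg = cfg or ComparisonConfig()
    matched_a = {m.interaction_a for m in matches}
    matched_b = {m.interaction_b for m in matches}
    ga = build_reaction_graph(map_a, matched_a, cfg.include_modifiers)
    gb = build_reaction_graph(map_b, matched_b, cfg.include_modifiers)
    sccs_a = strongly_connected_components(ga, cfg.component_mode)
    sccs_b = strongly_connected_components(gb, cfg.component_mode)
    return pair_components(sccs_a, sccs_b, matches, cfg, map_a, map_b)


def group_coverage(
    groups: Sequence[SimilarityGroup], map_a: DiseaseMap, map_b: DiseaseMap
) -> tuple[int, int, int, int]:
    """Distinct interactions of each map appearing in any group, with totals."""
    cov_a = {m.interaction_a for g in groups for m in g.matches}
    cov_b = {m.interaction_b for g in groups for m in g.matches}
    return len(cov_a), len(map_a.interactions), len(cov_b), len(map_b.interactions)


def element_group_frequency(
    groups: Sequence[SimilarityGroup],
    map_a: DiseaseMap,
    map_b: DiseaseMap,
) -> list[tuple[CanonicalId, int]]:
    """Number of groups whose member interactions involve each identifier.

    An identifier is counted once per group when any member interaction on
    either side involves it; ranked descending, ties lexicographic.
    """
    counts: dict[CanonicalId, int] = {}
    for g in groups:
        ids = _group_elements(g.scc_a, map_a) | _group_elements(g.scc_b, map_b)
        for cid in ids:
            counts[cid] = counts.get(cid, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def disease_specific_clusters(
    m: DiseaseMap,
    matches: Sequence[InteractionMatch],
    side: str = "a",
    cfg: Optional[ComparisonConfig] = None,
) -> list[SCC]:
    """Components of the reaction graph over interactions with no cross-map match.

    *side* selects which match column refers to *m* ("a" or "b"); sorted by
    size descending.
    """
    cfg = cfg or ComparisonConfig()
    matched = {
        m_.interaction_a if side == "a" else m_.interaction_b for m_ in matches
    }
    unmatched = [
        i.interaction_id for i in m.interactions if i.interaction_id not in matched
    ]
    g = build_reaction_graph(m, unmatched, cfg.include_modifiers)
    return strongly_connected_components(g, cfg.component_mode)


def groups_to_frame(groups: Sequence[SimilarityGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "scc_a": g.scc_a.scc_id,
                "scc_b": g.scc_b.scc_id,
                "members_a": ",".join(sorted(g.scc_a.members)),
                "members_b": ",".join(sorted(g.scc_b.members)),
                "n_similar": g.n_similar,
            }
            for g in groups
        ],
        columns=["group_id", "scc_a", "scc_b", "members_a", "members_b", "n_similar"],
    )


def groups_to_report(groups: Sequence[SimilarityGroup], mode: str = "scc") -> dict:
    """JSON-serializable report mirroring a supplementary group listing."""
    return {
        "component_mode": mode,
        "n_groups": len(groups),
        "groups": [
            {
                "group_id": g.group_id,
                "n_similar": g.n_similar,
                "scc_a": {"scc_id": g.scc_a.scc_id, "members": sorted(g.scc_a.members)},
                "scc_b": {"scc_id": g.scc_b.scc_id, "members": sorted(g.scc_b.members)},
                "matched_identifiers": sorted(
                    {str(c) for m in g.matches for c in m.matched}
                ),
                "matches": [
                    {
                        "interaction_a": m.interaction_a,
                        "interaction_b": m.interaction_b,
                        "similarity": round(m.similarity, 4),
                        "matched": sorted(str(c) for c in m.matched),
                    }
                    for m in g.matches
                ],
            }
            for g in groups
        ],
    }
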