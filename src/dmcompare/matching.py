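"""Cross-map interaction similarity scoring and filtered match lists.

An interaction is reduced to its participant set of canonical identifiers
(sources ∪ targets ∪ modifiers); cross-map pairs are scored with the Jaccard
index over those sets and retained only when similarity ≥ ``min_similarity``
AND the matched identifier set has at least ``min_shared_elements`` members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import CanonicalId, DiseaseMap, Interaction, canonical_identifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonConfig:
    """Thresholds governing the whole comparison pipeline."""

    min_similarity: float = 0.7
    min_shared_elements: int = 2
    min_similar_reactions: int = 5
    role_strict: bool = False
    include_modifiers: bool = True
    require_sign_agreement: bool = False
    omit_threshold: float = 0.05
    min_diagram_overlap: int = 3
    component_mode: str = "scc"  # "scc" | "weak"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must lie in [0, 1]")
        if self.min_shared_elements < 0 or self.min_similar_reactions < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.omit_threshold <= 1.0:
            raise ValueError("omit_threshold must lie in [0, 1]")
        if self.min_diagram_overlap < 0:
            raise ValueError("min_diagram_overlap must be non-negative")
        if self.component_mode not in ("scc", "weak"):
            raise ValueError("component_mode must be 'scc' or 'weak'")


@dataclass(frozen=True)
class ParticipantSet:
    interaction_id: str
    ids: frozenset[CanonicalId]
    # per-role id sets, used by the role_strict metric variant
    source_ids: frozenset[CanonicalId] = frozenset()
    target_ids: frozenset[CanonicalId] = frozenset()
    modifier_ids: frozenset[CanonicalId] = frozenset()


@dataclass(frozen=True)
class InteractionMatch:
    interaction_a: str
    interaction_b: str
    similarity: float
    matched: frozenset[CanonicalId]


class UnmatchableInteraction(ValueError):
    """Interaction with zero canonicalizable participants."""


def participant_set(
    i: Interaction, m: DiseaseMap, include_modifiers: bool = True
) -> ParticipantSet:
    """Canonical-identifier participant set of one interaction.

    Raises :class:`UnmatchableInteraction` when no participant has a
    canonical identifier; such interactions are excluded from matching.
    """

    def ids_of(element_ids: Sequence[str]) -> frozenset[CanonicalId]:
        out = set()
        for eid in element_ids:
            cid = canonical_identifier(m.element(eid))
            if cid is not None:
                out.add(cid)
        return frozenset(out)

    src = ids_of(i.sources)
    tgt = ids_of(i.targets)
    mod = ids_of(i.modifiers) if include_modifiers else frozenset()
    ids = src | tgt | mod
    if not ids:
        raise UnmatchableInteraction(
            f"interaction {i.interaction_id!r} has no canonicalizable participants"
        )
    return ParticipantSet(i.interaction_id, ids, src, tgt, mod)


def _role_matched(p: ParticipantSet, q: ParticipantSet) -> frozenset[CanonicalId]:
    return (
        (p.source_ids & q.source_ids)
        | (p.target_ids & q.target_ids)
        | (p.modifier_ids & q.modifier_ids)
    )


def interaction_similarity(
    p: ParticipantSet, q: ParticipantSet, role_strict: bool = False
) -> float:
    """Jaccard similarity of two participant sets.

    With *role_strict* the intersection is restricted to identifiers
    occupying the same role (source/target/modifier) on both sides; the
    union is unchanged.
    """
    if not p.ids or not q.ids:
        raise ValueError("participant sets must be non-empty")
    inter = _role_matched(p, q) if role_strict else p.ids & q.ids
    return len(inter) / len(p.ids | q.ids)


def match_interactions(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    cfg: Optional[ComparisonConfig] = None,
) -> list[InteractionMatch]:
    """All cross-map interaction pairs passing both retention thresholds.

    Pair enumeration is bounded by an inverted index on canonical ids: a
    pair is scored only if it shares at least ``min_shared_elements``
    identifiers, which cannot discard any retainable match.  Output is
    ordered by similarity descending, then (interaction_a, interaction_b)
    lexicographic.
    """
    cfg = cfg or ComparisonConfig()

    def psets(m: DiseaseMap) -> dict[str, ParticipantSet]:
        out = {}
        for i in m.interactions:
            try:
                out[i.interaction_id] = participant_set(i, m, cfg.include_modifiers)
            except UnmatchableInteraction:
                logger.info(
                    "map %s: interaction %s UNMATCHABLE (no canonical participants)",
                    m.map_id, i.interaction_id,
                )
        return out

    pa, pb = psets(map_a), psets(map_b)
    signs_a = {i.interaction_id: i.sign for i in map_a.interactions}
    signs_b = {i.interaction_id: i.sign for i in map_b.interactions}

    index_b: dict[CanonicalId, list[str]] = {}
    for iid, ps in pb.items():
        for cid in ps.ids:
            index_b.setdefault(cid, []).append(iid)

    min_shared = max(cfg.min_shared_elements, 1)
    matches: list[InteractionMatch] = []
    for iid_a, ps_a in pa.items():
        shared_count: dict[str, int] = {}
        for cid in ps_a.ids:
            for iid_b in index_b.get(cid, ()):
                shared_count[iid_b] = shared_count.get(iid_b, 0) + 1
        for iid_b, n_shared in shared_count.items():
            if n_shared < min_shared:
                continue
            ps_b = pb[iid_b]
            if cfg.require_sign_agreement and signs_a[iid_a] != signs_b[iid_b]:
                continue
            matched = (
                _role_matched(ps_a, ps_b) if cfg.role_strict else ps_a.ids & ps_b.ids
            )
            if len(matched) < cfg.min_shared_elements:
                continue
            sim = len(matched) / len(ps_a.ids | ps_b.ids)
            if sim < cfg.min_similarity:
                continue
            matches.append(
                InteractionMatch(iid_a, iid_b, sim, frozenset(matched))
            )

    for m in matches:  # retention contract, asserted on every run
        assert m.similarity >= cfg.min_similarity
        assert len(m.matched) >= cfg.min_shared_elements

    matches.sort(key=lambda m: (-m.similarity, m.interaction_a, m.interaction_b))
    return matches


def matches_to_frame(
    matches: Sequence[InteractionMatch],
    map_a: Optional[DiseaseMap] = None,
    map_b: Optional[DiseaseMap] = None,
) -> pd.DataFrame:
    diag_a = (
        {i.interaction_id: i.diagram_id for i in map_a.interactions} if map_a else {}
    )
    diag_b = (
        {i.interaction_id: i.diagram_id for i in map_b.interactions} if map_b else {}
    )
    return pd.DataFrame(
        [
            {
                "interaction_a": m.interaction_a,
                "interaction_b": m.interaction_b,
                "similarity": f"{m.similarity:.4f}",
                "matched": ",".join(sorted(str(c) for c in m.matched)),
                "diagram_a": diag_a.get(m.interaction_a, ""),
                "diagram_b": diag_b.get(m.interaction_b, ""),
            }
            for m in matches
        ],
        columns=[
            "interaction_a", "interaction_b", "similarity",
            "matched", "diagram_a", "diagram_b",
        ],
    )
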