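"""Identifier-level comparison of two maps.

Unique/shared identifier sets, per-diagram overlap matrices, cell-type
protein profiles and their Jaccard similarity.  "Unique identifiers" default
to HGNC symbols only; cell-type profiles default to PROTEIN-class elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import CanonicalId, DiseaseMap, EntityClass, canonical_identifier

logger = logging.getLogger(__name__)

DEFAULT_NAMESPACES = ("HGNC",)


@dataclass(frozen=True)
class DiagramOverlap:
    diagram_a: str
    diagram_b: str
    shared: frozenset[CanonicalId]

    @property
    def count(self) -> int:
        return len(self.shared)


@dataclass(frozen=True)
class CellTypeProfile:
    cell_type: str
    symbols: frozenset[CanonicalId]


@dataclass(frozen=True)
class JaccardCell:
    cell_type_a: str
    cell_type_b: str
    value: float
    omitted: bool


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """|A∩B| / |A∪B|, with J(∅,∅) defined as 0."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _canonical_ids(m: DiseaseMap, namespaces: Sequence[str]) -> set[CanonicalId]:
    wanted = set(namespaces)
    out: set[CanonicalId] = set()
    for e in m.elements:
        cid = canonical_identifier(e)
        if cid is not None and cid.namespace in wanted:
            out.add(cid)
    return out


def unique_identifiers(
    m: DiseaseMap, namespace_filter: Optional[Sequence[str]] = None
) -> set[CanonicalId]:
    """Distinct canonical identifiers across all diagrams of *m* (HGNC by default)."""
    return _canonical_ids(m, namespace_filter or DEFAULT_NAMESPACES)


def shared_identifiers(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    namespace_filter: Optional[Sequence[str]] = None,
) -> set[CanonicalId]:
    return unique_identifiers(map_a, namespace_filter) & unique_identifiers(
        map_b, namespace_filter
    )


def disease_specific_identifiers(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    namespace_filter: Optional[Sequence[str]] = None,
) -> tuple[set[CanonicalId], set[CanonicalId]]:
    ua = unique_identifiers(map_a, namespace_filter)
    ub = unique_identifiers(map_b, namespace_filter)
    return ua - ub, ub - ua


def _diagram_id_sets(
    m: DiseaseMap, namespaces: Sequence[str]
) -> dict[str, set[CanonicalId]]:
    wanted = set(namespaces)
    per: dict[str, set[CanonicalId]] = {d.diagram_id: set() for d in m.diagrams}
    for e in m.elements:
        cid = canonical_identifier(e)
        if cid is not None and cid.namespace in wanted:
            per[e.diagram_id].add(cid)
    return per


def diagram_overlap_matrix(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    min_overlap: int = 3,
    namespace_filter: Optional[Sequence[str]] = None,
) -> list[DiagramOverlap]:
    """Cross-map diagram pairs sharing at least *min_overlap* identifiers.

    Sorted by shared count descending, ties broken lexicographically by
    (diagram_a, diagram_b).
    """
    ns = namespace_filter or DEFAULT_NAMESPACES
    sets_a = _diagram_id_sets(map_a, ns)
    sets_b = _diagram_id_sets(map_b, ns)
    out = [
        DiagramOverlap(da, db, frozenset(sa & sb))
        for da, sa in sets_a.items()
        for db, sb in sets_b.items()
        if len(sa & sb) >= min_overlap
    ]
    out.sort(key=lambda o: (-o.count, o.diagram_a, o.diagram_b))
    return out


def symbol_incidence(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    symbols: Optional[Iterable[CanonicalId]] = None,
) -> pd.DataFrame:
    """Boolean symbol-by-diagram incidence over the diagrams of both maps.

    Rows are canonical identifiers (shared identifiers when *symbols* is
    omitted), columns a (map_id, diagram_id) MultiIndex.  Rows are ranked by
    total diagram count descending, ties lexicographic, so ``.head(10)``
    reproduces a top-ten listing.
    """
    shared = shared_identifiers(map_a, map_b)
    if symbols is None:
        wanted = shared
    else:
        wanted = set(symbols)
        outside = wanted - shared
        if outside:
            logger.warning(
                "%d requested symbols are not shared between the maps: %s",
                len(outside), sorted(str(s) for s in outside),
            )

    columns = pd.MultiIndex.from_tuples(
        [(map_a.map_id, d.diagram_id) for d in map_a.diagrams]
        + [(map_b.map_id, d.diagram_id) for d in map_b.diagrams],
        names=["map", "diagram"],
    )
    index = sorted(wanted, key=lambda c: (c.namespace, c.value))
    table = pd.DataFrame(False, index=[str(c) for c in index], columns=columns)

    for m in (map_a, map_b):
        for e in m.elements:
            cid = canonical_identifier(e)
            if cid in wanted:
                table.loc[str(cid), (m.map_id, e.diagram_id)] = True

    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda s: (-int(totals[s]), s))
    return table.loc[order]


def cell_type_profiles(
    m: DiseaseMap, include_gene_rna: bool = False
) -> list[CellTypeProfile]:
    """One HGNC-symbol profile per distinct non-empty compartment.

    PROTEIN elements only by default; *include_gene_rna* widens to GENE and
    RNA elements.
    """
    classes = {EntityClass.PROTEIN}
    if include_gene_rna:
        classes |= {EntityClass.GENE, EntityClass.RNA}
    acc: dict[str, set[CanonicalId]] = {}
    for e in m.elements:
        if not e.compartment or e.entity_class not in classes:
            continue
        cid = canonical_identifier(e)
        if cid is not None and cid.namespace == "HGNC":
            acc.setdefault(e.compartment, set()).add(cid)
    # compartments holding only non-canonicalizable elements still get a profile
    for e in m.elements:
        if e.compartment and e.entity_class in classes:
            acc.setdefault(e.compartment, set())
    return [
        CellTypeProfile(ct, frozenset(symbols))
        for ct, symbols in sorted(acc.items())
    ]


def jaccard_matrix(
    profiles_a: Sequence[CellTypeProfile],
    profiles_b: Sequence[CellTypeProfile],
    omit_threshold: float = 0.05,
) -> list[JaccardCell]:
    """Jaccard index for every cross-map cell-type pair.

    Cells with value ≤ *omit_threshold* (inclusive) are flagged omitted.
    """
    out = []
    for pa in profiles_a:
        for pb in profiles_b:
            v = jaccard(pa.symbols, pb.symbols)
            out.append(
                JaccardCell(pa.cell_type, pb.cell_type, v, omitted=v <= omit_threshold)
            )
    return out


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def overlap_to_frame(overlaps: Sequence[DiagramOverlap]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "diagram_a": o.diagram_a,
                "diagram_b": o.diagram_b,
                "count": o.count,
                "symbols": ",".join(sorted(str(c) for c in o.shared)),
            }
            for o in overlaps
        ],
        columns=["diagram_a", "diagram_b", "count", "symbols"],
    )


def jaccard_to_frame(cells: Sequence[JaccardCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_type_a": c.cell_type_a,
                "cell_type_b": c.cell_type_b,
                "jaccard": round(c.value, 6),
                "omitted": c.omitted,
            }
            for c in cells
        ],
        columns=["cell_type_a", "cell_type_b", "jaccard", "omitted"],
    )
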