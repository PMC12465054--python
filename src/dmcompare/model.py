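"""Disease-map data model, native JSON map-exchange format, and MINERVA-export adapter.

The native format is a versioned JSON document (``"format": "dmcompare-map"``,
``"version": 1``) that mirrors the in-memory model field-for-field; see
:func:`write_map` for the exact layout.  The MINERVA adapter reads the JSON
structure returned by a MINERVA project export (one model per diagram, with
element ``references`` lists and reaction ``reactants``/``products``/
``modifiers``); the field mapping is documented on
:func:`_map_from_minerva_export`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

logger = logging.getLogger(__name__)

NATIVE_FORMAT = "dmcompare-map"
NATIVE_VERSION = 1

#: Annotation namespaces accepted on elements.
ANNOTATION_NAMESPACES = frozenset({"HGNC", "UNIPROT", "CHEBI", "GO", "MESH"})


class EntityClass(str, Enum):
    PROTEIN = "PROTEIN"
    GENE = "GENE"
    RNA = "RNA"
    SIMPLE_MOLECULE = "SIMPLE_MOLECULE"
    PHENOTYPE = "PHENOTYPE"
    COMPLEX = "COMPLEX"
    OTHER = "OTHER"


class Sign(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNKNOWN = "UNKNOWN"


class DiagramKind(str, Enum):
    INTERCELLULAR = "INTERCELLULAR"
    PATHWAY = "PATHWAY"


class MapFormat(str, Enum):
    NATIVE = "NATIVE"
    MINERVA_EXPORT = "MINERVA_EXPORT"


class MapValidationError(ValueError):
    """Raised when a map file or in-memory map violates the schema."""


class CanonicalId(NamedTuple):
    """Per-element comparison key.

    ``HGNC`` for gene products (uppercase symbol), ``CHEBI`` for small
    molecules (``CHEBI:<id>``), ``NAME`` for phenotypes (lowercased,
    whitespace-collapsed display name).
    """

    namespace: str
    value: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.namespace}:{self.value}"


@dataclass(frozen=True)
class Element:
    element_id: str
    display_name: str
    entity_class: EntityClass
    annotations: tuple[tuple[str, str], ...] = ()
    diagram_id: str = ""
    compartment: str = ""

    def annotation(self, namespace: str) -> Optional[str]:
        """First annotation value in *namespace* (first occurrence wins)."""
        seen = False
        value = None
        for ns, val in self.annotations:
            if ns == namespace:
                if not seen:
                    value = val
                    seen = True
                else:
                    logger.debug(
                        "element %s: duplicate %s annotation %r ignored",
                        self.element_id, namespace, val,
                    )
        return value


@dataclass(frozen=True)
class Interaction:
    interaction_id: str
    diagram_id: str
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    modifiers: tuple[str, ...] = ()
    sign: Sign = Sign.UNKNOWN
    references: tuple[str, ...] = ()

    def participants(self) -> tuple[str, ...]:
        return self.sources + self.targets + self.modifiers


@dataclass(frozen=True)
class Diagram:
    diagram_id: str
    name: str
    kind: DiagramKind = DiagramKind.PATHWAY
    cell_type: str = ""


@dataclass
class DiseaseMap:
    map_id: str
    disease_label: str = ""
    diagrams: list[Diagram] = field(default_factory=list)
    elements: list[Element] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)

    _element_index: dict[str, Element] = field(
        default_factory=dict, repr=False, compare=False
    )

    def element(self, element_id: str) -> Element:
        if not self._element_index:
            self._element_index = {e.element_id: e for e in self.elements}
        return self._element_index[element_id]

    def validate(self) -> None:
        """Raise :class:`MapValidationError` on any invariant violation."""
        diagram_ids = [d.diagram_id for d in self.diagrams]
        if len(diagram_ids) != len(set(diagram_ids)):
            raise MapValidationError(f"map {self.map_id}: duplicate diagram_id")
        dset = set(diagram_ids)

        eids: set[str] = set()
        for e in self.elements:
            if e.element_id in eids:
                raise MapValidationError(
                    f"map {self.map_id}: duplicate element_id {e.element_id!r}"
                )
            eids.add(e.element_id)
            if e.diagram_id not in dset:
                raise MapValidationError(
                    f"element {e.element_id!r}: unknown diagram_id {e.diagram_id!r}"
                )
            for ns, val in e.annotations:
                if not ns or not val:
                    raise MapValidationError(
                        f"element {e.element_id!r}: empty annotation pair ({ns!r}, {val!r})"
                    )

        iids: set[str] = set()
        for i in self.interactions:
            if i.interaction_id in iids:
                raise MapValidationError(
                    f"map {self.map_id}: duplicate interaction_id {i.interaction_id!r}"
                )
            iids.add(i.interaction_id)
            if i.diagram_id not in dset:
                raise MapValidationError(
                    f"interaction {i.interaction_id!r}: unknown diagram_id {i.diagram_id!r}"
                )
            if not i.sources or not i.targets:
                raise MapValidationError(
                    f"interaction {i.interaction_id!r}: sources and targets must be non-empty"
                )
            for pid in i.participants():
                if pid not in eids:
                    raise MapValidationError(
                        f"interaction {i.interaction_id!r}: dangling participant "
                        f"reference {pid!r}"
                    )

    def reference_count(self) -> int:
        return len({r for i in self.interactions for r in i.references})


@dataclass(frozen=True)
class MapSummary:
    n_elements: int
    n_interactions: int
    n_unique_molecular_entities: int
    n_diagrams: int
    n_references: int


@dataclass
class LoadReport:
    path: str
    format: MapFormat
    n_elements_loaded: int = 0
    n_interactions_loaded: int = 0
    n_elements_dropped: int = 0
    n_interactions_dropped: int = 0
    warnings: list[str] = field(default_factory=list)


_WS = re.compile(r"\s+")

#: Classes whose elements canonicalize through HGNC symbols.
_GENE_PRODUCT_CLASSES = frozenset(
    {EntityClass.PROTEIN, EntityClass.GENE, EntityClass.RNA}
)
#: Classes counted as "molecular entities" in summaries.
MOLECULAR_CLASSES = _GENE_PRODUCT_CLASSES | {EntityClass.SIMPLE_MOLECULE}


def canonical_identifier(e: Element) -> Optional[CanonicalId]:
    """Comparison key for *e*, or ``None`` if the element has no stable identity.

    PROTEIN/GENE/RNA with an HGNC annotation map to the uppercased symbol;
    SIMPLE_MOLECULE with a CHEBI annotation maps to the normalized
    ``CHEBI:<id>`` form; PHENOTYPE maps to its lowercased,
    whitespace-collapsed display name.  COMPLEX and OTHER elements, and
    gene products lacking an HGNC annotation, contribute nothing and are
    excluded from identifier analyses.
    """
    if e.entity_class in _GENE_PRODUCT_CLASSES:
        symbol = e.annotation("HGNC")
        if symbol is None:
            return None
        return CanonicalId("HGNC", symbol.strip().upper())
    if e.entity_class is EntityClass.SIMPLE_MOLECULE:
        chebi = e.annotation("CHEBI")
        if chebi is None:
            return None
        value = chebi.strip().upper()
        if not value.startswith("CHEBI:"):
            value = "CHEBI:" + value
        return CanonicalId("CHEBI", value)
    if e.entity_class is EntityClass.PHENOTYPE:
        name = _WS.sub(" ", e.display_name).strip().lower()
        if not name:
            return None
        return CanonicalId("NAME", name)
    return None


def summarize(m: DiseaseMap) -> MapSummary:
    """Parse-level content statistics for one map."""
    molecular = {
        cid
        for e in m.elements
        if e.entity_class in MOLECULAR_CLASSES
        for cid in [canonical_identifier(e)]
        if cid is not None
    }
    return MapSummary(
        n_elements=len(m.elements),
        n_interactions=len(m.interactions),
        n_unique_molecular_entities=len(molecular),
        n_diagrams=len(m.diagrams),
        n_references=m.reference_count(),
    )


# ---------------------------------------------------------------------------
# native JSON format
# ---------------------------------------------------------------------------

def _dedup(seq: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for x in seq:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return tuple(out)


def map_to_dict(m: DiseaseMap) -> dict:
    return {
        "format": NATIVE_FORMAT,
        "version": NATIVE_VERSION,
        "map_id": m.map_id,
        "disease_label": m.disease_label,
        "diagrams": [
            {
                "diagram_id": d.diagram_id,
                "name": d.name,
                "kind": d.kind.value,
                "cell_type": d.cell_type,
            }
            for d in m.diagrams
        ],
        "elements": [
            {
                "element_id": e.element_id,
                "display_name": e.display_name,
                "entity_class": e.entity_class.value,
                "annotations": [[ns, val] for ns, val in e.annotations],
                "diagram_id": e.diagram_id,
                "compartment": e.compartment,
            }
            for e in m.elements
        ],
        "interactions": [
            {
                "interaction_id": i.interaction_id,
                "diagram_id": i.diagram_id,
                "sources": list(i.sources),
                "targets": list(i.targets),
                "modifiers": list(i.modifiers),
                "sign": i.sign.value,
                "references": list(i.references),
            }
            for i in m.interactions
        ],
    }


def map_from_dict(doc: dict, report: Optional[LoadReport] = None) -> DiseaseMap:
    if doc.get("format") != NATIVE_FORMAT:
        raise MapValidationError(
            f"not a {NATIVE_FORMAT} document (format={doc.get('format')!r})"
        )
    if doc.get("version") != NATIVE_VERSION:
        raise MapValidationError(f"unsupported version {doc.get('version')!r}")

    diagrams = [
        Diagram(
            diagram_id=str(d["diagram_id"]),
            name=str(d.get("name", "")),
            kind=DiagramKind(d.get("kind", "PATHWAY")),
            cell_type=str(d.get("cell_type", "")),
        )
        for d in doc.get("diagrams", [])
    ]

    elements: list[Element] = []
    for rec in doc.get("elements", []):
        try:
            elements.append(
                Element(
                    element_id=str(rec["element_id"]),
                    display_name=str(rec.get("display_name", "")),
                    entity_class=EntityClass(rec.get("entity_class", "OTHER")),
                    annotations=tuple(
                        (str(ns), str(val)) for ns, val in rec.get("annotations", [])
                    ),
                    diagram_id=str(rec.get("diagram_id", "")),
                    compartment=str(rec.get("compartment", "")),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise MapValidationError(f"bad element record {rec!r}: {exc}") from exc

    interactions: list[Interaction] = []
    for rec in doc.get("interactions", []):
        try:
            interactions.append(
                Interaction(
                    interaction_id=str(rec["interaction_id"]),
                    diagram_id=str(rec.get("diagram_id", "")),
                    sources=_dedup(str(s) for s in rec["sources"]),
                    targets=_dedup(str(t) for t in rec["targets"]),
                    modifiers=_dedup(str(x) for x in rec.get("modifiers", [])),
                    sign=Sign(rec.get("sign", "UNKNOWN")),
                    references=tuple(str(r) for r in rec.get("references", [])),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise MapValidationError(f"bad interaction record {rec!r}: {exc}") from exc

    m = DiseaseMap(
        map_id=str(doc.get("map_id", "")),
        disease_label=str(doc.get("disease_label", "")),
        diagrams=diagrams,
        elements=elements,
        interactions=interactions,
    )
    if report is not None:
        report.n_elements_loaded = len(elements)
        report.n_interactions_loaded = len(interactions)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# MINERVA export adapter
# ---------------------------------------------------------------------------

_MINERVA_TYPE_MAP = {
    "protein": EntityClass.PROTEIN,
    "gene": EntityClass.GENE,
    "rna": EntityClass.RNA,
    "antisense rna": EntityClass.RNA,
    "simple molecule": EntityClass.SIMPLE_MOLECULE,
    "simple_molecule": EntityClass.SIMPLE_MOLECULE,
    "phenotype": EntityClass.PHENOTYPE,
    "complex": EntityClass.COMPLEX,
}

_MINERVA_REF_MAP = {
    "HGNC_SYMBOL": "HGNC",
    "HGNC": "HGNC",
    "UNIPROT": "UNIPROT",
    "CHEBI": "CHEBI",
    "GO": "GO",
    "MESH_2012": "MESH",
    "MESH": "MESH",
}

_NEGATIVE_HINTS = ("inhibition", "negative", "repress")
_POSITIVE_HINTS = ("activation", "positive", "trigger", "stimulat", "catalysis")


def _minerva_sign(reaction_type: str) -> Sign:
    t = reaction_type.lower()
    if any(h in t for h in _NEGATIVE_HINTS):
        return Sign.NEGATIVE
    if any(h in t for h in _POSITIVE_HINTS):
        return Sign.POSITIVE
    return Sign.UNKNOWN


def _map_from_minerva_export(doc: dict, report: LoadReport) -> DiseaseMap:
    """Build a :class:`DiseaseMap` from a MINERVA project-export document.

    Field mapping (MINERVA -> model):

    ==========================  =======================================
    MINERVA export              model field
    ==========================  =======================================
    project.projectId           DiseaseMap.map_id
    project.name                DiseaseMap.disease_label
    models[].idObject           Diagram.diagram_id (stringified)
    models[].name               Diagram.name; cell_type for PATHWAY kind
    elements[].id               Element.element_id (``m<model>.e<id>``)
    elements[].name             Element.display_name
    elements[].type             Element.entity_class (see type table)
    elements[].compartmentName  Element.compartment
    elements[].references[]     Element.annotations (type/resource pairs)
    reactions[].id              Interaction.interaction_id (``m<model>.r<id>``)
    reactions[].reactants[]     Interaction.sources (``element`` ids)
    reactions[].products[]      Interaction.targets
    reactions[].modifiers[]     Interaction.modifiers
    reactions[].type            Interaction.sign (keyword heuristics)
    reactions[].references[]    Interaction.references (``resource``)
    ==========================  =======================================

    A model is classified INTERCELLULAR when its name contains
    "intercellular", "overview" or "main"; otherwise PATHWAY with the model
    name as cell type.  Unparseable element or reaction records are dropped
    with a warning and counted in the load report; reactions referencing
    element ids absent from the export are dropped likewise (the remaining
    map must still validate).
    """
    project = doc.get("project", {})
    map_id = str(project.get("projectId", doc.get("projectId", "minerva-export")))
    label = str(project.get("name", ""))

    models = doc.get("models", doc.get("maps", []))
    diagrams: list[Diagram] = []
    elements: list[Element] = []
    interactions: list[Interaction] = []

    for model in models:
        mid = str(model.get("idObject", model.get("id", len(diagrams))))
        name = str(model.get("name", mid))
        low = name.lower()
        if any(k in low for k in ("intercellular", "overview", "main")):
            kind, cell_type = DiagramKind.INTERCELLULAR, ""
        else:
            kind, cell_type = DiagramKind.PATHWAY, name
        diagrams.append(Diagram(diagram_id=mid, name=name, kind=kind, cell_type=cell_type))

        local_ids: set[str] = set()
        for rec in model.get("elements", []):
            try:
                eid = f"m{mid}.e{rec['id']}"
                etype = _MINERVA_TYPE_MAP.get(
                    str(rec.get("type", "")).lower(), EntityClass.OTHER
                )
                annotations = []
                for ref in rec.get("references", []):
                    ns = _MINERVA_REF_MAP.get(str(ref.get("type", "")).upper())
                    res = str(ref.get("resource", "")).strip()
                    if ns and res:
                        annotations.append((ns, res))
                elements.append(
                    Element(
                        element_id=eid,
                        display_name=str(rec.get("name", "")),
                        entity_class=etype,
                        annotations=tuple(annotations),
                        diagram_id=mid,
                        compartment=str(rec.get("compartmentName") or ""),
                    )
                )
                local_ids.add(str(rec["id"]))
            except (KeyError, TypeError) as exc:
                report.n_elements_dropped += 1
                report.warnings.append(f"dropped element record in model {mid}: {exc}")
                logger.warning("dropped element record in model %s: %s", mid, exc)

        for rec in model.get("reactions", []):
            try:
                rid = f"m{mid}.r{rec['id']}"

                def ids(key: str) -> tuple[str, ...]:
                    return _dedup(
                        f"m{mid}.e{p['element']}"
                        for p in rec.get(key, [])
                        if str(p.get("element")) in local_ids
                    )

                sources, targets, modifiers = ids("reactants"), ids("products"), ids("modifiers")
                if not sources or not targets:
                    raise ValueError("missing resolvable reactants or products")
                refs = tuple(
                    str(r.get("resource", "")).strip()
                    for r in rec.get("references", [])
                    if str(r.get("resource", "")).strip()
                )
                interactions.append(
                    Interaction(
                        interaction_id=rid,
                        diagram_id=mid,
                        sources=sources,
                        targets=targets,
                        modifiers=modifiers,
                        sign=_minerva_sign(str(rec.get("type", ""))),
                        references=refs,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                report.n_interactions_dropped += 1
                report.warnings.append(f"dropped reaction record in model {mid}: {exc}")
                logger.warning("dropped reaction record in model %s: %s", mid, exc)

    m = DiseaseMap(
        map_id=map_id,
        disease_label=label,
        diagrams=diagrams,
        elements=elements,
        interactions=interactions,
    )
    report.n_elements_loaded = len(elements)
    report.n_interactions_loaded = len(interactions)
    m.validate()
    return m


# ---------------------------------------------------------------------------
# i/o entry points
# ---------------------------------------------------------------------------

def load_map_with_report(
    path: str | Path, format: MapFormat = MapFormat.NATIVE
) -> tuple[DiseaseMap, LoadReport]:
    path = Path(path)
    report = LoadReport(path=str(path), format=format)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise MapValidationError(f"{path}: not valid JSON: {exc}") from exc
    if format is MapFormat.MINERVA_EXPORT:
        return _map_from_minerva_export(doc, report), report
    return map_from_dict(doc, report), report


def load_map(path: str | Path, format: MapFormat = MapFormat.NATIVE) -> DiseaseMap:
    """Load and validate a map file; see :func:`load_map_with_report`."""
    m, _ = load_map_with_report(path, format)
    return m


def write_map(m: DiseaseMap, path: str | Path) -> None:
    """Write *m* as a native JSON file.  Byte-stable for identical input."""
    m.validate()
    text = json.dumps(map_to_dict(m), indent=1, ensure_ascii=False, sort_keys=True)
    Path(path).write_text(text + "\n", encoding="utf-8")
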