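from __future__ import annotations

import pytest

from dmcompare import (
    Diagram,
    DiagramKind,
    DiseaseMap,
    Element,
    EntityClass,
    Interaction,
    Sign,
    SimConfig,
    generate_map_pair,
)


def protein(eid: str, symbol: str, diagram: str = "d1", compartment: str = "") -> Element:
    return Element(
        element_id=eid,
        display_name=symbol,
        entity_class=EntityClass.PROTEIN,
        annotations=(("HGNC", symbol),),
        diagram_id=diagram,
        compartment=compartment,
    )


def make_map(
    map_id: str,
    elements,
    interactions=(),
    diagrams=None,
) -> DiseaseMap:
    """Small-map builder; derives diagrams from element/interaction usage."""
    if diagrams is None:
        used = {e.diagram_id for e in elements} | {i.diagram_id for i in interactions}
        diagrams = [
            Diagram(d, d, DiagramKind.PATHWAY, cell_type="") for d in sorted(used)
        ] or [Diagram("d1", "d1")]
    m = DiseaseMap(
        map_id=map_id,
        disease_label=map_id,
        diagrams=list(diagrams),
        elements=list(elements),
        interactions=list(interactions),
    )
    m.validate()
    return m


def chain_interactions(map_tag: str, element_ids, diagram: str = "d1", cyclic=False):
    """Interactions e0→e1→…; with cyclic=True the last wraps to the first."""
    n = len(element_ids)
    last = n if cyclic else n - 1
    return [
        Interaction(
            interaction_id=f"{map_tag}.i{j}",
            diagram_id=diagram,
            sources=(element_ids[j],),
            targets=(element_ids[(j + 1) % n],),
            sign=Sign.POSITIVE,
        )
        for j in range(last)
    ]


@pytest.fixture
def sim_pair():
    """Default noiseless synthetic pair with its truth manifest."""
    return generate_map_pair(SimConfig(seed=42))


@pytest.fixture
def sim_cfg():
    return SimConfig(seed=42)
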