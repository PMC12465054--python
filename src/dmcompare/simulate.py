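"""Synthetic disease-map pairs with known ground truth.

The generator plants shared cyclic interaction modules (duplicated across
the two maps with identical canonical identifiers), cell-type compartments
with a configurable identifier overlap, and background interactions drawn
from per-map disjoint vocabularies.  All randomness flows from a single
seed, so identical configs yield byte-identical maps, and a truth manifest
records what the analysis pipeline is expected to recover.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .grouping import SimilarityGroup
from .model import (
    CanonicalId,
    Diagram,
    DiagramKind,
    DiseaseMap,
    Element,
    EntityClass,
    Interaction,
    Sign,
)


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cell_types_per_map: int = 3
    n_shared_cell_types: int = 2
    proteins_per_cell_type: int = 8
    identifier_overlap_fraction: float = 0.5
    n_planted_modules: int = 2
    module_size: int = 6  # interactions per planted module (directed cycle)
    n_background_interactions: int = 5
    corruption_rate: float = 0.0
    acyclic_modules: bool = False  # plant chains instead of cycles
    n_druggable_per_module: int = 2

    def validate(self) -> None:
        if self.n_shared_cell_types > self.n_cell_types_per_map:
            raise SimConfigError(
                "n_shared_cell_types cannot exceed n_cell_types_per_map"
            )
        for name in (
            "n_cell_types_per_map", "n_shared_cell_types", "proteins_per_cell_type",
            "n_planted_modules", "module_size", "n_background_interactions",
            "n_druggable_per_module",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        for name in ("identifier_overlap_fraction", "corruption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.n_planted_modules and self.module_size < 2:
            raise SimConfigError("module_size must be at least 2")
        n_shared = round(
            self.identifier_overlap_fraction * self.proteins_per_cell_type
        )
        if n_shared > self.proteins_per_cell_type:
            raise SimConfigError(
                "identifier_overlap_fraction demands more shared symbols than exist"
            )


@dataclass
class TruthManifest:
    planted_module_pairs: list[tuple[str, tuple[str, ...], tuple[str, ...]]]
    shared_identifier_set: frozenset[CanonicalId]
    shared_cell_types: list[tuple[str, float]]
    druggable_shared_targets: frozenset[CanonicalId]
    corrupted_interactions_b: frozenset[str] = frozenset()

    def planted_pairs(self, module_id: str) -> list[tuple[str, str]]:
        for mid, ids_a, ids_b in self.planted_module_pairs:
            if mid == module_id:
                return list(zip(ids_a, ids_b))
        raise KeyError(module_id)

    def to_dict(self) -> dict:
        return {
            "planted_module_pairs": [
                {"module_id": mid, "interactions_a": list(a), "interactions_b": list(b)}
                for mid, a, b in self.planted_module_pairs
            ],
            "shared_identifier_set": sorted(str(c) for c in self.shared_identifier_set),
            "shared_cell_types": [
                {"cell_type": ct, "expected_jaccard": j}
                for ct, j in self.shared_cell_types
            ],
            "druggable_shared_targets": sorted(
                str(c) for c in self.druggable_shared_targets
            ),
            "corrupted_interactions_b": sorted(self.corrupted_interactions_b),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _protein(eid: str, symbol: str, diagram_id: str, compartment: str) -> Element:
    return Element(
        element_id=eid,
        display_name=symbol,
        entity_class=EntityClass.PROTEIN,
        annotations=(("HGNC", symbol),),
        diagram_id=diagram_id,
        compartment=compartment,
    )


def generate_map_pair(
    cfg: SimConfig,
) -> tuple[DiseaseMap, DiseaseMap, TruthManifest]:
    """Generate a pair of maps plus the ground-truth manifest.

    Layout per map: one INTERCELLULAR diagram ("main") holding module and
    background elements with empty compartments, and one PATHWAY diagram per
    cell type whose protein elements carry the cell type as compartment.
    Planted modules are directed interaction cycles duplicated across maps
    with identical HGNC symbols; background interactions use per-map
    disjoint vocabularies and form a cycle of their own.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)

    n_shared_per_ct = round(
        cfg.identifier_overlap_fraction * cfg.proteins_per_cell_type
    )
    module_symbols = [
        [f"MOD{m}G{j}" for j in range(cfg.module_size)]
        for m in range(cfg.n_planted_modules)
    ]

    symbols_seen: dict[str, set[str]] = {"A": set(), "B": set()}

    def build_map(tag: str) -> DiseaseMap:
        diagrams = [Diagram("main", f"{tag} intercellular main", DiagramKind.INTERCELLULAR)]
        elements: list[Element] = []
        interactions: list[Interaction] = []
        seen = symbols_seen[tag]

        for ci in range(cfg.n_cell_types_per_map):
            shared_ct = ci < cfg.n_shared_cell_types
            ct = f"Shared cell {ci}" if shared_ct else f"{tag} cell {ci}"
            did = f"ct{ci}"
            diagrams.append(Diagram(did, ct, DiagramKind.PATHWAY, cell_type=ct))
            for pj in range(cfg.proteins_per_cell_type):
                if shared_ct and pj < n_shared_per_ct:
                    sym = f"SCT{ci}G{pj}"
                else:
                    sym = f"{tag}CT{ci}G{pj}"
                elements.append(_protein(f"{tag}.{did}.{sym}", sym, did, ct))
                seen.add(sym)

        # planted modules: directed interaction cycles in the main diagram
        for m, syms in enumerate(module_symbols):
            for sym in syms:
                elements.append(_protein(f"{tag}.main.{sym}", sym, "main", ""))
                seen.add(sym)
            n = len(syms)
            last = n - 1 if cfg.acyclic_modules else n
            for j in range(last):
                src, tgt = syms[j], syms[(j + 1) % n]
                interactions.append(
                    Interaction(
                        interaction_id=f"{tag}.mod{m}.i{j}",
                        diagram_id="main",
                        sources=(f"{tag}.main.{src}",),
                        targets=(f"{tag}.main.{tgt}",),
                        sign=Sign.POSITIVE,
                    )
                )

        # background: per-map vocabulary, arranged as one directed cycle
        n_bg = cfg.n_background_interactions
        bg_syms = [f"{tag}BGG{j}" for j in range(n_bg)]
        for sym in bg_syms:
            elements.append(_protein(f"{tag}.main.{sym}", sym, "main", ""))
            seen.add(sym)
        for j in range(n_bg):
            src, tgt = bg_syms[j], bg_syms[(j + 1) % n_bg]
            if src == tgt:
                continue
            interactions.append(
                Interaction(
                    interaction_id=f"{tag}.bg.i{j}",
                    diagram_id="main",
                    sources=(f"{tag}.main.{src}",),
                    targets=(f"{tag}.main.{tgt}",),
                    sign=Sign.UNKNOWN,
                )
            )

        m_ = DiseaseMap(
            map_id=f"SYN-{tag}",
            disease_label=f"synthetic disease {tag}",
            diagrams=diagrams,
            elements=elements,
            interactions=interactions,
        )
        return m_

    map_a = build_map("A")
    map_b = build_map("B")

    # corruption: replace participants of some planted map-B interactions
    # with fresh map-B-only symbols, severing their cross-map match
    corrupted: set[str] = set()
    if cfg.corruption_rate > 0:
        new_elements = list(map_b.elements)
        new_interactions = []
        counter = 0
        for i in map_b.interactions:
            if i.interaction_id.startswith("B.mod") and rng.random() < cfg.corruption_rate:
                fresh_src, fresh_tgt = f"BCORR{counter}", f"BCORR{counter + 1}"
                counter += 2
                for sym in (fresh_src, fresh_tgt):
                    new_elements.append(_protein(f"B.main.{sym}", sym, "main", ""))
                    symbols_seen["B"].add(sym)
                new_interactions.append(
                    Interaction(
                        interaction_id=i.interaction_id,
                        diagram_id=i.diagram_id,
                        sources=(f"B.main.{fresh_src}",),
                        targets=(f"B.main.{fresh_tgt}",),
                        sign=i.sign,
                    )
                )
                corrupted.add(i.interaction_id)
            else:
                new_interactions.append(i)
        map_b = DiseaseMap(
            map_id=map_b.map_id,
            disease_label=map_b.disease_label,
            diagrams=map_b.diagrams,
            elements=new_elements,
            interactions=new_interactions,
        )

    map_a.validate()
    map_b.validate()

    # truth bookkeeping, independent of the analysis code path
    shared_syms = symbols_seen["A"] & symbols_seen["B"]
    k, p = n_shared_per_ct, cfg.proteins_per_cell_type
    expected_j = k / (2 * p - k) if p else 0.0
    shared_cts = [
        (f"Shared cell {ci}", expected_j) for ci in range(cfg.n_shared_cell_types)
    ]
    pairs = [
        (
            f"mod{m}",
            tuple(
                f"A.mod{m}.i{j}"
                for j in range(cfg.module_size - (1 if cfg.acyclic_modules else 0))
            ),
            tuple(
                f"B.mod{m}.i{j}"
                for j in range(cfg.module_size - (1 if cfg.acyclic_modules else 0))
            ),
        )
        for m in range(cfg.n_planted_modules)
    ]
    druggable = {
        CanonicalId("HGNC", sym)
        for syms in module_symbols
        for sym in syms[: cfg.n_druggable_per_module]
        if sym in shared_syms
    }
    truth = TruthManifest(
        planted_module_pairs=pairs,
        shared_identifier_set=frozenset(
            CanonicalId("HGNC", s) for s in shared_syms
        ),
        shared_cell_types=shared_cts,
        druggable_shared_targets=frozenset(druggable),
        corrupted_interactions_b=frozenset(corrupted),
    )
    return map_a, map_b, truth


def write_drug_fixture(truth: TruthManifest, cfg: SimConfig, path: str | Path) -> None:
    """Drug–target TSV matching the generated pair: one synthetic drug per
    planted module, targeting that module's druggable symbols."""
    lines = ["drug_id\tdrug_name\tsource_db\ttarget_symbol\tevidence"]
    by_module: dict[str, list[str]] = {}
    for cid in sorted(truth.druggable_shared_targets):
        module = cid.value.split("G")[0]  # MOD<m>
        by_module.setdefault(module, []).append(cid.value)
    for module in sorted(by_module):
        drug_id = f"DB{module}"
        for target in by_module[module]:
            lines.append(f"{drug_id}\tdrug-{module.lower()}\tDRUGBANK\t{target}\t")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def evaluate_recovery(
    groups: Sequence[SimilarityGroup], truth: TruthManifest
) -> tuple[float, float]:
    """Module-level (precision, recall) of the grouping output.

    A planted module is recovered when some group contains at least half of
    its cross-map interaction pairs; a group is supported when it recovers
    some module.  Empty denominators yield 1.0 by convention.
    """
    module_pairs = {
        mid: set(zip(ids_a, ids_b))
        for mid, ids_a, ids_b in truth.planted_module_pairs
    }
    group_pairs = [
        {(m.interaction_a, m.interaction_b) for m in g.matches} for g in groups
    ]

    def covers(gp: set, mp: set) -> bool:
        return len(gp & mp) >= math.ceil(len(mp) / 2)

    recovered = sum(
        1 for mp in module_pairs.values() if any(covers(gp, mp) for gp in group_pairs)
    )
    supported = sum(
        1 for gp in group_pairs if any(covers(gp, mp) for mp in module_pairs.values())
    )
    precision = supported / len(groups) if groups else 1.0
    recall = recovered / len(module_pairs) if module_pairs else 1.0
    return precision, recall
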