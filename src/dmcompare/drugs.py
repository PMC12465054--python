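"""Projection of drug–target tables onto similarity groups.

Drug data is consumed from TSV files only (columns: drug_id, drug_name,
source_db, target_symbol, evidence); nothing is fetched live.  "Target in
group" means the canonical identifier participates in any interaction of
either component of the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .grouping import SimilarityGroup
from .model import CanonicalId

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("drug_id", "drug_name", "source_db", "target_symbol")
KNOWN_SOURCES = ("DRUGBANK", "CHEMBL", "OTHER")


class DrugTableError(ValueError):
    pass


@dataclass(frozen=True)
class DrugTargetRecord:
    drug_name: str
    drug_id: str
    source_db: str
    target: CanonicalId
    evidence: Optional[str] = None


@dataclass(frozen=True)
class GroupDrugReport:
    group_id: str
    targets_in_group: frozenset[CanonicalId]
    drugs: tuple[tuple[str, frozenset[CanonicalId]], ...]  # (drug_id, targets hit)


def load_drug_targets(path: str | Path) -> list[DrugTargetRecord]:
    """Load, validate, and deduplicate a drug–target TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DrugTableError(f"{path}: missing required columns {missing}")

    records: list[DrugTargetRecord] = []
    seen: set[tuple[str, CanonicalId]] = set()
    for rownum, row in enumerate(df.itertuples(index=False), 2):
        target = str(row.target_symbol).strip().upper()
        if not target:
            raise DrugTableError(f"{path}: row {rownum}: empty target_symbol")
        source = str(row.source_db).strip().upper()
        if source not in KNOWN_SOURCES:
            logger.warning(
                "%s: row %d: unknown source_db %r mapped to OTHER", path, rownum, source
            )
            source = "OTHER"
        cid = CanonicalId("HGNC", target)
        key = (str(row.drug_id), cid)
        if key in seen:
            logger.warning("%s: row %d: duplicate (drug, target) pair", path, rownum)
            continue
        seen.add(key)
        evidence = getattr(row, "evidence", "") or None
        records.append(
            DrugTargetRecord(
                drug_name=str(row.drug_name),
                drug_id=str(row.drug_id),
                source_db=source,
                target=cid,
                evidence=evidence,
            )
        )
    return records


def shared_drug_targets(
    groups: Sequence[SimilarityGroup], records: Sequence[DrugTargetRecord]
) -> set[CanonicalId]:
    """Identifiers present on both sides of some group and targeted by a drug."""
    both_sides: set[CanonicalId] = set()
    for g in groups:
        both_sides |= g.element_ids_a() & g.element_ids_b()
    targeted = {r.target for r in records}
    return both_sides & targeted


def group_drug_reports(
    groups: Sequence[SimilarityGroup],
    records: Sequence[DrugTargetRecord],
    min_targets_per_group: int = 2,
) -> list[GroupDrugReport]:
    """Per group, the drugs hitting at least *min_targets_per_group* targets
    within that group's interactions.  Deterministic ordering by group id
    then drug id."""
    by_drug: dict[str, set[CanonicalId]] = {}
    for r in records:
        by_drug.setdefault(r.drug_id, set()).add(r.target)

    reports: list[GroupDrugReport] = []
    for g in sorted(groups, key=lambda g: g.group_id):
        group_ids = g.element_ids_a() | g.element_ids_b()
        drugs = []
        for drug_id in sorted(by_drug):
            hit = frozenset(by_drug[drug_id] & group_ids)
            if len(hit) >= min_targets_per_group:
                drugs.append((drug_id, hit))
        # witness check: every reported pair is backed by enough in-group targets
        assert all(len(hit) >= min_targets_per_group for _, hit in drugs)
        reports.append(
            GroupDrugReport(
                group_id=g.group_id,
                targets_in_group=frozenset(group_ids & {r.target for r in records}),
                drugs=tuple(drugs),
            )
        )
    return reports


def reports_to_frame(reports: Sequence[GroupDrugReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for drug_id, hit in rep.drugs:
            rows.append(
                {
                    "group_id": rep.group_id,
                    "drug_id": drug_id,
                    "n_targets_in_group": len(hit),
                    "targets": ",".join(sorted(c.value for c in hit)),
                }
            )
    return pd.DataFrame(
        rows, columns=["group_id", "drug_id", "n_targets_in_group", "targets"]
    )


def reports_to_json(reports: Sequence[GroupDrugReport]) -> dict:
    return {
        "n_groups": len(reports),
        "groups": [
            {
                "group_id": rep.group_id,
                "targets_in_group": sorted(c.value for c in rep.targets_in_group),
                "drugs": [
                    {"drug_id": d, "targets": sorted(c.value for c in hit)}
                    for d, hit in rep.drugs
                ],
            }
            for rep in reports
        ],
    }
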