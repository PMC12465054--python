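"""End-to-end comparison run: loads two maps, executes every stage, writes
stage outputs plus a combined JSON report.

Two runs on identical inputs and config produce identical outputs (the
report carries no timestamp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

from . import __version__
from .drugs import (
    group_drug_reports,
    load_drug_targets,
    reports_to_frame,
    reports_to_json,
    shared_drug_targets,
)
from .grouping import (
    disease_specific_clusters,
    find_similarity_groups,
    group_coverage,
    element_group_frequency,
    groups_to_frame,
    groups_to_report,
)
from .identifiers import (
    cell_type_profiles,
    diagram_overlap_matrix,
    disease_specific_identifiers,
    jaccard_matrix,
    jaccard_to_frame,
    overlap_to_frame,
    shared_identifiers,
    symbol_incidence,
    unique_identifiers,
)
from .matching import ComparisonConfig, match_interactions, matches_to_frame
from .model import MapFormat, load_map, summarize

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(doc: dict, path: Path) -> None:
    path.write_text(
        json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def run_compare(
    map_a_path: str | Path,
    map_b_path: str | Path,
    cfg: Optional[ComparisonConfig] = None,
    out_dir: str | Path = ".",
    format: MapFormat = MapFormat.NATIVE,
    drug_table: Optional[str | Path] = None,
) -> dict:
    """Run the full comparison and write all stage outputs under *out_dir*.

    Returns the run report (also written as ``report.json``).
    """
    cfg = cfg or ComparisonConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    map_a = load_map(map_a_path, format)
    map_b = load_map(map_b_path, format)

    # identifiers
    ua, ub = unique_identifiers(map_a), unique_identifiers(map_b)
    shared = shared_identifiers(map_a, map_b)
    only_a, only_b = disease_specific_identifiers(map_a, map_b)
    for name, ids in (
        ("identifiers_shared.tsv", shared),
        (f"identifiers_only_{map_a.map_id}.tsv", only_a),
        (f"identifiers_only_{map_b.map_id}.tsv", only_b),
    ):
        (out / name).write_text(
            "identifier\n" + "".join(f"{c}\n" for c in sorted(str(x) for x in ids)),
            encoding="utf-8",
        )

    overlaps = diagram_overlap_matrix(map_a, map_b, cfg.min_diagram_overlap)
    overlap_to_frame(overlaps).to_csv(out / "diagram_overlap.tsv", sep="\t", index=False)

    incidence = symbol_incidence(map_a, map_b)
    incidence.replace({True: "v", False: ""}).to_csv(out / "symbol_incidence.tsv", sep="\t")

    prof_a, prof_b = cell_type_profiles(map_a), cell_type_profiles(map_b)
    cells = jaccard_matrix(prof_a, prof_b, cfg.omit_threshold)
    jaccard_to_frame(cells).to_csv(out / "jaccard.tsv", sep="\t", index=False)

    # interaction matching and grouping
    matches = match_interactions(map_a, map_b, cfg)
    matches_to_frame(matches, map_a, map_b).to_csv(out / "matches.tsv", sep="\t", index=False)

    groups = find_similarity_groups(map_a, map_b, matches, cfg)
    groups_to_frame(groups).to_csv(out / "groups.tsv", sep="\t", index=False)
    _write_json(groups_to_report(groups, cfg.component_mode), out / "groups.json")

    cov = group_coverage(groups, map_a, map_b)
    freq = element_group_frequency(groups, map_a, map_b)
    (out / "element_group_frequency.tsv").write_text(
        "identifier\tn_groups\n"
        + "".join(f"{cid}\t{n}\n" for cid, n in freq),
        encoding="utf-8",
    )

    spec_a = disease_specific_clusters(map_a, matches, "a", cfg)
    spec_b = disease_specific_clusters(map_b, matches, "b", cfg)
    for name, sccs in (("clusters_specific_a.tsv", spec_a), ("clusters_specific_b.tsv", spec_b)):
        (out / name).write_text(
            "scc_id\tsize\tmembers\n"
            + "".join(
                f"{s.scc_id}\t{len(s.members)}\t{','.join(sorted(s.members))}\n"
                for s in sccs
            ),
            encoding="utf-8",
        )

    report: dict = {
        "tool_version": __version__,
        "config": asdict(cfg),
        "inputs": {
            "map_a": {"path": str(map_a_path), "sha256": _sha256(map_a_path)},
            "map_b": {"path": str(map_b_path), "sha256": _sha256(map_b_path)},
        },
        "summary_a": asdict(summarize(map_a)),
        "summary_b": asdict(summarize(map_b)),
        "identifiers": {
            "unique_a": len(ua),
            "unique_b": len(ub),
            "shared": len(shared),
            "only_a": len(only_a),
            "only_b": len(only_b),
        },
        "diagram_overlaps": len(overlaps),
        "n_matches": len(matches),
        "n_groups": len(groups),
        "coverage": {
            "covered_a": cov[0], "total_a": cov[1],
            "covered_b": cov[2], "total_b": cov[3],
        },
        "n_specific_clusters_a": len(spec_a),
        "n_specific_clusters_b": len(spec_b),
        "component_mode": cfg.component_mode,
    }

    if drug_table is not None:
        records = load_drug_targets(drug_table)
        shared_targets = shared_drug_targets(groups, records)
        drug_reports = group_drug_reports(groups, records)
        reports_to_frame(drug_reports).to_csv(out / "drugs.tsv", sep="\t", index=False)
        _write_json(reports_to_json(drug_reports), out / "drugs.json")
        report["drugs"] = {
            "n_records": len(records),
            "n_shared_targets": len(shared_targets),
            "shared_targets": sorted(c.value for c in shared_targets),
        }

    _write_json(report, out / "report.json")
    return report
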