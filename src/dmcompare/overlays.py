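"""MINERVA-dialect data overlays from variant gene lists and expression tables.

Overlay files are TSV with ``#NAME=<name>`` / ``#TYPE=<type>`` header lines
followed by ``name<TAB>value`` (plus ``color`` when any entry carries one).
All values lie in [-1, 1]; log fold changes are max-abs scaled per dataset so
sign and zero are preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: Qualitative presence color for variant overlays.
VARIANT_COLOR = "#0000FF"


class OverlayError(ValueError):
    pass


@dataclass(frozen=True)
class OverlayEntry:
    label: str
    identifier: tuple[str, str]  # (namespace, value), namespace == "HGNC"
    value: float
    color: Optional[str] = None

    def __post_init__(self) -> None:
        ns, val = self.identifier
        if not val:
            raise OverlayError("overlay entry identifier value must be non-empty")
        if not -1.0 <= self.value <= 1.0:
            raise OverlayError(
                f"overlay value {self.value!r} for {val!r} outside [-1, 1]"
            )


@dataclass
class Overlay:
    name: str
    type_tag: str = "GENERIC"
    entries: list[OverlayEntry] = field(default_factory=list)


def variant_overlay(gene_list: Sequence[str], name: str) -> Overlay:
    """Qualitative presence overlay: one entry per distinct symbol, value 1."""
    symbols = []
    seen = set()
    for raw in gene_list:
        sym = raw.strip().upper()
        if sym and sym not in seen:
            seen.add(sym)
            symbols.append(sym)
    if not symbols:
        raise OverlayError("variant gene list is empty")
    return Overlay(
        name=name,
        type_tag="GENETIC_VARIANT",
        entries=[
            OverlayEntry(sym, ("HGNC", sym), 1.0, VARIANT_COLOR) for sym in symbols
        ],
    )


def scale_log_fold_changes(
    values: Iterable[tuple[str, float]]
) -> list[tuple[str, float]]:
    """Max-abs scale log fold changes into [-1, 1].

    ``scaled = lfc / max|lfc|`` over the dataset; sign and zero are
    preserved, and the transform is invariant under positive rescaling of
    the input.  Non-finite values are dropped with a warning; an all-zero
    input stays all zero.
    """
    clean: list[tuple[str, float]] = []
    for sym, lfc in values:
        if not math.isfinite(lfc):
            logger.warning("dropping non-finite log fold change for %r: %r", sym, lfc)
            continue
        clean.append((sym, float(lfc)))
    if not clean:
        raise OverlayError("no finite log fold change values")
    max_abs = max(abs(v) for _, v in clean)
    if max_abs == 0.0:
        return [(sym, 0.0) for sym, _ in clean]
    return [(sym, v / max_abs) for sym, v in clean]


def expression_overlay(
    values: Iterable[tuple[str, float]], name: str
) -> Overlay:
    """Diverging expression overlay from (symbol, log fold change) rows.

    Duplicate symbols keep the value of largest magnitude (strongest
    signal), logged; values are max-abs scaled.
    """
    best: dict[str, float] = {}
    order: list[str] = []
    for raw, lfc in values:
        sym = raw.strip().upper()
        if not sym:
            continue
        if sym in best:
            if abs(lfc) > abs(best[sym]):
                logger.info("duplicate symbol %s: keeping larger-magnitude value", sym)
                best[sym] = lfc
        else:
            best[sym] = lfc
            order.append(sym)
    scaled = dict(scale_log_fold_changes([(s, best[s]) for s in order]))
    return Overlay(
        name=name,
        type_tag="EXPRESSION",
        entries=[
            OverlayEntry(s, ("HGNC", s), scaled[s]) for s in order if s in scaled
        ],
    )


def write_overlay(o: Overlay, path: str | Path) -> None:
    """Write *o* as a MINERVA data-overlay TSV; byte-stable across runs."""
    seen = set()
    for e in o.entries:
        if not -1.0 <= e.value <= 1.0:
            raise OverlayError(
                f"overlay value {e.value!r} for {e.identifier[1]!r} outside [-1, 1]"
            )
        if e.identifier in seen:
            raise OverlayError(f"duplicate overlay identifier {e.identifier!r}")
        seen.add(e.identifier)
    with_color = any(e.color for e in o.entries)
    lines = [f"#NAME={o.name}", f"#TYPE={o.type_tag}"]
    lines.append("name\tvalue\tcolor" if with_color else "name\tvalue")
    for e in o.entries:
        row = f"{e.identifier[1]}\t{e.value:g}"
        if with_color:
            row += f"\t{e.color or ''}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_overlay(path: str | Path) -> Overlay:
    """Parse an overlay TSV written by :func:`write_overlay`."""
    name, type_tag = "", "GENERIC"
    entries: list[OverlayEntry] = []
    header: Optional[list[str]] = None
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip():
            continue
        if line.startswith("#NAME="):
            name = line[len("#NAME="):]
            continue
        if line.startswith("#TYPE="):
            type_tag = line[len("#TYPE="):]
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            continue
        try:
            sym = cells[header.index("name")]
            value = float(cells[header.index("value")])
            color = None
            if "color" in header and len(cells) > header.index("color"):
                color = cells[header.index("color")] or None
        except (ValueError, IndexError) as exc:
            raise OverlayError(f"{path}:{lineno}: malformed row {line!r}") from exc
        entries.append(OverlayEntry(sym, ("HGNC", sym), value, color))
    return Overlay(name=name, type_tag=type_tag, entries=entries)
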