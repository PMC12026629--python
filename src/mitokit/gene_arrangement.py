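"""Circular adjacency census: intergenic spacers, gene overlaps, gene order.

On a circular genome every feature has a successor in plus-strand start
order, including the wrap-around pair from the last feature back to the
first.  The signed gap between consecutive features is

    gap = next.start - prev.end - 1        (modulo genome length)

so a positive gap is an intergenic spacer, a negative gap an overlap, and
zero means the features abut.  The wrap-around gap is attributed to the
last feature's row, matching the convention of published gene tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .genome_model import AnnotatedGenome, feature_length

__all__ = [
    "AdjacencyRecord",
    "ArrangementSummary",
    "adjacency_census",
    "summarize_arrangement",
    "gene_order_signature",
]


@dataclass(frozen=True)
class AdjacencyRecord:
    upstream_gene: str
    downstream_gene: str
    gap: int  # bp; positive = spacer, negative = overlap, 0 = abutting


def adjacency_census(ag: AnnotatedGenome) -> list[AdjacencyRecord]:
    """One record per consecutive feature pair, including the wrap-around.

    Features are chained in plus-strand start order (stable order by
    (start, end, name) under ties, with a warning when coordinates are
    identical).  Features nested inside others are chained like any other;
    their gaps may be strongly negative.
    """
    feats = ag.features
    if len(feats) < 2:
        raise ValueError("adjacency census needs at least 2 features")
    for a, b in zip(feats, feats[1:]):
        if (a.start, a.end) == (b.start, b.end):
            warnings.warn(
                f"identical coordinates for {a.name} and {b.name}: "
                "order is ambiguous, using stable (start, end, name) order"
            )
    L = len(ag.genome)
    records = []
    for prev, nxt in zip(feats, feats[1:]):
        records.append(
            AdjacencyRecord(prev.name, nxt.name, nxt.start - prev.end - 1)
        )
    last, first = feats[-1], feats[0]
    wrap_gap = (first.start + L) - last.end - 1
    if wrap_gap >= L:
        wrap_gap -= L  # single feature ring or fully covered circle
    records.append(AdjacencyRecord(last.name, first.name, wrap_gap))
    return records


@dataclass(frozen=True)
class ArrangementSummary:
    n_spacers: int
    spacer_range: Optional[tuple[int, int]]  # (min, max) over positive gaps
    n_overlaps: int
    overlap_range: Optional[tuple[int, int]]  # (min, max) over |negative gaps|
    largest_spacer: Optional[AdjacencyRecord]
    largest_overlap: Optional[AdjacencyRecord]


def summarize_arrangement(records: list[AdjacencyRecord]) -> ArrangementSummary:
    """Spacer/overlap counts, size ranges and extremal pairs."""
    spacers = [r for r in records if r.gap > 0]
    overlaps = [r for r in records if r.gap < 0]
    return ArrangementSummary(
        n_spacers=len(spacers),
        spacer_range=(min(r.gap for r in spacers), max(r.gap for r in spacers))
        if spacers
        else None,
        n_overlaps=len(overlaps),
        overlap_range=(
            min(-r.gap for r in overlaps),
            max(-r.gap for r in overlaps),
        )
        if overlaps
        else None,
        largest_spacer=max(spacers, key=lambda r: r.gap) if spacers else None,
        largest_overlap=min(overlaps, key=lambda r: r.gap) if overlaps else None,
    )


def gene_order_signature(ag: AnnotatedGenome) -> str:
    """Canonical signed gene-order string of a circular annotation.

    Genes are listed in plus-strand start order, minus-strand genes
    prefixed with ``-``.  The rotation is canonicalized to start at
    ``cox1`` when present (the conventional anchor for mitogenome
    arrangements), otherwise at the lexicographically minimal rotation,
    so rotated copies of the same annotation yield identical signatures.
    Duplicate names are suffixed ``.2``, ``.3``, ... deterministically.
    """
    names = []
    seen: dict[str, int] = {}
    for f in ag.features:
        n = seen.get(f.name, 0) + 1
        seen[f.name] = n
        label = f.name if n == 1 else f"{f.name}.{n}"
        names.append(("-" if f.strand == "-" else "") + label)
    anchor = None
    for i, label in enumerate(names):
        if label.lstrip("-") == "cox1":
            anchor = i
            break
    if anchor is None:
        rotations = [names[i:] + names[:i] for i in range(len(names))]
        return " ".join(min(rotations))
    return " ".join(names[anchor:] + names[:anchor])
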