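"""Base composition and strand-skew statistics.

Strand compositional asymmetry is summarized by

    AT-skew = (A - T) / (A + T)
    GC-skew = (G - C) / (G + C)

computed from unrounded base counts.  Per-gene and pooled-category rows are
computed on each feature's sense (coding) strand; the whole-genome and
control-region rows on the deposited plus strand.  N bases count toward a
partition's size but are excluded from composition numerators and
denominators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .genome_model import AnnotatedGenome

__all__ = [
    "CompositionStats",
    "UndefinedCompositionError",
    "base_composition",
    "skew",
    "partition_report",
    "format_composition_table",
]

PARTITION_ORDER = ("Mitogenome", "PCGs", "tRNAs", "rRNAs", "Control region")


class UndefinedCompositionError(ValueError):
    """Raised when a sequence has no countable (non-N) positions."""


def skew(x_count: float, y_count: float) -> float:
    """(x - y) / (x + y); NaN when the denominator is zero."""
    total = x_count + y_count
    if total == 0:
        return math.nan
    return (x_count - y_count) / total


@dataclass(frozen=True)
class CompositionStats:
    """Composition of one partition (a gene, a pooled category, or the genome).

    Percentages and skews are stored unrounded; rounding to the customary
    display precision (1 decimal for percentages, 3 for skews) happens only
    in :func:`format_composition_table`.
    """

    partition_name: str
    size: int
    counts: dict[str, int]

    @property
    def n_counted(self) -> int:
        return sum(self.counts.values())

    def pct(self, base: str) -> float:
        return 100.0 * self.counts[base] / self.n_counted

    @property
    def pct_A(self) -> float:
        return self.pct("A")

    @property
    def pct_C(self) -> float:
        return self.pct("C")

    @property
    def pct_G(self) -> float:
        return self.pct("G")

    @property
    def pct_T(self) -> float:
        return self.pct("T")

    @property
    def at_content(self) -> float:
        return self.pct_A + self.pct_T

    @property
    def at_skew(self) -> float:
        return skew(self.counts["A"], self.counts["T"])

    @property
    def gc_skew(self) -> float:
        return skew(self.counts["G"], self.counts["C"])


def base_composition(seq: str, name: str = "") -> CompositionStats:
    """Count A/C/G/T over the non-N positions of ``seq``.

    A zero-denominator skew (e.g. GC-skew of an AT-only sequence) is
    reported as NaN with a warning rather than raised, so that whole tables
    can still be produced.
    """
    if not seq:
        raise UndefinedCompositionError(f"{name or 'sequence'} is empty")
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in "ACGT"}
    if sum(counts.values()) == 0:
        raise UndefinedCompositionError(
            f"{name or 'sequence'} has no non-N positions"
        )
    stats = CompositionStats(partition_name=name, size=len(seq), counts=counts)
    if counts["A"] + counts["T"] == 0:
        warnings.warn(f"{name or 'sequence'}: AT-skew undefined (A+T = 0)")
    if counts["G"] + counts["C"] == 0:
        warnings.warn(f"{name or 'sequence'}: GC-skew undefined (G+C = 0)")
    return stats


def _pooled(ag: AnnotatedGenome, category: str) -> str:
    return "".join(ag.sense_sequence(f) for f in ag.by_category(category))


def partition_report(ag: AnnotatedGenome) -> list[CompositionStats]:
    """Composition rows for the standard mitogenome partitions.

    Row order: whole mitogenome (plus strand); pooled PCGs (sense strands,
    annotation order); each PCG; pooled tRNAs; pooled rRNAs; control region.
    Pooled categories concatenate each feature's full sense sequence, so
    bases shared by overlapping genes are counted once per gene and pooled
    sizes equal the sum of the annotated gene lengths.
    """
    rows = [base_composition(ag.genome.sequence, "Mitogenome")]
    pcgs = ag.by_category("PCG")
    if pcgs:
        rows.append(base_composition(_pooled(ag, "PCG"), "PCGs"))
        for f in pcgs:
            rows.append(base_composition(ag.sense_sequence(f), f.name))
    else:
        warnings.warn("no PCG features: PCG rows omitted")
    for category, label in (("tRNA", "tRNAs"), ("rRNA", "rRNAs")):
        seq = _pooled(ag, category)
        if seq:
            rows.append(base_composition(seq, label))
        else:
            warnings.warn(f"no {category} features: {label} row omitted")
    cr = ag.by_category("CR")
    if cr:
        rows.append(base_composition(ag.sense_sequence(cr[0]), "Control region"))
    else:
        warnings.warn("no control region: CR row omitted")
    return rows


def _fmt_skew(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.3f}"


def format_composition_table(rows: list[CompositionStats]) -> str:
    """TSV with columns Partition, Size, T, C, A, G, A+T, AT-skew, GC-skew."""
    out = ["Partition\tSize (bp)\tT (%)\tC (%)\tA (%)\tG (%)\tA+T (%)\tAT-skew\tGC-skew"]
    for r in rows:
        out.append(
            f"{r.partition_name}\t{r.size}\t{r.pct_T:.1f}\t{r.pct_C:.1f}\t"
            f"{r.pct_A:.1f}\t{r.pct_G:.1f}\t{r.at_content:.1f}\t"
            f"{_fmt_skew(r.at_skew)}\t{_fmt_skew(r.gc_skew)}"
        )
    return "\n".join(out) + "\n"
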