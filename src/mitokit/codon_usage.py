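"""Codon extraction, codon counting, and relative synonymous codon usage.

Works under any NCBI translation table (default 5, the invertebrate
mitochondrial code, where AGA/AGG code for serine, AUA for methionine and
UGA for tryptophan).  Codons are reported in the RNA alphabet.

Mitochondrial CDSs commonly end on an incomplete stop codon — a terminal
``T`` or ``TA`` completed to ``TAA`` by post-transcriptional
polyadenylation.  Such trailing nucleotides are reported in the customary
parenthesized form (``"T(AA)"``) and excluded from codon counts; complete
terminal stop codons are counted.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

from .genome_model import AnnotatedGenome, CircularGenome, GeneFeature, extract_sense_sequence

__all__ = [
    "GeneticCode",
    "CodonCountTable",
    "extract_codons",
    "pooled_codon_counts",
    "rscu",
    "start_stop_table",
    "StartStopRow",
    "format_codon_table",
]

_RNA_BASES = "UCAG"
# UUU, UUC, UUA, UUG, UCU, ... — the classic codon-table reading order
ALL_CODONS = [a + b + c for a in _RNA_BASES for b in _RNA_BASES for c in _RNA_BASES]
DISPLAY_ORDER = ALL_CODONS


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with its synonymous-codon families.

    ``families`` partitions all 64 RNA codons by translation product, with
    the stop codons forming one family (labelled ``"*"``).
    """

    table_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_rna_by_id[table_id]
        mapping = dict(t.forward_table)
        for c in t.stop_codons:
            mapping[c] = "*"
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


CodonCountTable = dict  # codon (RNA alphabet) -> non-negative count


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_codons(
    genome: CircularGenome, pcg: GeneFeature, code: Optional[GeneticCode] = None
) -> tuple[list[str], str, str]:
    """Split a protein-coding gene's sense sequence into codons.

    Returns ``(codons, start_codon, stop_codon)``.  ``codons`` contains all
    complete triplets (RNA alphabet) including a complete terminal stop;
    ``start_codon`` is the first triplet (DNA alphabet, matching annotation
    conventions) and ``stop_codon`` is either the final complete triplet or
    the incomplete parenthesized form built from the trailing 1-2 nt.
    """
    if pcg.category != "PCG":
        raise ValueError(f"{pcg.name} is not a protein-coding gene")
    sense = extract_sense_sequence(genome, pcg)
    if len(sense) < 6:
        raise ValueError(f"{pcg.name}: CDS of {len(sense)} nt is too short")
    n_full = len(sense) // 3
    tail = len(sense) - 3 * n_full
    codons = [_to_rna(sense[3 * i : 3 * i + 3]) for i in range(n_full)]
    start = sense[:3].upper()
    if tail:
        trailing = sense[3 * n_full :].upper()
        stop = f"{trailing}({'A' * (3 - tail)})"
    else:
        stop = codons[-1].replace("U", "T")
    return codons, start, stop


def pooled_codon_counts(
    ag: AnnotatedGenome, code: Optional[GeneticCode] = None
) -> CodonCountTable:
    """Sum codon counts over all protein-coding genes (RNA alphabet)."""
    counts: Counter = Counter()
    for f in ag.by_category("PCG"):
        codons, _, _ = extract_codons(ag.genome, f, code)
        counts.update(codons)
    return dict(counts)


def rscu(counts: CodonCountTable, code: Optional[GeneticCode] = None) -> dict[str, float]:
    """Relative synonymous codon usage.

    For codon *c* in synonymous family *F*:
    ``RSCU(c) = count(c) * |F| / sum of counts over F`` — the observed count
    divided by the count expected under uniform usage within the family.
    Stop codons form a family like any other.  A family with zero total gets
    RSCU 0 for all members, with a warning.
    """
    if code is None:
        code = GeneticCode.from_table_id(5)
    unknown = set(counts) - set(ALL_CODONS)
    if unknown:
        raise ValueError(f"unknown codon keys: {sorted(unknown)}")
    values: dict[str, float] = {}
    for aa, family in code.families.items():
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            warnings.warn(f"family {aa}: zero total count, RSCU set to 0")
            for c in family:
                values[c] = 0.0
        else:
            for c in family:
                values[c] = counts.get(c, 0) * len(family) / total
    return values


@dataclass(frozen=True)
class StartStopRow:
    gene: str
    start_codon: str
    stop_codon: str

    @property
    def incomplete_stop(self) -> bool:
        return "(" in self.stop_codon


@dataclass
class StartStopTable:
    rows: list[StartStopRow]

    def start_counts(self) -> Counter:
        return Counter(r.start_codon for r in self.rows)

    def stop_counts(self) -> Counter:
        return Counter(r.stop_codon for r in self.rows)

    @property
    def n_incomplete(self) -> int:
        return sum(1 for r in self.rows if r.incomplete_stop)

    def genes_with_stop(self, stop: str) -> list[str]:
        return [r.gene for r in self.rows if r.stop_codon == stop]

    def genes_with_start(self, start: str) -> list[str]:
        return [r.gene for r in self.rows if r.start_codon == start]


def start_stop_table(
    ag: AnnotatedGenome, code: Optional[GeneticCode] = None
) -> StartStopTable:
    """Observed start and stop codon of every protein-coding gene."""
    rows = []
    for f in ag.by_category("PCG"):
        _, start, stop = extract_codons(ag.genome, f, code)
        rows.append(StartStopRow(gene=f.name, start_codon=start, stop_codon=stop))
    return StartStopTable(rows=rows)


def format_codon_table(
    counts: CodonCountTable, code: Optional[GeneticCode] = None
) -> str:
    """TSV codon report (Codon, AA, Count, RSCU) in standard display order."""
    if code is None:
        code = GeneticCode.from_table_id(5)
    values = rscu(counts, code)
    out = ["Codon\tAA\tCount\tRSCU"]
    for codon in DISPLAY_ORDER:
        out.append(
            f"{codon}\t{code.translate(codon)}\t{counts.get(codon, 0)}\t"
            f"{values[codon]:.2f}"
        )
    return "\n".join(out) + "\n"
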