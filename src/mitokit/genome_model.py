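"""Circular-genome data model and strand/wrap-aware sequence extraction.

Coordinates are 1-based inclusive everywhere in the public API, matching the
convention of published mitogenome gene tables.  A feature that spans the
origin of the circle is expressed with ``start > end`` on the plus strand;
its length is ``(genome_length - start + 1) + end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "CircularGenome",
    "GeneFeature",
    "AnnotatedGenome",
    "CoordinateError",
    "ValidationIssue",
    "ValidationReport",
    "reverse_complement",
    "extract_sense_sequence",
    "feature_length",
    "validate_annotation",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "CR")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class CoordinateError(ValueError):
    """A feature's coordinates fall outside the genome."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA molecule.

    Parameters
    ----------
    sequence
        Plus-strand sequence over the alphabet A/C/G/T/N.  ``U`` is accepted
        on input and normalized to ``T``.
    """

    sequence: str
    topology: str = "circular"

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid characters in genome sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a circular genome.

    ``start``/``end`` are 1-based inclusive plus-strand coordinates;
    ``start > end`` means the feature wraps the origin.  ``anticodon`` is the
    anticodon triplet as DNA text for tRNA features.  ``start_codon`` and
    ``stop_codon`` carry the annotated codons when known (stop possibly in
    the incomplete form ``"T(AA)"``); they are annotation metadata, verified
    against the sequence by :func:`validate_annotation`.
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.name}: coordinates must be >= 1 (got {self.start}..{self.end})"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end


def feature_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length``."""
    _check_coords(feature, genome_length)
    if feature.wraps:
        return (genome_length - feature.start + 1) + feature.end
    return feature.end - feature.start + 1


def _check_coords(feature: GeneFeature, genome_length: int) -> None:
    if feature.start > genome_length or feature.end > genome_length:
        raise CoordinateError(
            f"{feature.name}: {feature.start}..{feature.end} exceeds genome "
            f"length {genome_length}"
        )


def extract_sense_sequence(genome: CircularGenome, feature: GeneFeature) -> str:
    """Sequence of a feature on its coding (sense) strand.

    For a plus-strand feature this is the plus-strand substring
    ``start..end`` (wrapping the origin when ``start > end``); for a
    minus-strand feature it is the reverse complement of that substring.
    """
    _check_coords(feature, len(genome))
    seq = genome.sequence
    if feature.wraps:
        sub = seq[feature.start - 1 :] + seq[: feature.end]
    else:
        sub = seq[feature.start - 1 : feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub


@dataclass
class AnnotatedGenome:
    """A circular genome plus its ordered gene features.

    Features are kept sorted by plus-strand start position (then end, then
    name, for a stable order under duplicated starts).  At most one control
    region (category ``CR``) is permitted.
    """

    genome: CircularGenome
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        for f in self.features:
            _check_coords(f, len(self.genome))
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))
        n_cr = sum(1 for f in self.features if f.category == "CR")
        if n_cr > 1:
            raise ValueError(f"at most one control region allowed, found {n_cr}")

    def __len__(self) -> int:
        return len(self.genome)

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def sense_sequence(self, feature: GeneFeature) -> str:
        return extract_sense_sequence(self.genome, feature)


@dataclass(frozen=True)
class ValidationIssue:
    gene: str
    level: str  # "WARN" | "FAIL"
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]
    n_plus: int
    n_minus: int
    n_checked: int

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.level == "WARN")

    @property
    def n_failures(self) -> int:
        return sum(1 for i in self.issues if i.level == "FAIL")

    @property
    def passed(self) -> bool:
        return self.n_failures == 0


def validate_annotation(ag: AnnotatedGenome, code=None) -> ValidationReport:
    """Verify annotated start/stop codons of every protein-coding gene.

    For each PCG the annotated start codon is compared with the first sense
    triplet and the annotated stop codon with the final (possibly
    incomplete) triplet.  A mismatch is a FAIL.  A start codon that is not
    among the genetic code's initiation codons (for example the published
    ``CAA`` start of *cox1* in some caridean shrimps) is a WARN, not a
    failure.  The report also counts features per strand.
    """
    from . import codon_usage  # deferred: avoids an import cycle

    if code is None:
        code = codon_usage.GeneticCode.from_table_id(5)
    issues: list[ValidationIssue] = []
    n_checked = 0
    for f in ag.features:
        if f.category != "PCG":
            continue
        n_checked += 1
        codons, start, stop = codon_usage.extract_codons(ag.genome, f, code)
        start_dna = start.replace("U", "T")
        if f.start_codon and f.start_codon.upper() != start_dna:
            issues.append(
                ValidationIssue(
                    f.name,
                    "FAIL",
                    "START_MISMATCH",
                    f"annotated start {f.start_codon} but sequence reads {start_dna}",
                )
            )
        if start_dna.replace("T", "U") not in code.start_codons:
            issues.append(
                ValidationIssue(
                    f.name,
                    "WARN",
                    "NONSTD_START",
                    f"nonstandard start codon {start_dna}",
                )
            )
        if f.stop_codon:
            annotated = f.stop_codon.upper()
            if annotated != stop.replace("U", "T"):
                issues.append(
                    ValidationIssue(
                        f.name,
                        "FAIL",
                        "STOP_MISMATCH",
                        f"annotated stop {annotated} but sequence reads {stop}",
                    )
                )
        if "(" not in stop and stop.replace("T", "U") not in code.stop_codons:
            issues.append(
                ValidationIssue(
                    f.name, "WARN", "NONSTD_STOP", f"non-stop final codon {stop}"
                )
            )
    n_minus = sum(1 for f in ag.features if f.strand == "-")
    return ValidationReport(
        issues=issues,
        n_plus=len(ag.features) - n_minus,
        n_minus=n_minus,
        n_checked=n_checked,
    )
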