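"""Reading and writing the formats the pipeline touches.

FASTA and GenBank flat files go through Biopython; gene tables and reports
are plain TSV (tab-separated, UTF-8, ASCII ``-`` for the minus strand).
Coordinates are 1-based inclusive at every interface.  A feature spanning
the origin of the circular genome appears in GenBank as a
``join(a..L,1..b)`` location and internally as ``start > end``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import gene_arrangement
from .genome_model import (
    AnnotatedGenome,
    CircularGenome,
    CoordinateError,
    GeneFeature,
    feature_length,
)

__all__ = [
    "FormatError",
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "write_genbank",
    "write_gene_table",
    "read_gene_table",
    "normalize_gene_name",
]


class FormatError(ValueError):
    pass


# Both spellings of several mitochondrial genes circulate in annotations
# and in the literature (e.g. COI vs cox1, 16S vs rrnL); normalize to the
# lower-case short forms used throughout this package.
GENE_ALIASES = {
    "coi": "cox1", "cox1": "cox1", "co1": "cox1",
    "coii": "cox2", "cox2": "cox2", "co2": "cox2",
    "coiii": "cox3", "cox3": "cox3", "co3": "cox3",
    "cytb": "cob", "cob": "cob", "cob/cytb": "cob",
    "16s": "rrnL", "rrnl": "rrnL", "l-rrna": "rrnL", "16s rrna": "rrnL",
    "12s": "rrnS", "rrns": "rrnS", "s-rrna": "rrnS", "12s rrna": "rrnS",
    "nad4l": "nad4L", "nd4l": "nad4L",
    "d-loop": "CR", "control region": "CR", "cr": "CR",
}
for _i in range(1, 7):
    GENE_ALIASES[f"nd{_i}"] = f"nad{_i}"


def normalize_gene_name(name: str) -> str:
    key = name.strip().lower()
    if key in GENE_ALIASES:
        return GENE_ALIASES[key]
    m = re.fullmatch(r"trn([a-z])(\d?)", key)
    if m:
        return "trn" + m.group(1).upper() + m.group(2)
    return name.strip()


# ----------------------------------------------------------------- FASTA


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


_ALPHABETS = {
    "dna": set("ACGTUN"),
    # amino acids plus ambiguity/stop/gap marks — also covers aligned DNA
    "protein": set("ABCDEFGHIKLMNPQRSTUVWXYZ*-?."),
}


def read_fasta(path: Union[str, Path], alphabet: str = "dna") -> list[FastaRecord]:
    """Read sequence records from a FASTA file.

    With the default ``alphabet="dna"`` sequences are validated against
    A/C/G/T/U/N (case-insensitive) and ``U`` is normalized to ``T``;
    ``alphabet="protein"`` accepts amino acids and gap characters (for
    aligned input) with no normalization beyond upper-casing.  Malformed
    headers, empty sequences and foreign characters raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    valid = _ALPHABETS[alphabet]
    text = path.read_text()
    header_line = None
    has_seq = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if header_line is not None and not has_seq:
                raise FormatError(
                    f"{path}: empty sequence for header at line {header_line}"
                )
            if len(stripped) == 1:
                raise FormatError(f"{path}: empty FASTA header at line {lineno}")
            header_line = lineno
            has_seq = False
        else:
            if header_line is None:
                raise FormatError(
                    f"{path}: sequence before any header at line {lineno}"
                )
            bad = set(stripped.upper()) - valid
            if bad:
                raise FormatError(
                    f"{path}: invalid characters {sorted(bad)} at line {lineno}"
                )
            has_seq = True
    if header_line is None:
        raise FormatError(f"{path}: no FASTA records found")
    if not has_seq:
        raise FormatError(f"{path}: empty sequence for header at line {header_line}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "dna":
            seq = seq.replace("U", "T")
        records.append(
            FastaRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[FastaRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA with canonical 60-column wrapping."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


# ---------------------------------------------------------------- GenBank

_FEATURE_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
_ANTICODON_RE = re.compile(r"anticodon[:=\s]+([ACGTUacgtu]{3})")


def _feature_name(feat) -> str:
    for key in ("gene", "product", "note"):
        if key in feat.qualifiers:
            return normalize_gene_name(str(feat.qualifiers[key][0]))
    return feat.type


def _feature_anticodon(feat) -> Optional[str]:
    for key in ("note", "anticodon", "product"):
        for val in feat.qualifiers.get(key, []):
            m = _ANTICODON_RE.search(str(val))
            if m:
                return m.group(1).upper().replace("U", "T")
    return None


def read_genbank(path: Union[str, Path]) -> AnnotatedGenome:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS features become PCGs, tRNA/rRNA features keep their category, and
    ``misc_feature``/``D-loop`` features annotated as the control region
    become the CR.  ``complement(...)`` locations give minus-strand
    features; a ``join`` whose parts bracket the origin gives a wrapped
    feature (``start > end``).
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    seq = str(record.seq).upper()
    if not seq:
        raise FormatError(f"{path}: missing ORIGIN sequence")
    L = len(seq)
    features = []
    for feat in record.features:
        if feat.type == "source":
            continue
        if feat.type in _FEATURE_CATEGORY:
            category = _FEATURE_CATEGORY[feat.type]
        elif feat.type in ("misc_feature", "D-loop"):
            note = " ".join(
                str(v) for vs in feat.qualifiers.values() for v in vs
            ).lower()
            if "control region" in note or feat.type == "D-loop" or "d-loop" in note:
                category = "CR"
            else:
                continue
        else:
            continue
        loc = feat.location
        parts = loc.parts
        # Biopython locations are 0-based half-open; convert to 1-based
        # inclusive.  A two-part join ending at the origin is a wrap.
        if len(parts) == 2 and int(parts[0].end) == L and int(parts[1].start) == 0:
            start, end = int(parts[0].start) + 1, int(parts[1].end)
        elif len(parts) == 1:
            start, end = int(loc.start) + 1, int(loc.end)
        else:
            raise FormatError(
                f"{path}: unsupported compound location for {_feature_name(feat)}"
            )
        if int(loc.end) > L and not (start > end):
            raise CoordinateError(
                f"{path}: feature {_feature_name(feat)} extends beyond sequence"
            )
        strand = "-" if loc.strand == -1 else "+"
        features.append(
            GeneFeature(
                name=_feature_name(feat),
                category=category,
                strand=strand,
                start=start,
                end=end,
                anticodon=_feature_anticodon(feat) if category == "tRNA" else None,
            )
        )
    ag = AnnotatedGenome(genome=CircularGenome(seq), features=features)
    return ag


def write_genbank(
    ag: AnnotatedGenome, path: Union[str, Path], locus_name: str = "mitogenome"
) -> None:
    """Minimal GenBank writer preserving feature name/strand/coordinates."""
    L = len(ag.genome)
    record = SeqRecord(
        Seq(ag.genome.sequence),
        id=locus_name,
        name=locus_name[:16],
        description="annotated circular mitochondrial genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in ag.features:
        strand = -1 if f.strand == "-" else 1
        if f.start > f.end:  # wraps the origin
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, L, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}[
            f.category
        ]
        qualifiers: dict[str, list[str]] = {"gene": [f.name]}
        if f.category == "PCG":
            qualifiers["transl_table"] = ["5"]
        if f.category == "tRNA" and f.anticodon:
            qualifiers["note"] = [f"anticodon:{f.anticodon}"]
        if f.category == "CR":
            qualifiers["note"] = ["control region"]
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


# -------------------------------------------------------------- gene table

_TABLE_HEADER = (
    "Gene\tDirection\tStart\tEnd\tSize (bp)\tAnticodon\tStart Codon\t"
    "Stop Codon\tIntergenic Nucleotides"
)


def write_gene_table(ag: AnnotatedGenome) -> str:
    """Gene-arrangement table as TSV, one row per feature in start order.

    Sizes are recomputed from coordinates and the intergenic-nucleotide
    column from the circular adjacency census; start/stop codons of PCGs
    are read off the sequence itself.
    """
    from . import codon_usage

    if not ag.features:
        raise ValueError("annotation is empty")
    L = len(ag.genome)
    if len(ag.features) >= 2:
        gaps = {
            r.upstream_gene: r.gap for r in gene_arrangement.adjacency_census(ag)
        }
    else:
        only = ag.features[0]
        gaps = {only.name: L - feature_length(only, L)}
    code = codon_usage.GeneticCode.from_table_id(5)
    rows = [_TABLE_HEADER]
    for f in ag.features:
        if f.category == "PCG":
            try:
                _, start_codon, stop_codon = codon_usage.extract_codons(
                    ag.genome, f, code
                )
            except ValueError:
                start_codon, stop_codon = f.start_codon or "", f.stop_codon or ""
        else:
            start_codon, stop_codon = "", ""
        rows.append(
            "\t".join(
                [
                    f.name,
                    f.strand,
                    str(f.start),
                    str(f.end),
                    str(feature_length(f, L)),
                    f.anticodon or "",
                    start_codon,
                    stop_codon,
                    str(gaps[f.name]),
                ]
            )
        )
    return "\n".join(rows) + "\n"


def read_gene_table(path: Union[str, Path]) -> list[GeneFeature]:
    """Read a TSV gene table (as written by :func:`write_gene_table`)."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty gene table")
    header = lines[0].split("\t")
    required = {"Gene", "Direction", "Start", "End"}
    if not required.issubset(header):
        raise FormatError(f"{path}: gene table must have columns {sorted(required)}")
    idx = {col: header.index(col) for col in header}
    features = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")

        def cell(col: str) -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        name = normalize_gene_name(cell("Gene"))
        if name == "CR":
            category = "CR"
        elif name.startswith("trn"):
            category = "tRNA"
        elif name.startswith("rrn"):
            category = "rRNA"
        else:
            category = "PCG"
        if cell("Category"):
            category = cell("Category")
        try:
            features.append(
                GeneFeature(
                    name=name,
                    category=category,
                    strand=cell("Direction") or "+",
                    start=int(cell("Start")),
                    end=int(cell("End")),
                    anticodon=cell("Anticodon") or None,
                    start_codon=cell("Start Codon") or None,
                    stop_codon=cell("Stop Codon") or None,
                )
            )
        except ValueError as e:
            raise FormatError(f"{path}: line {lineno}: {e}") from e
    return features
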