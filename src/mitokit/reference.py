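"""Published reference tables for the *Caridina mariae* mitogenome.

These are the printed annotation and summary statistics of the 15,581 bp
mitogenome of the tiger shrimp *C. mariae* (GenBank PQ359442): the gene
arrangement (name, strand, 1-based coordinates, anticodon, start/stop codons,
intergenic nucleotides), the per-partition nucleotide composition, and the
pooled codon-usage counts of the 13 protein-coding genes under the
invertebrate mitochondrial code.  They serve two roles:

* desk-scale inputs — every structural statistic of the published genome
  (partition sizes, spacer/overlap census, RSCU, skews) is recomputable from
  these tables alone, without the deposited sequence;
* default targets for the synthetic-genome generator, so simulated genomes
  share the published genome's layout and statistical structure.
"""

from __future__ import annotations

from .genome_model import GeneFeature

GENOME_LENGTH = 15_581

# name, category, strand, start, end, anticodon, start codon, stop codon,
# intergenic nucleotides to the next feature (negative = overlap)
GENE_TABLE: list[tuple] = [
    ("cox1",  "PCG",  "+",  1,     1533,  None,  "CAA", "TAA",   2),
    ("trnL2", "tRNA", "+",  1536,  1599,  "TAA", None,  None,    1),
    ("cox2",  "PCG",  "+",  1601,  2308,  None,  "ATG", "TAA", -20),
    ("trnK",  "tRNA", "+",  2289,  2355,  "TTT", None,  None,   22),
    ("trnD",  "tRNA", "+",  2378,  2442,  "GTC", None,  None,    2),
    ("atp8",  "PCG",  "+",  2445,  2603,  None,  "ATT", "TAA",  -7),
    ("atp6",  "PCG",  "+",  2597,  3271,  None,  "ATG", "TAA",  -1),
    ("cox3",  "PCG",  "+",  3271,  4056,  None,  "ATG", "TAA",   3),
    ("trnG",  "tRNA", "+",  4060,  4124,  "TCC", None,  None,    0),
    ("nad3",  "PCG",  "+",  4125,  4478,  None,  "ATT", "TAA",  -2),
    ("trnA",  "tRNA", "+",  4477,  4540,  "TGC", None,  None,   -1),
    ("trnR",  "tRNA", "+",  4540,  4601,  "TCG", None,  None,    3),
    ("trnN",  "tRNA", "+",  4605,  4671,  "GTT", None,  None,    0),
    ("trnS1", "tRNA", "+",  4672,  4738,  "TCT", None,  None,    0),
    ("trnE",  "tRNA", "+",  4739,  4806,  "TTC", None,  None,   -2),
    ("trnF",  "tRNA", "-",  4805,  4870,  "GAA", None,  None,    0),
    ("nad5",  "PCG",  "-",  4871,  6562,  None,  "ATT", "TAA",  36),
    ("trnH",  "tRNA", "-",  6599,  6662,  "GTG", None,  None,    0),
    ("nad4",  "PCG",  "-",  6663,  8001,  None,  "ATG", "T(AA)", -7),
    ("nad4L", "PCG",  "-",  7995,  8294,  None,  "ATG", "TAA",   2),
    ("trnT",  "tRNA", "+",  8297,  8361,  "TGT", None,  None,    0),
    ("trnP",  "tRNA", "-",  8362,  8427,  "TGG", None,  None,   17),
    ("nad6",  "PCG",  "+",  8445,  8945,  None,  "ATA", "TAA",  -1),
    ("cob",   "PCG",  "+",  8945,  10081, None,  "ATG", "TAG",  -2),
    ("trnS2", "tRNA", "+",  10080, 10149, "TGA", None,  None,   18),
    ("nad1",  "PCG",  "-",  10168, 11106, None,  "ATA", "TAG",  30),
    ("trnL1", "tRNA", "-",  11137, 11203, "TAG", None,  None,  -40),
    ("rrnL",  "rRNA", "-",  11164, 12489, None,  None,  None,   50),
    ("trnV",  "tRNA", "-",  12540, 12606, "TAC", None,  None,    2),
    ("rrnS",  "rRNA", "-",  12609, 13405, None,  None,  None,    0),
    ("CR",    "CR",   "+",  13406, 14151, None,  None,  None,    0),
    ("trnI",  "tRNA", "+",  14152, 14216, "GAT", None,  None,   19),
    ("trnQ",  "tRNA", "-",  14236, 14303, "TTG", None,  None,    6),
    ("trnM",  "tRNA", "+",  14310, 14377, "CAT", None,  None,    0),
    ("nad2",  "PCG",  "+",  14378, 15382, None,  "ATT", "TAA",  -2),
    ("trnW",  "tRNA", "+",  15381, 15450, "TCA", None,  None,   -1),
    ("trnC",  "tRNA", "-",  15450, 15513, "GCA", None,  None,    0),
    ("trnY",  "tRNA", "-",  15514, 15579, "GTA", None,  None,    2),
]

# Per-partition composition: partition -> (size, %T, %C, %A, %G).
# A+T content and both skews are derived quantities, not stored.
COMPOSITION: dict[str, tuple[int, float, float, float, float]] = {
    "Mitogenome":     (15_581, 33.4, 18.9, 35.5, 12.2),
    "PCGs":           (11_128, 39.6, 16.3, 27.4, 16.6),
    "tRNAs":          (1_455, 33.5, 14.0, 34.6, 17.9),
    "rRNAs":          (2_123, 39.0,  9.2, 33.9, 17.9),
    "Control region": (746,   39.7,  7.0, 47.1,  6.3),
}

# Pooled codon counts of the 13 PCGs (RNA alphabet), including the complete
# terminal stop codons; the one incomplete stop (nad4, "T(AA)") is not a
# countable codon, which is why the stop family totals 12 over 13 genes.
CODON_COUNTS: dict[str, int] = {
    "UUU": 258, "UCU": 115, "UAU": 104, "UGU": 37,
    "UUC": 47,  "UCC": 21,  "UAC": 32,  "UGC": 5,
    "UUA": 305, "UCA": 75,  "UAA": 10,  "UGA": 75,
    "UUG": 55,  "UCG": 10,  "UAG": 2,   "UGG": 23,
    "CUU": 115, "CCU": 70,  "CAU": 51,  "CGU": 19,
    "CUC": 26,  "CCC": 29,  "CAC": 30,  "CGC": 3,
    "CUA": 62,  "CCA": 44,  "CAA": 71,  "CGA": 30,
    "CUG": 15,  "CCG": 9,   "CAG": 10,  "CGG": 9,
    "AUU": 271, "ACU": 102, "AAU": 76,  "AGU": 20,
    "AUC": 30,  "ACC": 21,  "AAC": 46,  "AGC": 7,
    "AUA": 169, "ACA": 77,  "AAA": 59,  "AGA": 77,
    "AUG": 31,  "ACG": 7,   "AAG": 17,  "AGG": 25,
    "GUU": 100, "GCU": 152, "GAU": 53,  "GGU": 54,
    "GUC": 18,  "GCC": 33,  "GAC": 28,  "GGC": 20,
    "GUA": 110, "GCA": 54,  "GAA": 54,  "GGA": 87,
    "GUG": 28,  "GCG": 10,  "GAG": 17,  "GGG": 89,
}

# Published RSCU values, printed to 2 decimals; used only as cross-checks.
RSCU_PUBLISHED: dict[str, float] = {
    "UUU": 1.69, "UCU": 2.63, "UAU": 1.53, "UGU": 1.76,
    "UUC": 0.31, "UCC": 0.48, "UAC": 0.47, "UGC": 0.24,
    "UUA": 3.17, "UCA": 1.71, "UAA": 1.67, "UGA": 1.53,
    "UUG": 0.57, "UCG": 0.23, "UAG": 0.33, "UGG": 0.47,
    "CUU": 1.19, "CCU": 1.84, "CAU": 1.26, "CGU": 1.25,
    "CUC": 0.27, "CCC": 0.76, "CAC": 0.74, "CGC": 0.20,
    "CUA": 0.64, "CCA": 1.16, "CAA": 1.75, "CGA": 1.97,
    "CUG": 0.16, "CCG": 0.24, "CAG": 0.25, "CGG": 0.59,
    "AUU": 1.80, "ACU": 1.97, "AAU": 1.25, "AGU": 0.46,
    "AUC": 0.20, "ACC": 0.41, "AAC": 0.75, "AGC": 0.16,
    "AUA": 1.69, "ACA": 1.49, "AAA": 1.55, "AGA": 1.76,
    "AUG": 0.31, "ACG": 0.14, "AAG": 0.45, "AGG": 0.57,
    "GUU": 1.56, "GCU": 2.44, "GAU": 1.31, "GGU": 0.86,
    "GUC": 0.28, "GCC": 0.53, "GAC": 0.69, "GGC": 0.32,
    "GUA": 1.72, "GCA": 0.87, "GAA": 1.52, "GGA": 1.39,
    "GUG": 0.44, "GCG": 0.16, "GAG": 0.48, "GGG": 1.42,
}


def gene_features() -> list[GeneFeature]:
    """The published gene arrangement as :class:`GeneFeature` objects."""
    return [
        GeneFeature(
            name=name,
            category=cat,
            strand=strand,
            start=start,
            end=end,
            anticodon=ac,
            start_codon=sc,
            stop_codon=stc,
        )
        for name, cat, strand, start, end, ac, sc, stc, _gap in GENE_TABLE
    ]


def intergenic_plan() -> list[int]:
    """Published intergenic-nucleotide column, in gene-table order."""
    return [row[8] for row in GENE_TABLE]
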