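"""Seeded generator of annotated circular mitogenomes with known ground truth.

The generator builds a full mitogenome from a layout plan (gene names,
categories, strands, lengths and signed intergenic gaps), planting:

* protein-coding genes codon-by-codon from a codon-usage weight profile,
  with the annotated start codon, a complete or incomplete stop codon, and
  no internal stops;
* tRNA genes as cloverleaf structures with Watson-Crick stems, a planted
  anticodon, a configurable budget of G.U/C.C/U.U/C.A/U.C slots, and
  optionally D-armless topology (by default at the trnS1 position);
* rRNA, control-region and spacer sequence by per-partition composition
  sampling (spacers at control-region-like A+T richness).

Overlapping genes genuinely share sequence: the downstream feature's first
bases are the upstream feature's last bases, and sampling only ever fills
positions not already fixed.  Every realized quantity — codon counts,
start/stop codons, per-partition base counts, adjacency gaps, tRNA
structures and pair labels — is recorded in a :class:`TruthManifest` so the
analysis pipeline can be checked end-to-end against the generator's own
bookkeeping.  The defaults reproduce the published layout and statistical
targets of the *Caridina mariae* mitogenome (15,581 bp; 16 spacers, 12
overlaps; 39 planted non-Watson-Crick slots over the 22 tRNAs).

Identical seeds give byte-identical output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import reference, trna_structure
from .genome_model import AnnotatedGenome, CircularGenome, GeneFeature
from .phylogeny import PhyloTree, TreeNode
from .trna_structure import CloverleafStructure, FoldingConfig, fold_cloverleaf

__all__ = [
    "LayoutEntry",
    "GenomeSimSpec",
    "TruthManifest",
    "SpecError",
    "simulate_genome",
    "evolve_alignment",
]

_COMPL = {"A": "T", "T": "A", "C": "G", "G": "C"}
_DNA = "TCAG"  # order matches the (T, C, A, G) composition tuples


class SpecError(ValueError):
    """The simulation spec is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class LayoutEntry:
    name: str
    category: str  # PCG | tRNA | rRNA | CR
    strand: str
    length: int
    anticodon: Optional[str] = None  # DNA triplet, tRNAs only
    start_codon: Optional[str] = None  # PCGs only
    stop_codon: Optional[str] = None  # PCGs; "T(AA)" marks an incomplete stop


@dataclass
class GenomeSimSpec:
    """Parameters of one simulated mitogenome.

    ``gaps[i]`` is the signed number of unannotated bases between layout
    entry *i* and entry *i + 1* (the last gap wraps back to the first
    entry); negative gaps make the two features share sequence.
    ``composition_targets`` maps partition labels (``tRNAs``, ``rRNAs``,
    ``Control region``, ``spacer``) to (T, C, A, G) percentages.
    """

    layout: list[LayoutEntry]
    gaps: list[int]
    codon_weights: dict[str, float]
    composition_targets: dict[str, tuple[float, float, float, float]]
    mismatch_plan: dict[str, int] = field(
        default_factory=lambda: {"GU": 31, "CC": 1, "UU": 2, "CA": 2, "UC": 3}
    )
    d_armless: tuple[str, ...] = ("trnS1",)
    seed: int = 0
    folding: FoldingConfig = field(default_factory=FoldingConfig)

    @classmethod
    def default(cls, seed: int = 0) -> "GenomeSimSpec":
        """The published tiger-shrimp layout and statistical targets."""
        layout = []
        for name, cat, strand, start, end, ac, sc, stc, _g in reference.GENE_TABLE:
            layout.append(
                LayoutEntry(
                    name=name,
                    category=cat,
                    strand=strand,
                    length=end - start + 1,
                    anticodon=ac,
                    start_codon=sc,
                    stop_codon=stc,
                )
            )
        comp = {}
        for label in ("tRNAs", "rRNAs", "Control region"):
            _, t, c, a, g = reference.COMPOSITION[label]
            comp[label] = (t, c, a, g)
        comp["spacer"] = comp["Control region"]
        return cls(
            layout=layout,
            gaps=reference.intergenic_plan(),
            codon_weights={k: float(v) for k, v in reference.CODON_COUNTS.items()},
            composition_targets=comp,
            seed=seed,
        )

    def validate(self) -> int:
        """Check feasibility; return the implied genome length."""
        if len(self.gaps) != len(self.layout):
            raise SpecError("need one gap per layout entry (last gap wraps)")
        total = sum(e.length for e in self.layout) + sum(self.gaps)
        if total <= 0:
            raise SpecError(f"gaps exceed layout length (total {total})")
        if any(e.length > total for e in self.layout):
            raise SpecError("a feature is longer than the genome")
        for label, tcag in self.composition_targets.items():
            if abs(sum(tcag) - 100.0) > 0.5:
                raise SpecError(f"composition target {label} does not sum to 100%")
        return total


@dataclass
class TruthManifest:
    """Exact record of what the generator realized (not merely targeted)."""

    genome_length: int
    compositions: dict[str, dict[str, int]]  # partition -> base counts (sense)
    codon_counts: dict[str, int]  # pooled over PCGs, RNA alphabet
    codons_by_gene: dict[str, list[str]]
    start_stop: dict[str, tuple[str, str]]
    adjacency: list[tuple[str, str, int]]
    trna_structures: dict[str, CloverleafStructure]
    d_armless_flags: dict[str, bool]

    @property
    def pair_census(self) -> Counter:
        total: Counter = Counter()
        for s in self.trna_structures.values():
            total.update(s.pair_labels)
        return total


class _Assembler:
    """Mutable plus-strand sequence with never-overwrite semantics."""

    def __init__(self, length: int):
        self.L = length
        self.slots: list[Optional[str]] = [None] * length

    def sense_pos(self, feat_start: int, feat_end: int, strand: str, k: int) -> int:
        """0-based plus-strand index of sense position k (0-based)."""
        if strand == "+":
            pos = feat_start - 1 + k
        else:
            pos = feat_end - 1 - k
        return pos % self.L

    def get_sense(self, start: int, end: int, strand: str, k: int) -> Optional[str]:
        b = self.slots[self.sense_pos(start, end, strand, k)]
        if b is None or strand == "+":
            return b
        return _COMPL[b]

    def set_sense(self, start: int, end: int, strand: str, k: int, base: str) -> None:
        pos = self.sense_pos(start, end, strand, k)
        b = base if strand == "+" else _COMPL[base]
        if self.slots[pos] is not None:
            if self.slots[pos] != b:
                raise SpecError(
                    f"conflicting constraints at genome position {pos + 1}: "
                    f"{self.slots[pos]} vs {b}"
                )
            return
        self.slots[pos] = b

    def sense_slice(self, start: int, end: int, strand: str, length: int) -> str:
        return "".join(
            self.get_sense(start, end, strand, k) or "N" for k in range(length)
        )


def _sample_base(rng: np.random.Generator, tcag: tuple) -> str:
    p = np.asarray(tcag, dtype=float)
    return _DNA[rng.choice(4, p=p / p.sum())]


def _codon_candidates(pattern: list[Optional[str]]) -> list[str]:
    """All RNA codons compatible with a (possibly partially fixed) DNA pattern."""
    from .codon_usage import ALL_CODONS

    out = []
    for codon in ALL_CODONS:
        dna = codon.replace("U", "T")
        if all(p is None or p == dna[i] for i, p in enumerate(pattern)):
            out.append(codon)
    return out


def _plant_pcg(
    asm: _Assembler,
    entry: LayoutEntry,
    start: int,
    end: int,
    spec: GenomeSimSpec,
    rng: np.random.Generator,
    stop_codons: frozenset,
) -> None:
    n_full = entry.length // 3
    weights = {
        c: w for c, w in spec.codon_weights.items() if c not in stop_codons and w > 0
    }
    terminal_fixed = "(" not in (entry.stop_codon or "(")
    for i in range(n_full):
        ks = (3 * i, 3 * i + 1, 3 * i + 2)
        pattern = [asm.get_sense(start, end, entry.strand, k) for k in ks]
        if all(p is not None for p in pattern):
            continue  # fully forced by an upstream overlap or a planted codon
        if i == n_full - 1 and terminal_fixed:
            continue  # complete stop was planted up front
        cands = _codon_candidates(pattern)
        internal = [c for c in cands if c not in stop_codons]
        if internal:
            cands = internal
        w = np.array([weights.get(c, 0.0) for c in cands])
        if w.sum() <= 0:
            w = np.ones(len(cands))
        codon = cands[rng.choice(len(cands), p=w / w.sum())]
        dna = codon.replace("U", "T")
        for j, k in enumerate(ks):
            asm.set_sense(start, end, entry.strand, k, dna[j])


# preferred pair slots for planting non-Watson-Crick labels: stable indices
# into the slot list (acceptor 7, [D], anticodon 5, T) chosen away from the
# helix ends so single perturbations stay unambiguous
def _mismatch_slot_order(n_slots: int) -> list[int]:
    prefs = [2, 4, 1, 5, 3]
    rest = [i for i in range(n_slots) if i not in prefs]
    return [i for i in prefs if i < n_slots] + rest


_MM_BASES = {
    "GU": ("G", "U"),
    "CC": ("C", "C"),
    "UU": ("U", "U"),
    "CA": ("C", "A"),
    "UC": ("U", "C"),
}


def _choose_segmentation(
    length: int, armless: bool, cfg: FoldingConfig
) -> tuple[int, int, int, int, int, int, int]:
    """Deterministic (a, d, dl, b, v, t, tl) template for a planted tRNA."""
    best = None
    target = {"dl": 8, "tl": 7, "v": 4, "dlink": 5}
    d_opts = (
        [
            (0, dl)
            for dl in range(
                cfg.d_absent_linker_range[0], cfg.d_absent_linker_range[1] + 1
            )
        ]
        if armless
        else [
            (d, dl)
            for d in range(cfg.d_stem_range[0], cfg.d_stem_range[1] + 1)
            for dl in range(cfg.d_loop_range[0], cfg.d_loop_range[1] + 1)
        ]
    )
    fixed = 2 * cfg.acceptor_pairs + 2 * cfg.ac_stem + cfg.ac_loop
    for a in range(cfg.linker1_range[0], cfg.linker1_range[1] + 1):
        for d, dl in d_opts:
            for b in range(cfg.linker2_range[0], cfg.linker2_range[1] + 1):
                for t in range(cfg.t_stem_range[0], cfg.t_stem_range[1] + 1):
                    for tl in range(cfg.t_loop_range[0], cfg.t_loop_range[1] + 1):
                        v = length - fixed - a - 2 * d - dl - b - 2 * t - tl
                        if not (cfg.variable_range[0] <= v <= cfg.variable_range[1]):
                            continue
                        loop_target = target["dlink"] if d == 0 else target["dl"]
                        cost = (
                            abs(dl - loop_target)
                            + abs(tl - target["tl"])
                            + abs(v - target["v"])
                            + abs(a - 2)
                            + abs(b - 1)
                            + (0 if (d == 0) == armless else 100)
                            + (0 if d in (0, 3) else 1)
                            + (0 if t == 5 else 1)
                        )
                        key = (cost, a, d, dl, b, v, t, tl)
                        if best is None or key < best:
                            best = key
    if best is None:
        raise SpecError(f"no cloverleaf template fits a {length} nt tRNA")
    return best[1:]


def _plant_trna(
    asm: _Assembler,
    entry: LayoutEntry,
    start: int,
    end: int,
    spec: GenomeSimSpec,
    rng: np.random.Generator,
    mismatches: list[str],
    max_tries: int = 60,
) -> tuple[CloverleafStructure, bool]:
    """Plant a cloverleaf into the assembler; return (structure, d_armless).

    The planted structure is verified by refolding (with the annotated
    anticodon) and by the D-arm presence test; free bases are resampled
    until the refold reproduces the plant.  The returned structure is the
    refolded one — the realized truth.
    """
    armless = entry.name in spec.d_armless
    cfg = spec.folding
    a, d, dl, b, v, t, tl = _choose_segmentation(entry.length, armless, cfg)
    skeleton = trna_structure._build_structure(
        "N" * entry.length, a, d, dl, b, v, t, tl, cfg
    )
    pairs = skeleton.all_pairs()
    paired_pos = {p for ij in pairs for p in ij}
    anticodon_rna = (entry.anticodon or "").upper().replace("T", "U")
    ac_loop_start = skeleton.anticodon_arm.loop[0]
    tcag = spec.composition_targets.get(
        "tRNAs", (25.0, 25.0, 25.0, 25.0)
    )

    fixed = {
        k + 1: asm.get_sense(start, end, entry.strand, k)
        for k in range(entry.length)
        if asm.get_sense(start, end, entry.strand, k) is not None
    }

    best_result = None
    for attempt in range(max_tries):
        bases: dict[int, str] = dict(fixed)
        ok = True
        # anticodon at the centre of the anticodon loop
        if anticodon_rna:
            for j, ch in enumerate(anticodon_rna.replace("U", "T")):
                pos = ac_loop_start + 2 + j
                if pos in bases and bases[pos] != ch:
                    ok = False
                    break
                bases[pos] = ch
        if not ok:
            raise SpecError(
                f"{entry.name}: overlap constraints contradict anticodon plant"
            )
        # distribute planted non-WC labels over free slots
        slot_label: dict[int, str] = {}
        order = _mismatch_slot_order(len(pairs))
        free_slots = [
            s for s in order if pairs[s][0] not in bases and pairs[s][1] not in bases
        ]
        for label, slot in zip(mismatches, free_slots):
            slot_label[slot] = label
        # fill stems
        for s, (i, j) in enumerate(pairs):
            if s in slot_label:
                x, y = _MM_BASES[slot_label[s]]
                if slot_label[s] in ("GU", "CA", "UC") and rng.random() < 0.5:
                    x, y = y, x
                bases[i], bases[j] = x.replace("U", "T"), y.replace("U", "T")
            elif i in bases and j in bases:
                pass  # both forced; realized label recorded from refold
            elif i in bases:
                bases[j] = _COMPL[bases[i]]
            elif j in bases:
                bases[i] = _COMPL[bases[j]]
            else:
                x = _sample_base(rng, tcag)
                bases[i], bases[j] = x, _COMPL[x]
        # fill loops and linkers
        for pos in range(1, entry.length + 1):
            if pos not in bases:
                bases[pos] = _sample_base(rng, tcag)
        seq_dna = "".join(bases[p] for p in range(1, entry.length + 1))
        try:
            refold = fold_cloverleaf(seq_dna, entry.anticodon, cfg)
        except trna_structure.FoldFailure:
            continue
        if refold.all_pairs() == pairs and refold.has_d_arm == (not armless):
            # when the best global fold has a D-arm it can never be flagged
            # D-armless; only a planted armless tRNA needs the margin check
            if armless:
                flags = trna_structure.detect_missing_arms(
                    refold, entry.anticodon, cfg
                )
                d_absent = flags.d_arm_absent
                if not d_absent:
                    if best_result is None:
                        best_result = (seq_dna, refold, d_absent)
                    continue
            else:
                d_absent = False
            best_result = (seq_dna, refold, d_absent)
            break
        if best_result is None:
            flags = trna_structure.detect_missing_arms(refold, entry.anticodon, cfg)
            best_result = (seq_dna, refold, flags.d_arm_absent)
    if best_result is None:
        raise SpecError(f"{entry.name}: could not plant a foldable cloverleaf")
    seq_dna, refold, d_absent = best_result
    for k, ch in enumerate(seq_dna):
        asm.set_sense(start, end, entry.strand, k, ch)
    return refold, d_absent


def simulate_genome(spec: GenomeSimSpec) -> tuple[AnnotatedGenome, TruthManifest]:
    """Generate an annotated circular mitogenome and its truth manifest."""
    from .codon_usage import GeneticCode

    L = spec.validate()
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.from_table_id(5)
    asm = _Assembler(L)

    # coordinates from lengths + gap plan, chained from position 1
    coords: list[tuple[int, int]] = []
    pos = 1
    for entry, gap in zip(spec.layout, spec.gaps):
        start = pos
        end = start + entry.length - 1
        if end > L:
            raise SpecError(f"{entry.name} extends beyond the implied genome length")
        coords.append((start, end))
        pos = end + gap + 1

    # plant every PCG's start codon and (possibly incomplete) stop up front,
    # so overlap sharing can never silently destroy them
    for entry, (start, end) in zip(spec.layout, coords):
        if entry.category != "PCG":
            continue
        sc = (entry.start_codon or "ATG").upper()
        for k, ch in enumerate(sc):
            asm.set_sense(start, end, entry.strand, k, ch)
        stop = (entry.stop_codon or "TAA").upper()
        tail = stop.split("(")[0] if "(" in stop else stop
        n_tail = len(tail)
        if entry.length % 3 != n_tail % 3:
            raise SpecError(
                f"{entry.name}: stop {stop} inconsistent with length "
                f"{entry.length} (mod 3 = {entry.length % 3})"
            )
        for k, ch in enumerate(tail):
            asm.set_sense(start, end, entry.strand, entry.length - n_tail + k, ch)

    # deal the planted non-Watson-Crick slots round-robin over the tRNAs
    mm_labels: list[str] = []
    for label, n in spec.mismatch_plan.items():
        mm_labels.extend([label] * n)
    trna_entries = [e for e in spec.layout if e.category == "tRNA"]
    per_trna: dict[str, list[str]] = {e.name: [] for e in trna_entries}
    for i, label in enumerate(mm_labels):
        if not trna_entries:
            break
        per_trna[trna_entries[i % len(trna_entries)].name].append(label)

    trna_structures: dict[str, CloverleafStructure] = {}
    d_flags: dict[str, bool] = {}
    for entry, (start, end) in zip(spec.layout, coords):
        if entry.category == "PCG":
            _plant_pcg(asm, entry, start, end, spec, rng, code.stop_codons)
        elif entry.category == "tRNA":
            structure, d_absent = _plant_trna(
                asm, entry, start, end, spec, rng, per_trna[entry.name]
            )
            trna_structures[entry.name] = structure
            d_flags[entry.name] = d_absent
        else:  # rRNA or CR: composition-target sampling
            label = "rRNAs" if entry.category == "rRNA" else "Control region"
            tcag = spec.composition_targets.get(label, (25.0, 25.0, 25.0, 25.0))
            for k in range(entry.length):
                if asm.get_sense(start, end, entry.strand, k) is None:
                    asm.set_sense(
                        start, end, entry.strand, k, _sample_base(rng, tcag)
                    )

    # unannotated spacer positions
    spacer_tcag = spec.composition_targets.get("spacer", (25.0, 25.0, 25.0, 25.0))
    for i in range(L):
        if asm.slots[i] is None:
            asm.slots[i] = _sample_base(rng, spacer_tcag)

    sequence = "".join(asm.slots)  # type: ignore[arg-type]

    # ---- realized truths, recorded from the generator's own bookkeeping
    def sense(start: int, end: int, strand: str, length: int) -> str:
        return asm.sense_slice(start, end, strand, length)

    codons_by_gene: dict[str, list[str]] = {}
    start_stop: dict[str, tuple[str, str]] = {}
    comp: dict[str, dict[str, int]] = {}
    pooled: dict[str, list[str]] = {"PCG": [], "tRNA": [], "rRNA": [], "CR": []}
    for entry, (start, end) in zip(spec.layout, coords):
        s = sense(start, end, entry.strand, entry.length)
        pooled[entry.category].append(s)
        if entry.category == "PCG":
            comp[entry.name] = {b: s.count(b) for b in "ACGT"}
            n_full = entry.length // 3
            codons = [
                s[3 * i : 3 * i + 3].replace("T", "U") for i in range(n_full)
            ]
            codons_by_gene[entry.name] = codons
            tail = entry.length - 3 * n_full
            stop = (
                s[3 * n_full :] + "(" + "A" * (3 - tail) + ")"
                if tail
                else s[-3:]
            )
            start_stop[entry.name] = (s[:3], stop)
    comp["Mitogenome"] = {b: sequence.count(b) for b in "ACGT"}
    for cat, label in (
        ("PCG", "PCGs"),
        ("tRNA", "tRNAs"),
        ("rRNA", "rRNAs"),
        ("CR", "Control region"),
    ):
        joined = "".join(pooled[cat])
        if joined:
            comp[label] = {b: joined.count(b) for b in "ACGT"}

    adjacency = []
    for i, (entry, (start, end)) in enumerate(zip(spec.layout, coords)):
        nxt = spec.layout[(i + 1) % len(spec.layout)]
        adjacency.append((entry.name, nxt.name, spec.gaps[i]))

    pooled_counts: Counter = Counter()
    for codons in codons_by_gene.values():
        pooled_counts.update(codons)

    features = [
        GeneFeature(
            name=e.name,
            category=e.category,
            strand=e.strand,
            start=start,
            end=end,
            anticodon=e.anticodon,
            start_codon=e.start_codon,
            stop_codon=e.stop_codon,
        )
        for e, (start, end) in zip(spec.layout, coords)
    ]
    ag = AnnotatedGenome(genome=CircularGenome(sequence), features=features)
    manifest = TruthManifest(
        genome_length=L,
        compositions=comp,
        codon_counts=dict(pooled_counts),
        codons_by_gene=codons_by_gene,
        start_stop=start_stop,
        adjacency=adjacency,
        trna_structures=trna_structures,
        d_armless_flags=d_flags,
    )
    return ag, manifest


# ------------------------------------------------------------- evolution

ALPHABETS = {"JC": "ACGT", "poisson": "ACDEFGHIKLMNPQRSTVWY"}


def evolve_alignment(
    tree: PhyloTree, model: str, length: int, seed: int
) -> dict[str, str]:
    """Evolve a gap-free alignment down a tree with branch lengths.

    ``model`` is ``"JC"`` (Jukes-Cantor nucleotides) or ``"poisson"``
    (equal-rates amino acids).  The root sequence is drawn from the uniform
    equilibrium; along an edge of length *b* (expected substitutions/site)
    each site changes with probability ``(K-1)/K * (1 - exp(-K*b/(K-1)))``
    for alphabet size *K*, landing uniformly on one of the other K-1
    states — for K=4 this is exactly the Jukes-Cantor transition
    probability ``3/4 * (1 - exp(-4b/3))``.
    """
    if model not in ALPHABETS:
        raise ValueError(f"unknown model {model!r}; use one of {sorted(ALPHABETS)}")
    alphabet = np.frombuffer(ALPHABETS[model].encode(), dtype="S1")
    K = len(alphabet)
    rng = np.random.default_rng(seed)
    for node in tree.root.walk():
        if node is not tree.root and (node.length or 0.0) < 0:
            raise ValueError(f"negative branch length at {node.name or 'internal'}")
    out: dict[str, str] = {}

    def descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            p_change = (K - 1) / K * (1.0 - math.exp(-K * b / (K - 1)))
            child_state = state.copy()
            hits = rng.random(length) < p_change
            n_hits = int(hits.sum())
            if n_hits:
                # uniform over the K-1 states different from the current one
                shift = rng.integers(1, K, size=n_hits)
                idx = np.searchsorted(alphabet, child_state[hits])
                child_state[hits] = alphabet[(idx + shift) % K]
            if child.is_leaf:
                out[child.name] = child_state.tobytes().decode()
            else:
                descend(child, child_state)

    root_state = alphabet[rng.integers(0, K, size=length)]
    if tree.root.is_leaf:
        out[tree.root.name] = root_state.tobytes().decode()
    descend(tree.root, root_state)
    return out
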