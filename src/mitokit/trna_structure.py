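"""Constrained cloverleaf secondary-structure inference for mitochondrial tRNAs.

Mitochondrial tRNAs (here 55-75 nt) fold into the canonical cloverleaf:
an acceptor stem, a dihydrouracil (D) arm, an anticodon arm, a variable
region and a T-arm.  Some mitochondrial tRNAs — classically the
serine tRNA trnS1 — lack the D-arm entirely, leaving an unpaired linker.

Rather than thermodynamic folding, this module does an exhaustive search
over a parametric cloverleaf template.  A placement is a segmentation of
the sequence into

    [acceptor 5' half: 7 nt] [linker: 1-3 nt]
    [D-arm: stem 3-4 + loop 4-12 + stem  |  absent: 0-12 nt linker]
    [linker: 0-2 nt]
    [anticodon arm: stem 5 + loop 7 + stem 5]
    [variable region: 0-13 nt]
    [T-arm: stem 4-5 + loop 4-9 + stem]
    [acceptor 3' half: 7 nt]

Every stem position is a *pair slot*; slots are scored by the bases they
juxtapose (Watson-Crick +2, G.U wobble +1, the tolerated mismatches
C.C/U.U/C.A/U.C 0, anything else -1) and the placement with the highest
total score wins.  Ties are broken by more Watson-Crick pairs, then fewer
unpaired nucleotides, then the leftmost D-arm (a placement with a D-arm
beats an equal-scoring D-armless one).  Following the descriptive
convention of the mitogenome literature, the G.U wobble is censused as a
"mismatch" class alongside the genuine mismatches, even though it is an
admissible pair.

No 3' CCA or discriminator is required: mitochondrial tRNA genes do not
encode it.  Scores are invariant under the T/U alphabet choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

__all__ = [
    "FoldingConfig",
    "Arm",
    "CloverleafStructure",
    "FoldFailure",
    "ArmFlags",
    "fold_cloverleaf",
    "detect_missing_arms",
    "pair_census",
]

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
# tolerated mismatch classes, keyed by unordered base pair
MISMATCH_LABELS = {
    frozenset({"C"}): "CC",
    frozenset({"U"}): "UU",
    frozenset({"C", "A"}): "CA",
    frozenset({"U", "C"}): "UC",
}


def pair_label(x: str, y: str) -> str:
    """Classify the bases juxtaposed at one stem slot."""
    if (x, y) in WC_PAIRS:
        return "WC"
    if (x, y) in WOBBLE_PAIRS:
        return "GU"
    return MISMATCH_LABELS.get(frozenset({x, y}), "other")


@dataclass(frozen=True)
class FoldingConfig:
    """Tunable constants of the cloverleaf template and its scoring."""

    score_wc: int = 2
    score_gu: int = 1
    score_mismatch: int = 0
    score_other: int = -1
    acceptor_pairs: int = 7
    linker1_range: tuple[int, int] = (1, 3)  # acceptor 5' -> D region
    d_stem_range: tuple[int, int] = (3, 4)
    d_loop_range: tuple[int, int] = (4, 12)
    d_absent_linker_range: tuple[int, int] = (0, 12)
    linker2_range: tuple[int, int] = (0, 2)  # D region -> anticodon arm
    ac_stem: int = 5
    ac_loop: int = 7
    variable_range: tuple[int, int] = (0, 13)
    t_stem_range: tuple[int, int] = (4, 5)
    t_loop_range: tuple[int, int] = (4, 9)
    min_length: int = 55
    max_length: int = 75
    min_score: int = 0
    d_absent_margin: int = 0

    def slot_score(self, label: str) -> int:
        return {
            "WC": self.score_wc,
            "GU": self.score_gu,
            "other": self.score_other,
        }.get(label, self.score_mismatch)


DEFAULT_CONFIG = FoldingConfig()


@dataclass(frozen=True)
class Arm:
    """One stem-loop: stem pair slots (1-based position pairs) and loop span."""

    stem_pairs: tuple[tuple[int, int], ...]
    loop: tuple[int, int]  # 1-based inclusive span


@dataclass(frozen=True)
class CloverleafStructure:
    sequence: str  # RNA alphabet, upper case
    acceptor_stem: tuple[tuple[int, int], ...]
    d_arm: Optional[Arm]
    anticodon_arm: Arm
    t_arm: Arm
    variable_region: tuple[int, int]  # span, may be empty (start > end)
    score: int

    @property
    def has_d_arm(self) -> bool:
        return self.d_arm is not None

    def all_pairs(self) -> tuple[tuple[int, int], ...]:
        pairs = list(self.acceptor_stem)
        if self.d_arm:
            pairs += list(self.d_arm.stem_pairs)
        pairs += list(self.anticodon_arm.stem_pairs)
        pairs += list(self.t_arm.stem_pairs)
        return tuple(pairs)

    @property
    def pair_labels(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(pair_label(s[i - 1], s[j - 1]) for i, j in self.all_pairs())

    @property
    def anticodon_loop(self) -> str:
        a, b = self.anticodon_arm.loop
        return self.sequence[a - 1 : b]

    @property
    def anticodon(self) -> str:
        """Triplet at the center (positions 3-5) of the 7-nt anticodon loop."""
        a, _ = self.anticodon_arm.loop
        return self.sequence[a + 1 : a + 4]

    def label_counts(self) -> Counter:
        return Counter(self.pair_labels)

    def dot_bracket(self) -> str:
        out = ["."] * len(self.sequence)
        for i, j in self.all_pairs():
            out[i - 1] = "("
            out[j - 1] = ")"
        return "".join(out)


class FoldFailure(Exception):
    """No placement reached the configured minimum score.

    Carries the best partial structure found (or None when no placement
    fits the length constraints at all).
    """

    def __init__(self, message: str, best: Optional[CloverleafStructure]):
        super().__init__(message)
        self.best = best


def _normalize(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _enumerate_placements(
    L: int, cfg: FoldingConfig
) -> Iterator[tuple[int, int, int, int, int, int, int]]:
    """Yield (linker1, d_stem, d_loop_or_linker, linker2, variable, t_stem,
    t_loop) with d_stem == 0 meaning D-arm absent.  The variable-region
    length is solved from the total-length constraint."""
    fixed = 2 * cfg.acceptor_pairs + 2 * cfg.ac_stem + cfg.ac_loop
    d_options = [
        (0, dl)
        for dl in range(cfg.d_absent_linker_range[0], cfg.d_absent_linker_range[1] + 1)
    ] + [
        (d, dl)
        for d in range(cfg.d_stem_range[0], cfg.d_stem_range[1] + 1)
        for dl in range(cfg.d_loop_range[0], cfg.d_loop_range[1] + 1)
    ]
    for a in range(cfg.linker1_range[0], cfg.linker1_range[1] + 1):
        for d, dl in d_options:
            d_len = 2 * d + dl
            for b in range(cfg.linker2_range[0], cfg.linker2_range[1] + 1):
                for t in range(cfg.t_stem_range[0], cfg.t_stem_range[1] + 1):
                    for tl in range(cfg.t_loop_range[0], cfg.t_loop_range[1] + 1):
                        v = L - fixed - a - d_len - b - 2 * t - tl
                        if cfg.variable_range[0] <= v <= cfg.variable_range[1]:
                            yield a, d, dl, b, v, t, tl


def _build_structure(
    seq: str, a: int, d: int, dl: int, b: int, v: int, t: int, tl: int,
    cfg: FoldingConfig,
) -> CloverleafStructure:
    L = len(seq)
    n_acc = cfg.acceptor_pairs
    acceptor = tuple((i, L + 1 - i) for i in range(1, n_acc + 1))
    pos = n_acc + a + 1  # 1-based start of the D region
    if d > 0:
        d_end = pos + 2 * d + dl - 1
        d_arm = Arm(
            stem_pairs=tuple((pos + j, d_end - j) for j in range(d)),
            loop=(pos + d, d_end - d),
        )
        pos = d_end + 1
    else:
        d_arm = None
        pos += dl  # unpaired linker standing in for the D-arm
    pos += b
    ac_end = pos + 2 * cfg.ac_stem + cfg.ac_loop - 1
    ac_arm = Arm(
        stem_pairs=tuple((pos + j, ac_end - j) for j in range(cfg.ac_stem)),
        loop=(pos + cfg.ac_stem, ac_end - cfg.ac_stem),
    )
    pos = ac_end + 1
    var = (pos, pos + v - 1)
    pos += v
    t_end = pos + 2 * t + tl - 1
    t_arm = Arm(
        stem_pairs=tuple((pos + j, t_end - j) for j in range(t)),
        loop=(pos + t, t_end - t),
    )
    struct = CloverleafStructure(
        sequence=seq,
        acceptor_stem=acceptor,
        d_arm=d_arm,
        anticodon_arm=ac_arm,
        t_arm=t_arm,
        variable_region=var,
        score=0,
    )
    score = sum(cfg.slot_score(lbl) for lbl in struct.pair_labels)
    return replace(struct, score=score)


from functools import lru_cache


@lru_cache(maxsize=16)
def _score_tables(cfg: FoldingConfig) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Slot score and is-Watson-Crick lookup, indexed by 4*x + y base codes."""
    bases = "ACGU"
    score, iswc = [0] * 16, [0] * 16
    for x in range(4):
        for y in range(4):
            lbl = pair_label(bases[x], bases[y])
            score[4 * x + y] = cfg.slot_score(lbl)
            iswc[4 * x + y] = 1 if lbl == "WC" else 0
    return tuple(score), tuple(iswc)


@lru_cache(maxsize=64)
def _placement_cache(L: int, cfg: FoldingConfig):
    """All admissible placements for length L, with precomputed geometry:
    (params, 0-based pair indices, anticodon-loop slice, D-start, n pairs)."""
    entries = []
    for params in _enumerate_placements(L, cfg):
        s = _build_structure("N" * L, *params, cfg)
        pairs0 = tuple((i - 1, j - 1) for i, j in s.all_pairs())
        ac0 = (s.anticodon_arm.loop[0] - 1, s.anticodon_arm.loop[1])
        d_start = s.d_arm.stem_pairs[0][0] if s.d_arm else L + 1
        entries.append((params, pairs0, ac0, d_start, len(pairs0)))
    return tuple(entries)


def fold_cloverleaf(
    seq: str,
    anticodon: Optional[str] = None,
    config: FoldingConfig = DEFAULT_CONFIG,
    require_d_arm: Optional[bool] = None,
) -> CloverleafStructure:
    """Best-scoring cloverleaf placement for a tRNA sequence.

    Parameters
    ----------
    seq
        tRNA gene sequence (sense strand, DNA or RNA alphabet), 55-75 nt.
    anticodon
        Optional anticodon triplet; placements whose 7-nt anticodon loop
        does not contain it are rejected.
    require_d_arm
        ``True`` restricts the search to placements with a D-arm,
        ``False`` to D-armless placements, ``None`` (default) searches both.

    Raises
    ------
    FoldFailure
        When no admissible placement reaches ``config.min_score``; the
        exception carries the best partial structure.
    """
    rna = _normalize(seq)
    L = len(rna)
    if not (config.min_length <= L <= config.max_length):
        raise ValueError(
            f"sequence length {L} outside [{config.min_length}, {config.max_length}]"
        )
    bad = set(rna) - set("ACGU")
    if bad:
        raise ValueError(f"invalid characters in tRNA sequence: {sorted(bad)}")
    ac = _normalize(anticodon) if anticodon else None
    if ac is not None and len(ac) != 3:
        raise ValueError(f"anticodon must be a triplet, got {anticodon!r}")

    codes = ["ACGU".index(ch) for ch in rna]
    score_t, wc_t = _score_tables(config)
    best = None  # (sort key, params)
    best_any = None  # ignoring the anticodon filter
    for params, pairs0, ac0, d_start, n_pairs in _placement_cache(L, config):
        d = params[1]
        if require_d_arm is True and d == 0:
            continue
        if require_d_arm is False and d != 0:
            continue
        sc = wc = 0
        for i, j in pairs0:
            c = (codes[i] << 2) | codes[j]
            sc += score_t[c]
            wc += wc_t[c]
        # ordered tie-break: score, WC pairs, fewer unpaired nt, leftmost
        # D-arm; the raw template parameters make the order total
        key = (-sc, -wc, L - 2 * n_pairs, d_start) + params
        if best_any is None or key < best_any[0]:
            best_any = (key, params)
        if ac is not None and ac not in rna[ac0[0] : ac0[1]]:
            continue
        if best is None or key < best[0]:
            best = (key, params)
    if best is None:
        raise FoldFailure(
            "no admissible cloverleaf placement"
            + (f" containing anticodon {ac}" if ac else ""),
            _build_structure(rna, *best_any[1], config) if best_any else None,
        )
    structure = _build_structure(rna, *best[1], config)
    if structure.score < config.min_score:
        raise FoldFailure(
            f"best placement scores {structure.score} < minimum {config.min_score}",
            structure,
        )
    return structure


@dataclass(frozen=True)
class ArmFlags:
    d_arm_absent: bool
    score_with_d: Optional[int]
    score_without_d: Optional[int]


def detect_missing_arms(
    structure: CloverleafStructure,
    anticodon: Optional[str] = None,
    config: FoldingConfig = DEFAULT_CONFIG,
) -> ArmFlags:
    """Decide whether a tRNA is genuinely D-armless.

    Refolds the structure's sequence with the D-arm required and with it
    forbidden; the tRNA is flagged D-armless when the best D-armless score
    exceeds the best D-arm score by more than ``config.d_absent_margin``
    (default 0, i.e. strictly better).  The comparison is about arm
    topology only, so the two searches are not anticodon-constrained (the
    ``anticodon`` argument is accepted for call-site symmetry but unused).
    """
    def _best_score(require: bool) -> Optional[int]:
        try:
            relaxed = replace(config, min_score=-(10**9))
            return fold_cloverleaf(
                structure.sequence, None, relaxed, require_d_arm=require
            ).score
        except (FoldFailure, ValueError):
            return None

    with_d = _best_score(True)
    without_d = _best_score(False)
    if without_d is None:
        absent = False
    elif with_d is None:
        absent = True
    else:
        absent = (without_d - with_d) > config.d_absent_margin
    return ArmFlags(d_arm_absent=absent, score_with_d=with_d, score_without_d=without_d)


def pair_census(structures: list[CloverleafStructure]) -> Counter:
    """Pair-slot label counts summed over a set of structures."""
    if not structures:
        raise ValueError("pair census needs at least one structure")
    total: Counter = Counter()
    for s in structures:
        total.update(s.pair_labels)
    return total
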