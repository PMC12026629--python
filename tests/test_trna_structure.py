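from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from oracles import brute_force_best

from mitokit.synthetic_data import GenomeSimSpec, LayoutEntry, simulate_genome
from mitokit.trna_structure import (
    DEFAULT_CONFIG,
    FoldFailure,
    FoldingConfig,
    _build_structure,
    detect_missing_arms,
    fold_cloverleaf,
    pair_census,
    pair_label,
)


def single_trna_spec(length=66, anticodon="TAA", mismatches=None, armless=False,
                     seed=0):
    """A genome that is one tRNA on a closed circle: the cheapest way to get
    a planted cloverleaf with its manifest."""
    return GenomeSimSpec(
        layout=[LayoutEntry("trnX", "tRNA", "+", length, anticodon=anticodon)],
        gaps=[0],
        codon_weights={},
        composition_targets={"tRNAs": (33.5, 14.0, 34.6, 17.9)},
        mismatch_plan=mismatches or {},
        d_armless=("trnX",) if armless else (),
        seed=seed,
    )


def planted_structure(**kw):
    ag, man = simulate_genome(single_trna_spec(**kw))
    return ag.genome.sequence, man.trna_structures["trnX"], man


class TestFoldRecovery:
    def test_perfect_cloverleaf_recovered_exactly(self):
        seq, planted, _ = planted_structure(length=66, seed=3)
        folded = fold_cloverleaf(seq, "TAA")
        assert folded.all_pairs() == planted.all_pairs()
        assert folded.anticodon == "UAA"
        assert folded.has_d_arm

    def test_single_gu_slot_recovered(self):
        seq, planted, _ = planted_structure(length=66, mismatches={"GU": 1}, seed=4)
        folded = fold_cloverleaf(seq, "TAA")
        assert folded.all_pairs() == planted.all_pairs()
        assert folded.label_counts()["GU"] == 1

    def test_recovery_rate_with_planted_mismatches(self):
        """Planted structures with up to two non-Watson-Crick slots are
        recovered, and the planted label budget is realized in nearly all
        seeded replicates."""
        n, planned = 40, 0
        for seed in range(n):
            mm = {"GU": 1, "UC": 1} if seed % 2 else {"GU": 2}
            length = 62 + (seed % 9)
            seq, planted, man = planted_structure(
                length=length, mismatches=mm, seed=seed
            )
            folded = fold_cloverleaf(seq, "TAA")
            assert folded.all_pairs() == planted.all_pairs()
            counts = folded.label_counts()
            if all(counts.get(k, 0) == v for k, v in mm.items()):
                planned += 1
        assert planned / n >= 0.95

    def test_fold_matches_brute_force_enumeration(self):
        """The template search equals exhaustive enumeration of every
        admissible arm placement, on random sequences of 62-70 nt."""
        rng = np.random.default_rng(20_24)
        cfg = DEFAULT_CONFIG
        for _ in range(20):
            L = int(rng.integers(62, 71))
            seq = "".join(rng.choice(list("ACGU"), size=L))
            oracle_key = brute_force_best(seq, cfg)
            try:
                folded = fold_cloverleaf(seq, config=replace(cfg, min_score=-999))
            except FoldFailure:
                assert oracle_key is None
                continue
            n_wc = sum(1 for l in folded.pair_labels if l == "WC")
            unpaired = L - 2 * len(folded.all_pairs())
            d_start = (
                folded.d_arm.stem_pairs[0][0] if folded.d_arm else L + 1
            )
            assert (-folded.score, -n_wc, unpaired, d_start) == oracle_key

    def test_t_u_alphabet_invariance(self):
        seq, _, _ = planted_structure(length=64, seed=5)
        as_dna = fold_cloverleaf(seq, "TAA")
        as_rna = fold_cloverleaf(seq.replace("T", "U"), "UAA")
        assert as_dna.all_pairs() == as_rna.all_pairs()
        assert as_dna.score == as_rna.score

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="length"):
            fold_cloverleaf("ACGU" * 10)  # 40 nt, below the 55 nt floor

    def test_fold_failure_carries_best_partial(self):
        seq, _, _ = planted_structure(length=66, seed=6)
        with pytest.raises(FoldFailure) as exc:
            fold_cloverleaf(seq, "TAA", config=replace(DEFAULT_CONFIG, min_score=999))
        assert exc.value.best is not None
        assert exc.value.best.score < 999


class TestDArmDetection:
    def test_planted_d_armless_flagged(self):
        seq, planted, man = planted_structure(length=67, armless=True, seed=7)
        assert planted.d_arm is None
        folded = fold_cloverleaf(seq, "TAA")
        flags = detect_missing_arms(folded, "TAA")
        assert flags.d_arm_absent
        assert man.d_armless_flags["trnX"]

    def test_full_cloverleaf_not_flagged(self):
        seq, _, _ = planted_structure(length=66, seed=8)
        flags = detect_missing_arms(fold_cloverleaf(seq, "TAA"), "TAA")
        assert not flags.d_arm_absent
        assert flags.score_with_d >= flags.score_without_d

    def test_prohibitive_margin_never_flags(self):
        seq, _, _ = planted_structure(length=67, armless=True, seed=9)
        cfg = replace(DEFAULT_CONFIG, d_absent_margin=10_000)
        folded = fold_cloverleaf(seq, "TAA", cfg)
        assert not detect_missing_arms(folded, "TAA", cfg).d_arm_absent


def _engineered_structure(labels):
    """Build a 66-nt cloverleaf whose pair slots carry exactly ``labels``
    (padded with Watson-Crick G-C), bypassing the folding search."""
    params = (2, 3, 8, 1, 4, 5, 4)  # linker, D-stem/loop, linker, var, T-stem/loop
    skeleton = _build_structure("N" * 66, *params, DEFAULT_CONFIG)
    bases = {}
    slot_bases = {
        "WC": ("G", "C"), "GU": ("G", "U"), "CC": ("C", "C"),
        "UU": ("U", "U"), "CA": ("C", "A"), "UC": ("U", "C"),
    }
    pairs = skeleton.all_pairs()
    padded = list(labels) + ["WC"] * (len(pairs) - len(labels))
    for (i, j), lbl in zip(pairs, padded):
        bases[i], bases[j] = slot_bases[lbl]
    seq = "".join(bases.get(p, "A") for p in range(1, 67))
    return _build_structure(seq, *params, DEFAULT_CONFIG)


class TestPairCensus:
    def test_published_mismatch_totals_as_planted_fixture(self):
        """22 structures carrying 31 GU + 1 CC + 2 UU + 2 CA + 3 UC slots in
        total census back exactly."""
        budget = (["GU"] * 31 + ["CC"] + ["UU"] * 2 + ["CA"] * 2 + ["UC"] * 3)
        structures = [
            _engineered_structure(budget[i::22]) for i in range(22)
        ]
        census = pair_census(structures)
        assert census["GU"] == 31
        assert census["CC"] == 1
        assert census["UU"] == 2
        assert census["CA"] == 2
        assert census["UC"] == 3
        assert census["other"] == 0

    def test_all_wc_set(self):
        structures = [_engineered_structure([]) for _ in range(3)]
        census = pair_census(structures)
        assert set(census) == {"WC"}

    def test_census_is_additive(self):
        s1 = _engineered_structure(["GU", "UU"])
        s2 = _engineered_structure(["CA"])
        total = pair_census([s1, s2])
        assert total == pair_census([s1]) + pair_census([s2])
        assert sum(total.values()) == len(s1.all_pairs()) + len(s2.all_pairs())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pair_census([])


@pytest.mark.parametrize(
    "x,y,label",
    [
        ("A", "U", "WC"), ("G", "C", "WC"), ("G", "U", "GU"), ("U", "G", "GU"),
        ("C", "C", "CC"), ("U", "U", "UU"), ("C", "A", "CA"), ("A", "C", "CA"),
        ("U", "C", "UC"), ("C", "U", "UC"), ("A", "A", "other"), ("G", "G", "other"),
        ("A", "G", "other"),
    ],
)
def test_pair_slot_labels(x, y, label):
    assert pair_label(x, y) == label
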