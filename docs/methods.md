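# Methods

## Scope and data model

The package analyses a *circular* annotated mitogenome.  Coordinates are
1-based inclusive everywhere at the interfaces; a feature spanning the
origin is written `start > end` and has length
`(L − start + 1) + end` on a circle of length `L`.  Features carry a
category (`PCG`, `tRNA`, `rRNA`, `CR`); the control region is carried as a
feature like any gene so that arrangement tables close the circle, but it
is labelled distinctly — gene counts are therefore reported as 37 genes
plus one control region (38 rows).

Per-gene and pooled-category statistics are computed on each feature's
*sense* (coding) strand; whole-genome and control-region statistics on the
deposited plus strand.  This matters for skews, which change sign between
strands, and it is the accounting under which published per-gene skews of
opposite signs across genes are coherent.  Pooled categories concatenate
each feature's full sense sequence, so bases shared by overlapping genes
count once per gene and pooled sizes equal the sums of annotated gene
lengths (e.g. 11,128 bp for the 13 PCGs of the reference layout).

`N` bases count toward a partition's size but never toward composition
numerators or denominators.  A skew whose denominator is zero is reported
as NaN with a warning rather than raised, so whole tables still print.

## Codon usage

Codon extraction splits the sense sequence of a protein-coding gene into
consecutive triplets.  Mitochondrial CDSs may end on an incomplete stop
codon (a terminal `T` or `TA`, completed to `TAA` by polyadenylation);
the trailing 1–2 nt are reported as `T(AA)`/`TA(A)` and excluded from all
codon counts, while complete terminal stops are counted.  Under the
reference layout this is why the stop family totals 12 codons over 13
genes.  RSCU is computed per synonymous family of the active genetic code
(default NCBI table 5); a zero-total family gets RSCU 0 with a warning.
Annotated nonstandard starts (the published `CAA` of cox1) are honoured
and surfaced as warnings (`NONSTD_START`), never failures.

## tRNA cloverleaf search

No thermodynamic folding is attempted.  A tRNA (55–75 nt) is segmented
against a parametric cloverleaf template:

    [acceptor 5′, 7 nt] [linker 1–3] [D-arm: stem 3–4 + loop 4–12 + stem,
    OR an unpaired linker 0–12] [linker 0–2] [anticodon arm: 5 + 7 + 5]
    [variable region 0–13] [T-arm: stem 4–5 + loop 4–9 + stem] [acceptor 3′, 7 nt]

Every admissible segmentation is enumerated (a few thousand for these
lengths) and scored per stem slot: Watson–Crick +2, G·U wobble +1, the
tolerated mismatches C·C/U·U/C·A/U·C 0, all else −1.  Ties break toward
more Watson–Crick pairs, then fewer unpaired nucleotides, then the
leftmost D-arm; the remaining template parameters make the order total, so
the result is deterministic.  When an anticodon is supplied, placements
whose 7-nt anticodon loop does not contain it are rejected.  Following the
descriptive convention of the mitogenome literature, G·U is censused as a
"mismatch" class although it is an admissible pair.  Mitochondrial tRNA
genes do not encode the 3′ CCA, so none is required.

A tRNA is called D-armless when the best D-arm-free fold outscores the
best D-arm fold by more than a configurable margin (default 0, i.e.
strictly better).  These two comparison folds are *not*
anticodon-constrained: the question is purely about arm topology, and
constraining them can leave the required-D-arm search with no admissible
placement at all, which would make the margin semantics (including the
"margin high enough never flags" boundary) ill-defined.

All template ranges and slot scores live in `FoldingConfig`; the defaults
were chosen so that published cloverleaf figures are reachable and the
search remains exhaustively enumerable at ≤75 nt.

## Synthetic genomes and ground truth

The generator builds a full mitogenome from a layout plan (names,
categories, strands, lengths) and a signed gap plan; the default plan is
the published *C. mariae* arrangement, which forces the structural numbers
(15,581 bp; 16 spacers up to 50 bp; 12 overlaps up to 40 bp; partition
sizes 11,128/1455/2123/746) by construction.

Placement uses never-overwrite semantics on the plus strand: overlapping
genes genuinely share sequence, with the downstream feature inheriting the
upstream feature's bases.  PCG start codons and (possibly incomplete) stop
codons are planted first as hard constraints; internal codons are then
sampled from a codon-weight profile (default proportional to the published
codon counts), restricted to codons compatible with any already-fixed
bases and excluding in-frame stops whenever a compatible non-stop codon
exists.  tRNAs are planted as cloverleaves: a deterministic segmentation
is chosen for the gene length, the anticodon is placed at the loop centre,
a budget of non-Watson–Crick slots (default 31 G·U + 1 C·C + 2 U·U +
2 C·A + 3 U·C over the 22 tRNAs, ≤2 per tRNA) is distributed over free
slots, remaining slots get sampled Watson–Crick pairs, and loops/linkers
are sampled from the tRNA composition target.  Each planted tRNA is
verified by refolding; free bases are resampled (bounded retries) until
the refold reproduces the planted arms — and, for the designated D-armless
tRNA (default trnS1), until the margin test flags it.  rRNA, control
region and spacer positions are sampled from per-partition composition
targets (spacers at control-region-like A+T richness, emulating the
A+T-rich non-coding background).

The `TruthManifest` records *realized* quantities from the generator's own
bookkeeping — per-gene codon lists, start/stop codons, per-partition base
counts, adjacency gaps, the verified tRNA structures and D-armless flags —
so the analysis pipeline can be checked end-to-end for exact agreement.
Identical seeds give byte-identical genomes.

What the generator does **not** emulate: real codon autocorrelation along
genes, rRNA secondary structure, replication-driven within-strand skew
gradients, or sequencing error.  Whole-genome plus-strand skew is an
*emergent* property of the strand mixture here, not a target: passing
tests show the pipeline computes the statistics correctly on data with the
right structure, not that the generator reproduces every marginal of the
real genome.

## Sequence evolution

`evolve_alignment` evolves gap-free alignments down a rooted tree with
branch lengths in expected substitutions/site, under Jukes–Cantor
(nucleotides) or an equal-rates Poisson model (amino acids): the root is
drawn from the uniform equilibrium and each site on an edge of length *b*
changes with probability `(K−1)/K · (1 − e^(−Kb/(K−1)))`, landing
uniformly on another state — exactly the JC transition probability for
K = 4.  No indels are simulated.

## Phylogeny stage

The phylogeny stage is a deliberately small, fully implemented distance
pipeline, not a reimplementation of Bayesian or maximum-likelihood
inference: supermatrix concatenation (missing genes gap-filled and
logged), p-distances under pairwise gap deletion (gap-filled columns never
count), optional Poisson correction −ln(1−p) behind a flag, and
Saitou–Nei neighbor joining with the Q-criterion, deterministic smallest-
index tie-breaking, and negative branch estimates clamped to zero with the
deficit logged.  NJ is consistent on additive matrices, which the suite
exploits as an exact oracle.  Trees from external inference can be
imported as Newick and queried for monophyly the same way.

## Numerical and reporting conventions

Percentages are reported to 1 decimal and skews to 3 decimals (matching
the conventions of published composition tables); all internal arithmetic
is unrounded.  RSCU prints to 2 decimals.  Gene-name aliases (COI/cox1,
cytb/cob, 16S/rrnL, 12S/rrnS, ND*n*/nad*n*) are normalized on input.  TSV
output is tab-separated UTF-8 with ASCII `-` for the minus strand.

## Problem sizes used by the test suite

The suite verifies the composition-convergence property over 3 seeded
genomes (the binomial 3σ band at partition sizes of 746–2123 bp is already
a tight check), planted-cloverleaf recovery over 40 seeded single-tRNA
replicates with up to two planted mismatch slots, NJ consistency on 100
seeded additive matrices of 4–10 taxa, folding-vs-enumeration agreement on
20 seeded sequences, and the JC closed form on 20 replicates of 10^5
sites.  The full suite runs in about half a minute on one CPU.

## Known limitations

* The cloverleaf template fixes the anticodon stem at 5 pairs and the loop
  at 7 nt; genuinely aberrant anticodon arms would be mis-segmented.
* The published tRNA mismatch totals and per-gene compositions of the real
  genome depend on the deposited sequence; without it they are emulation
  targets, not recomputable claims, and are exercised through planted
  fixtures.
* p-distance NJ is a stand-in for model-based inference; branch supports
  (posterior probabilities, bootstraps) are out of scope.
* Linear genomes are not supported.
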