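# Methods

This note documents the model implemented by `mlconsensus`, the choices
made where the published description of this family of models is silent
or inconsistent, the synthetic data generator, and what the test suite
does and does not establish.

## Model and assumptions

One factor's binding sites are modelled jointly: all reported sites,
whatever their lengths, enter the training set. The only structural
assumption is that a single *core region* is shared — in part or whole —
by every site of the factor. The model has three stages: a multiple
sequence alignment of the sites, an ambiguity-code consensus derived from
the alignment's column profile, and a sliding-window scoring function that
compares a candidate sequence with the consensus at every offset and keeps
the maximum.

### Alignment

The built-in aligner is deliberately naive. It sorts sites from shortest
to longest (short sites are assumed to be mostly core), seeds the
alignment with the shortest, and adds each next site as a contiguous,
ungapped block at the offset that maximises the basic match score against
the consensus of the current partial alignment, which is re-derived after
every addition. Only row ends are padded with `-`; no internal gaps are
ever introduced, so every row degaps exactly to its source sequence — a
hard invariant checked by property tests. Pre-computed alignments from
external tools (e.g. ClustalW2) can be imported instead; they may contain
internal gaps.

Choices the published description leaves open, and how they are fixed
here:

* **Mid-build scoring.** Offsets during construction are scored with the
  basic match score only; the IC and pair-IC weights are defined for a
  finished alignment, so they cannot steer construction.
* **Offset ties.** Equal-scoring offsets are broken by `tie_rule`:
  `last_best` (default) keeps the rightmost maximum encountered scanning
  left to right, `first_best` the leftmost. The default reproduces the
  documented placement of the second site of the classic four-site worked
  example (a three-way tie at score 4, offsets −4..−2).
* **Equal-length sites** are ordered lexicographically by default, or by a
  seeded draw when a seed is supplied, so alignments are reproducible.
* **Re-basing.** When a new site overhangs the current alignment, all rows
  are padded on that side and column 1 becomes the leftmost occupied
  column.

A caveat discovered while reproducing the published four-site worked
example: its printed shortest-first alignment is *not* the greedy optimum
under the rules above — the third site scores 5 at offset +1 against the
mid-build consensus but only 4 at the printed placement. The aligner
therefore guarantees per-step optimality (each placement attains the
brute-force maximum at its step, replayable from the recorded build log),
not reproduction of that printed table.

### Consensus

With `f_j(b) = n_j(b)/N` (gaps count in the denominator), column *j*
becomes base *b* if `f_j(b) > 0.5`, else the two-base code `amb(b, d)` if
`f_j(b) + f_j(d) > 0.75`, else `-`. Both thresholds are strict: a column
with two of four rows reading C and one gap (`f(C) = 0.5`) and a column
with `f(C)+f(T) = 0.75` both yield `-`. At most one base or pair can
exceed its threshold (frequencies sum to at most 1), but a deterministic
tie-break (highest frequency, then alphabetical) is implemented anyway.
The codes I, J, K, L, M, N are the model's own alphabet, not IUPAC; an
IUPAC rendering (I→M, J→R, K→W, L→S, M→Y, N→K) is available for display
only. One known wrinkle: in the published worked example the
ClustalW2-side consensus prints `-` at a column whose rows read
{T, T, C, C}, although the stated rule forces the C/T code there
(`0.5 + 0.5 > 0.75`); this implementation follows the rule, so it
reproduces the printed string at every column except that one.
Consistently, neither printed example consensus contains any ambiguity
code, which suggests the original experiments never emitted them.

### Information content

`IC(A, j) = 2 + Σ_b f_j(b) log f_j(b)` with base-2 logarithms, so a fully
conserved column scores exactly 2 bits and a uniform one 0; `0·log 0 = 0`.
The pair analogue is `IC_pair = 4 + Σ f_ij log₂ f_ij` over the 16 joint
cells, with `f_ij` again divided by N so gapped rows shrink the mass. The
logarithm base is chosen so the additive constants are attained exactly.
An all-gap column literally evaluates to 2 bits, but such columns always
carry the consensus gap and never contribute to any score. The overall
frequencies `n(b)`, `f(b)` are computed and exposed for completeness; no
score uses them and no background correction is applied.

### Scoring

Four per-overlap scores (basic, IC-weighted, pairwise, combined) are
defined in the README. Decisions worth recording:

* **Max over overlaps applies to all four variants**, with no length
  normalisation between overlaps of different width. The minimum overlap
  is 1 column by default (`min_overlap` raises it for users who dislike
  single-column overhangs).
* **The pairwise triple sum is implemented exactly as printed**, index
  bounds included: `Σ_{s=1..K} Σ_{i=1..|w|−s} Σ_{k=1..s}`. A pair at
  separation *k* starting at position *i* is therefore revisited once for
  every `s` from *k* to `min(K, |w|−i)` — near pairs are intentionally
  over-weighted, and pairs whose first position lies close to the
  overlap's right edge receive fewer repetitions. "Full" scope resolves to
  `|w| − 1` per overlap. The tests pin this against brute-force loops, and
  the cumulative structure (scope K extends scope K−1) yields the
  monotonicity property.
* **Consensus positions map 1:1 onto alignment columns**, so the IC tables
  are indexed directly by column.
* The production scanner vectorises the offset sweep (diagonal sums of a
  column-by-position match matrix, accumulated over pair separations);
  its contract is exact value-equality with the literal per-overlap
  loops, enforced by a 500-instance exhaustive-oracle test.

## Evaluation harness

Leave-one-out cross-validation admits factors with at least three sites.
The negatives for a factor are all sites of the other factors of the same
species, minus any sequence identical to one of the factor's own sites; a
negative is a false positive only when it scores strictly above the
positive (ties favour the positive). Slot ROC: the allowable FPR range
0–`fpr_max` (default 20 %) is divided into `n_slots` equal slots
(default 20, i.e. one percentage point per slot — the slot count is a free
parameter of this reconstruction, and because the area is the plain sum of
per-slot TPRs every report states it). Averaging is per-experiment →
per-factor → per-species, in that order.

The Wilcoxon matched-pair signed-ranks test uses per-experiment
false-positive counts: zero differences dropped, midranks for ties, exact
two-sided p by enumeration of the signed-rank distribution for n ≤ 12,
and the tie-corrected normal approximation (reported as Z, computed from
the larger rank sum without continuity correction) otherwise. Direction
comes from the rank sums: the configuration with the smaller FP rank sum
is superior. When two configurations' ROC curves cross, the comparison
report flags that their areas alone are not decisive.

The *significance plateau* of a scope track (ordered none, 1..10, full)
starts, under the literal rule, at the first scope significantly better
(p ≤ 0.05) than its predecessor *and* followed by a non-significant
change, and extends through consecutive non-significant changes. Because
that reading is ambiguous when several consecutive significant rises
precede the first flat step, the alternative reading (plateau starts at
the first significant rise) is available as `rule="first_better"`; no
claim is made about which was originally intended.

## Synthetic data generator

The generator emulates curated TFBS collections: per factor a random core
of length 6 (default), each site = random left flank + noised core + right
flank. Defaults: 20 factors × 8 sites, per-position core conservation
0.9, site-length mean 12 and SD 6, no truncation. The total flank length
is a negative-binomial draw — the overdispersed generalisation of a
geometric tail, solved in closed form from the two length moments
(a per-side geometric cannot reach SD 6 at mean 12 with a length-6 core,
its variance being pinned by its mean) — and split binomially between the
sides. Optional truncation removes a uniform prefix or suffix of the core
so sites can carry it "in part". All randomness flows through one seeded
generator; a truth record (per-factor core, per-site core span) is emitted
alongside.

What the generator does **not** emulate: genomic sequence composition,
phylogenetic correlation between sites, multiple or degenerate cores, and
database idiosyncrasies. Passing tests on synthetic data therefore show
the machinery behaves as specified, not that any biological conclusion
transfers.

### Measured behaviour on the default synthetic conditions

Averaged over 20 seeded replicates of the default species, the AUC-vs-
scope track *declines monotonically* from its maximum at "no PS", and IC
weighting does not raise mean AUC — although the decline at large scopes
is shallower with IC, matching the qualitative "flatter with IC" pattern.
Two directional acceptance checks encode the opposite expectations
(IC ≥ no-IC at matched scope; scope ≈ core ≥ no PS) and fail honestly at
these conditions. The analysis: with a single well-conserved planted core
the basic score is already near ceiling (mean AUC ≈ 19.2 of 20), the
fitted consensus retains essentially only high-IC core columns (so IC
re-weighting adds variance, not information), and the standalone pairwise
score amplifies chance match clusters among the ~150 negatives
quadratically. On harder generator settings (conservation 0.65, truncation
0.4, longer core) the pair score does overtake the basic score at small
scopes, i.e. the implementation reproduces the rise-then-fall pattern
where the task leaves headroom. The default conditions were fixed first
and deliberately not revisited.

## Numerical and degenerate-input choices

* Scores are exact integer counts for the basic and pairwise variants;
  IC-weighted scores are float sums whose equality with reference loops is
  asserted to 1e-10 relative tolerance (summation order differs).
* A single-row alignment is valid (its consensus is the site itself);
  a sequence of length 1 scores 0 under any pairwise configuration.
* `run_sweep` trains each held-out model once per alignment strategy and
  scores all (IC, scope) variants in one pass; experiment order is
  deterministic (sorted factor id, site order), which the pairing of
  Wilcoxon comparisons relies on.
* Problem sizes used by the test suite — 500 oracle instances with
  lengths ≤ 12, 20 synthetic replicates of 20 × 8 sites — keep the full
  run in the low minutes while leaving the statistical checks
  well-determined.

## Known limitations

* Reverse-strand scanning, PWM extensions, pseudocounts and p-value
  calibration of scores are out of scope.
* Imported leave-one-out training drops the held-out row from the
  imported alignment (removing columns left all-gap) rather than
  re-running the external aligner, which is unavailable at evaluation
  time; a freshly re-aligned training set could differ.
* The sum-of-TPR area depends on the slot count; areas are comparable
  only at equal `n_slots`, and crossing ROC curves are flagged rather
  than ranked.
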