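# Methods

## Motif model and scanning

A candidate intramolecular G-quadruplex (QGRS) is the motif
`G(x) N(y1) G(x) N(y2) G(x) N(y3) G(x)`: four guanine tracts of equal
length `x ≥ 2` (the stacked-tetrad count) separated by three loops.  The
scanner enumerates **every** assignment `(start, x, y1, y2, y3)` that
satisfies the bounds — overlapping motifs, nested motifs and alternative
placements of an x-window inside a longer G-run are all distinct results.
Exhaustiveness matters because conservation is later maximized over these
variants; a G-rich 39-nt region can legitimately contain hundreds of them.

Scan bounds (`ScanParams`) and defaults:

| parameter          | default | meaning                                      |
|--------------------|---------|----------------------------------------------|
| `min_tetrads`      | 2       | smallest tract length considered             |
| `max_tetrads`      | none    | optional cap (otherwise length-bound)        |
| `max_motif_length` | 45 nt   | admits the longest well-known UTR quadruplexes (42 nt) |
| `min_loop_length`  | 0 nt    | loops may be empty …                         |
| `max_loop_length`  | 36 nt   | … but not arbitrarily long                   |
| `max_zero_loops`   | 1       | at most one empty loop per motif             |

Input is DNA or RNA (U folded to T, case-insensitive); `N` is allowed in
loops and never counts as G.  Coordinates are 0-based half-open
internally and 1-based inclusive in every exported table.

### G-score

Each motif gets a heuristic stability score implementing the three
standard ranking principles — more tetrads, shorter loops, more even
loops:

    G = 20·(x − 2) + 10·(1 − ȳ/Ymax) + 10·(1 − (y_max − y_min)/Ymax),
    Ymax = max_loop_length.

Only the *ordering* of G-scores is consumed downstream (family
representative selection, optional filtering), not the absolute value, so
the formula is deliberately pluggable (`ScanParams.g_score_fn`) for users
who prefer a different stability heuristic.

### Fractional tetrads

For tetrad-similarity scoring only, a motif's tetrad count is augmented by
¼ for each tract with at least one extra guanine immediately adjacent to
it in the underlying sequence (a single mutation there would lengthen the
tract).  A 2-tetrad motif whose tracts are drawn from G-runs of lengths
3, 2, 3, 3 therefore counts as 2.75.  Extra guanines beyond the first add
nothing, and the fraction is capped at +0.75: if all four tracts can
extend, the (x+1)-tetrad motif exists outright and is enumerated as its
own result.

## Alignment

Homologous mRNAs vary mostly in UTR length, so the homolog pair is
aligned *semi-globally*: a global affine-gap optimum (Gotoh three-state
DP) with free leading and trailing gaps.  Defaults mirror EMBOSS needle's
DNA settings — match +5, mismatch −4, gap open 10, gap extend 0.5 — with
the convention that a gap of length L costs `open + L·extend`.  Traceback
is deterministic: diagonal is preferred, then a gap in the comparison
sequence, then a gap in the principal; among equal-scoring end cells the
full-global corner wins, then deeper cells of the last column, then of
the last row.  The DP is vectorized row-wise (the horizontal gap state is
a running prefix maximum), and the implementation is validated in the
test suite against an independently formulated memoized recursion — which
is itself validated against exhaustive enumeration of every alignment
path on tiny inputs.

Motif *positions* are translated into gapped columns through monotone
coordinate maps kept on the alignment object; loop lengths and total
lengths used by the scorer are always ungapped nucleotide counts.  A
configurable safety limit (10⁶ nt per sequence) guards against accidental
genome-scale inputs.

## Conservation score

Components for a motif pair, each in [0, 1]:

* **Overlap (weight 0.65).**  Both gapped-column intervals are padded on
  each end by `floor(0.5 · smaller motif length)`; the ratio is
  |intersection| / |union| of the padded intervals.  A step transform
  saturates ratios ≥ 0.85 at 1.0, leaves 0 at 0, and scales intermediate
  ratios by 1/0.85.  The union denominator (Jaccard) was chosen because it
  is symmetric, bounded and saturates exactly at identity; an
  intersection-over-smaller variant is available
  (`ScoringParams.overlap_denominator = "smaller"`).  Padding intervals
  may extend past the alignment ends; columns are treated as an abstract
  integer axis, so no clamping is applied.
* **Tetrad (0.20).**  `r = min/max` of the fractional tetrad counts;
  `r ≤ 0.5` scores 0, larger ratios pass through unchanged (forced by the
  published 3-vs-4 → 0.75 example).
* **Loop (0.10).**  Loops are compared positionally (first with first …)
  — no best-matching permutation.  Per-loop `r = min/max` with `0/0 → 1`
  and `0/k → 0`; ratios strictly below 0.5 are zeroed; the three
  transformed ratios are averaged.
* **Length (0.05).**  `r = min/max` of total lengths; 0 for `r ≤ 0.6`,
  then linear: `(r − 0.6)/0.4`.

Boundary semantics are asymmetric on purpose: a tetrad ratio of exactly
0.50 scores 0 and a length ratio of exactly 0.60 scores 0, while a loop
ratio of exactly 0.50 is kept.  The composite is the weighted sum; a pair
with zero overlap is flagged disposable and never persisted.

A reference cross-check kept in the acceptance tests: the published
human/mouse KISS1 pair (tetrads 2 vs 4, loops 7,3,16 vs 8,4,3, lengths
42 vs 23, saturated overlap) recomputes here to 0.704167, against a
reported 0.706.  The 0.002 residual is plausibly the mouse motif's
fractional tetrad count, which the printed structural values do not
determine; the component breakdown is printed so the residual stays
inspectable, and no constant was tuned to force agreement.

## Families of overlapping motifs

Motifs of one sequence, sorted 5′→3′, are partitioned greedily: a new
family opens when the next start is ≥ `family_distance` (default 5 nt,
from the "differ by less than five bases" rule) beyond the current
family's first start — seeding from the 5′-most member guarantees all
pairwise start differences within a family stay below the threshold.
Each motif lands in exactly one family (a pure partition keeps aggregate
counts meaningful; allowing multi-family membership was considered and
rejected).  The family representative is the member with the highest
G-score, ties broken by 5′-most start and then shortest length — a
function of the family alone, so one sequence's records can be
cross-referenced against any number of comparison species.

A family *pair* is scored over the full member cross-product: pairs with
zero overlap are disposed first, then the maximal composite wins (ties:
larger overlap, then 5′-most principal member).  If everything is
disposed the family pair produces no record.  Disposing before maximizing
means a zero-overlap pairing can never be reported on the strength of
structural similarity alone.

## Pipeline

`run_pair` executes: exhaustive scan of each sequence → family grouping →
semi-global alignment → all family-pair scores → filtering.  Records are
kept when the composite meets `min_conservation` (default 0.95, the
conventional "highly conserved" threshold) and, optionally, the principal
representative's G-score meets `min_g_score`.  Output ordering is by
principal then comparison family id; the run is fully deterministic.

Regional classification assigns a motif to the 5′-UTR, CDS or 3′-UTR by
the region containing its 5′ start (a boundary-spanning motif takes its
start's region); a majority-overlap rule is available
(`region_rule="majority"`), falling back to the start rule on ties.

## Synthetic homolog pairs

The generator builds a principal sequence from a random G-free backbone
(alphabet {A, C, T}) with QGRS planted at specified positions, then
derives a comparison homolog by per-site point substitutions and
single-base indels.  Because guanine never appears outside planted
tracts — the mutation alphabet also excludes it — the QGRS content of
both sequences is exactly the planted set (asserted at generation time),
and the truth table of planted coordinates is exact, including
indel-induced shifts.  G-tracts are exempt from substitutions and whole
motifs from indels unless `mutate_g_tracts` is set; with tract protection
and substitution-only noise the planted motif survives structurally
intact in both homologs, so tests can degrade loop *identity* while
holding loop lengths fixed.  When `mutate_g_tracts` is set (or motifs are
deliberately planted only in the principal) the truth table reports no
comparison coordinates, since survival is no longer guaranteed.

Defaults — chosen once as a plausible moderately diverged vertebrate
ortholog pair at test scale — are a 400-nt backbone, 2 % substitutions,
0.5 % indels, tract protection on.  What the generator does *not*
emulate: realistic base composition (real UTRs contain G outside
quadruplexes, giving overlapping families far richer than the planted
ones), rate heterogeneity, large structural rearrangements and
duplications.  Passing recovery tests therefore demonstrates correctness
of the machinery under controlled divergence, not expected sensitivity on
real transcriptomes.

## Verification strategy and problem sizes

* Scanner vs. naive brute-force enumeration over every
  `(start, x, y1, y2, y3)` assignment: 1,000 random sequences of length
  ≤ 60 over several base compositions, plus hypothesis-driven cases.
* Aligner score vs. an independent memoized recursion with explicit
  gap-state bookkeeping: 200 random pairs of length ≤ 12 (the recursion
  itself checked against full path enumeration at length ≤ 4), both
  end-gap modes.
* Family optimality (best ≥ representative pairing) on ≥ 500 family pairs
  from simulated homologs, with a constructed case where the inequality
  is strict.
* Component range/symmetry/monotonicity sweeps over randomized inputs,
  and a 50-seed parameter-recovery study (5 % substitutions, no indels,
  tracts protected; every planted motif must reach composite ≥ 0.95 in
  ≥ 95 % of seeds).

These sizes keep the whole suite under ~10 s on one CPU while exercising
each component against an independent oracle.

## Known limitations

* The G-score is a documented stand-in consistent with published ranking
  principles, not a reproduction of any specific historical formula;
  absolute G-score values are not comparable across tools.
* The overlap denominator and the sub-threshold interpolations (linear)
  are the package's own choices where the method description leaves the
  algebra open; both are parameterized.
* Loop-composition similarity and ion-binding preference are deliberately
  not part of the score.
* No multimolecular quadruplexes, no G4-potential "region" calling, no
  genome-scale scanning optimizations.
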