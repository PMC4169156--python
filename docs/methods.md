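# Methods

## Finger detection and helix numbering

C2H2 fingers are found with a spacing pattern matcher rather than a profile
HMM: the default pattern `C-x(2,4)-C-x(11,14)-H-x(3,5)-H` captures the
canonical repeat, and downstream statistics need only the coordinates of
the four conserved residues, not profile scores. Matching is
leftmost-first and non-overlapping; when several gap assignments fit at one
start, the lexicographically smallest `(gap1, gap2, gap3)` wins
(shortest-gap-first). This single deterministic rule is also what the
brute-force enumeration oracle in the test suite implements, so scanner
equivalence is checked end to end. `X` is accepted in gap regions but
never matches a conserved anchor.

Helix positions are anchored on the first conserved His, which occupies
helix position 7 in the canonical finger: position 1 = His1 − 6, −1 =
His1 − 7, −2 = His1 − 8, 2/3 = His1 − 5/−4, 5/6 = His1 − 2/−1. Anchoring
on His rather than on the second Cys keeps positions −2…6 well defined
when the Cys-loop length varies. Position C2 is placed two residues after
the first conserved Cys, in the β-turn. A finger whose spacing would push
a helix position into the Cys knuckle is rejected as malformed (impossible
with the default gap ranges).

"TGEKP-like" linkers: best exact-match identity of any length-5 window to
`TGEKP` ≥ 3, with linker length (residues strictly between His2 and the
next Cys1) between 4 and 8. These defaults admit the common natural
variants (TGQKP, TGERP, SGEKP) and exclude unrelated spacers; both are
configurable. Linkers shorter than five residues are aligned against every
same-length window of TGEKP. Arrays are maximal runs of fingers whose
adjacent linkers all pass, and runs of ≥ 3 fingers are reported — every
linker in an array must pass, not just one.

## Variant classes and filters

Contacting = helix {−1, 2, 3, 6}; non-contacting = {C2, −2, 1, 5}; any
other residue (including helix position 4) is unknown. The retained set
for the headline contrast is missense variants at tracked positions.
Common means MAF ≥ 0.01 (the threshold is inclusive and configurable).
Duplicate records are collapsed on (protein, residue, alternate amino
acid). Variant mapping considers only fingers inside assembled arrays —
the DNA-binding-competent subset. Prediction-method thresholds are strict
inequalities (SIFT < 0.05, PolyPhen2-HDIV > 0.95, MutationTaster > 0.90,
FATHMM < −1.5); a missing score never flags a method.

## Hardy-Weinberg machinery

Allele frequencies are estimated per population from genotyped individuals
only. The exact conditional test enumerates all heterozygote counts with
the parity of the minor-allele count and sums the probabilities of
outcomes no more probable than the observed one (ties included in the
rejection mass). The weight of heterozygote count h is the integer
`C(n, h)·C(n−h, n_aa)·2^h`; p-values are exact rationals converted to
float at the end, so no tolerance or tie-epsilon is needed and agreement
with enumeration holds to machine precision at any n. The χ² test uses
the 1-df Pearson statistic without continuity correction. Monomorphic
SNPs get p = 1 and D = 0, flagged rather than raised. The skip rule
(any genotype category < 5) is applied before both tests; it can be
disabled by setting the minimum to 0. No multiple-testing correction is
applied by default — deviation summaries count raw p < α per population.

D = (observed − expected heterozygotes)/2 is a diagnostic of direction
only; no inbreeding-coefficient estimation is attempted beyond it.

## Fisher exact test

The two-sided 2×2 test is computed by exact integer enumeration of the
fixed-margin hypergeometric distribution, summing tables with weight
≤ the observed table's weight. The odds ratio is oriented so that
depletion of common variants at contacting positions gives OR < 1; a zero
denominator cell reports infinity, 0/0 reports NaN with a degenerate-table
flag (p = 1). scipy's implementation serves as an independent
cross-check in the test suite, never as the implementation.

## Kullback-Leibler distances

`D(R‖S) = Σᵢ Rᵢ ln(Rᵢ/Sᵢ)` summed over every cell of the matrices, natural
log, plus the reciprocal; the sum is symmetric. Because PFMs contain
zeros, a global pseudocount (default 1e−6) is added to every cell and
columns are renormalized before taking logs; the pseudocount used is
recorded in every result. Matrices are compared column-by-column in given
order with no offset search (pairs are same-finger predictions of equal
width; width mismatch is an error). Missing PFM files in a manifest yield
NA rows rather than failures. A summed KL > 2.5 (strict) is labelled a
dramatic specificity shift.

## Synthetic studies

The generator's defaults define the package's standard study conditions:

* 200 proteins, 50 of them carrying one array of 3 canonical fingers
  (`C-x(4)-C-x(12)-H-x(3)-H`, 23 residues) joined by exact TGEKP linkers,
  with random prefix/suffix of 10–30 residues. All non-anchor residues
  are drawn from the 18-letter alphabet without C and H, so the planted
  parse is provably unique and boundary recovery can be asserted exactly.
  Decoys are residue-shuffled copies of planted sequences: same length and
  composition, motifs destroyed — a composition-matched negative control.
* 14 populations of 100 individuals each (a phase1-style cohort layout:
  one VCF for the whole cohort, populations only in the panel file).
  Genotypes follow the inbreeding model P(het) = 2pq(1−f),
  P(hom_alt) = q² + pqf, P(hom_ref) = p² + pqf, with f validated against
  f ≥ −q/p. Inbreeding was chosen as the deviation mechanism because it
  directly controls the sign of D (f > 0 ⇒ heterozygote deficit ⇒ D < 0).
  Each SNP is independent: no linkage disequilibrium, admixture or
  mutation process is simulated.
* 200 variants splitting 40% contacting, 40% non-contacting, 10% at the
  untracked helix position 4, 5% silent, 5% stop-gain ("other"). The MAF
  spectrum mixes rare U(0.001, 0.01) and common U(0.01, 0.5) draws at
  50/50, so the 1% threshold partitions non-trivially. A
  `common_odds_ratio` parameter tilts the common-variant probability for
  contacting variants only, planting a known true odds ratio for the
  depletion analysis.
* Per-method deleterious probability 0.09 (union across four independent
  methods ≈ 30% flagged by ≥ 1 method, matching the flavor of real
  prediction-method sparsity), 5% missing scores, and score draws kept
  strictly clear of the threshold boundaries so planted sets are
  recoverable exactly.
* PFM pairs of width 4 with variant columns mixed toward random columns at
  weight w = min(divergence, 1); in the full pipeline rare variants
  (MAF < 0.1) draw larger divergences than common ones, reproducing the
  pattern that dramatic specificity shifts concentrate among rare
  variants.

Every generator draws from its own seed stream derived from
(seed, stream index); identical configurations give byte-identical files.
What passing tests on these data do **not** show: performance on real
proteomes (degenerate fingers without canonical C2H2 residues are not
detected by design), on genotypes with linkage or admixture, or on real
prediction-score distributions — the generator validates the machinery,
not the biology.

## Problem sizes and numerical choices

The validation suite uses sizes chosen to make the statistical assertions
sharp while staying quick: exhaustive exact-test verification for all
genotype configurations up to n = 50 (Fraction-arithmetic oracle);
type-I error over 1000 simulated SNPs at n = 500 with MAF ∈ U(0.1, 0.5)
(healthy expected counts for the χ² band); power/sign recovery over 200
SNPs at f = 0.3, MAF = 0.3, n = 500; Fisher-vs-enumeration exhaustively to
table total 40 plus 400 sampled tables to total 200 (the implementation is
exact-rational, so sampling checks the formula, not numerics); and 100
depletion replicates of 1000 variants at true OR 0.3. The reproduction
script (`scripts/acceptance.py`) uses a 60-protein, 120-variant,
4×60-individual pipeline for the determinism and truth-matching checks.

Tie-breaking and degenerate-input policy throughout: exact-rational
comparisons where enumeration is involved (no float tie epsilon), p = 1
conventions for monomorphic/degenerate inputs with explicit flags, strict
inequalities at every published threshold, and 1-based inclusive residue
coordinates in every report.

## Known limitations

* The scanner requires all four canonical C2H2 anchors; degenerate fingers
  and non-DNA-binding finger discrimination beyond the linker heuristic
  are out of scope.
* MAFs in the simulator are shared across populations; real cohorts have
  population-specific frequencies.
* The deviation-rate comparison treats "deviates in ≥ 1 population" as the
  per-variant outcome; with many populations this inflates the background
  rate relative to a single-population analysis (visible in the worked
  example).
* PFM widths are fixed per pair; no alignment or offset search is
  attempted between matrices of different widths.
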