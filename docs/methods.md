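# Methods

## Model and roles

Two feature sets are compared on a fixed genome. One set (the *reference*)
is conditioned on; the other (the *query*) is tested for non-uniform
placement relative to it. Every statistic below is therefore asymmetric
except the Jaccard ratio, and the orchestrator runs each comparison in both
directions by default. Intervals are reduced to midpoints for the
distance-based tests; the projection test uses query midpoints against
reference intervals; the Jaccard test uses both sets as intervals.

Coordinates are 0-based half-open internally (BED convention); GFF input
(1-based closed) is converted on read by `start − 1`. Strand is ignored.
The midpoint of `[s, e)` is `floor((s + e − 1)/2)` — the midpoint of the
covered bases, rounding down for even lengths. A fixed rule matters only
for reproducibility; no statistic is sensitive to the half-base choice.
Duplicate query midpoints are retained (repeated insertion sites are
data); reference midpoints are deduplicated before gap construction, since
coincident reference points would create zero-width gaps with undefined
relative position.

## Relative distance

For query point `q` with flanking reference points `k_left ≤ q < k_right`,
`r = (q − k_left)/(k_right − k_left)` and `d = min(r, 1 − r) ∈ [0, ½]`;
under independence `d ~ Uniform(0, ½)`.

**Edge handling.** A query outside the outermost references has no flanks
on a linear chromosome. The default (`edge_mode=circular`) closes the
chromosome into a ring: the gap from the last reference wraps to the
first, every query keeps a defined `d`, a single reference point suffices,
and the statistic is invariant under joint rotation of all positions
(property-tested). `edge_mode=drop` excludes queries outside
`[first_ref, last_ref)` and reports the dropped count; both modes agree on
interior queries.

**Inference.**
- One-sample KS test of `2d` against Uniform(0, 1), asymptotic two-sided
  p-value. The asymptotic distribution is adequate at the sample sizes
  where the KS test has any power; the permutation test below covers
  small samples.
- Signed ECDF area `S = ∫₀^½ (ECDF(x) − 2x) dx`, computed exactly from the
  sorted sample (piecewise-constant ECDF against the line). For a sample
  this integral collapses to `S = ¼ − mean(d)`; the exact-integration code
  path is verified against that closed form to 1e−9. The permutation
  p-value redraws `n` values from Uniform(0, ½) `n_perm` times and is
  two-sided on `|S|` with the add-one correction.
- Correlation measure `4S = 1 − 4·mean(d) ∈ [−1, 1]`: +1 all-coincident,
  −1 all-mid-gap, 0 in expectation under the null.
- Reported direction: *closer* if the correlation is positive and
  `min(ks_p, area_p)` falls below the reporting α (default 0.05), *farther*
  if negative and significant, else *none*.

## Absolute distance

Per query point, the distance to the nearest reference point (linear, no
wraparound by default — there is no flanking requirement, so no closure is
needed; a circular option exists), scaled by the expected inter-reference
gap. The gap is `g = L/(n_ref + 1)`: `n_ref` points partition a linear
chromosome into `n_ref + 1` segments of mean length `g`. The alternative
convention `g = L/n_ref` is a config switch (`gap_rule=n`); it rescales
the statistic by a constant and leaves the permutation p-value unchanged.
The statistic is the mean scaled distance; its null distribution depends
on the reference configuration, so inference is purely permutational: each
permutation redraws all query points uniformly per chromosome (counts held
at observed values). The permutation null mean is verified against exact
per-base enumeration on 10 kb chromosomes. Two-sided p =
`min(1, 2·min(p_le, p_ge))` with add-one on each tail; direction *closer*
when the observed mean lies below the permutation median.

## Projection

Hit count `K` = query midpoints inside merged reference intervals;
`K ~ Binomial(n, coverage)` under independence. The two-sided p-value uses
the minimum-likelihood ("minlike") convention — the sum of probabilities
of all outcomes no more likely than the observed one — which is what
`scipy.stats.binomtest` computes; the implementation is checked against
full enumeration for n ≤ 12. Results with coverage < 0.01 or > 0.99 carry
a `low_information` flag: with the reference covering almost nothing or
almost everything, no interesting deviation is detectable.

## Jaccard

`J = |Q ∩ R|/|Q ∪ R|` in base pairs over merged sets, computed by an
interval sweep (prefix-sum coverage function evaluated by binary search)
and verified against a per-base membership oracle. "Randomize the query
while maintaining spacing" is implemented as a uniform circular rotation
per chromosome — the only transformation that preserves *all* interval
lengths and inter-interval gaps exactly — with intervals wrapping the
origin split in two. A gap-shuffle mode (permute ring gaps, apply a
uniform phase; preserves the spacing multiset rather than the spacing
sequence) is available since the wording admits it. The hot path evaluates
rotated intersections against a periodically doubled reference, which is
algebraically identical to materialized rotation (dual-route tested).
J = 0 is returned, with a warning, when both sets are empty on the scope.

## Pooling and reporting

Per-chromosome results use only that chromosome. Genome-wide results pool
per-chromosome distance vectors before testing (relative, absolute) or sum
hit counts and covered/intersected lengths before the single binomial or
Jaccard computation (overlap tests); permutations always act per
chromosome. Chromosomes missing a feature set, or with too few references
to define gaps, are skipped with a logged reason rather than erroring, and
listed in the report. No multiple-testing correction is applied across
chromosomes, tests or directions; all p-values are raw.

Determinism: every (direction, scope, test) triple derives its own RNG
substream from the master seed via a CRC-32 hash of the triple, so reports
are byte-identical across runs and invariant to which other tests are
requested or their execution order.

## Synthetic data

The generator (`intervalcorr.simulate`) produces query/reference pairs
with known ground truth on a default genome of 4 × 1 Mb chromosomes;
features default to 1 bp so midpoint reduction is the identity. All
anchored placements act on the chromosome ring so stated offsets are
exact. Relationships: `independent` (the null), `coincident` (query
midpoints are reference midpoints, each used at most once so equal counts
give a perfectly symmetric pairing), `fixed_offset` (constant offset,
random side), `attraction` (Laplace displacement of a given scale),
`repulsion` (uniform placement in the middle third of length-weighted ring
gaps, forcing d ≥ 1/6), `spike_in` and `asymmetric` (below).

What the generator does *not* emulate: chromatin-driven clustering of
features, chromosome-scale density gradients, length distributions of real
annotation, or assembly gaps. Passing tests therefore demonstrate the
statistics' behaviour under their stated sampling models, not robustness
to every artefact of real genomes — on real data the null is "uniform
placement", and departures from it for *biological* reasons other than the
reference under study will register as association.

**Spike-in regime.** A fraction *f* = 0.1 of query points is held at a
uniform offset of 75–100 bp from a reference anchor; the background sits
at offsets of 10–10,000 bp. On the 1 Mb test chromosome we use 2,500
reference points (mean gap ≈ 400 bp, the promoter spacing of a compact,
gene-dense genome) and 10,000 query points. The choice is an a-priori
power calculation, not a fit: with background offsets spanning ~25 gaps,
background relative positions are near-uniform and background nearest
distances near-null, so only the spike carries signal. The spike shifts
the mean scaled nearest distance by ≈ f·(0.5 − 87/400) ≈ 0.045 against a
null standard error of 0.5/√10000 = 0.005 (z ≈ 9, power ≈ 1 at p < 0.01),
while the same spike spreads across variable gap lengths in relative
coordinates (d = 87/gap with gap ~ Exp(400)), leaving the KS test with a
diluted, broad excess and visibly lower rejection rates. This reproduces
the regime where the absolute-distance test is the right tool.

**Asymmetric regime.** 12 query points placed within 20 bp of members of
a 5,000-point reference (4 Mb genome, mean gap 800 bp). Sparse→dense,
every query has d ≲ 0.03 and both relative-distance tests reject; dense→
sparse, only the 12 anchor points (0.24% of the sample) deviate from
uniformity, which the KS test cannot see at n = 5,000. The sparse:dense
ratio is deliberately extreme; at milder ratios the anchors alone begin to
inflate the reverse-direction rejection rate, which is a real property of
perfectly-anchored data rather than an artefact.

## Numerical and degenerate-input choices

- Permutation p-values use the add-one correction and are two-sided
  (|S| for the area test; doubled smaller tail for absolute and Jaccard);
  `n_perm ≥ 100` is enforced, so the smallest attainable p is
  `2/(n_perm + 1)` for the doubled-tail tests.
- Direction calls at a permutation-median tie, and the Jaccard of two
  empty sets, resolve to *none* / 0 with a warning rather than erroring.
- An empty genome file is a valid (empty) coordinate universe; any
  analysis on it fails fast with a clear message.
- Problem sizes in the test suite (2,000 null replicates at n_query = 200
  and n_perm = 500; 100 seeds for the power/asymmetry regimes; 10 kb
  chromosomes for per-base oracles) were chosen to keep Monte-Carlo error
  comfortably inside the asserted tolerances at single-CPU-minutes cost.

## Known limitations

- The KS p-value is asymptotic; for n below a few dozen rely on the
  permutation area test instead.
- The absolute-distance permutation redraws queries uniformly, ignoring
  any query-internal clustering; heavily autocorrelated queries will look
  anti-conservative, as in any marked-point randomization of this kind.
- Genome-wide pooling of relative distances weights chromosomes by query
  count; a chromosome-stratified combination is not provided.
- No BAM/VCF input, no strand awareness, no liftover, and no weighted
  (multiplicity-aware) generalization of the Jaccard measure.
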