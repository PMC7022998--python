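# Methods

## Model

The pipeline treats a season of athlete monitoring as a supervised
two-dimensional classification problem with a geometric, non-iterative
solution. Weekly values of two monitoring metrics (one of five fixed
combinations of distance, session-RPE, strain, monotony, ACWR and
recovery) are normalised by their season maximum, placing every week at a
point (x, y) ∈ [0,1]². Weeks with a competition carry a label: +1 if the
best weekly %PBT = (PB/time)²·100 strictly exceeds 100 (a new personal
best), −1 otherwise — an exact 100 counts as no improvement. The fitted
object is a partition of the unit square into an adaptation region Ω⁺, a
maladaptation region Ω⁻ and a thin neutral layer, built as follows:

1. **Per-class clustering.** Each label class is partitioned by
   average-linkage agglomerative clustering under each of three
   dissimilarities (Bray–Curtis, Chebyshev, and a normalised squared
   Euclidean distance in its ½-normalised, self-centred form). Average
   linkage was chosen because it accepts an arbitrary precomputed
   dissimilarity and is deterministic. The cluster count k is selected in
   2..k_max by the Calinski–Harabasz criterion, always evaluated in
   Euclidean coordinates (CH is variance-based and undefined at k = 1);
   classes with fewer than 3 points form a single cluster. Among the three
   per-metric solutions the one with the fewest total clusters wins; ties
   break to the higher CH score, then to the fixed metric order.
2. **Convexification.** Each cluster becomes its convex hull. Degenerate
   clusters (1–2 points, collinear sets) are buffered by radius δ into a
   disk/capsule clipped to the unit square, so every pattern has positive
   area.
3. **Region assignment.** On a grid of `grid_resolution`² cell centres the
   signed field f = d(Ω⁻ hulls) − d(Ω⁺ hulls) of Euclidean point-to-hull
   distances is evaluated; a cell takes the label sign(f). Cells with
   |f| ≤ ε form the neutral separating layer; cells lying inside hulls of
   *both* labels are never neutral and are decided by the nearest hull
   centroid. The boundary is extracted as the zero contour of f.

GAPI is the cell-count ratio area(Ω⁺)/area(Ω⁻) (flagged infinite when Ω⁻ is
empty). Goodness of fit is 100·correct/total over the labelled weeks,
rounded half-up to an integer percent; point classification applies the
same nearest-hull rule as the grid but evaluated exactly at the point, so a
training point inside its own hull is never misclassified by grid
quantisation (at resolution 256 the literal cell-centre lookup loses ~0.5%
of boundary-hugging points, breaking the guarantee that separable data fit
perfectly). A mean-cross-entropy diagnostic of the hard predictions is
reported alongside (clipped at 10⁻¹², so it is 0 for a perfect fit and
grows with each misclassification); it plays no role in fitting, which is
fully geometric.

**Jittering and ensembling.** Each replicate adds independent Gaussian
noise to the *raw* x, y and z series before normalisation and binarisation
— so labels of weeks near %PBT = 100 can flip across replicates — with SD =
`noise_level` × the series' own sample SD (an additive,
relative-to-signal reading of "10% noise"; a multiplicative variant is a
config switch). Replicate r draws from an independent stream seeded by
(master seed, r). Scalar outputs are combined by arithmetic means; the
region maps by a per-cell modal label (averaging boundaries directly is
ill-defined). Replicates whose jittered labels collapse to one class have
no model and are excluded from the means with a warning. At noise 0 every
replicate sees identical data, so the member is fitted once and replicated.

**Association.** Spearman's ρ uses average ranks, with an exact
full-permutation two-sided p for n ≤ 9 and the t-approximation above.
Blomqvist's β counts quadrants around the two sample medians, drops
points on a median (Blomqvist's original treatment — unavoidable at odd n),
and takes its p from the exact Binomial(m, ½) distribution of the
concordant count. Holm's step-down correction is applied within each
(test, outcome) family across the five combinations, i.e. m = 5 per
family; p-values are two-sided throughout. Welch's t with
Welch–Satterthwaite degrees of freedom serves the two-group comparison.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| ε `layer_width` | 0.01 | unit-square lengths | thin enough to leave areas essentially unchanged, wide enough to absorb grid-scale ambiguity at resolution 256 |
| δ `buffer_radius` | 0.02 | unit-square lengths | gives degenerate patterns a visible, positive-area footprint ≈ one tenth of typical inter-point spacing |
| `grid_resolution` | 256 | cells/axis | area discretisation error ≤ ~2/256 per region; hard floor at 32 |
| `k_max` | 4 | clusters/class | seasons contribute 4–8 labelled weeks per athlete |
| `noise_level` | 0.10 | fraction of series SD | the stated jitter amplitude |
| `replicates` | 50 | — | the stated ensemble size |
| monotony SD | sample (n−1) | — | the convention consistent with the worked examples; ddof switchable |
| ACWR chronic window | weeks w−3..w | — | matches the defining example (acute week included); `exclude_current` variant available |
| recovery input | global item | Likert | the single global-recovery question; a composite of the five wellness items is a switch |

## Synthetic cohort

The generator emulates the study conditions: 26 Monday-aligned weeks,
~7 sessions/week splitting a lognormal weekly distance (mean 20 km, SD
5 km, the published squad's range being roughly 14–32 km/week), CR-10
ratings increasing with relative session volume plus noise, duration =
distance/pace with a per-athlete pace, twice-weekly wellness entries whose
global recovery falls with the week's load z-score, fortnightly mood
profiles, and 4–8 competition weeks drawn from weeks 4 on. A latent rule
(halfplane, band or disk, with closed-form area ratio) on the normalised
combination coordinates sets each competition's %PBT to 100 ± a margin
drawn uniformly from (0.1, 6] percentage points — matching the spread of
published best-%PBT values — with optional label-flip noise. Athletes whose
competitions all land on one side of the rule fail inclusion prerequisite
(3) and are filtered out, mirroring a real cohort's exclusion flow;
recovery experiments generate a surplus (35) and keep the first 20
included.

What it does *not* emulate: periodisation/taper structure, autocorrelated
fatigue carry-over, missing-data patterns (compliance is perfect by
construction), inter-athlete heterogeneity beyond pace/volume, or any
physiological dose–response. Passing recovery tests therefore show that
the estimator recovers a geometric rule *under its own assumptions*, not
that GAPI is physiologically valid.

Recovery experiments use the transversal halfplane x + y < 1 (true area
ratio 1): combination 1's coordinates (distance, session-RPE) are
intrinsically correlated, so a season's points stretch along the main
diagonal, and a rule boundary *along* that diagonal is unidentifiable from
the data cloud, whereas a transversal boundary is crossed by it. Recovery
is asserted on the cohort mean of per-athlete ensemble GAPI: with only 4–8
labelled points, a single athlete's hull geometry cannot pin the ratio
tightly, and the per-athlete distribution is heavy-tailed to the right
(a 7:1 label split can push GAPI near 8), which is also why the acceptance
report includes the cohort median alongside the mean.

## Numerical choices and degenerate inputs

- Undefined quantities (monotony of a constant week, ACWR before week 4 or
  over a zero chronic load, recovery of an entry-less week) are NaN/None
  and propagate; they are never raised mid-aggregation.
- Normalisation requires a positive series maximum and errors on all-zero
  series; output maximum is exactly 1.
- Bray–Curtis of two zero vectors and the normalised squared Euclidean of
  two zero-variance vectors are defined as 0.
- Quartile banding uses minimum (competition-style) ranks with
  floor((r−1)·4/n)+1 — the only convention reproducing all 65 published
  quartile cells; ties land the whole group in its best member's band.
- Strict inequalities in the inclusion prerequisites (">80%", ">75%") are
  taken literally; exactly 80% fails.
- GAPI with an empty maladaptation region is flagged infinite, not raised;
  infinite members are excluded from ensemble means.
- Jittered x/y values are clipped at 0 and z at a small positive floor.
- Areas are cell-count fractions, so the three regions sum to 1 exactly up
  to floating-point addition (tested at 10⁻⁶).
- Goodness of fit rounds half-up (87.5 → 88, 62.5 → 63), matching the
  published integer-percent format.

## Problem sizes

Default analyses run at grid 256², 50 replicates. The test suite fits most
property checks at grid 64–128 and exercises the full-resolution path in
the recovery tests (20 athletes × 50-replicate ensembles plus a 3-level
label-noise sweep, ~25 s); the acceptance script repeats the same recovery
at the caller's seed in under a minute.

## Known limitations

- The construction is two-dimensional by design; higher-dimensional metric
  combinations are out of scope (readability was the stated point of the
  original graphs).
- GAPI depends on the *data's* coverage of the unit square, not only on the
  latent rule: correlated coordinates compress the cloud and bias the
  implied boundary (see the transversality note above).
- Cross-validation is impossible at 4–8 labelled weeks per athlete; the
  jittered ensemble quantifies stability, not out-of-sample validity.
- The embedding of the weekly triplets is the raw normalised coordinates; a
  fractal-dimension-based projection mentioned in the source literature has
  no computable recipe and is recorded as unresolved.
- Holm-corrected tables published alongside the original analysis are
  internally inconsistent with textbook Holm on the printed raw p-values;
  this implementation uses textbook Holm and does not attempt to match
  them.
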