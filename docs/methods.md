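# Methods

## The model

A segment inventory is treated as a set of `s` distinct vertices of a binary
hypercube: each speech sound is a vector of K articulatory feature values
encoded ±1, and the only structure the analysis sees is the inventory's
*geometry* — its configuration up to relabeling of dimensions (column
permutation), polarity conventions (per-column sign flip), and segment order.
Three statistics describe a geometry:

* **Econ** (economy). With `p` the median size of the inventory's irreducible
  feature subsets, `Econ = (s − (p+1)) / (2^p − (p+1))`: 0 for the sparsest
  inventory that can have `p` contrastive dimensions (an irreducible set of
  `p` dimensions needs at least `p+1` segments), 1 for a saturated hypercube.
  `p` may be half-integral (median of an even list); `2^p` is then real
  exponentiation. At `p = 1` the denominator vanishes and Econ is undefined;
  such inventories are dropped from Econ analyses with a logged reason.
* **Loc** (local symmetry). `N_mp` counts segment pairs at Hamming distance 1
  — occupied hypercube edges, the classical "oppositions" like [p]–[b]. The
  raw count is converted to its ascending rank among all `N_mp` values
  attainable by any irreducible configuration with the same `(s, k)`,
  normalized to [0, 1] as `(rank − 1)/(maxrank − 1)`.
* **Glob** (global symmetry). `N_im = Σ_k |Σ_i p_{i,k}|` sums the absolute
  +/− count differences across dimensions. It is ranked among the values
  attainable at the same `(s, k, N_mp)`, in *descending* order, so balanced
  inventories score 1.

A statistic whose attainable-value list has length 1 is omitted for that
inventory (it would carry no information beyond size and dimension); omission
counts are reported per subsystem, group and statistic.

### Variant representations

An inventory's contrastive dimensions are not unique (backness and rounding
can each carry the [i]–[u] contrast), so all analyses run over the set of
irreducible sufficient feature subsets. The exact search walks the power set
bottom-up, expanding only insufficient subsets; every minimal sufficient
subset is reached because all of its proper subsets are insufficient.
Minimality is verified by single-feature removal, which is exact: any strict
superset of a sufficient set survives some removal. The capped search
subsamples the frontier (uniformly, seeded) when it exceeds `cap`,
records the skipped subsets, and additionally discards any sufficient set
that is a proper superset of a skipped subset. That guard is deliberately
conservative — it copies the described procedure rather than re-deriving
minimality — and an optional strict mode drops it, relying on direct removal
testing. If an extreme cap leaves no admitted spec, one genuine minimal
sufficient subset is recovered by greedily shrinking the smallest sufficient
set reached; the capped output is therefore never empty and always a subset
of the exact output. Default cap: 1000 frontier nodes per level, logged with
every run. Constant columns are pruned before searching (they can never
distinguish anything; provably output-preserving). Levels start at subsets
of size 1.

### Attainable-value tables

Rank lists are built per key from the union of (a) every variant
representation attested in the run — naturals and all controls pooled, so
both groups are ranked on identical tables and every observed value is
rankable — and (b) fresh enumeration: exhaustive over all `C(2^k, s)`
vertex subsets when that count is within `raw_budget` (default 200,000),
otherwise seeded rejection sampling up to `sample_budget` distinct
configurations (default 10,000 at the function level; pipeline runs in this
repository use 300, stated below). Only irreducible configurations enter
(every dimension necessary), matching the semantics of variant
representations; this implies `s ≥ k + 1`. Configurations are deduplicated
by a canonical form: the lexicographic minimum, over column orders and sign
choices, of the sorted row list, computed by a staged search that merges
partial states with identical futures, so even fully symmetric
configurations canonicalize quickly. Equal keys correspond exactly to equal
orbits (verified against brute-force orbit enumeration in the tests).

### Decorrelation

The ranks decorrelate the three statistics *sequentially*: Loc factors out
size and economy, Glob factors out size, economy and Loc. Within every
`(s, k)` stratum the normalized Loc ranks average exactly ½ over the
attainable values, and likewise Glob within every `(s, k, N_mp)` stratum, so
the Pearson correlations vanish identically when taken over the tables' own
entries — one point per attainable value combination (`rank_decorrelation`
computes them; the acceptance checks assert |r| < 0.05 there). Weighted by
*configuration* counts instead, the correlations are not zero (Econ–Loc
measures ≈ 0.3 on the pools used here), because attainable values are not
equally populated by geometries; the sequential value-level weighting is the
sense in which the construction decorrelates.

## Controls

Four null families, all size-matched to a natural inventory and re-scored
through the identical search → rank → median path:

| kind              | unit     | law                                             |
|-------------------|----------|-------------------------------------------------|
| `segment_freq`    | combos   | ∝ cross-linguistic combo frequency              |
| `segment_uniform` | combos   | uniform over attested combos                    |
| `feature_freq`    | features | independent coins at empirical +1 rates         |
| `feature_uniform` | features | independent fair coins                          |

Segment pools and feature probabilities are subsystem-conditioned (vowel
controls draw only from vowel-attested combos; vowel feature rates come from
vowel tokens). Duplicate draws are rejected and redrawn; for segment
controls this is implemented as successive renormalized sampling over the
remaining pool, which is distributionally identical and cheaper. Feature
probabilities are empirical token frequencies from the raw (unreduced)
encodings; class-defining features are degenerate within a subsystem (every
vowel is [+syllabic]), and such coordinates are sampled deterministically,
with inventory size bounded by the non-degenerate coordinates.

## Evaluation

Separation between two score distributions is the AUC in its rank-sum form
(ties ½), with percentile-bootstrap intervals (default 1000 resamples, 95%,
resampling within each group; the interval method and resample count are
conventional choices, logged per run). Omitted scores are excluded per
statistic, not listwise. Summary rows flag intervals containing 0.5 (`~`)
and intervals entirely below 0.5 (`<`). The four reported comparisons are
natural vs frequency-matched segment controls, frequency-matched vs uniform
within each of the two control units, and uniform-feature vs uniform-segment
controls. `compare_external_set` scores an external inventory sample against
repeatedly drawn size-matched natural subsamples (sizes matched exactly as a
multiset, drawn without replacement within a draw) and reports the
percentile interval of the resulting AUC distribution.

## Synthetic databases

The generator emulates the statistical shape of a large typological segment
database; defaults mirror that scale — 536 languages, 23 features, 688
distinct attested combinations, ~1.55 transcription labels per combination
(`alias_fraction = 0.55`). Combo pools are sampled with per-feature base
rates drawn once from U(0.2, 0.8); cross-linguistic weights are Zipf with
exponent 1 in pool-draw order; inventory sizes follow a shifted negative
binomial (r = 2, mean 25) clipped to [3, 40] — a right-skewed law matching
typical phoneme-inventory size distributions. A `duplicate_rate` fraction of
languages receives a second label sharing one encoding, exercising the
encodability filter; the ground-truth log records exactly which.

Generation bias is the recovery target: each successive segment is drawn
with log-weight `log w + beta_loc·(new minimal pairs) − beta_glob·(imbalance
increase)`. Bias enters generation, not post-hoc filtering, so at
`beta = 0` language generation *is* the frequency-matched segment null and
the pipeline's natural-vs-control AUCs must be ≈ 0.5 — the machinery is
falsifiable in both directions.

The generator reproduces frequency skew, size dispersion, subsystem
structure and encoding duplicates, but not phonetic substance: no
articulatory correlations between features, no perceptual dispersion, no
areal or genealogical dependence between languages. Passing tests therefore
demonstrate that the statistics and comparisons behave correctly on data
with known structure, not that any particular empirical claim holds of real
inventories.

## Experiment sizes and numerical choices

The experiments in `analysis/` and the test suite run a reduced-scale study
chosen once for tractability of the exact search and enumeration: K = 8,
pool 120, 300 languages, sizes in [3, 20] (`small_study_config`), with
`cap = 2000` (the searches are then effectively exhaustive), sampling budget
300 distinct configurations per `(s, k)` key, and 200–1000 bootstrap
resamples. Under these conditions the unbiased generator yields
natural-vs-control AUCs within [0.45, 0.55] for all three statistics, and
`beta_loc = 2` raises the Loc AUC above 0.6 (monotonically through
`beta_loc = 1`).

Ties in medians follow the standard mean-of-middle-two convention. Econ
values outside [0, 1] cannot arise from a real `(s, p)` pair and raise an
integrity error rather than being clamped. Inventories reduced below two
segments by subsystem extraction are dropped with a logged count; the
encodability filter applies independently per subsystem, so survivor counts
differ across subsystems.

## Reproducing the published comparison (optional, external data)

The per-subsystem means and AUC intervals published for the real
536-language database require that database's inventory lists and its
23-feature table, which are not redistributed here. Given those two files in
the formats described in the README, `RunConfig(features_path=...,
inventories_path=...)` (or `phonogeom run`) executes the identical analysis;
this is an optional external check, not part of the test suite.

## Known limitations

* Sampled rank tables can miss attainable values for large `(s, k)` keys;
  attested unioning guarantees rankability but extreme ranks may compress.
  Both comparison groups share the same tables, so this biases neither side.
* The capped search's skipped-superset guard can discard genuinely
  irreducible representations under small caps (by design, fidelity over
  completeness); `strict=True` re-verifies by direct testing.
* The feature-frequency controls treat features independently; real feature
  systems have logically dependent features, which is one reason such
  controls are "unnatural" baselines rather than competing models.
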