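# Methods

## Problem and model

`trapnet` post-processes a bait-panel AP-MS/Virotrap screen. The unit of
evidence is the spectral count: the number of PSMs assigned to a protein
in one LC-MS/MS run. The screen design is 12 baits × 2 conditions
(untreated, TNF) × 3 biological replicates plus 15 negative-control
purifications with baits unrelated to the studied pathway. The analysis
makes no distributional assumption about counts; every decision is a set
operation or an integer threshold, which is why a control experiment with
a single spectral count for a protein is already disqualifying evidence.

Stages, in run order:

1. **PSM FDR** — per spectrum, the best-scoring match across the target and
   reversed-database searches is kept; FDR = decoys / all retained PSMs.
   A score tie between a target and a decoy match resolves to the decoy:
   this biases the FDR upward, never downward. The FDR of an empty set is
   0 (nothing reported, nothing false). The operation is run-scoped;
   `aggregate_fdr` pools decoy and total counts across runs.
2. **Census** — identified proteins, and bait–prey pairs with a nonzero
   count in ≥ 1 of the bait's columns. Bait self-identifications count as
   pairs here and are only removed at the lean stage (self-loops), so the
   pre-filter census is defined before any filtering.
3. **Control filter** — global removal: one control hit removes a protein
   from every bait's candidate list, not just the bait it co-occurred
   with. The published protein-level checkpoint after this step only makes
   sense with global removal.
4. **Replicate summation and strength** — per bait × condition group;
   summed count 1 = one-hit, 2 = weak, ≥ 3 = strong. Boundaries are
   configurable (`weak_value`, `strong_min`, strong must exceed weak).
5. **One-hit-wonder removal** — default grouping is per condition: a pair
   survives iff some condition sum reaches 2. The alternative (summing
   both conditions before the test) is behind `one_hit_mode="combined"`
   for sensitivity analysis. A surviving pair's sum-1 condition is kept as
   presence evidence, flagged `one_hit`; it never confers strength and can
   be dropped entirely with `keep_one_hit_presence=False`. This choice
   matters for dynamics: keeping the presence row makes a weak/one-hit
   pair `independent` rather than `appears`/`disappears`.
6. **Extensive network** — directed bait → prey; per-condition counts,
   strengths, presence; dynamics labels (appears / disappears /
   independent) partition the edges; known/novel flags from an unordered
   reference pair set.
7. **Lean network** — fixed default order: strong-edge restriction →
   self-loop removal → degree computation in the strong graph → prey
   retention (degree ≥ 3 OR rescue). The published counts do not pin this
   order down, so `order="degree_first"` (degrees include self-loops) and
   `degree_graph="extensive"` (degrees in the unfiltered graph) are
   provided as switches. Baits are exempt from the degree rule and survive
   whenever they keep an edge. Rescue semantics: a prey below the degree
   threshold is retained iff it has a known strong edge, and then keeps
   **only** its known strong edges — rescue never introduces a pair absent
   from the reference. Degree-retained preys keep all their strong edges,
   known or novel.

## Synthetic data

The generator emulates what the filters assume, not the biochemistry:

- **Background pool** (`n_background=150`): each contaminant is detected in
  any experiment — bait or control alike — with probability
  `background_detect_prob=0.8`. With 15 controls the probability a
  contaminant evades every control is 0.2^15 ≈ 3×10⁻¹¹, which is what makes
  the control filter nearly perfect under the default design.
- **Planted interactors** (`interactors_per_bait=10`) appear only in their
  bait's columns, with profile constitutive / TNF-induced / TNF-lost drawn
  from `profile_mix` (0.5/0.25/0.25). Condition-dependent profiles are
  structural zeros off-condition so dynamics ground truth is unambiguous;
  `leaky=True` adds off-condition singletons with probability `leak_prob`
  for stress tests.
- **Counts** are zero-truncated negative binomial with mean
  `count_mean=5.0` and dispersion `count_dispersion=2.0`
  (variance = μ + μ²/r), the standard overdispersed law for spectral
  counts; each replicate of an active condition is detected with
  `replicate_detect_prob=0.9`. The study constrains none of these
  abundance knobs; the values are realistic free parameters, chosen once.
- **One-hit wonders**: a fraction `one_hit_rate=0.1` of planted interactors
  is forced to a summed count of exactly 1 per active replicate group.
- **Shared preys** (`n_shared_preys=6`) bind 3–5 baits each, emulating the
  interwoven complex members seen in the real screen and giving the lean
  degree filter survivors that do not depend on rescue.
- **Bait self-counts** give every bait strong counts in its own runs,
  exercising self-loop removal.
- **Ground truth** records every planted pair with its profile and an
  expected strength derived from the realized sums, so recovery scoring is
  consistent with the data by construction. The reference-set generator
  samples a fraction (`reference_coverage=0.5`) of planted pairs plus
  never-planted decoy pairs, emulating a partial curated database.

What the simulator does **not** model: peptide-level identification and
protein inference, abundance-correlated detection, correlated
contamination across runs, batch effects, or baits appearing as preys of
other baits. Passing tests therefore demonstrate the correctness of the
filtering logic under the design assumptions, not the biological error
rate of a real screen.

## Numerical and degenerate-input choices

- Identifiers are opaque strings; decoy accessions are recognized by a
  configurable prefix (default `REV_`).
- All randomness flows through one `numpy` `default_rng(seed)` per
  generator call; identical (config, seed) reproduce byte-identical files.
- Degenerate inputs: an empty PSM list has FDR 0; an empty candidate table
  yields an empty network; a matrix without control columns makes the
  control filter error rather than silently pass everything; SIF export of
  an empty network errors (a topology-only format with no topology).
- `DiGraph.degree` counts a self-loop twice; the `degree_first` mode
  inherits that convention, and the brute-force oracle in the tests
  mirrors it independently.
- Problem sizes in the tests and the acceptance script are the default
  screen design (87 experiments, ~290 proteins); the recovery property is
  scored over 100 seeded replicate screens, enough to bound the
  background false-positive rate while keeping the suite fast.

## Known limitations

- No probabilistic interaction scoring (SAINT / CompPASS style) and no
  abundance normalization — the method operates on raw counts by design.
- The FDR module consumes PSM tables; it does not parse search-engine
  native output.
- PSI-MITAB export is the 2.5 column set with fixed detection-method and
  interaction-type terms; alias/taxon columns are left unpopulated.
- Reproducing the original screen's printed checkpoint numbers requires
  the deposited spectral-count and experiment-overview tables plus the
  matching BioGRID snapshot; the wide-TSV ingestion path and the
  order-of-operations switches exist for that purpose.
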