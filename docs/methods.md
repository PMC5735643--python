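# Methods

## Data model

A survey consists of specimen records and stomach-content items. Specimens
carry species, sex (male/female/undetermined), total length (mm), total,
gutted and stomach weight (g), capture date, the 3-h net-check label and a
repletion class — void (empty), partly full (25–75%) or full (> 75%).
Items attach a food category (fish, crustacean, microcrustacean, insect,
plant, other — a closed six-state scheme) and a raw volume to a specimen.
Volumes may be in any unit as long as it is consistent within a sample;
every downstream index is invariant to a global rescaling.

Two conventions are fixed in `core_data` and used everywhere:

* **Seasons** are month-granular: January–June is the flood (rainy)
  season, July–December the dry season, matching the Amazonian
  hydrological cycle. A record's season is derived from its capture date
  and must agree with an explicitly supplied season.
* **Interval semantics.** The eight check labels (18:00, 21:00, 24:00,
  03:00, 06:00, 09:00, 12:00, 15:00) each denote the END of a 3-h window.
  The nocturnal period 18:00–06:00 therefore owns five checks (18:00
  through 06:00) and the diurnal period three. "24:00" is kept verbatim as
  a label. The day/night chi-square defaults to an exposure-weighted
  expectation (E_night = 5n/8) because the design samples the night five
  times and the day three times; an unweighted 50/50 expectation would
  mistake sampling effort for activity. `expectation="equal"` reproduces
  the naive test for comparison with studies that used it.

## Diet composition

For a group (species × season by default) the number of content-bearing
stomachs N counts specimens with repletion ≠ void and at least one item.
FOᵢ counts a category once per stomach regardless of how many item rows of
that category the stomach has. VFᵢ is pooled: category volume summed over
all the group's stomachs divided by the grand total, not a per-stomach
mean of percentages — the standard reading of "relative volume", and the
one under which VF columns sum to 100. The feeding-importance index
IFᵢ = FOᵢ·VFᵢ/Σⱼ FOⱼ·VFⱼ is computed from the full-precision FO/VF; the
presentation layer (`diet_frame`, CLI output) rounds FO/VF to 3 decimals
and IFᵢ to 4, the conventional reporting precision. Because IFᵢ
normalises a product of two per-group quantities, it is invariant both to
volume units and to whether VF was expressed per-stomach or pooled — which
is why the published index values are reproducible even though the
published VF columns are on inconsistent scales between the two species.

## Niche breadth and overlap

Utilization matrices default to VF-based rows (volume share is the
conventional utilization measure for carnivore diets); FO- and IFᵢ-based
matrices are one switch away for sensitivity analyses. Levins standardized
breadth uses n = the number of columns of the matrix (the fixed
six-category scheme), not the count of resources actually used, so Bᵢ is
comparable across groups; pass `n_states` explicitly to change this. The
banding treats the boundary values 0.4 and 0.6 as "moderate" (closed
middle interval). Pianka overlap is computed on row-normalised
proportions; both indices are scale-invariant and covered by property
tests (symmetry, scale invariance, breadth monotonicity under spreading
mass to an unused state).

## RA3 null model

Each iteration independently permutes every row of the utilization matrix
uniformly at random, zeros included — Lawlor's RA3, which conserves the
row's value multiset and hence its Levins breadth while destroying the
resource assignment (retaining zeros is what distinguishes RA3 from RA4).
The statistic is the mean pairwise Pianka overlap; with two rows this is
the single pair's overlap, and the implementation accepts any number of
rows ≥ 2. The two one-tailed Monte-Carlo probabilities are plain
proportions of simulated values at or beyond the observed one with ties
counted in both tails (EcoSim's convention, no +1 correction), so
p_le + p_ge ≥ 1 and p = 0 is attainable when no simulated value reaches
the observed one. Tie detection uses a 1e-12 absolute tolerance so exact
permutation ties survive floating-point summation-order noise; the
vectorised simulation evaluates norms in the same order as the scalar
overlap so degenerate matrices tie exactly. Default 5000 iterations; a
single top-level seed drives one generator stream, and identical
(matrix, seed, iterations) triples give bit-identical results.

Interpretation: observed overlap in the lower tail (p(obs ≤ exp) ≤ α) is
the pattern conventionally read as competition-consistent niche
divergence; the upper tail indicates shared resource use beyond chance.
Note that a matrix with "disjoint dominant" rows is only in the lower tail
if the observed arrangement is actually extreme among permutations —
i.e. rows anti-sorted, dominants disjoint and the remaining mass in
opposite rank order; tests validate this against exhaustive enumeration of
all joint permutations on 3-state matrices.

## Frequency and size statistics

The chi-square goodness-of-fit statistic is Σ(O−E)²/E with p-values from
the asymptotic χ² distribution (counts in this design are large; no exact
tests). Yates' correction (|O−E| reduced by 0.5) is restricted to df = 1.
The G-test is 2·Σ O·ln(O/E) with margin-based expectations; the Williams
correction is available but off by default. Seasonal variation in a
category's occurrence is tested on the per-item 2×2 (season ×
present/absent) table over content-bearing stomachs. Size-structure
comparison runs Kolmogorov–Smirnov normality checks on each standardized
sample and Bartlett's variance test, then Student's t regardless,
attaching `non_normal`/`heteroscedastic` flags rather than refusing — the
caller decides whether the t-test stands. `class_histogram` allocates
lengths/weights to half-open classes [lo, lo+w) anchored at zero.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
dataset (no likelihood fitting): per species and season the specimen count
is Poisson(abundance/number of seasons); each specimen gets a sampling day
(uniform over mid-month dates of the season's sampling months), a net
check drawn from the species' activity weights, Bernoulli sex, truncated
normal length and weight (resampled below 5% of the mean — gillnets do not
catch near-zero fish — rather than clipped, to avoid a spike at the
floor), a categorical repletion class, and, if not void, 1 + Binomial(3,
0.3) items. Item categories follow the season's diet vector; volumes are
i.i.d. lognormal (σ = 0.5 by default) around a common base volume, so the
expected volumetric composition converges to the generating diet vector —
the property the parameter-recovery tests exercise (L1 error < 0.05 at
~2000 stomachs). Void stomachs carry no items by construction.

The `preset_paper_like` scenario encodes the study conditions the package
targets: abundances 341 vs 61, sex ratios 0.48 vs 0.64 female,
fish-dominated diets with the commoner species adding plant matter in the
flood season and the rarer species purely piscivorous in the dry season
(forcing its dry-season Bᵢ to 0), uniform vs nocturnal-bimodal activity.
The bimodal weight vector (peaks at 21:00 and 03:00) places 87% of
captures in the five nocturnal checks; at n ≈ 61 this gives the
exposure-weighted day/night chi-square essentially full power at α = 0.05,
which the pipeline tests verify over 100 replicates. Default sampling
layout: three days per season in a single nominal year.

What the generator does **not** emulate: size-dependent gear selectivity,
digestion-state biases in volume estimates, spatial structure, correlation
between repletion and time of capture, and prey identity below the six
broad categories. Passing tests therefore demonstrate the pipeline's
correctness and statistical behaviour under the stated sampling model, not
robustness to those field realities.

## Numerical and scope choices

* Full precision end to end; rounding only at presentation.
* Delimiter auto-detection covers comma/semicolon/tab; decimal commas are
  accepted in semicolon-delimited (regional) exports; writers always emit
  UTF-8, comma-delimited, "." decimals.
* Undetermined-sex specimens are excluded from sex-ratio tests only.
* Problem sizes in the test suite are chosen to keep the full run around
  a few seconds: null-model calibration uses 500 replicates × 200
  iterations, enumeration cross-checks use 2-row matrices with ≤ 5
  states, and power checks use 100–200 replicates.
* Only Pianka's overlap is implemented (the single index the analysis
  reports); Czekanowski/Morisita variants, RA1/RA2/RA4 algorithms and
  presence/absence C-score metrics are out of scope, as are circular
  statistics for the diel data and any prey identification below the
  six-category scheme.
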