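# Methods

## Distances

Each SGB's phylogeny is read from Newick (dendropy; plain labels, internal
node labels ignored, negative branch lengths and duplicate leaves rejected,
parse errors reported with a byte offset). The normalized phylogenetic
distance nGD is the leaf-to-leaf patristic distance divided by the total
branch length of that tree; since any leaf-to-leaf path is a subset of the
tree's branches, nGD ∈ [0, 1], and it is invariant to a global rescaling of
branch lengths. Centred nGD divides by the median off-diagonal nGD of the
same tree, placing the unrelated bulk at ~1; trees whose median distance is
zero (or whose total branch length is zero) are rejected from analysis
rather than producing 0/0.

## Calibration pair sets

Same-individual pairs: for each subject, the closest-in-time pair of
strain-profiled samples with gap ≤ 183 days ("six months"), at most one pair
per subject, ties broken toward the earliest pair. Unrelated pairs: all
cross-subject pairs excluding same-household pairs and recorded
parent–child links, with one seeded random sample per subject per SGB to
avoid pseudo-replicating individuals with many samples. Unrelated pairs are
pooled across datasets by default (calibration benefits from the largest
available set); a within-dataset mode is available.

## Threshold calibration

Candidate thresholds are the midpoints between consecutive sorted unique
pooled distance values plus one candidate strictly below the minimum (half
the minimum when it is positive, a tiny negative value otherwise). Midpoints
make the choice insensitive to floating-point noise — any threshold between
two adjacent observed values is equivalent. Among candidates with
fraction(unrelated ≤ t) ≤ 0.05, the one maximizing J = TPR + TNR − 1 is
chosen, ties broken toward the smallest threshold (conservative against
false positives). The below-minimum candidate guarantees feasibility: it
classifies nothing as shared, with J = 0. The strain-identity comparison is
inclusive (nGD ≤ t ⇒ same strain) everywhere, so a threshold equal to an
observed value captures it; a strict mode is available.

SGBs with ≥ 50 same-individual pairs are Youden-calibrated; all others, and
all oral SGBs (whose species-specific distributions cannot be reliably
estimated), use the percentile fallback: the 3rd percentile of the
unrelated distribution under linear interpolation between closest ranks
(the numpy default; recorded in output metadata). The fallback requires
≥ 34 values so that the 3rd percentile rests on at least one order
statistic rather than extrapolating below the minimum. `calibrate_all`
skips (with a logged warning) SGBs that cannot meet even that. The 3rd
percentile is itself the median unrelated percentile of Youden-calibrated
SGBs, and `derive_fallback_percentile` recomputes that quantity on any
calibrated suite.

SNV-rate-based thresholds are deliberately not implemented: at the low
per-species coverage typical of metagenomes, tree-based distances are the
more reliable signal. SNV rates enter only through the food filter.

## Food-origin strains and sharing

Within each SGB, samples whose minimum SNV rate to any fermented-food
reference genome is ≤ 0.0015 (inclusive) are excluded before any sharing
analysis, so that strains co-acquired from commercial foods are not read as
person-to-person transmission. The ≥ 10-shared-SGB gate below counts SGBs
after this exclusion (exclusion removes the strain profile).

Sharing calls are made per sample pair (nGD ≤ threshold) and collapsed to
subject pairs: sharing at any time point counts, and the minimum nGD over
contributing sample pairs is recorded. The person-to-person strain-sharing
rate is 100 × shared strains / shared strain-profiled SGBs, reported only
for pairs sharing ≥ 10 SGBs. The offspring strain acquisition rate is the
proportion of the offspring's strain-profiled SGBs whose strain is shared
with the mother, under the same ≥ 10 gate on mother–offspring shared SGBs.
Gut and oral samples are never mixed within a pair. Networks connect
subject pairs with ≥ 5 shared strains (or ≥ 50 shared SGB profiles in the
species variant), with lexicographic edge ordering for determinism.

Relationship categories are assigned with precedence mother_offspring >
father_offspring > twins > partners > siblings > household > same_village >
same_population > inter_population. Twins are subjects sharing both
recorded parents with ages within 0.25 years; partners cohabit and have a
recorded common child; subjects with missing household identifiers default
to non-cohabiting (conservative for household inference). Parent–offspring
pairs carry the offspring's age bin (≤1y, 1–3y, 3–18y, 18–30y, 50–85y; ages
outside these ranges have no bin).

## Transmissibility

Per SGB and mode, potential events are mode-eligible subject pairs in which
both subjects carry a strain profile; transmissibility is events/potential,
reported only with ≥ 10 potential events for pooled estimates and ≥ 3 for
single-dataset cells (below-minimum cells are missing, never zero). Modes
and their matched among-group (unrelated) comparison sets: mother–infant
(offspring ≤ 1 year) vs. unrelated mother × infant pairs of the same
dataset; household (cohabiting pairs) vs. same-dataset different-household
pairs; intra-population (same dataset, different household, no kinship) vs.
cross-dataset pairs. Significance uses the Pearson χ² on the 2×2
events/non-events table with Yates continuity correction on by default
(toggleable, recorded in output), a direction check (within proportion >
among proportion) standing in for one-sidedness, and Benjamini–Hochberg
correction across the SGBs tested in a mode. Highly transmitted =
transmissibility > 0.5 and adjusted p < 0.05. Cross-dataset concordance is
Spearman's ρ between per-dataset transmissibility vectors over ≥ 10 jointly
assessed SGBs.

## Synthetic cohorts

The generator emulates a multi-population transmission study: datasets
(populations) × villages × households, each household a mother, usually a
father, and 0–3 offspring (first child an infant ≤ 1 year in 60% of
households; 20% of multi-child households carry a same-age twin pair). A
configured fraction of subjects (default 0.8) is sampled twice within 183
days by exact quota. Defaults: 2 datasets × 20 households across 4 villages,
20 SGBs, ~250 samples — sized so that every SGB has ≥ 50 same-individual and
several thousand unrelated pairs while the whole suite simulates and
analyses in seconds.

Strain identity is planted as a per-SGB partition of samples. Close
relationships share dyadically with pairwise probabilities (defaults:
household 0.12, partners 0.13, father–offspring 0.12, siblings 0.12, adult
twins 0.08, mother–offspring beyond infancy 0.19 — mirroring the median
sharing rates such cohorts report), merged by union–find so "same strain"
is transitive by construction. Mother–infant pairs share with a per-SGB
transmission probability (default spread over [0.05, 0.95], mean 0.5,
mirroring both the ~50% mother–infant sharing rate and the broad spread of
per-species transmissibility). Village- and population-level sharing is
modelled as a *circulating strain*: each subject independently adopts the
village (population) strain with probability √p (defaults p = 0.08 and
0.02), so any two members share it with probability ≈ p. A dense pairwise
random graph at these rates would percolate into one giant strain class
under transitivity; the circulating-strain construction keeps classes
bounded while family members of an adopter are still dragged in, so
realized village/population sharing modestly exceeds the nominal p.
Longitudinal samples retain the subject's strain with probability 0.87 (the
within-individual retention rate such data show); otherwise they found a
new singleton class. With four small villages per population, ~2–5% of
unrelated calibration pairs are genuinely same-strain — consistent with the
calibrated thresholds sitting near the low single-digit percentiles of the
unrelated distribution, which is exactly the regime the percentile fallback
encodes.

Trees are built per SGB as a random binary backbone over strain classes
with branch lengths `backbone_scale × (0.5 + Exp(1))` — the 0.5 floor keeps
every between-class path ≥ one backbone_scale — and same-class samples
attached to their class tip with pendants ~ Exp(same_strain_scale). The
enforced scale ratio ≤ 0.01 (default 0.005) makes the same-strain peak and
the unrelated bulk separate with overwhelming probability. The class-level
distance matrix is accumulated during construction, so the generator emits
both Newick files (the primary emission, exercising the reader end to end)
and matching nGD matrices (a fast secondary emission used for large
parameter-recovery runs); a test confirms both routes agree. Food-origin
strains: a random ~30% of SGBs carry two food-reference leaves; ~5% of
carrier subjects are planted as food-origin, attached to the food class,
with SNV rates to the references drawn ≤ 0.0015 (others ≥ 0.005). FMT
triads: donors are sampled twice (always same strain), recipients
contribute pre-FMT (own strain) and post-FMT samples, the latter sharing
the donor strain with the engraftment probability (default 0.9); the
validation mapping covers donor and post samples only, since the pre-FMT
strain has no expected relation to the donor. Donor longitudinal pairs vs.
cross-triad pairs provide an independent calibration set for the FMT
threshold, keeping validation non-circular.

What the generator does *not* emulate: sequencing noise and coverage-driven
profiling dropout, within-class phylogenetic structure (same-strain leaves
are exchangeable), realistic species prevalence/abundance distributions,
and body-site differences (all samples are gut by default; oral dispatch is
tested with constructed inputs). Passing tests therefore demonstrate the
correctness and calibration of the inference machinery under the planted
model, not the biological accuracy of any real-data estimate.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation; χ² uses scipy with Yates correction;
BH uses statsmodels. Zero-margin 2×2 tables, constant concordance vectors,
SGBs without unrelated pairs, subjects without profiles, and empty
categories all yield missing values with logged warnings, never silent
zeros. Outputs are TSV with empty fields for missing values; all stages are
deterministic given seed and inputs (the run manifest records config,
package version and input hashes). Problem sizes in tests and the
acceptance script (20-SGB suites, ~450-pair recovery cohorts, 1,000-tree
oracle sweeps) were chosen as the smallest scales at which the statistical
tolerances are comfortably met.

## Known limitations

Transitive drag makes realized dyadic sharing slightly exceed nominal
probabilities in densely connected families; the planted partition (not the
nominal probability) is the ground truth used for recovery checks. The
among-group construction for mother–infant significance uses all unrelated
mother × infant pairs within a dataset rather than matched shuffles. Only
the dominant strain per sample per SGB is modelled, as in the profiling
tools this consumes; minority-strain transmission is invisible at this
resolution.
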