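# Methods

`phylopart` implements a divergence-partition analysis for multilocus
phylogeographic data: given per-locus alignments and a specimen → locality →
clade → region assignment, it quantifies how genetic divergence is
partitioned between and within mitochondrial clades and tests whether
"northern" (extra-Mediterranean) localities carry lineages that persisted in
situ through glaciations or descend from postglacial expansion out of
southern refugia.

## Distances

All analyses rest on the uncorrected p-distance: the proportion of
mismatched sites among jointly resolved sites of a sequence pair.  A site is
jointly resolved only when both sequences carry A, C, G or T there; gaps,
`N` and IUPAC ambiguity codes are excluded per pair (*pairwise deletion*).
Ambiguity codes are never scored as partial matches — an uncorrected
distance has no natural fractional-mismatch rule, and inventing one would
change every downstream statistic.  A complete-deletion mode (drop every
column with any unresolved symbol, then compute all pairs) is provided for
sensitivity checks; the two modes coincide on complete data.

A pair with zero jointly resolved sites has an undefined distance: it is
flagged and excluded from means (with a warning), never raised as an error,
so a sparse locus degrades gracefully.

Two between-group summaries exist and are deliberately kept separate:

* `group_mean_distance` / `clade_distance_table` — the *unweighted mean of
  clade-pair means* (the between-group-mean convention of standard distance
  software), used for divergence tables and the >1% clade-delimitation
  check;
* `bc_wc_statistics` — the *pooled individual-pair means* D_bc and D_wc
  (every cross-clade pair weighted equally), used by the permutation tests.

The two differ when clade sizes are unequal; both are exposed
(`bc_mode="pooled" | "pair_means"`) because published divergence figures do
not always state which convention produced them.

## Diversity statistics and rarefaction

Per group: segregating sites S (columns with ≥2 distinct resolved bases
among rows resolved there), nucleotide diversity π (mean pairwise
p-distance, per site), haplotype number h and haplotype diversity
Hd = N/(N−1)·(1 − Σp_k²).  Haplotypes are equivalence classes by exact
identity over the columns fully resolved in *every* row of the group
(complete deletion within the group); this makes h well defined in the
presence of missing data at the cost of discarding columns a single poor
sequence ruins.

Groups of unequal size are compared by rarefaction: s is set to the
smallest compared group size (sizes 0 and 1 are ignored when choosing s,
and s is chosen per locus, since loci differ in which specimens they
cover).  Each larger group is averaged over 100 random subsets of size s
drawn **without replacement** — the procedure subsamples, it does not
bootstrap (a bootstrap option exists).  Averaged h is fractional by
construction.  Each group draws from its own deterministic random
substream (derived from the top-level seed and a hash of the group id), so
adding or removing a group never changes another group's resampled values.
For small groups an exhaustive mode averages over all C(N, s) subsets.

In the standardized report rows, the sites column (`ns`) is the
complete-deletion site count pooled over the compared groups — an
interpretation of the convention used in the original diversity tables,
where the standardized rows carry a smaller, constant site count; it is
configurable because that convention is not documented anywhere
authoritative.

## AMOVA Φ_ST

Genetic differentiation among clades is the distance-based fixation index
from a two-level analysis of molecular variance on squared p-distances:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    σ²_w = SS_within / (N − G)
    σ²_a = (SS_among/(G−1) − σ²_w) / n̄,   n̄ = (N − Σ n_g²/N)/(G−1)
    Φ_ST = σ²_a / (σ²_a + σ²_w)

Groups with fewer than two members are dropped (with a warning) before the
decomposition — a single sequence carries no within-group information.
Significance comes from shuffling individuals among groups, holding group
sizes fixed, and counting permuted Φ_ST values at least as large as the
observed one.

## Permutation tests

All permutation p-values use p = (exceedances + 1)/(n_perm + 1), so the
smallest reportable value at 1000 permutations is 0.001; ties
(T_perm = T_obs) count as exceedances.  Both choices are conservative; a
raw-proportion mode exists for oracle comparisons.  Note the consequence
on degenerate toys: with two clades of two sequences, one third of
permutations reproduce the observed partition and tie, so the exact p is
1/3 even under "perfect" structure — the p-value floor is only reachable
when re-drawing the observed partition by chance is negligible.  All tests
are bit-reproducible from an integer seed.  Sequences can be grouped into
exchangeable units (e.g. the two phased haplotypes of a diploid) that are
permuted together, avoiding pseudo-replication at nuclear loci.

**D_bc vs D_wc.**  The prerequisite of the origin tests: T = D_bc − D_wc
with a null built by shuffling individuals among clades.  One-sided — the
question is whether between-clade divergence exceeds within-clade
diversity.

**Northern-origin tests.**  For a northern locality *i* and a reference
set of southern localities, D_i is the mean p-distance between the
northern sequences and the reference pool.  Each permutation reassigns
individuals to locality slots (locality sizes fixed; clade labels follow
localities through the locality → clade map, which is how a test that
shuffles "among localities" can still recompute clade-level statistics).
Two one-sided p-values are reported per comparison:

* `p_wc` for D_i − D_wc: is the locality's divergence from the reference
  pool significantly *above* the within-clade level?
* `p_bc` for D_bc − D_i: is it significantly *below* the between-clade
  level?

Localities or clades with a single sequence still contribute to D_i (one
sequence suffices for a cross-mean) but never to D_wc.

**Battery and classification.**  `run_origin_battery` tests every sampled
northern locality against the all-southern set and against each contiguous
southern refugium its block defines (a locality between two refugia gets
both).  `classify_battery` then calls a locality `southern_origin` when
*any* reference pool leaves D_i at the within-clade level (its sequences
are exchangeable with that pool — the signature of a postglacial colonist,
which the contiguous comparison is designed to catch), and `in_situ` when
D_i is significantly above the within-clade level against every reference
pool.  The between-level comparison (`p_bc`) is reported per row as a
diagnostic but does not drive the call: when lineage divergences vary
severalfold — as they do in real data — an independent northern lineage of
middling divergence legitimately sits below the pooled between-clade mean,
and `p_bc` alone would flip on the sign of that sampling accident.  The
per-comparison interpretation (`classify_origin`: p_wc significant and
p_bc non-significant ⇒ between-clade-level divergence) is retained for
single tests.

## The synthetic-data generator

`simulate_dataset` produces clade-structured alignments with known ground
truth, emulating the statistical structure the analysis consumes without a
full coalescent:

* a root sequence uniform over {A,C,G,T}, length L per locus;
* clade ancestors evolved from the root under Jukes–Cantor with branch
  lengths chosen so the **expected observed p-distance** between two
  ancestors equals the configured d (the JC relation
  T = −¾·ln(1 − 4d/3) converts observed distance to substitutions; each
  ancestor gets T/2) — d is stated on the scale the tests consume;
* per-clade branch heterogeneity: each ancestor's branch is scaled by
  Uniform(1 − spread, 1 + spread), default spread 0.75, so pairwise
  divergences span roughly [0.25d, 1.75d] around mean d.  Real refugial
  lineages diverge severalfold around their mean (the motivating dataset
  spans 1–7.4% around 4.5%), and this heterogeneity materially widens the
  permutation nulls of the origin tests — a generator with equal branches
  is an unrealistically easy target;
* within each clade a star genealogy: every individual receives an
  independent Poisson(θ·L/2) number of site mutations from its clade
  ancestor, giving expected within-clade pairwise diversity ≈ θ for small
  θ (between-clade distances gain the same ≈ θ tip contribution on top of
  the ancestor divergence);
* optional i.i.d. masking of symbols to N (`missing_rate`).

Scenarios: `panmixia` collapses all ancestors onto the root;
`refugial_structure` is the plain K-clade model;
`northern_recent_expansion` draws the designated northern locality's
individuals from a named southern clade's pool (and labels them with that
clade, as a data-driven delimitation would); `northern_in_situ` gives the
northern locality its own ancestor at divergence d.  Defaults are K=4
clades of n=6, d=0.03, θ=0.005, L=1284 — the scale of the motivating
dataset's combined mitochondrial fragment.  `study_scale_config` produces
17 clades with the study's per-clade sample sizes (79 sequences) at
d=0.04, i.e. pairwise divergences ≈ 1–7%.  `scenario_suite` bundles one
dataset per scenario for end-to-end checks.

What the generator does **not** emulate: coalescent genealogies within
clades (so site-frequency-spectrum shape is not realistic — π is
calibrated, Tajima-style skew is not), recombination, rate variation among
sites, unequal base composition, selection, migration, or geographically
structured sampling within localities.  Passing tests on simulated data
therefore validate the partition statistics and the permutation machinery,
not inference under demographic complications the model omits.

## Problem sizes and numerical choices

The calibration batteries run at: 200 panmictic replicates (θ=0.005,
L=1000, 20 sequences in 4 pseudo-clades) for type-I error; 100 structured
replicates (defaults above) for power; 100 replicates per northern
scenario for classification accuracy; 1000 permutations per test (999 for
the type-I battery), 10⁴ where Monte-Carlo p-values are compared against
exhaustive enumeration.  Distance matrices are computed exactly (integer
mismatch counts over integer site counts); no tolerance is involved in the
distance/diversity oracles.  Random draws use NumPy's PCG64 generator
throughout; every public entry point takes an explicit seed.

## Limitations

* Clade assignments are consumed as given; the package checks the >1%
  divergence rule but does not infer clades (no tree building).
* Φ_ST follows one standard AMOVA dialect; other software differs in
  small-sample corrections, so cross-program agreement is expected only to
  about ±0.01.
* The origin tests assume the locality → clade map stays meaningful under
  permutation; localities without clade assignment join the shuffling but
  contribute nothing to D_bc/D_wc.
* p-values are Monte-Carlo estimates with resolution 1/(n_perm + 1).
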