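# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `acutoxmap`, and what the synthetic benchmark does and does
not demonstrate.

## Toxicity labels and GHS categories

A chemical is **nontoxic** when its rat oral LD50 exceeds 2,000 mg/kg or it
carries an explicit limit-test "nontoxic" designation, and **toxic**
otherwise; the boundary dose of exactly 2,000 mg/kg is toxic.  A nontoxic
flag combined with an LD50 at or below the threshold is rejected as an
inconsistent record rather than silently resolved.  GHS acute oral
categories are the bands 1: ≤ 5, 2: ≤ 50, 3: ≤ 300, 4: ≤ 2,000,
5: ≤ 5,000 mg/kg, boundaries assigned to the lower (more toxic) category per
GHS convention.  LD50 above 5,000 mg/kg is *unclassified* by default; a
config switch (`merge_ghs_above_5000`) folds it into category 5 for users
whose upstream curation already does so.  "Very acutely toxic" is
LD50 ≤ 50 mg/kg (GHS 1–2).  This threshold is a documented choice — the
vocabulary of "very" vs "extremely" toxic (≤ 25 mg/kg) varies between
sources — and is configurable (`very_toxic_threshold`).

Inputs must already be reduced to one representative LD50 per chemical;
multi-study LD50 curation is upstream of this package.

## Tanimoto/Ward clustering

Distances are `1 − |a∧b|/|a∨b|` on binary fingerprints.  Two all-zero
fingerprints get distance 0 (the 0/0 case): identical inputs are identical,
preserving the identity axiom; such chemicals are warned about because
co-clustering on an empty fingerprint is rarely meaningful.

Ward clustering is implemented in-package with the Lance–Williams
recurrence because two details are part of the contract and are not
guaranteed by library implementations:

- **Dialect.** The default ("D2") applies the recurrence to squared
  distances and reports square-root merge heights — the textbook Ward
  objective.  The unsquared variant ("D") is available via
  `ward_dialect="D"`; the dialect in force is recorded in the run manifest.
- **Determinism.** When two candidate merges tie exactly, the pair with the
  lexicographically smallest member indices is merged, so a fixed input
  ordering yields a fixed tree.  Exact ties are common with binary
  fingerprints of modest width.

Flat clusters are the connected components after removing merges above the
cut height (default 0.7), renumbered 1..k by first appearance.  Chemicals
without fingerprints are excluded from clustering, reported as
`unclustered`, and can still receive a cytotoxicity-based composite AC50
downstream.  Tests cross-check the D2 dialect against
`scipy.cluster.hierarchy` on tie-free instances and against a separately
coded naive O(n³) agglomerator on random instances.

## Burst filtering

`burst_hit = 1` iff tested, raw hit, AC50 defined, and AC50 strictly below
the chemical's lower bound of cytotoxicity ("below" is read strictly; a
switch admits equality).  Untested combinations are a distinct state,
written as an empty field, never 0.  Chemicals with no lower bound follow
the conservative default policy: every raw hit is treated as within the
cytotoxicity range (no target-specific activity is manufactured) and the
chemical is flagged; an alternative policy applies a configurable global
bound (default 1,000 µM).

## Enrichment

2×2 tables are oriented conventionally (TP = labeled and active,
FP = unlabeled and active, FN = labeled and inactive, TN = neither); MCC and
the Fisher p are invariant under the FP↔FN swap, so either verbal convention
yields the same statistics.  MCC with a zero marginal is defined as 0
(standard convention, avoids NaN propagation).  A chemical enters an assay's
table only when tested in that assay: counting untested chemicals as
inactive would couple MCC to testing coverage rather than biology.
The FDR is Benjamini–Hochberg across the assays of one analysis (per cluster
for the cluster contrast); the enriched flag itself uses the raw p (≤ 0.05)
together with MCC ≥ 0.1 and ≥ 3 labeled actives.  Fisher exact p-values come
from `scipy.stats.fisher_exact`; the reported odds ratio is the sample odds
ratio TP·TN/(FP·FN), +∞ when only the off-diagonal is empty.

## Greedy set cover

Per step the score is (newly covered toxics) − (nontoxic burst-actives in
the assay).  The toxic term is recomputed over still-uncovered chemicals
each iteration; the nontoxic penalty is static, since only covered toxics
are ever removed from consideration.  Tie-break ladder: static total of
toxic burst-actives (including already-covered — otherwise it would
duplicate the first criterion), ascending FDR from the toxic-vs-all
enrichment, ascending FDR from the very-toxic enrichment, then lexicographic
assay id as a final deterministic tie-break (an addition; the ladder can
otherwise still tie).  Assays contributing zero new toxics are never
selected; selection ends when every coverable target is covered.  Targets
unreachable through the candidate pool are reported in `uncovered_toxics`
with a warning, not an error.

Cluster-scope candidate pools are the cluster's enriched assays.  A cluster
whose members are too sparsely tested can never satisfy the ≥ 3-active
enrichment gate (a single-tested-chemical cluster being the extreme case),
so such clusters fall back to every assay with ≥ 1 burst-active toxic
member, flagged `fallback` in the output.  Both the toxic targets and the
nontoxic penalty of a cluster run are the cluster's own members; the global
run uses all chemicals.  Cytotoxicity-type assays can be excluded from pools
via a config list, since an assay that measures cytotoxicity itself cannot
serve as a cluster-specific mechanism readout.  Greedy set cover is an
approximation; tests verify feasibility always and report the gap against
an exhaustive minimum-cover oracle on small instances (exact cover at
production scale is out of scope).

## Composite activity and association

`composite_ac50 = min(cluster_ac50, cytotox_point)` over whichever are
defined, where `cluster_ac50` is the minimum AC50 among the chemical's
cluster assays in which it is **raw**-active — the composite deliberately
re-admits cytotoxicity-range activity, since the minimum with the
cytotoxicity point is meant to be a single potency summary, not a
target-purity call.  Status: active iff composite < 1,000 µM; a chemical
tested in ≥ 1 cluster assay or carrying a cytotoxicity point but with no
composite value is inactive; a chemical with neither is unevaluable and is
excluded from association tests.

The r×c Monte-Carlo Fisher test fixes both margins by randomly permuting the
column-label vector, compares fixed-margin table probabilities (via
log-factorial sums; margin-constant terms cancel), and uses the add-one
estimator `(1 + #{P(sim) ≤ P(obs)}) / (1 + n_reps)`, which never returns 0 —
its floor at the default 20,000 replicates is 1/20,001.  Zero rows/columns
are dropped with a warning.  The simulation seed is recorded in the
manifest.  "Neighboring" GHS categories in the cluster-span summary are
consecutive integers; unclassified chemicals are excluded from spans.

## Synthetic study generator

The generator emulates a curated LD50 reference set joined to a sparse
screening database, with ground truth for every pipeline stage:

- **Structure**: each of 40 clusters shares 24 core bits of a 256-bit
  fingerprint (width kept below typical chemotype sets for test speed;
  configurable), copied per member with 2% per-bit flip noise; 40 background
  chemicals get random fingerprints at matched density.  At these defaults
  Ward at cut 0.7 recovers the planted partition with ARI ≈ 1.0, and still
  ≥ 0.9 at 5% flip noise.
- **Toxicity**: each cluster draws a base GHS tier (the four toxic tiers
  with total probability 0.8, the nontoxic tier 5 otherwise); members drift
  to one fixed neighboring tier with probability 0.2, so clusters span 1–2
  neighboring GHS categories by construction.  LD50s are lognormal around
  the geometric centre of the tier band (σ = 0.5 log-units, clipped to the
  band).  10% of tier-5 chemicals carry only a limit-test flag, no LD50.
- **Activity**: each cluster with ≥ 1 toxic member gets one mechanism assay;
  its toxic members, where tested (70% coverage, with one member forced
  tested so every planted assay has an active toxic), are active with
  lognormal AC50 around 1 µM.  Cytotoxicity points are lognormal
  (σ = 0.9) with median 20·1.8^(tier−1) µM for toxic tiers and 1,500 µM for
  nontoxic chemicals — more toxic chemicals are cytotoxic at lower
  concentrations, planting the positive activity–toxicity dependence the
  association stage is meant to detect.  The lower bound of cytotoxicity is
  the point divided by 3.  Background hits occur at 1% of tested pairs; 30%
  of them fall below the lower bound (surviving the filter as false
  mechanism signal), the rest at 1–5× the cytotoxicity point.
- The mechanism potency median must sit below the most-toxic-tier
  cytotoxicity lower-bound median (validated before generation), so planted
  hits survive the burst filter with high probability (> 97% at defaults).

One `numpy` Generator drives everything in a documented draw order, so a
seed pins the study byte-for-byte across platforms.  `null_study` regenerates
the identical study and then shuffles only the (LD50, flag) pairs across
chemicals, preserving every marginal while severing the activity–toxicity
link.

**What passing tests show — and don't.**  The benchmark demonstrates that
the implementation recovers planted structure under calibrated noise and
reproduces the qualitative contrast of interest (cluster-conditioned
selection slashes the selection FDR at a modest coverage cost).  Real
screening data differ in ways the generator does not model: assay-technology
covariance, dose–response curve-fit artifacts, heavily non-uniform testing
designs, structural series that straddle mechanism boundaries, and realistic
chemistry (fingerprints are abstract bit patterns, not molecules).  Absolute
rates measured here (FDRs, recovery percentages, odds ratios) are properties
of the generator's settings, not predictions for any real dataset.

## Problem sizes and runtime

Unit tests run a reduced study (12 clusters, ~90 chemicals, 40 assays); the
default study (40 clusters, ~440 chemicals, 120 assays) is used for
end-to-end checks and the acceptance script.  Monte-Carlo agreement is
checked on 50 tables at 20,000 replicates; the greedy-cover oracle on 200
instances with ≤ 12 assays (exhaustive search is exponential in the assay
count).  The whole suite completes in well under a minute on one CPU.

## Known limitations

- Greedy cover gives no optimality guarantee; the oracle comparison reports
  the gap only at small scale.
- Permutation invariance of the clustering partition holds up to exact
  distance ties; with heavily tied binary data, different input orders can
  yield different (equally valid) trees.
- The composite AC50 ignores toxicokinetics; in vitro–in vivo extrapolation
  is explicitly out of scope.
- Fingerprint computation from structures (SMILES) is not included;
  fingerprints are consumed as input.
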