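# Methods

This note records the models, parameter choices and numerical decisions
behind `circregnet`, and what the synthetic-data validation does and does
not establish about real data.

## Experimental design and data model

The target design is a five-stage adipogenic differentiation course of
chicken abdominal preadipocytes (0, 12, 48, 72, 120 h; stages A0–A120)
with three replicate libraries per stage, profiled in three layers:
back-splice-junction (BSJ) read counts per circRNA, read counts per mature
miRNA, and fragment counts per gene.  Every layer is carried as an
`ExpressionMatrix` — features x samples with an explicit abundance unit
(`raw_count`, `SRPBM`, `TPM`, `FPKM`) and the sample design attached — so
that feeding the wrong unit into a stage raises instead of silently
computing nonsense.

Normalizations are the conventional within-sample scalings:

* SRPBM = junction count x 10^9 / total mapped reads of the library
  (the denominator is total mapped reads; a uniquely-mapped variant can be
  supplied instead, since which total a given upstream caller used is not
  always recorded);
* FPKM = fragment count x 10^9 / (library fragment total x length in nt);
* TPM = length-corrected rate rescaled so each sample sums to 10^6.

No between-sample normalization (size factors, quantile) is applied — these
layers are conventionally reported as SRPBM/TPM/FPKM without it.  No
pseudocounts are added at normalization time; the log pseudocount belongs
to the testing and correlation steps (default c = 1).

## Synthetic-data generator

The generator is first-class, tested code: it draws the three count layers,
matched sequences (circRNA spliced sequences, gene 3'UTRs, mature miRNAs)
and a GTF-lite annotation, together with a `SyntheticTruth` object naming
every planted structure.

**Counts.** Negative binomial, `var = mu + d * mu^2`, with per-feature
baselines `base_mean x Lognormal(0, 0.4)` and per-layer defaults

| layer | base mean | dispersion d |
|-------|-----------|--------------|
| circRNA BSJ | 150 | 0.05 |
| miRNA | 500 | 0.05 |
| mRNA | 500 | 0.02 |

These are deep-library (~1.1 x 10^8 mapped reads, drawn uniformly from
[0.9, 1.3] x 10^8 per sample) clonal-cell-line conditions: replicates of an
immortalized line are technical-plus-culture replicates, which is the low
dispersion regime in which an FDR < 0.01 gene threshold is attainable at
n = 3.  The miRNA panel defaults to 150 features because TPM couples
features through its denominator: with very small panels the planted
swingers dominate the column totals and imprint systematic anti-phase
trajectories on every flat miRNA — a real compositional artifact, but one
that would dominate a tiny panel unrealistically.

**Trajectories.** Planted features follow one of seven stage-trajectory
families, written as shapes over (A0, A12, A48, A72, A120) in [0, 1] and
scaled to a log2 amplitude of 4 (16-fold swing) around their own mean:
three "module" families (`early_peak`, `late_peak`, `mid_peak` — transient
induction/repression shapes) and four "triplet" families (`early_jump`,
`early_drop`, `late_burst`, `late_decline` — single-switch shapes whose one
step is the full 4-log2 jump).  The library was designed with two
properties:

* *negation closure where couplings need it* — `1 - shape` of
  `early_peak`, `early_jump` and `late_burst` are themselves families, so a
  planted negative coupling produces a partner whose trajectory is again a
  library family rather than an eighth, unnamed pattern;
* *mutual near-orthogonality* — all cross-family correlations are ≤ 0.28 in
  absolute value apart from the three negation pairs.  With 15 samples the
  p < 0.05 correlation filter passes |r| > 0.514, so planted structure in
  one family cannot leak into another through the correlation constraints.

**Planted structure.** By default: 50% of circRNAs and genes carry a
trajectory; 8 ceRNA triplets (circRNA and mRNA share a triplet family, the
miRNA gets its negation; one 8mer seed site planted on the circRNA and on
the gene's 3'UTR); 30 exonic circRNAs negatively coupled to a dedicated
parental gene (gene trajectory = negated family) and 15 intronic circRNAs
positively coupled (same family); class mix ~75% exonic / 12% intronic /
13% intergenic; 70% of circles carry one planted ORF (150–300 nt, 30% of
them crossing the BSJ); circle spliced lengths 250–600 nt, 3'UTRs 200–400
nt.  Planted counts scale down proportionally for small layer sizes.
Sequences use the DNA alphabet for circles/UTRs and RNA (ACGU) for miRNAs;
the seed matcher normalizes U/T.  The annotation is constructed so each
planted class is recoverable: exonic circles sit on exact exon boundaries
of their host gene, intronic circles strictly inside one intron,
intergenic circles on a chromosome whose only gene is > 10 kb away.

**What this does and does not emulate.** The generator reproduces the
count character, depth, design and effect structure of the target
experiment, but it is deliberately identifiable: trajectory families are
near-orthogonal, triplet families are distinct from the bulk module
families, planted sites are 8mers, and there is no isoform ambiguity,
mapping error, batch structure or GC bias.  Passing recovery tests
demonstrates that the inference stack is correct and calibrated under its
own assumptions — not that ceRNA triplets or parental couplings are
identifiable at these rates in real tissue, where trajectory families
overlap and the number of true sponges is unknown.

## Differential expression

DE is Welch's unequal-variance t on log2(x + c) of normalized abundances,
per stage-adjacent contrast (A0 vs A12, A12 vs A48, A48 vs A72,
A72 vs A120), with Benjamini–Hochberg adjustment within each contrast
(delegated to statsmodels behind the `bh_adjust` surface and verified
against the brute-force min-over-tail definition).  Calls: circRNA and
miRNA at fold change ≥ 1.5 and p < 0.05; genes at |log2FC| ≥ 1 and
FDR < 0.01; a feature is "differential" if called in any contrast.  This
is a deliberate, documented replacement for a count-model fit: it keeps
the threshold semantics while remaining simple and calibrated at desk
scale.  At n = 3 it is mildly conservative — the null positive rate at
p < 0.05 sits near 0.03–0.045 rather than 0.05 (measured on ≥ 2,000 null
features) — and its variance estimates are noisy, which is why detection
of a given jump is only near-certain in the low-dispersion regime above.
Features with zero variance in both groups are assigned p = 1: degenerate
features are never called.  Fold changes use pseudocount c = 1, so
zero-mean features get bounded log2FC.

## Pattern clustering

Differential circRNAs and genes are reduced to 5-point stage profiles
(log2(x+1), replicates averaged per stage), z-scored per feature (the
heat-map transform), and clustered with Euclidean K-means: k-means++
initialization, 10 restarts, ≤ 300 iterations, fixed seed (k defaults to
15).  Clusters are then merged into trend groups by single linkage on
centroid Pearson correlation at r ≥ 0.8, and groups are ordered by their
first-stage centroid mean.  The cluster→group step has no canonical
definition in the field; single linkage on centroid correlation is this
package's choice because it is deterministic and reproduces the planted
family count on synthetic data.  Features that pass the DE thresholds by
chance (null features with a lucky contrast) enter clustering with
arbitrary profiles and can form extra low-occupancy groups; recovery tests
therefore score group count and purity on truth-labelled features.

## Signed co-expression network

Input is all circRNAs + mRNAs on log2(x+1) abundances (constant features
dropped with a warning).  Signed adjacency `a_ij = ((1 + r_ij)/2)^beta`;
topological overlap
`TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)` with unit
diagonal.  The soft power is scanned over 1..30 against approximate
scale-free topology (10-bin log-log regression of p(k) on k; signed fit
−sign(slope)·R², target 0.8); when no power reaches the target — the usual
situation for strongly modular desk-scale data, whose degree distribution
is not scale-free — the scan warns and falls back to the conventional
operating point beta = 12, which is also the pipeline default.

Modules come from average-linkage hierarchical clustering of `1 − TOM`
with a static cut.  The cut height defaults to **0.92**: correlated
families complete their subtrees below ~0.89 while mutually unrelated
features merge between ~0.93 and 1.0, so a cut between the regimes sends
noise to the unassigned (`grey`) label; cutting at ~0.995 instead merges
everything into a handful of giant clusters and recovers nothing.  (The
adaptive dynamic tree cut used by the standard implementation solves the
same problem; a static cut is reproducible and sufficient here, and the
height is configurable.)  Clusters below the minimum size (30) are grey.
Module eigengenes are first principal components of the standardized
module expression, sign-oriented to correlate positively with the module
mean — the PC sign is arbitrary and must be fixed for testability.
Modules whose eigengenes correlate above 1 − 0.25 are merged iteratively.

Module–trait statistics use one-hot stage indicators: module–stage Pearson
r with two-sided p from the t transform (df = n − 2); gene significance
GS (feature vs stage indicator) and module membership MM (feature vs
eigengene); a feature is a hub when its module has a stage correlation at
p < 0.01 and |GS| > 0.8 and |MM| > 0.8 for that stage.  Top intra-module
edges are ranked by TOM with lexicographic tie-breaking (default 200).

One behavior worth knowing: FPKM/TPM denominators vary across stages when
many features swing, so "flat" features acquire a weak shared anti-trend
and can assemble into a normalization-driven module (M1 in the README
example).  This is a faithful property of ratio normalizations, not a
bug; recovery is scored against planted memberships.

## Parental-gene correlation

Each circRNA is paired with its parental gene (exonic/intronic: host gene;
intergenic: nearest gene within 10 kb, else none) and correlated across
all samples on log2(x+1) abundances — Pearson by default (a Spearman flag
exists), with the exact t-transform p.  Pairs with p < 0.05 are effective;
effective pairs are classified strong-negative (r < −0.5), strong-positive
(r > 0.5) or weak, and summarized per circRNA class.  Pairs whose members
are missing from a matrix are reported as skipped, never dropped silently.

## ceRNA triplets

Seed matching follows the canonical classes: 6mer core (target
complementary to miRNA positions 2–7), 7mer-m8 (2–8), 7mer-A1 (2–7 plus A
opposite position 1), 8mer (both).  The scanner reports the best class per
core position, floors at 7mer by default, and extends circRNA targets a
short window across the BSJ so junction-spanning sites are found (they are
real on the circle).  Free-energy and context scoring are deliberately not
re-implemented: the downstream filter uses site existence plus
correlation, not scores.

A triplet (circRNA, miRNA, mRNA) is emitted when all of: the miRNA has a
site on the circRNA and on the gene's 3'UTR; circRNA–miRNA r < 0 and
miRNA–mRNA r < 0 and circRNA–mRNA r > 0, each at p < 0.05; and (by
default) all three members are differentially expressed.  An independent
audit pass re-checks every emitted triplet against all five conditions.
The *pipeline* default for assembly is the 8mer floor: a bare 7mer floor
is far laxer than intersecting two dedicated target predictors, and at
desk scale it lets chance 7mers on members of large co-expression families
multiply through the correlation filter (a single fluke differential
miRNA weakly anti-correlated with a 100-feature family can seed several
spurious triplets).  The scanner's own default remains 7mer for users who
want sensitivity.

## Circular ORFs and coding potential

ORFs are enumerated on the doubled sequence (seq + seq): every ATG with
start below L is walked in-frame to its first stop; ORFs of ≥ 150 nt are
reported with `crosses_bsj = start + length > L`.  Reading is capped at
two laps: a stop-free frame (potential rolling-circle translation) is
reported at the maximal scanned length with a `no_stop` flag rather than
extended indefinitely, since the downstream accounting only distinguishes
ORF presence and BSJ crossing.  Stops are TAA/TAG/TGA (standard nuclear
code); all ATG starts are reported by default (per-circle presence is
insensitive to this); only the given strand is scanned.  Correctness is
pinned to an independent all-rotations oracle.  IRES prediction is out of
scope — flags from an external predictor are accepted as input (the
pipeline simulates a 70% prevalence when none are supplied) — and coding
potential is the conjunction: IRES present AND ≥ 150 nt ORF present, with
Venn-style accounting overall and per circRNA class.

## Pipeline and reproducibility

`run_pipeline` executes the nine stages (simulate/ingest, normalize,
annotate, DE, cluster, network, parental, ceRNA, ORF) from a single JSON
configuration that rejects unknown keys; every output lands in a manifest
with SHA-256 hashes, and identical configurations reproduce identical
hashes.  A circRNA is nominated "candidate regulatory" when it is a hub in
a stage-significant module and differentially expressed.  All randomness
flows from the single seed; the generator refuses to run without one.

Problem sizes used throughout testing and in `scripts/acceptance.py`
(200 circRNAs, 150 miRNAs, 500 genes, 15 samples; 2,500 features for null
calibration; 200 random circles and 1,000 random p-vectors for oracle
equivalence) were chosen as the smallest scales at which all planted
structure is comfortably above the detection thresholds and the
Monte-Carlo tolerances are meaningful.

## Known limitations

* Welch's t at n = 3 is low-powered and slightly conservative; a shared
  dispersion model would be required for weaker effects than the planted
  16-fold swings.
* The static tree cut replaces dynamic tree cutting; its default height is
  tuned to the two-regime structure of desk-scale dendrograms and may need
  adjustment for very different feature counts or powers.
* Seed matching ignores pairing thermodynamics, 3' supplementary pairing
  and conservation.
* Classification trusts exact exon boundaries within ±2 nt; callers with
  larger systematic offsets would need a wider tolerance.
* Recovery rates quoted by the acceptance script are properties of the
  generator's identifiable regime, not estimates of real-data performance.
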