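# Methods

This note documents the models, estimators and numerical choices behind
`gutsort`, and what its synthetic benchmark does and does not establish
about real data.

## Read model and tag-aware dereplication

A read is `MID + PERMUTAG + linker + primer + insert`. Parsing is staged
and strict-to-tolerant: the MID must match exactly (barcodes are designed
codes; tolerating mismatches would confound libraries), the 8-base
PERMUTAG must satisfy its IUPAC pattern positionwise (an invalid tag is
excluded, never "repaired" — the tag's job is discrimination), the 2-base
linker must match exactly (too short for tolerance), and the primer
tolerates up to 2 substitutions with no indels (priming-site variation
without alignment machinery). Failures are categorized (`no_mid`,
`bad_permutag`, `bad_linker`, `bad_primer`) so read accounting is exact
at every stage. Reads are assumed forward-oriented; an optional flag
checks the reverse complement before declaring `no_mid`.

Dereplication collapses reads identical in **length and full tagged
sequence**, PERMUTAG included, keeping the first occurrence. Because an
emulsion-PCR duplicate is a byte-identical copy (same tag), while two
reads of the same template sequence from different molecules carry
independent tags (collision probability 1/256 per pair), this removes
amplification artifacts with minimal loss of true abundance signal. The
operation is idempotent and conserving (multiplicities sum to the input
count).

## LCA assignment

For each read, hits below 80% identity are dropped; of the rest, hits
with bitscore ≥ 0.9 × the read's best bitscore are retained (ties at the
maximum always survive). The read is assigned to the lowest common
ancestor of the retained subjects' lineages. Both thresholds are
config-exposed; the defaults follow the common LCA-binning convention
since no single pair of values is canonical. A read whose LCA is
shallower than family counts as *unclassified* at family rank (it still
counts at the ranks its LCA does reach); a read with no retained hits is
*unassigned* and excluded from abundance tables but reported. Counts are
conserved: Σ taxa + unclassified + unassigned = reads in, at every rank.

## Community statistics

Family counts are normalized per library to percentages (columns sum to
100). Bray-Curtis dissimilarity, complete-linkage clustering (ties broken
toward the lowest index pair, so dendrograms are deterministic; the
clusterer is a direct O(n³) implementation verified in tests against both
a stepwise brute-force oracle and scipy), analytic rarefaction via the
hypergeometric expectation E[Sₙ] = Σᵢ(1 − C(N−Nᵢ,n)/C(N,n)) computed with
log-gamma for stability (a seeded resampling mode exists for
cross-checking), and Shannon H with natural log.

### Sequential PERMANOVA

The distance matrix is squared, Gower-centered (G = −½·J·D²·J), and its
trace — the total sum of squares — is partitioned sequentially among the
ordered terms *actives-vs-totals*, *samples*, *fractions*. Each term's SS
is tr(HₖG) where Hₖ is the orthogonal projector onto the column space the
term's dummy block adds beyond its predecessors (projectors via SVD;
rank-deficiency handled, a fully aliased term keeps df 0 and no test).
Order matters and is config-exposed: entered first, the active/total
contrast absorbs one of the fraction factor's four contrasts, giving the
df column 1, 3, 3 with residual 12 on a 20-library design. Pseudo-F is
(SSₖ/dfₖ)/(SS_res/df_res); p-values come from free permutation of library
labels (no strata) with the (+1)/(+1) convention, p = (#{F* ≥ F}+1)/(B+1),
which avoids zero p at finite B. With B = 199 the null rejection rate at
α = 0.05 is exact by construction, and the implementation agrees with
vegan's `adonis2(..., by="terms")` to 8 decimals and reduces to classical
sequential ANOVA under Euclidean distances on univariate data (both are
test oracles).

### Welch comparison

For each family, each subject contributes one active value (median
percentage across its PA/LC/HC libraries) and one total value (median
across FS/R): n = #subjects per group. This per-subject-median reading
keeps subjects as the unit of replication; pooling libraries instead
(n = 12 vs 8) would treat correlated within-subject fractions as
independent. Subjects in which a family is absent are dropped from that
group (a config flag includes zeros instead). The statistic is Welch's
t with Welch-Satterthwaite df, two-sided. Groups whose variance is zero
to float precision (relative tolerance 1e-9) are handled explicitly:
equal means give t = 0, p = 1; unequal means are flagged degenerate
rather than reported as astronomically significant. Raw p-values by
default, matching the single-family-at-a-time reporting convention;
Benjamini-Hochberg is available behind a flag.

## The ORB/URB cutoff

Per library, family percentages are sorted descending (ties
alphabetical). log₁₀(percentage) is smoothed against rank by local
quadratic regression with tricube weights (window = `span` × number of
points, default span 0.15); local quadratic reproduces a log-linear
(single geometric) curve exactly, so such a curve yields zero curvature.
The second derivative is the central finite difference of the smoothed
values at integer ranks. Curvature within a deadband — 5% of the curve's
maximum |d²|, floored at 1e-4 log-units/rank² — counts as zero, so float
jitter and deep-tail count plateaus cannot manufacture sign changes. An
inflection is any rank where the thresholded curvature sign changes
(entering or leaving a curvature region included).

The library cutoff is the smoothed percentage at the **last inflection
along the sorted curve**. Under the conventional ascending sort, "last"
is the high-abundance end — the head side of the head/tail elbow — and
that is the default (`endpoint="high"`); the opposite reading is
available as `endpoint="low"`. The choice is not cosmetic: on communities
with a planted knee, the high-end reading recovers the knee (consensus
1.0–1.2% for a 1% knee at 10,000 reads/library) while the low-end reading
chases the discreteness floor of the tail (0.01–0.1%). The span and
deadband defaults were calibrated once against planted-knee recovery
across seeds on two scenario families and then frozen; wider spans
(≥0.3 of ~80 points) smear the elbow an order of magnitude into the tail.

The consensus cutoff histograms the per-library cutoffs in log₁₀ space
(bin width 0.25, bins anchored half a bin below the minimum) and returns
the geometric mean of the modal bin's members — which leaves a single or
unanimous cutoff unchanged and is insensitive to where edges fall inside
the bin. Classification: a family is ORB where its percentage strictly
exceeds the cutoff, URB where positive but at or below it (the boundary
is URB); group-level labels use each family's median percentage within
the active and total library sets.

**Depth dependence.** The cutoff is a property of the *observed* curve.
At 2,000 reads/library, tail families below ~0.05% are largely invisible
and the observable elbow — hence the consensus cutoff — sits several-fold
above the planted knee; by 10,000 reads/library it converges onto the
knee. Cutoffs from libraries at very different depths should not be
pooled.

## The synthetic benchmark

The generator emulates the study conditions: 4 subjects × 5 fractions,
13 phyla / 79 families (the realistic scale for this community), a
two-regime rank-abundance profile — a geometric head above a 1% knee
(head minimum 1.5 × knee by default) and a log-series-shaped tail
(w ∝ xʲ/j) scaled so its largest family sits at 0.6 × knee and its
smallest near one expected read at the nominal 2,000-read depth, giving
the long even tail that high Shannon indices imply. Per-library lognormal
jitter (σ = 0.10 in log space) is clipped so no family crosses the knee,
keeping ORB/URB ground truth global. Active-vs-total fold changes are
applied as a symmetric square-root split (totals × √f, actives ÷ √f)
before renormalization, so the realized percentage ratio tracks f — a
one-sided multiplication would distort a 9× fold beyond 25% after
renormalization. Default effects: one head family at fold 9
(total-enriched) and three at fold ¼ (active-enriched), placed only where
the fold cannot cross the knee in any library. A "clear separation"
variant (head ≥ 3 × knee, tail ≤ knee/3) provides the regime where
ORB/URB truth is unambiguous for label-recovery checks.

Reads: insert length uniform in 460–520 nt (the 27F–530R amplicon
scale), per-base substitution errors only (no flowgram or homopolymer
model), duplicates drawn after error injection so they are byte-identical
— matching the dereplication definition. Hit tables plant the true
species as top bitscore with identity 100 − divergence + Gaussian noise,
plus 0–2 decoys among congeners (3–6 extra identity points) and
confamilials (8–15). All randomness derives from one seed via labelled
SeedSequence streams, so any module can be regenerated independently and
byte-identically.

Because decoys are confined to the true family, family-level assignment
accuracy is near-perfect by construction: passing recovery tests shows
the pipeline is *internally consistent* (it recovers what was planted
through parsing, dereplication, LCA, normalization and classification),
not that any particular reference database would classify real reads
this well. Likewise the generator's clean tag structure means demux
failure paths are exercised by constructed reads in tests, not by the
simulation.

## Scales and sizes

Tests run the full pipeline at 150–500 reads/library and 24–79 families;
statistical calibration uses 500 null simulations at 199 permutations;
recovery checks sample counts at 10,000 reads/library directly from the
community truth (multinomial), which is distributionally equivalent to
generating and perfectly assigning that many error-free reads and keeps
the checks fast. The analysis scripts run at 2,000 reads/library with
999 permutations.

## Known limitations

- The inflection machinery needs ≥5 observed families and a depth that
  resolves the tail; its cutoff is biased toward the tail-top edge of the
  head/tail gap rather than the gap's center.
- No chimera detection, quality trimming, OTU clustering or ordination —
  outside this pipeline's scope.
- The Welch comparison with 4 subjects has low power for subtle folds;
  only strong planted effects (≥4×) are reliably flagged at α = 0.05.
- Substitution-only error model; 454-specific homopolymer artifacts are
  not simulated, so the identity fingerprint is narrower than real
  pyrosequencing data would produce.
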