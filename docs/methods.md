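# Methods

## Scope and data model

The package analyses matched miRNA and mRNA count matrices (features ×
samples, integer counts) from a tumor cohort split into a mutated and a
wild-type group, together with a miRNA→gene target-prediction table
carrying a confidence class, gene-set catalogs in GMT format, and a
per-patient clinical table. All stages operate on these tabular inputs;
read mapping and quantification are upstream of the package, and target
prediction is consumed as data, not re-derived.

## Differential expression

**Filtering.** A feature is removed when fewer than `min_reads` (default
5) raw counts are observed in at least half of the samples, "at least
half" resolved as ≥ ⌈n/2⌉ so ties at exactly half count. The filter is
idempotent and leaves the sample set untouched.

**Normalization.** Median-of-ratios size factors: the reference set is
every feature with strictly positive counts in all samples; the factor of
sample *j* is the median over that set of `k_fj / geomean_f`. Factors are
identified only up to a common scale (multiplying one sample's counts by
*c* multiplies its factor ratio to every other sample by *c*). When no
feature is positive everywhere the factors are undefined and the stage
raises — no silent pseudo-reference fallback.

**Test.** Fold change is the plain ratio of arithmetic means of
normalized counts, mutated group in the numerator. Each feature gets a
Wald statistic `z = log2(FC) / SE` with the delta-method standard error
under the NB variance function `var = μ + αμ²`:

    SE² = [ (m₁ + α m₁²)/(n₁ m₁²) + (m₀ + α m₀²)/(n₀ m₀²) ] / ln(2)²

The dispersion α is estimated per feature by the method of moments on
normalized counts, `α̂ = (v − μ̄)/μ̄²` with v the within-group pooled
variance (so a real group effect does not inflate it), clipped to
[1e−8, 10]. A mean–dispersion trend `α ~ a/μ + b` is fitted by least
squares across features and the working dispersion is
`max(α̂, trend)` — the moments estimator is noisy and downward-biased at
small n, and flooring at the trend keeps the test near its nominal level
(the null suite checks a type-I rate of 0.05 ± 0.03 and near-uniform
p-values at 10 + 10 samples). Two-sided p-values come from the standard
normal; BH step-up adjustment (statsmodels' `fdr_bh`) follows, NaN
entries excluded from the family.

This is a deliberately simple, fully documented NB Wald pipeline. It is
not a re-implementation of any particular external tool, and parity with
one is not a goal or an invariant; shrinkage of fold changes, outlier
handling and independent filtering are intentionally absent.

**Degenerate features.** All-zero features get p = 1 and undefined FC; a
feature with exactly one zero group mean gets a 0/∞ FC sentinel and
NaN p (it cannot be tested on the log-ratio scale) and is excluded from
DEM calls with a warning.

**Calls.** DEM: `padj < 0.05` and FC outside [0.5, 2] — the threshold is
read two-sidedly on the ratio scale since strongly down-regulated miRNAs
(FC ≈ 0.37) are bona fide calls. DEG: `padj < 0.05` only.

## Interaction screen and attribution

Predictions are gated at the top confidence class by default, with the
ordering VeryHigh > High > Medium > Low fixed. For each (DEM, predicted
target) pair the Spearman ρ is Pearson on mid-ranks (tie-safe), missing
values removed pairwise with the per-pair n recorded (minimum 4). The
two-sided p uses the t approximation `t = ρ√((n−2)/(1−ρ²))` on n−2 df;
at |ρ| = 1 the statistic degenerates and the exact permutation limit
2/n! is reported. Pairs with unadjusted p < 0.01 are retained. No
multiple-testing correction is applied in the screen — it is a candidate
filter whose retention rate under independence (≈ 1% by construction) is
checked by simulation, not an inferential family.

Attribution joins retained pairs with both differential tables and keeps
pairs whose gene is a DEG, miRNA a DEM, and whose fold-change directions
are concordant with the correlation sign (negative ρ → opposite
directions; positive ρ → same; FC exactly 1 has no direction and never
concordant). Correlation records naming features absent from a
differential table indicate inconsistent upstream keying and raise with
the orphaned ids.

## Over-representation

Fixed-list enrichment: for a query of n genes in a universe of N, a set
with K members in the universe and k in the query scores
`p = P(X ≥ k)` for X hypergeometric(N, K, n); BH adjustment is applied
across the catalog's tested sets, independently per run (all targets,
negative-correlation targets, positive-correlation targets). The
universe is all genes present in the expression matrix after filtering —
an explicit choice, echoed in the output, since enrichment against a
whole-genome universe would overstate significance for any
expression-restricted query. Catalogs ship as small GMT fixtures in the
tests; term-level reproduction of public catalog results is out of scope
because it is release-dependent.

## Clinical contrasts

Derived features: ellipsoid volume `h·l·w·π/6` (mm³), invasiveness from
Knosp grade (0–2 non-invasive, 3–4 invasive), macroadenoma iff any
diameter strictly exceeds 10 mm. Proportions use the two-sided exact
Fisher test under the point-probability rule — the sum over all tables
with the observed margins whose probability does not exceed the observed
table's (relative tie tolerance 1e−7). This convention, rather than the
doubling rule, is the one that reproduces all published contrasts in
this setting, and scipy's implementation follows it; equivalence to an
exhaustive enumeration oracle is tested for totals ≤ 60. Quantitative
variables pass a Shapiro–Wilk gate at α = 0.05 in both groups to earn a
pooled-variance t-test, otherwise a two-sided Mann–Whitney U-test (exact
when both n ≤ 8 without ties, tie- and continuity-corrected normal
approximation otherwise). When grouping by *USP8* status, patients
carrying a *USP48* mutation are excluded: the second deubiquitinase
mutation acts on the same pathway and would blur the wild-type group.
Remission is undefined for hormonally silent tumors and such all-missing
variables are skipped per stratum.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes: two
groups, NB counts, library-size variation, planted DEMs, and planted
miRNA→gene couplings.

Each feature has a per-sample latent level
`baseline · group_effect · exp(bio_sd · ε)`, ε ~ N(0,1); counts are
NB(mean = latent · libsize, var = μ + αμ²) conditional on it. The
log-normal biological term (default sd 0.5) is what couplings act on: a
coupling of strength c ∈ [0,1] and sign s sets the target's latent
log-level to `scale · (s·c·u + √(1−c²)·η)` with u the miRNA's
standardized latent log-level. c = 0 is independence; c = 1 a
deterministic monotone link whose latent Spearman correlation is exactly
±1; on realized counts the correlation is attenuated by counting noise,
which is precisely what the screen must tolerate on real data. Because
the coupling passes the miRNA's group shift through to the gene, coupled
genes are themselves differential with the concordant direction — so the
planted truth exercises the full attribution path.

Defaults (the package's reference study conditions): 10 + 10 samples,
200 miRNAs, 500 genes, 20 DEMs at fold change 4 (80% up in the mutated
group, mirroring the predominantly up-regulated profiles reported for
this tumor type), dispersion α = 0.1, library-size factors uniform on
[0.7, 1.3], 40 couplings with 30% positive sign (real integration
screens find roughly one positive pair per two negative), baselines
log-normal(5, 1.2) giving a median of ≈ 150 counts. The target map
carries every true coupling at VeryHigh plus 10× as many decoy
predictions spread over all confidence classes, so the gate and the
screen are both exercised. All randomness flows from a single seeded
`numpy` generator; identical configuration gives byte-identical
serialized cohorts.

What the simulator does **not** model: sequencing reads and their
processing, FFPE degradation, correlated co-regulation among genes,
batch structure, or gene-level group effects that do not pass through a
miRNA. Passing tests therefore demonstrate the pipeline's correctness
and calibration under a clean generative model, not performance on the
full messiness of archival tumor material.

## Numerical choices and edge cases

- Dispersion clipped to [1e−8, 10]; trend predictions clipped the same.
- BH over non-NaN entries only; untestable features propagate NaN.
- Spearman declines constant vectors (NaN) and requires ≥ 4 complete
  pairs; ρ = 0 records cannot arise under the p < 0.01 gate and are
  dropped from sign splits with a warning.
- TSV outputs use a fixed dialect (tab, UTF-8, '.' decimal, `%.6g`
  floats) so repeated runs are byte-identical.
- Problem sizes in the shipped studies (20 seeds × 200-feature cohorts,
  3000 null screen pairs) were chosen as the smallest that estimate the
  recall/calibration quantities stably.

## Known limitations

Cohort-level discovery counts from the original sequencing study (e.g.
how many miRNAs pass the DEM thresholds genome-wide) depend on raw
matrices that are not published and are not reproduction targets; the
packaged summary-table fixtures cover the attribution arithmetic
instead. Printed correlation p-values in those tables imply a smaller
effective sample size than the nominal 24 (missing-sample handling
unstated upstream); the screen therefore records n per pair and the
fixtures' p-values are treated as data, not recomputation targets. The
NB Wald test is asymptotic: at very small group sizes (< 5 per group) it
runs but its calibration degrades, and the moments/trend dispersion is a
simplification relative to shrinkage estimators.
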