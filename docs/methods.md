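# Methods

This note documents the statistical models, conventions and defaults of
`adaptsig`, the assumptions behind the synthetic-experiment generator, and
the numerical choices that were genuinely open.

## Study design being modeled

The package targets a drug-adaptation design: cancer cell lines profiled
as drug-naive **parental**, short-term drug-exposed **persistent**
(slow-cycling survivors of ~6 days of treatment) and chronically adapted
**resistant** populations.  Two mechanism classes are distinguished:
**RTK**-mechanism lines (receptor-tyrosine-kinase upregulation with a
mesenchymal/invasive de-differentiation shift) and **NRAS**-mechanism
lines (MAPK reactivation), the latter serving as the specificity control
throughout.  Measurements are label-free LC-MS intensities (phospho-site,
protein or ECM-protein level) or expression values, analyzed on the log2
scale.

## Differential statistics

**Student's t.**  Per feature, a two-sided pooled-variance t-test between
two (cell line, state) groups; Welch is available by flag but the pooled
form is the default.  `log2fc = mean(group_b) − mean(group_a)` (b is the
treated/adapted group); the `stat` column follows the a-vs-b t convention
(so an upregulated feature has positive `log2fc` and negative `stat`) —
direction is always read from `log2fc`.  Features with < 2 present
replicates in a group are kept with NaN statistics and an
`insufficient_replicates` flag, never silently dropped.  Zero pooled
variance with unequal means (saturated/censored label-free values) gets a
sentinel p of 1e−300 and a `zero_variance` flag rather than p = 0.

**Signed log-t score.**  s = sign(log2fc)·(−log10 p), capped at ±300 so
sums stay finite.  A sign(log2fc)·log10(1+|t|) variant is exposed
(`signed_log_t(..., mode="log_t")`) because the transform of "signed log
t-test values" admits both readings; the default logs the p-value, which
makes s add like evidence across contrasts.

**ANOVA.**  One-way F across ≥ 3 state groups, per feature; the fold
change reported alongside is the group-mean difference of a designated
pair (default: second group vs first, i.e. persistent vs parental),
with all pairwise mean differences vs the reference group as extra
columns.  The "3-fold average" in the proteome filter is interpreted as
the linear fold of group means (the per-replicate-average alternative
is reachable through the extra columns).

**Multiple testing.**  Benjamini–Hochberg across tested features (BY is
used only as an option in RRHO map correction).

**Filters.**  Three named presets keep the published thresholds:
`proteome_anova_3fold` (raw ANOVA p < 0.05 and ≥ 3-fold — raw p, not q,
is deliberate and matches the proteome comparison), `phospho_fdr2_2fold`
(BH q < 0.2 and ≥ 2-fold), `ecm_fdr1` (q < 0.1).  Fold thresholds are
inclusive (|log2fc| ≥ log2(fold)).

**Protein summarization.**  Each peptide row is mean-centered over its
present values; the protein value per sample is the median over that
protein's centered peptides (midpoint for even counts).  This makes the
summary invariant to peptide duplication and per-peptide constant
offsets.

**Normalization.**  Sample-median centering on the log2 scale.  The
upstream normalization of real label-free runs is instrument-specific and
out of scope; median centering is the minimal location adjustment the
downstream statistics need and is idempotent.

## Direction concordance

Sites significant in either contrast (policy `either`; `both` available)
are cross-tabulated by fold-change sign; the default alpha is the
phospho-profile FDR threshold q < 0.2, since the "significantly altered"
preset of the original comparison is configurable rather than fixed.
Association is Fisher's exact test, two-sided by minimum-likelihood
summation (the convention of the common implementations); the
implementation delegates to `scipy.stats.fisher_exact` and is verified
against exhaustive enumeration for all tables with margins ≤ 12.

## Rank-based enrichment

**Permutation KS.**  For a gene set of size m in a ranking of N
identifiers with member ranks p₁ < … < p_m, the one-sided statistic is
D = max_j (j/m − p_j/N): the maximal excess of the set's ECDF over the
uniform background.  Significance comes from B gene-label permutations
(random m-subsets of positions, drawn without replacement) with the
add-one estimator p = (#{D* ≥ D}+1)/(B+1), so p ≥ 1/(B+1) and p = 0 is
impossible.  One-sided, unweighted is the default; the opposite end is
tested by reversing the list (`side="bottom"`), and directed (up/down)
signatures are tested as two one-sided runs reported jointly.  Under the
null the test is calibrated: the empirical type-I error at α = 0.05 over
1,000 simulations at B = 199 sits in [0.03, 0.07] (checked in the
acceptance suite).

**GSEA ES/NES.**  The running sum gains |score|^w (normalized over
members) at a hit and loses 1/(N−m) at a miss; ES is the signed extremum,
the leading edge the members at or before (after, for negative ES) the
peak.  w = 0 is the classic unweighted walk, w = 1 (default) the
score-weighted form.  NES divides ES by the mean |ES*| of same-sign
permutations and p is computed against same-sign permutations, the
standard GSEA convention; q is BH across scored sets.  Sets smaller than
`min_size` (3) after universe intersection are skipped with a record.
Note the unweighted ES is *not* numerically equal to the KS D above —
the KS background ECDF is uniform over N while the ES miss-step is
1/(N−m) — so the two are cross-checked against independent literal
implementations, not against each other.

**Specificity filter.**  A set passes if q < 0.1 in *all* case
collections and q > 0.2 in the control collection; survivors are ordered
by the summed case NES.  Sets missing or unscored anywhere are excluded
with a record.

**Kinase-substrate enrichment.**  Phospho-sites are ranked by log2 fold
change and each kinase's substrate-site set is scored with the GSEA
machinery; kinases pass at q < 0.2.

**Permutation scheme.**  Gene-label permutation (random member positions
on the fixed ranking), not sample permutation: the compared rankings are
summary signatures without replicate-level columns, so a sample-label
null is not available.  Default B: 10,000 for headline signature tests,
1,000 for per-set GSEA/kinase runs, 199 inside calibration loops.  All
seeds are explicit.

## RRHO

For rank thresholds (i, j) on a shared universe of N identifiers,
k = |top-i of A ∩ top-j of B| and p = P(X ≥ k), X ~ Hypergeometric(N, i, j),
computed in log space; the map holds −log10 p.  The universe is the
intersection of the two lists (discarded identifiers are counted), the
default step is max(1, ⌊N/100⌋), and BH/BY correction across all cells is
optional.  One-sided over-enrichment is the default; the signed variant
reports depletion as negative values via P(X ≤ k).  Note that for two
exactly reversed rankings the one-sided map is identically zero (the
overlap always equals its floor), so discordance is only visible in the
signed map.

## Signature comparison

Pearson r per signature pair on pairwise-complete identifiers (minimum
overlap 3 in tests, raise for real cross-platform use); r for a constant
vector is left NaN, never coerced to 0.  Clustering is agglomerative on
distance 1 − r — not 1 − |r|, because anti-correlating control signatures
carry real information — with average linkage by default and a
deterministic scipy implementation, rendered as newick when needed.

## Combined perturbation score

Per site, S = Σ s over the four contrasts (two resistant/parental, two
persistent/parental).  The default coverage policy `allow_missing` sums
over the contrasts in which the site was tested, flags incomplete
coverage, and breaks S-ties in favor of fuller coverage — motivated by
real detection gaps between MS runs, where a key site can be absent from
some runs; a site present in one contrast can therefore never outrank an
equally scored site present in all.  `require_all` restricts to the
intersection.  Sites collapse per protein to the site with the largest
|S| (ties: prefer positive, then lexicographic site label, recorded).
Shared-up and shared-down candidates are reported as two directional
rankings rather than one absolute-value list.

## Synthetic-data generator

Log2 intensities are baseline + planted effect + N(0, σ²) — i.e.
log-normal raw intensities, the standard label-free noise model.
Defaults: 1,000 proteins with 1–5 sites each, baseline ~ N(24, 2²),
σ = 0.5 log2 units, n = 3 replicates per (line, state) group (the
replicate depth of the real MS runs is not published; 3 is a choice),
three cell lines (RTK1, RTK2, NRAS1).  Planted programs on disjoint
protein sets, each ±2 log2 (4-fold) by default:

* `shared_up` (20 proteins) — up in persistent AND resistant states;
  the JUN-like target program.
* `persistent_down` (30) — down in persistent only (growth arrest).
* `resistant_up` (30) — up in resistant only (mesenchymal/invasive-like).
* `resistant_down` (30) — down in resistant only (proliferative-program
  loss); also gives the direction-concordance table its down-down cell.

Mechanism gating: NRAS-mechanism lines receive neither the shared nor the
mesenchymal programs by default (both gates are independent config
switches), mirroring the BRAF-mutant specificity of the shared response.
Missingness is optional and intensity-dependent (logistic detection
probability in the log2 intensity — a left-censoring flavor); lowering
the midpoint strictly increases detection.  Decoy sets are random draws
from the full universe, so they are exchangeable with planted sets under
zero effect.  The expression twin emits one row per protein with effects
inherited from the protein-level truth and independent noise (σ = 0.3)
under a child seed.  Everything is deterministic given the seed.

What the generator does **not** model: batch effects, peptide-level
interference/co-isolation, correlated noise across sites of one protein,
non-additive program interactions, and realistic identifier mismatch
across platforms.  Passing tests therefore demonstrate correctness and
calibration of the statistics under a clean additive model, not
robustness to those real-data pathologies.

## Numerical choices

* p-values floored at 1e−300; signed log-t scores capped at ±300.
* Permutation p uses the add-one estimator everywhere.
* Ranking ties break lexicographically by identifier and are recorded.
* Hypergeometric tails in log space (`hypergeom.logsf`), accurate to
  ~1e−14 relative in log space against exact enumeration at N ≤ 50.
* Summary JSON rounds derived fractions to 6 decimals and sorts keys, so
  pipeline runs are byte-identical given a config.

## Problem sizes in the test and acceptance runs

Simulated experiments use 150–1,000 proteins; permutation counts are
10,000 for headline signature tests, 1,000 for per-set runs, 199 inside
the 1,000-iteration calibration loop; planted-recovery statistics average
seeds 1–10 at the default noise level (σ = 0.5, n = 3, 4-fold effects).
These sizes were chosen to give stable statistics (recovery SEs ≪ the
margins asserted) at interactive runtimes.

## Known limitations

* No empirical-Bayes variance moderation: with n = 3 the plain t-test has
  limited power, which is faithful to the published statistics but means
  per-site q-values are conservative.
* No meta-analytic p-value combination for the perturbation score (the
  statistic is a score sum by design).
* No permutation significance for the RRHO map maximum.
* No bootstrap confidence for the signature clustering.
* Identifier matching is exact and case-sensitive; cross-platform alias
  mapping must happen upstream.
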