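# Methods

This note documents the models behind `driverscope`, the parameters that
matter, the numerical choices, what the synthetic cohorts do and do not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Mutation classification

MAF `Variant_Classification` strings are mapped case-insensitively to four
categories. Truncating: `Nonsense_Mutation`, `Frame_Shift_Del/Ins`,
`Splice_Site`, `Translation_Start_Site`, `Nonstop_Mutation` — events that
destroy or disable the protein product. Missense: `Missense_Mutation`,
`In_Frame_Del/Ins` — amino-acid-level changes that can create or enhance a
function, hence grouped for hotspot scoring. Silent: synonymous SNVs.
Everything non-coding (UTR, intron, flank, IGR, RNA) is excluded but
retained in the record stream; unknown classes are excluded with a
warning, never dropped silently. Indels are classified from the MAF
annotation only; the frame is never re-inferred from sequence. Protein
positions are 1-based indices on the canonical isoform, parsed from
HGVSp-style or bare position columns; records without a usable position
(e.g. splice-site) count in all totals but cannot contribute to the
positional density.

## Genetic-code accounting

With 64 codons and 9 single-base changes per codon there are 576 possible
substitutions. Exhaustive enumeration under the standard genetic code
gives five disjoint classes: 23 stop gains, 23 stop losses, 392
sense-to-sense missense changes, 134 synonymous changes and 4
stop-to-stop changes. The classical three-way accounting reported by
`substitution_census()` is 23 truncating (stop gains), 415 non-synonymous
(missense + stop loss) and 138 silent (synonymous + stop-to-stop). The
census keeps the fine classes visible because the three-way split is a
convention: the 23 stop losses could defensibly be counted as truncating
instead (we classify stop-loss *mutations* as truncating in MAF terms),
and making the mapping explicit avoids baking the ambiguity into the
statistics. The NS/S test never uses the aggregate: it enumerates the
gene's own codon composition.

`gene_ns_probability` computes, for one CDS (or a 64-vector of codon
counts), the probability that a uniformly placed single-base substitution
is non-silent. An optional 12-entry nucleotide-change spectrum reweights
the 9 changes per site; the default is uniform because the cohort's true
spectrum is unknown and estimating it from the same cohort being tested
would couple the null to the data. A known consequence: we do not
reproduce codon-usage-weighted summary fractions; the per-gene enumeration
makes such global constants unnecessary.

## Functional step

**TSG-S.** For a gene with `k_trunc` truncating of `n` total coding
mutations, TSG-S = −log₁₀ P(X ≥ k_trunc), X ~ Binomial(n, p₀), upper tail
inclusive. The background p₀ is estimated in the gene's own patient
environment: each carrier's truncating/total ratio is shrunk toward the
cohort mean with weight nᵢ/(nᵢ + κ) (κ = `shrinkage_k`, default 20 coding
mutations — the scale at which a patient's own ratio becomes as
informative as the cohort prior), and p₀ is the mean of the shrunk ratios,
clipped to [10⁻⁴, 1−10⁻⁴]. This operationalizes "a truncating mutation in
a sparsely mutated sample means more" while keeping p₀ stable when
carriers have few mutations. When the binomial tail underflows double
precision, the score falls back to the dominant log-pmf term, keeping the
score finite and monotone.

**OG-S.** Missense positions (impact-weighted; weight 1 when no impact
table is supplied) are smoothed on the integer grid 1..L with a Gaussian
kernel of σ = max(2, L/50) amino acids, renormalized on [1, L] so no mass
is lost off the protein ends, and normalized to a density (sum 1 ± 10⁻⁹
before entropy). The default bandwidth resolves a 1–2 residue hotspot on
a ~200-aa protein while still smoothing sparse patterns on a 3000-aa one.
The score is the entropy deficit standardized against a bootstrap null
(default 1000 replicates, seeded per gene from the run seed and a CRC of
the gene symbol, so results are independent of iteration order): the same
number of mutations placed uniformly on 1..L, weights resampled with
replacement from the observed weights. Genes with fewer than two
positioned missense mutations score 0 — one point carries no clustering
information. An integer position grid is used because protein positions
are integers; a continuous grid changes nothing at σ ≥ 2.

**Thresholds.** Base thresholds default to 2.0 for both scores (a 10⁻²
binomial tail; a 2σ clustering excess). With a labeled driver list they
are instead set by scanning every observed score value and maximizing the
Matthews correlation coefficient, ties broken toward the larger threshold
(fewer calls); MCC is used because the driver/non-driver classes are
extremely unbalanced and accuracy-style objectives saturate. Effective
thresholds are base × g(cohort) with
g = sqrt(min(1, S/200)) × clip(median_mutations/40, 0.5, 2):
monotone in both sample count S and per-sample burden, equal to 1 at the
reference scale (200 samples, 40 coding mutations/sample). The g function
and its constants are this package's design (configurable); smaller or
quieter cohorts cannot reach the same evidence, so their bar is lowered,
but never below 25% of base unless `lax` is set — the escape hatch for
very small cohorts where even the floor blocks everything.

**Minimum evidence.** Genes with fewer than 2 non-silent mutations are
reported as "insufficient evidence" and not scored; both scores are
degenerate at one mutation.

## Frequentist step

All four tests are one-sided in the driver direction and exact
(binomial/convolution/permutation, no normal approximations). Each
returns both P(X ≥ k) and P(X > k).

**Higher frequency.** Successes = the gene's non-silent mutations (all of
which belong to its carriers), reference = the carriers' total non-silent
burden, success probability = gene CDS length / territory (default 30 Mb
of exome, configurable; the synthetic cohorts pass their own territory).
Because a carrier by definition contributes at least one in-gene mutation,
the plain binomial null is stochastically too small — for a passenger
gene with c carriers the observed count is ≥ c while the binomial expects
far less, so every mutated gene would look significant. The pipeline
therefore conditions on the carrier definition: the null of the extra
count (k − c) is the convolution of per-carrier binomials truncated to
≥ 1, computed exactly. The unconditioned binomial form remains available
(`carrier_totals=None`) and is the right tool when carrier structure is
unknown.

**NS/S ratio.** P(X ≥ k_ns), X ~ Binomial(n, p_ns) with p_ns from the
gene's codon composition. The pipeline applies it to SNVs only,
subtracting indels from both counts: a frame-shift or in-frame indel is
non-silent with probability one, so placing "the same number and type of
mutations" on the codon structure means indels carry no information for
this ratio and would only bias the test toward significance.

**Tumor specificity.** P(X ≥ carriers), X ~ Binomial(S, f_bg) with f_bg
the gene's background non-silent carrier frequency. Absent (dropped from
the combination) when no background table or entry exists. This test
inherits any offset between the cohort's overall mutation rate and the
background population's — a known confounder, which is why its default
Stouffer weight is half that of the other tests.

**Functional impact.** Permutation test (default 10,000 seeded
replicates): observed statistic = mean impact score of the gene's scored
mutations; null replicates redraw that many scores without replacement
from the pooled scores of all mutations in the carrier patients;
p = (1 + #{null ≥ obs}) / (1 + n_perm). Absent when no impact data exist
or the pool is smaller than the gene's own set.

**Combination and correction.** Stouffer: zᵢ = Φ⁻¹(1 − pᵢ) with p clipped
to [10⁻¹⁵, 1−10⁻¹⁵], Z = Σwᵢzᵢ/√Σwᵢ², combined p = 1 − Φ(Z); absent tests
are dropped with their weights. Default weights (1, 1, 0.5, 1). The
combination consumes **mid-p** values (P(X > k) + P(X = k)/2): the
inclusive tail of a discrete test has a large atom at p = 1 — a typical
driver sits exactly at the carrier-conditioned frequency test's null
mode — which would map to z ≈ −8 and veto the other tests; mid-p has mean
≈ 0.5 under the null and is the standard correction when combining
discrete tests. Output tables report the exact inclusive tails. BH
step-up q-values are computed within the TSG family and the OG family
separately (distinct hypothesis families; a gene may appear in both), and
calls are made at q ≤ 0.1 (configurable). Tables are ranked by q, then
combined p, then carrier frequency descending.

**Calibration diagnostics.** Discrete p-values are never uniform, so the
package checks calibration through the randomized probability integral
transform p_gt + U·(p_ge − p_gt), exactly Uniform(0,1) iff the null is
correct. `diagnostics.frequentist_calibration_pits` evaluates all four
tests cohort-wide; the ≥ 5-mutation floor applies to the three tests whose
statistics are compositions conditional on the count, while the
specificity test is evaluated on every modeled gene — its statistic *is*
(essentially) the mutation tally, and filtering on the tally would select
on the statistic and bias the check for any correctly calibrated test.

## Synthetic cohorts

Defaults are the package's study conditions: 100 samples, 500 genes,
protein lengths log-normal (median 400 aa, σ_log 0.6, floor 50 aa),
per-patient coding mutation counts log-normal (median 40, σ_log 0.5),
target cohort truncating/total ratio p₀ = 0.14 — the ratio typical of
cancer exomes once frame-shift indels are included, far above the ~4%
that SNVs alone produce.

Passenger mutations land on genes in proportion to CDS length. A
passenger SNV picks a uniform codon and base change and is classified by
the genetic code, so a neutral gene's non-silent fraction matches its
codon-structure expectation *by construction* and the NS/S test is
calibrated with no tuning. An indel admixture (fraction solved from p₀;
90% frame-shift) supplies the rest of the truncating mass. Planted TSGs
(default 3) get 30 carriers with one driver mutation each, truncating
with probability 0.85 (diffuse positions, nonsense/frame-shift mixed) —
the APC-like landscape. Planted OGs (default 3) are 190-aa proteins (the
small-GTPase scale of the archetypal hotspot oncogene) with 20 carriers;
each driver mutation is missense, on the hotspot codon with probability
0.83. The fishy gene is simply a 10×-median-length passenger gene: it
accumulates length-proportional neutral mutations and must be rejected.
Planted driver genes receive no passenger mutations, keeping truth labels
sharp. Impact scores are 4·Beta(2,2) (a Mutation-Assessor-like 0–4
range) on every non-silent mutation, +1.0 on planted driver mutations.

The background table holds each gene's neutral expected carrier frequency
evaluated at the cohort's realized per-patient passenger burdens — a
*burden-matched* background. With a fixed population table the realized
mean cohort burden fluctuates by a few percent between runs and shifts
every gene's carrier count coherently, which is exactly the
cohort-vs-population rate offset the specificity test is known to
confound; matching the burden makes the neutral cohort a test of the
binomial form itself. Real COSMIC-style tables are *not* burden-matched,
and the specificity test's half weight reflects that.

What the generator does **not** emulate: trinucleotide mutational
signatures, GC/replication-timing covariation of the background rate,
copy number, gene-level selection on silent sites, shared pathway
structure, or annotation errors in real MAFs. Passing tests therefore
demonstrate the statistical machinery — classification, scoring,
calibration, combination, gating — under a faithful null and planted
alternatives, not robustness to every artifact of real sequencing data.

## Determinism and problem sizes

Every stochastic component (bootstrap, permutation, generator) is driven
by explicit seeds; per-gene seeds derive from the run seed and a CRC32 of
the gene symbol, so outputs are bit-identical across runs and independent
of gene iteration order. The shipped experiments use 100 × 500 cohorts,
1000 bootstrap replicates and 10,000 permutations — sizes at which the
full pipeline fits in well under a minute on one CPU while every planted
effect is far from the decision boundary.

## Limitations

- The MAF is trusted as annotated; there is no re-annotation, liftover or
  variant calling, and positions refer to whichever isoform the MAF used.
- The exome territory is a single constant per run; per-gene coverage is
  not modeled (by design — no BAM/coverage inputs).
- The carrier-conditioned frequency test loses power when every carrier
  has exactly one in-gene mutation (its signal then lives entirely in the
  carrier count, which the specificity test covers); the two tests are
  complementary, not independent, and the Stouffer weights acknowledge
  the dependence only coarsely.
- Threshold rescaling constants and base thresholds are pragmatic
  defaults, not estimates; with a labeled gene set, MCC calibration
  replaces the bases.
- OG-S compares entropy against uniform placement; domain-restricted but
  non-hotspot missense patterns can score moderately without being
  KRAS-like.
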