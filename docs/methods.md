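# Methods and design notes

This note records the statistical models the package implements, the
choices made where the design was genuinely open, the synthetic study
conditions, and the numerical details a user re-deriving results will
want.

## RMG calibration and MG labels

The relative maturity group (RMG) is a continuous maturity scale;
negative values denote classes earlier than MG 0, adapted to
progressively shorter seasons. Calibration regresses the reference
cultivars' assigned RMG on their VE–R7 day counts by ordinary least
squares (RMG is the response; days the predictor). Where a reference
was phenotyped in several environments at the calibration site, its
day count is the mean over those environments. Classification predicts
RMG from a cultivar's mean VE–R7 days over the calibration site's
environments and rounds half-away-from-zero to one decimal.

The categorical MG label is derived from the rounded RMG. For
RMG ≥ 0 the label is the decimal value itself ("0.0", "0.5"). For
negative RMG each whole unit earlier adds a leading zero and the
decimal counts up from the next-earlier class boundary:

| RMG | −2.2 | −2.0 | −1.2 | −1.1 | −1.0 | −0.1 | 0.0 |
|-----|------|------|------|------|------|------|-----|
| MG  | 0000.8 | 0000.0 | 000.8 | 000.9 | 000.0 | 00.9 | 0.0 |

Formally, writing a negative RMG as −(z + d/10) with integer z ≥ 0 and
digit d: the label has 2 + z leading zeros and decimal 10 − d when
d > 0, and 2 + z zeros with decimal 0 when d = 0. This rule is the
unique linear-in-zeros mapping consistent with the table above; the
direction of the regression (RMG on days rather than days on RMG
inverted) is a choice — with the noise-free reference sets used for
calibration the two coincide.

Maturity before first frost uses an inclusive boundary (R7 on the
frost date counts as matured); a cultivar with no recorded R7 is not
matured. Site-adapted sets require maturation before frost in every
one of a site's environments (both trial years).

## Photothermal sensitivity

TS and PTCRS are relative changes in days from emergence to beginning
bloom (DTB) between a contrast site and the baseline site, in percent
of the contrast-site DTB. Site DTB is the mean over that site's years.
Cultivars missing a required site DTB get an absent statistic — no
imputation — and correlations with RMG use pairwise deletion (the
choice between pairwise and listwise deletion was open; pairwise keeps
the most information and is recorded here). Both statistics are
bounded above by 100 % and are invariant to rescaling both DTBs.

## Variant filtering

All thresholds are inclusive as written: max-missing ≤ 0.1,
QUAL ≥ 50.0, DP ≥ 5.0, QD ≥ 5.0, MQ ≥ 30, biallelic only, MAF ≥ 0.01.
A sample-coverage criterion of "≥ 90 % genotyped" is the complement of
max-missing ≤ 0.1 and is therefore implemented as the single
missingness criterion. QD/MQ are taken from site-level INFO fields; an
absent quality field fails its criterion (and is logged) rather than
passing silently. Heterozygous calls contribute half an alternate
allele to MAF. Rejections are attributed to the first failing
criterion in the order missingness, QUAL, DP, QD, MQ, biallelic, MAF;
the retained set itself is order-independent.

## Consequence annotation

A variant is mapped through the gene's exon structure to a CDS
coordinate; alleles are reverse-complemented for minus-strand genes.
Substitutions replace the mapped base; insertions insert after the
anchor base (an insertion whose anchor gap is not inside a single exon
is noncoding); deletions remove the mapped bases, and a deletion
removing both exonic and non-exonic bases is reported as unsupported
rather than guessed. SNVs are classified by the affected codon
(standard nuclear code): stop_gained when the new codon is a stop
before the terminal codon, stop_lost when a stop is destroyed,
synonymous/missense otherwise. Exonic indels are frameshift when the
length change is not a multiple of three. Gene-local offsets in
reports are genomic position − gene span start + 1; published
gene-offset positions are reproduced on that convention, whatever the
annotation's own origin was.

## Haplotypes

The panel is fully inbred, so haplotypes are read directly off
homozygous genotypes; a heterozygous call is treated as missing. By
default a cultivar with any unresolved site at a gene is unassigned
(tolerance configurable; within tolerance a cultivar joins the unique
compatible haplotype if exactly one exists). Labels H1, H2, … order
haplotypes by descending membership with ties broken lexicographically
by allele string; the all-reference string is additionally tagged as
the reference (Williams 82-like) haplotype. The labelling is
deterministic but data-derived — it need not match any externally
published H-numbering. Frequency comparisons build the 2×2 table of
haplotype-set carriers vs non-carriers by group and use the
continuity-corrected chi-square, switching to Fisher's exact test when
any expected count is below 5.

## BLUE

The multi-environment trial model is y = cultivar (fixed) +
environment (random intercept) + residual. The package solves
Henderson's mixed-model equations for this single-random-intercept
structure directly, profiling the variance ratio
γ = σ²_env/σ²_e out of the restricted likelihood and optimizing the
1-D REML criterion (bounded Brent on log γ); fixed-effect solves use
the Woodbury identity, so the cost is O(n·q²) with q the number of
environments. The solution is numerically identical to a generic
REML mixed-model fit (cross-checked against statsmodels MixedLM in the
test suite) but runs in milliseconds on a 438-cultivar panel and is
well-behaved when the environment variance estimate approaches the
boundary. Reported BLUEs are cultivar effects plus the mean estimated
environment effect, so with balanced complete data they equal cultivar
means exactly; zero-residual (noise-free) data falls back to the
equivalent two-way fixed-effects least squares, which is exact there.
Censored (frost-lost) records contribute no row rather than an imputed
value; an environment with total frost loss simply contributes no
rows.

## ANOVA, Duncan letters, early/late sets

Haplotype effects are tested by one-way ANOVA on BLUEs; with exactly
two groups the equal-variance t-test is also reported (t² = F). Mean
separation uses Duncan's multiple-range test: means sorted descending,
and for a span of p ordered means the critical range is
q(1 − (1−α)^(p−1); p, df_error) · sqrt(MSE/n_h), with q the
studentized-range quantile, MSE the pooled within-group mean square
and n_h the harmonic mean group size (Duncan's original
span-dependent protection level, not Tukey's fixed α; α = 0.05 by
default). The letter display follows the protected step-down rule: a
span whose range does not exceed its critical range is homogeneous as
a whole and none of its sub-spans is tested; maximal homogeneous spans
receive letters. Two groups share a letter exactly when some
containing span is homogeneous.

The studentized-range quantile is computed by direct quadrature of the
scale-mixture CDF (Gauss–Legendre, 64 nodes in both the location and
scale integrals) inverted with Brent's method, cached on
(probability, span, df). It matches the reference distribution to
about 1e−6 — far below anything a letter display can resolve — and
costs ~15 ms per fresh quantile, which keeps letter displays cheap in
simulation loops.

Early/late classification: the late set is every haplotype sharing a
letter with the largest mean; the early set shares a letter with the
smallest mean and none with the largest. If one letter covers all
haplotypes the gene is non-significant and both sets are empty.
No multiple-testing correction is applied across genes (a
Benjamini–Hochberg option exists in spirit via the reported p-values;
the per-gene tests are reported raw by design).

## Synthetic study conditions

The generator emulates the trial structure end-to-end; its defaults
are fixed once and define the conditions all tests run under:

* **Panel**: 438 inbred cultivars, 12 candidate genes, 28 maturity
  references spanning RMG −2.2 … 0.5 in even steps.
* **Environments**: three sites × two years. HH (50.25° N, 154 m) is
  the baseline with sowing May 9, emergence 8 days later and first
  frost Sep 28; BJC (53.47° N, 295 m) and LBDL (50.25° N, 577 m) have
  first frost Sep 3 and Sep 5, so the baseline site censors least —
  essentially the whole panel matures there while roughly half to
  two-fifths mature at the harsher sites. Additive environment effects
  are 0–5 days.
* **Genetics**: each gene has an all-reference haplotype and one
  alternate haplotype defined by one exonic variant (the first gene's
  variant is a premature-stop SNV, the second's a 1-bp frameshift
  deletion); haplotype effects on VE–R7 days are −2 … −6 for nine
  genes and 0 for three (distinct haplotypes, no phenotypic effect),
  additive across genes with a polygenic background (sd 3 d). True
  genotypes are homozygous; heterozygosity (1 %) and missingness (2 %)
  are injected call noise only.
* **Phenotype**: VE–R7 = 115 d (the RMG 0 anchor) + 6 d panel offset +
  polygenic + Σ haplotype effects + environment effect + N(0, 3 d),
  rounded to whole days; R7 is censored past first frost. References
  lie noise-free on the 10-days-per-RMG-unit line, so their day counts
  are exact integers and calibration recovers the line exactly.
* **Bloom**: per-cultivar TS and PTCRS are linear in true RMG
  (TS = 20 − 3·RMG, PTCRS = 25 + 4·RMG, each with 1 % noise), and the
  contrast-site DTBs are back-computed from them — so the panel is
  built with the field-observed pattern that later cultivars are less
  temperature-sensitive and more photothermally sensitive. Recovering
  those correlation signs is therefore a consistency check of the
  pipeline, not an empirical finding about real cultivars.

What the generator does **not** emulate: linkage disequilibrium within
or between genes, epistasis, genotype×environment interaction beyond
additive environment effects, real climate drivers of bloom, multi-site
reference phenotyping, or sequencing-level artifacts (the VCF is
emitted directly, not called from reads). Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, at
realistic sizes and noise — not that the assumptions hold in any real
panel.

Scaled-down conditions are used in two simulation loops so they run in
seconds: the end-to-end recovery check uses 200 cultivars and 2 genes
(one planted −5 d effect, one null) with the panel offset set to
−8 d so the two-gene panel is centred at the same maturity as the
twelve-gene panel and frost censoring at the harsher sites stays
informative; ANOVA calibration uses 3 groups × 30 observations.

## Numerical details and degenerate inputs

* RMG rounding is half-away-from-zero; −0.0 is normalized to 0.0.
* A calibration set with identical day values raises a degenerate-
  design error; fewer than 2 references, or fewer than 3 complete
  inter-year pairs, is insufficient data.
* All-equal ANOVA inputs report F = 0, p = 1 (scipy returns NaN
  there); groups with fewer than 2 members are excluded with a
  warning.
* Zero MSE makes every Duncan critical range zero: equal means share a
  letter, distinct means get distinct letters.
* Multi-allelic VCF records are never split: they flow through parsing
  and are rejected by the biallelic filter (and refused by the
  consequence caller if passed directly).
* Pipeline manifests contain a config digest, stage row counts and the
  package version; a stage failure aborts the run with the stage name,
  keeps completed outputs and writes the partial manifest.

## Known limitations

* The consequence caller handles SNVs and simple left-anchored indels;
  complex substitutions and deletions spanning exon boundaries are
  reported as unsupported rather than annotated.
* BLUE assumes a single random intercept per environment; more
  elaborate variance structures (heterogeneous residuals, G×E) are out
  of scope.
* Duncan's test controls the per-span protected error rate, not the
  family-wise rate; that is the procedure's known character, kept
  deliberately.
* The haplotype labelling is frequency-derived and will not reproduce
  any particular published numbering, though the partition itself is
  invariant to input order.
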