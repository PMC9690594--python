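# Methods

## The model

`tgskit` implements the total-genotype-score (TGS) methodology used in
sports genomics to aggregate several biallelic candidate polymorphisms into
a single 0–100 profile score. Each locus contributes an integer genotype
score: 2 for the "optimal" homozygote, 1 for the heterozygote, 0 for the
other homozygote. For a score table over `L` loci,

```
TGS = 100 / (2L) × Σ_l s_l ,   s_l ∈ {0, 1, 2}
```

so the score of an individual always lies in [0, 100]. Two packaged models
cover the weightlifter study the package reproduces:

* **PWM** (power-oriented whole model): 12 loci, score directions taken
  from prior literature on strength/power phenotypes.
* **WRM** (weightlifting-related model): 6 loci, selected and oriented from
  the study's own case–control screen.

The scaling constant is `100/(2L)` for *whichever* model is in hand
(`100/24` for the PWM, `100/12` for the WRM). The alternative reading —
a fixed `100/24` denominator regardless of model size — does not reproduce
the published WRM group means (32.93 / 35.53), so the per-model scaling is
used throughout.

## Case–control screen

Association between athlete status and each locus is tested by Pearson
chi-square without continuity correction on collapsed genotype tables:

* **dominant** – one homozygote vs. {heterozygote + other homozygote};
* **recessive** – the complementary split;
* **allele** – 2×2 on allele counts (`2n` alleles per group);
* **genotypic** – the raw 2×3 comparison (available, not part of the
  default screen).

The orientation of the dominant/recessive pair is **locus-specific data**,
stored on the `Locus`: for ACTN3 and CKM the published table isolates the
lo-homozygote under "dominant" (e.g. `RR+RX / XX`), for the other ten loci
the first-listed homozygote stands alone. Plain Pearson chi-square (no
Yates correction, no exact test) is the convention under which the
published significant cells reproduce to their printed precision; Fisher's
exact test is available behind an option but is never the default.

Hardy–Weinberg equilibrium is tested per locus and group by chi-square
goodness of fit against `n·(p², 2pq, q²)` with the allele frequency
estimated from the sample, df = 1, α = 0.05. Monomorphic samples are in
equilibrium by construction and flagged. On the packaged counts this
reproduces the published deviation sets exactly: controls at CHRNB3 and
TRHR; weightlifters at ACE, CKM and CNTFR.

Bonferroni adjustment is `min(1, p·m)`. The source analysis is ambiguous
about `m` (the claim that only CNTFR survives correction implies an `m`
nearer 6 than 36); report tables therefore carry unadjusted p-values plus
an adjusted column with an explicit, configurable `m` (default: the number
of loci screened). Model *selection* always uses unadjusted p-values —
the published 6-locus model includes loci at p = 0.043/0.049, which could
not survive any multiple-testing correction.

## Data-driven model construction (`build_wrm`)

A locus enters the data-driven model when any screened model reaches
`p < α` (default 0.05) in either case group (all weightlifters vs.
controls, or international-level vs. controls). The score direction rule,
which the source describes only as "order of relevance", is implemented
as allele enrichment: the allele with higher frequency in the *trigger
group* than in controls defines the score-2 homozygote. The trigger group
is the first group in priority order (broadest first) with a significant
result, so a locus significant only in the elite comparison is oriented by
elite-group enrichment. On the packaged counts this rule reproduces the
published 6-locus model cell-for-cell, including the two loci whose
direction flips relative to the literature model (ACE: DD optimal;
CHRNB3: GG optimal). Exact allele-frequency ties raise an error rather
than guessing a direction; an empty selection raises `EmptyModelError`.

## Exact TGS distributions from marginal counts

Group *means* follow from marginal genotype counts alone by linearity of
expectation. Standard deviations and threshold proportions do **not**:
they depend on the within-person joint distribution across loci, which a
published marginal table does not determine. `tgs_distribution` therefore
computes the exact probability mass function of the score sum *under
between-locus independence* by convolving the per-locus score
distributions, and every quantity derived from it (sd, P(TGS ≥ 50)) is
labelled as an independence approximation. On the packaged counts the
independence approximation lands close to the published individual-level
threshold proportions (controls ≈ 16.4% vs. published 15.62%;
international ≈ 28.4% vs. 28.36%), but those numbers are reported, not
asserted.

## Group comparisons

* Unpaired two-sided t-test, pooled variance by default (Welch behind a
  flag); zero-variance degenerate inputs return p = 1 (equal means) or
  p = 0 (unequal), flagged in `note`.
* One-way ANOVA omnibus F; for ordered groups a linear-trend contrast with
  equally spaced centred coefficients (−1, 0, +1 for three groups), pooled
  within-group mean square as the error term, and N − k error df. For
  equal group sizes this agrees closely (not exactly — the error df
  differ) with regressing values on the group index.
* TGS→performance: ordinary least squares of Wilks points on individual
  TGS (slope, slope test, R²).
* Genotype–performance contrasts use the locus's stored dominant/recessive
  split, so "ACTN3 dominant" compares RR+RX vs. XX and "CNTFR dominant"
  compares CC vs. CT+TT, matching the published comparisons.

Wilks points are consumed as given; no body-weight formula is computed.

## Synthetic cohorts

The generator emulates the study's sampling design so every pipeline stage
is testable without external data:

* **Genotypes**: independent categorical draws per locus, per group, with
  probabilities defaulting to the packaged per-group frequencies
  (controls 416 / national 125 / international 67). An `hwe` mode replaces
  each probability vector with `(p², 2pq, q²)` at the same allele
  frequency. An `enrichment` knob in [0, 1] interpolates case-group
  frequencies between control frequencies (0, the null) and the group's
  own study frequencies (1, default).
* **Performance**: `baseline + Σ genotype shifts + N(0, noise_sd)`.
  The default effect model uses shifts ACTN3 TT(=XX): −8.77 and CNTFR CC:
  −11.68 Wilks points — the two published genotype contrasts — with
  baseline 199.65 chosen so the marginal carrier-group means reproduce
  193.32/184.55 and ≈185.3/197 at the weightlifter genotype frequencies,
  and noise sd 26.4 so the marginal sd is near the published ≈27.3 after
  the genotype shifts contribute their own variance (≈ 50 points²).
  Effects combine additively (the source is silent on interaction); sexes
  are pooled.
* **Reproducibility**: a single seed; the stream is split per group and
  then per locus (`SeedSequence.spawn`), so adding loci or groups never
  perturbs previously drawn columns, and identical configs give
  byte-identical TSV output.

What the generator does *not* emulate: linkage disequilibrium between loci
(the analysis itself never models it), sex-specific allele frequencies,
and the true within-person correlation among the six model loci — the
latter is unknowable from marginal counts, which is why the published
threshold proportions (15.62%/28.36%) and individual-level p-values
(0.04, 0.004, 0.167, 0.02) are treated qualitatively rather than asserted.
Passing tests therefore demonstrate internal consistency and calibration
of the machinery, not that real weightlifter data would reproduce those
exact individual-level numbers.

## Numerical and design notes

* Counts are exact integers; chi-square tests run in double precision and
  are verified against a first-principles expected-count oracle to 1e-10.
* Convolution pmfs normalise to 1 within 1e-12 and their means match the
  linearity-of-expectation means to 1e-10; the pmf is validated against a
  large Monte-Carlo oracle (total variation < 0.005 at 10⁶ draws).
* Type-I error of every inferential test is calibrated to 0.05 ± 0.01
  over ≥ 2000 null replicates in the test suite; test problem sizes
  (e.g. 3000 replicates, 200 recovery seeds, 10⁵-row convergence checks)
  were chosen as the smallest giving stable Monte-Carlo margins.
* Genotype labels are case- and allele-order-insensitive; dialect synonyms
  (ACTN3 R/X, ACE I/D via its proxy SNP, IGF2 opposite-strand G/A) resolve
  to one canonical spelling per locus. Missing genotypes are first-class:
  excluded from counts, and individuals missing any model locus are
  excluded from individual-level TGS without proration (with a logged
  count).
* Published-table discrepancies: a small number of printed association
  cells are not reproducible from the printed counts under any standard
  collapse (e.g. a recessive cell duplicating the allele-test value, and
  one garbled row); the test suite pins every printed cell under a frozen
  per-cell tolerance class and asserts an independently computed oracle
  value for the unreproducible ones. Likewise the published international
  WRM mean (38.60) is not recoverable from the printed counts — linearity
  gives 38.06, consistent with a digit transposition — so the
  recomputation is asserted instead.

## Known limitations

* Between-locus independence is an approximation wherever a distribution
  (not a mean) is derived from marginal counts.
* No covariate adjustment (sex, age) and no logistic-regression
  association; the screen is marginal per locus.
* The data-driven model builder implements one defensible direction rule;
  other rules could orient a locus differently on other datasets even when
  the selection set agrees.
* VCF/PLINK input is out of scope; the data model is a small named-SNP
  panel per individual (plain TSV).
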