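# tgskit

Total genotype scores (TGS) for strength/power sports genomics: a tested,
reusable implementation of the case–control → score-model → performance
pipeline used to profile weightlifters against non-athlete controls.

The package is aimed at sports-genomics researchers who work with small
panels of named candidate SNPs (ACE I/D, ACTN3 R577X, CNTFR, PPARGC1A, …)
rather than genome-wide data. It provides:

* **`genotype_data`** – a 12-locus study panel with dialect-aware genotype
  canonicalization (`RX` ≡ `CT`, `AG` ≡ `GA`, opposite-strand reports),
  packaged per-group genotype counts (controls n=416, all weightlifters
  n=192, international-level n=67), and TSV I/O for individual-level
  cohorts with optional Wilks-point performance values.
* **`association`** – Hardy–Weinberg tests and case–control Pearson χ²
  under dominant / recessive / allele / genotypic collapses, odds ratios
  with Wald CIs, and Bonferroni adjustment.
* **`tgs`** – score tables (`TGS = 100/(2L) · Σ scores`), the packaged
  12-locus literature model (PWM) and 6-locus weightlifting-related model
  (WRM), a data-driven model builder (`build_wrm`), and exact score
  distributions from marginal counts by convolution.
* **`group_comparison`** – unpaired t-tests, one-way ANOVA with a
  linear-trend contrast for ordered groups, TGS→performance regression,
  and genotype-group performance contrasts.
* **`synthetic_cohort`** – a seeded generator for individual-level cohorts
  matching the study's group sizes and genotype frequencies, with a
  calibrated Gaussian performance model.
* **`pipeline` / CLI** – end-to-end study-1 (screen → model → scores) and
  study-2 (fixed model on an independent athlete group) runs with
  deterministic TSV/JSON reports.

## The score

For `L` biallelic loci, each genotype contributes 0 (less optimal), 1
(heterozygote) or 2 (optimal homozygote), and

```
TGS = 100/(2L) × (s₁ + s₂ + … + s_L)  ∈  [0, 100].
```

Group means follow from marginal genotype counts by linearity of
expectation; distributions (sds, threshold proportions) additionally
assume between-locus independence — see `docs/methods.md`.

## Worked example

```python
import tgskit as tk

fx = tk.load_fixture_table2()                       # packaged group counts
national = tk.derive_national(fx.all_weightlifters, fx.international)
cases = {"all_weightlifters": fx.all_weightlifters,
         "international": fx.international}

screen = tk.run_case_control_screen(cases, fx.controls)
wrm, audit = tk.build_wrm(screen, cases, fx.controls, alpha=0.05)
print([tk.STUDY_PANEL[rs].gene for rs in wrm.loci])

for name, table in [("controls", fx.controls), ("national", national),
                    ("international", fx.international)]:
    print(name, round(tk.tgs_mean_from_counts(wrm, table).mean, 2))
```

prints

```
['ACE', 'ACTN3', 'CHRNB3', 'CNTFR', 'MCT1', 'PPARGC1A']
controls 32.93
national 35.53
international 38.06
```

i.e. the screen selects six of the twelve loci at α = 0.05, orients their
scores by case-allele enrichment, and the resulting mean WRM score rises
from controls through national- to international-level lifters. The same
run from a shell:

```
tgskit study1 --fixture --out report/     # HWE + association + WRM + TGS tables
tgskit simulate --seed 1 --out cohort.tsv # synthetic individual-level cohort
tgskit study2 --wrm report/wrm.json --simulate 1 --out study2.json
```

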