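# Methods

`oxidiet` re-implements, as a tested library, the computational analysis of
a rat diet-intervention study of hepatic oxidative stress: three diet groups
(standard chow, STD; high-fat high-sucrose, HFHS; HFHS supplemented with
EPA/DHA fish oil 1:1, HFHS+ω3), n = 9 animals per group, read out through
protein carbonylation on 1-D/2-D gels, liver fatty-acid composition,
antioxidant enzyme activities and biometric panels. This note records the
models, conventions and numerical choices the package commits to.

## Carbonylation indexes

Protein carbonyls are tagged with FTSC (fluorescein-5-thiosemicarbazide);
gels are counter-stained with Coomassie for total protein. The
carbonylation index of a feature (spot, band or lane) is

    index = FTSC signal / Coomassie signal

i.e. carbonylation normalized for protein amount. 2-D spot intensities are
first expressed as parts per million of the gel's total integrated optical
density (`ppm_normalize`), removing whole-gel loading/exposure scale; the
index is then the ratio of matched ppm values. Because ppm normalization
divides both channels of a gel by their own totals, the ppm-mode index
equals the raw-ratio index times one constant per gel — within-gel
contrasts are identical in the two modes, and a raw mode is provided for
1-D lane totals and for round-trip checks where the simulated raw ratio is
the quantity of interest. Whether the original analysis ratioed raw or ppm
intensities for 2-D spots is not stated; ppm is the package default, raw is
one keyword away.

A spot whose raw Coomassie intensity falls below the stain's detection
limit (about 100 ng of protein; configured here as a raw-intensity
threshold, since nanograms are not observable from densitometry tables) has
an **undefined** index: the denominator is not quantifiable even when the
FTSC signal is strong. Undefined indexes propagate as missing values, never
as zeros — zeros would drag group means down and manufacture spurious diet
effects. This mirrors the study's five intensely fluorescent but
Coomassie-invisible spots (A–E).

## Fatty-acid profile indexes

Liver total fatty acids (GC-FID) are percentages of total fatty acids,
named `C:DωN`. Class sums: SAT = Σ saturated, MUFA = Σ one double bond,
PUFA = Σ two or more; the ω-3 and ω-6 rows count only PUFAs, so 18:1ω7
belongs to MUFA and to no family row — this is the convention that
reproduces the published class rows from their printed components.
Derived ratios:

| index | definition | proxy for |
|---|---|---|
| SCD-16 | 16:1ω7 / 16:0 | Δ9 stearoyl-CoA desaturase |
| SCD-18 | 18:1ω9 / 18:0 | Δ9 stearoyl-CoA desaturase |
| Δ4D | 22:6ω3 / 22:5ω3 | Δ4 desaturase |
| Δ5D | 20:4ω6 / 20:3ω6 | Δ5 desaturase |
| Δ6D | 20:3ω6 / 18:2ω6 (also 18:3ω6 / 18:2ω6) | Δ6 desaturase |
| Δ5/6D | 20:5ω3 / 18:3ω3 | combined ALA→EPA pathway |
| ω-6/ω-3 | class-sum ratio | inflammation index |
| EPA/DHA | 20:5ω3 / 22:6ω3 | selective incorporation |

All are plain percentage ratios (scale-invariant); a zero denominator makes
the index undefined, not an exception. Ratios can be computed per animal
and then averaged (the pipeline default) or as a ratio of group means.
The two differ by a Jensen gap: the published desaturase panel is
consistent with per-animal averaging (its SCD-18 STD cell, 0.87, does not
equal the ratio of the printed group means, 8.24/9.81 = 0.84), so the
reproduction report recomputes those cells in ratio-of-means mode and
flags which cells that mode can and cannot reproduce — SCD-16 (all
groups), Δ6D-DGLA (STD, HFHS) and Δ6D-GLA (all groups) match at 2 dp, the
rest are reported as mismatches. Two published rows ("% EPA PUFAs",
"% DHA PUFAs") match no ratio of printed cells we can identify; their
defining computation is undocumented and they are excluded from
reproduction.

Rounding for printed-cell reproduction is half-up at the printed precision
(2 dp for composition and desaturase cells, 3 dp for EPA/DHA, 1–2 dp for
biometric indexes), matching how summary tables are typeset.

## Biometric indexes

Adiposity index = abdominal fat × 100 / body weight; hepatosomatic index =
liver weight × 100 / body weight (both %). "Total abdominal fat" is taken
as the perigonadal depot — the only fat mass published — which reproduces
the printed adiposity cells. Ratio panels (GSSG/GSH, AST/ALT, ALT/AST) are
computed per animal and then summarized; the published GSSG/GSH cell
(2.45) differs from the ratio of the printed GSSG and GSH means
(2.72/1.38 = 1.97), confirming the per-animal convention.

## Group statistics

Per variable, the route follows the field's standard workflow: Shapiro–Wilk
normality per group and Brown–Forsythe (median-centred Levene) homogeneity,
each at α = 0.05; any failure — or an untestable assumption (group smaller
than 3, or constant values) — routes to the nonparametric branch. The
omnibus test is one-way ANOVA or Kruskal–Wallis; the post-hoc is Fisher's
LSD, i.e. pairwise t statistics on the pooled mean-square error and
residual degrees of freedom of the full one-way model, two-sided, with
**no multiplicity adjustment** (LSD is unadjusted by definition, and no
correction is applied across the 36 spots — a deliberate fidelity choice
users should keep in mind when reading the star flags). The original
report does not say which normality/homogeneity tests were used, nor what
pairwise test followed a nonparametric omnibus; both choices here
(Shapiro/Brown–Forsythe; unadjusted two-sided Mann–Whitney with midrank
ties) are package conventions, configurable at the routing level, not
claims about the original software.

Pairwise tests are computed unconditionally rather than gated on omnibus
significance, so the per-comparison operating level is the nominal α.
Null-simulation calibration (3 × n = 9 normal groups, 5000 replicates)
puts the per-pair type-I error of the full route near 0.05 (the
`calibration` module recomputes this). Annotation: `*` for p < 0.05, `**`
for p < 0.01 (strict inequalities) against a reference group, and `+`/`−`
direction marks for significant pairs only, always matching the sign of
the group-mean difference.

## Synthetic cohorts

No per-animal data were deposited; the study's public summary is group
means and standard deviations. The generator draws cohorts at exactly
those parameters (shipped as `data/printed_tables.json`): scalar variables
from a normal truncated at zero; fatty acids per acid, then renormalized
to a 100% compositional total (no covariance structure is published, so
closure induces the only dependence); per-spot carbonylation indexes from
truncated normals at the published per-spot (mean, sd); 2-D densitometry
built backwards as Coomassie ~ log-normal (ln-scale mean 11, sd 0.3 —
roughly 60 000 density units with ~30% CV, typical of spot densitometry)
and FTSC = index × Coomassie; five low-abundance spot analogues drawn
below the Coomassie detection limit; and seven invented 1-D bands per
lane encoding the qualitative pattern HFHS > STD ≈ HFHS+ω3 (no lane-level
numbers are published). All randomness flows from one integer seed;
cohorts are bit-reproducible and the config + seed are serialized in the
run manifest.

Truncation at zero was chosen over a log-normal because printed s.d. are
small relative to means, making truncation bias negligible *almost*
everywhere: the exception is one published pair (0.56 ± 0.46), where the
truncated distribution's mean exceeds the parent mean by ~0.10. Round-trip
recovery checks therefore target the generator's true expectation — the
closed-form truncated-normal mean (`truncated_mean`), rescaled by
compositional closure for fatty acids — rather than the parent parameter;
at n = 500 per group, sample means land within 3 standard errors of those
targets for ≥ 99% of the 234 configured (variable, group) pairs.

What passing tests on synthetic cohorts do *not* show: real gel data have
spot-to-spot and animal-to-animal correlation, non-normal error, and
shared technical structure (batch, staining day) that the generator does
not emulate; power and calibration results transfer to real data only to
the extent that the published means/s.d. capture them.

## Annotation and network summaries

Facet proportions (cellular component, molecular function, protein class,
biological process) are percentages of annotated proteins carrying each
term; multi-term proteins count once per term, and the `within=` argument
computes shares inside a parent term (e.g. lipid-metabolic among
metabolic). Network summaries filter edges below a confidence threshold
(default 0.4, "medium"), drop isolated nodes, and report node/edge counts,
degrees and connected components; component detection stands in for
cluster analysis, which (like live PANTHER/STRING queries) is out of scope
because external-database contents drift between releases. The shipped
annotation and edge-list fixtures are **synthetic**: constructed to the
published aggregate proportions and counts (23 nodes / 52 medium-confidence
interactions), not retrieved per-protein assignments. The published
metabolic-process sub-split (36.4% amino acid / 21.2% lipid / 18.2%
carbohydrate) cannot all be realized simultaneously on the ~47 nameable
proteins; the fixture matches the first two within a percentage point and
reports the third as constructed (15.8%).

## Problem sizes and defaults

| quantity | value | why |
|---|---|---|
| groups × n | 3 × 9 | study conditions |
| routing α | 0.05 | conventional; configurable |
| significance | p < 0.05 (`*`), p < 0.01 (`**`), strict | published thresholds |
| profile total tolerance | 100 ± 0.5% | absorbs printed rounding |
| Coomassie detection limit | 5000 raw units | configurable stand-in for the ~100 ng stain limit |
| null calibration | 5000 replicates | per-pair rate s.e. ≈ 0.002 |
| power sweep | 200 replicate cohorts | rate s.e. ≈ 0.02 at 0.9 |
| recovery cohort | n = 500/group | 3 s.e. ≈ 0.13 sd |

These replicate counts keep the full self-check suite around a minute on
one core while making the Monte-Carlo bands decisively narrower than the
acceptance margins.

## Known limitations

* Printed group means/s.d. are the only data; nothing here can recover
  per-animal distributions, covariances or outliers of the original study.
* The unadjusted-LSD convention inflates familywise error across 36 spots
  by design (fidelity to the source analysis).
* ppm-mode indexes are comparable within a gel and across gels only up to
  the per-gel FTSC/Coomassie total ratio; cross-gel absolute comparisons
  should use a common loading design, which densitometry tables alone
  cannot verify.
* Annotation/network fixtures are synthetic reconstructions of aggregate
  summaries; per-protein assignments in them are not authoritative.
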