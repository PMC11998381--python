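# Methods

## The cfDNA mixture model

All quantitative reasoning rests on one mixture identity.  Plasma
cell-free DNA is a mix of tumor-derived fragments (fraction `TF`) and
normal-cell fragments (fraction `1−TF`, two reference copies).  For a
locus at tumor copy number `c`, of which `m` copies carry a clonal
mutation:

* expected VAF: `v = TF·m / (TF·c + 2(1−TF))`
* expected segment log2 ratio: `log2((TF·c + 2(1−TF)) / 2)`
* expected major-allele ratio of a heterozygous SNP under one-copy loss:
  `1/(2−TF)`; under a single-copy gain to 3 copies: `(1+TF)/(2+TF)`.

The synthetic generator simulates observables from these expectations
(binomial reads at Poisson depth, Gaussian segment noise shrinking as
`1/√bins`), and the analysis inverts them, so parameter-recovery tests
close the loop end to end.

## Variant filter chain

Plasma SNV/indel calls from four simulated callers are merged by
(chrom, pos, ref, alt); a site is retained when supported by
`min_snv_callers` (default 2) callers, with the merged VAF the
depth-weighted mean.  The exact multi-caller consensus used in practice
varies between laboratories; ≥ 2-of-4 is standard practice and the
threshold is exposed.  SVs follow a different published rule: events seen
by one caller are discarded unless that caller is Svcaller.  Breakpoints
within ±50 bp (configurable) are treated as the same event, reflecting
caller imprecision.

Buffy-coat calls are split into germline (VAF > 0.4, moderate/high
impact, population AF < 0.005; missing population AF counts as rare —
absence from population databases implies rarity) and clonal
hematopoiesis (buffy VAF in [0.01, 0.35); CHIP when additionally
(likely) pathogenic at VAF ≥ 2%).  CH keys are subtracted from the plasma
consensus at both baseline and progression; removed records keep their
plasma VAF so CH leakage can be reported.  Manual review is replaced by a
deterministic curation-override TSV hook (`apply_curation_overrides`),
keeping runs reproducible.

For clinical-outcome analyses only (likely) pathogenic or high-impact
SNVs/indels, amplifications and homozygous deletions count as
alterations; SVs and heterozygous deletions are excluded.

## Focal copy number

Gene status is called differentially against pooled flanking control
windows 3–8 Mb up- and downstream of the gene (one-sided when the other
side is off the chromosome — genes near a chromosome end would otherwise
be systematic no-calls).  Medians are bin-weighted: a segment contributes
its log2 value once per bin overlapping the queried window, computed in
exact integer arithmetic; the even-count median is the mean of the two
middle elements, matching a plain median over the expanded bins.  Calls
require ≥ 10 control bins (configurable), otherwise NOCALL.  Thresholds:
AMP at gene − control ≥ 0.5, DEL at control − gene ≥ 0.3, HOMDEL at gene
log2 ≤ −1 (absolute, and overriding DEL when both fire — the more
specific call).  The differential rules are invariant to adding a
constant to every segment; the homozygous-deletion rule is deliberately
not.

BAF support declares a call consistent with the data when the mean folded
deviation `|ratio − 1/2|` over ≥ 3 heterozygous SNPs reaches half the
mixture-model expectation for the called state; the half-way criterion
trades sensitivity at low TF against false support from binomial noise at
depth ~1000.  LOH is a deletion call or a BAF deviation matching one-copy
loss, which also captures copy-neutral LOH.

Note a structural limit: under the mixture model a homozygous deletion
reaches log2 ≤ −1 only when TF ≥ 0.5, so at moderate tumor fractions
HOMDEL truth presents as an ordinary focal deletion.  Recovery tests
therefore count a DEL-or-HOMDEL call as detecting HOMDEL truth, and
simulated amplifications default to 8 total copies (high-level focal
gain) so the ≥ 0.5 differential threshold is reachable at TF ≥ 0.2.

## Tumor fraction

The driver is the highest-VAF somatic variant with moderate/high impact
(ties: higher depth, then lexicographic key), after CH subtraction.  The
copy state defaults to diploid-heterozygous (`TF = 2v`) — the most common
configuration and conservative in the absence of copy information — and
switches to the LOH model (`TF = 2v/(1+v)`) when LOH is assessed at the
driver locus.  Estimates are clamped to [0, 1] with clamping flagged.
Subclonality is ignored: the highest-VAF definition targets the clonal
fraction.  An externally supplied estimate (ichorCNA-style, from low-pass
WGS) is carried through as a comparison column and never recomputed.
With no eligible variant the fraction is reported missing rather than
zero, mirroring the occasional patient with detectable tumor burden but
no panel variant.

## MSI

Each microsatellite locus is reduced to the number of alleles holding
≥ 5% of reads (loci with < 30 reads are not evaluated and never enter the
denominator).  A locus is unstable when that count exceeds the
stable-panel baseline mean by more than 2 baseline SDs; a sample is MSI
when the unstable fraction over evaluated loci is ≥ 0.2 (boundary
inclusive).  The baseline shipped with the generator is a deterministic
synthetic stand-in for a stable reference cohort.

## Endpoints and statistics

PSA progression follows the PCWG3 reading: a value ≥ 25% and ≥ 2 ng/mL
above the nadir-so-far, confirmed by a second qualifying measurement
≥ 21 days later (21/30.4375 months); otherwise censored at the last
observation.  PSA30/50/90 are any on-treatment decline past the
respective fraction of baseline.  Primary resistance is an observed
progression at ≤ 3.0 months (inclusive); patients censored inside the
window (e.g. a side-effect treatment switch) are unevaluable and excluded
from responder analyses rather than counted as responders.

Survival machinery is delegated to lifelines (Kaplan–Meier, log-rank,
Cox partial likelihood with Wald intervals); the proportional-hazards
check is the scaled-Schoenfeld-residual association with rank-transformed
time at α = 0.05.  Degenerate designs — constant covariate, < 5 events,
separation, collinearity with the ctDNA% adjuster — are flagged
non-estimable instead of raising.  BH correction (statsmodels) is applied
per endpoint × adjustment family across all tested genes/gene sets.
Fisher tests are scipy's two-sided exact test (sum of outcomes at most as
probable as the observed table), which reproduces the printed p = 0.40
for the 16/18 vs 13/18 AR-region table; tests cross-check it against a
full hypergeometric enumeration.  Enrichment only tests genes altered in
≥ 2 labeled patients.

## Actionability

Knowledge content is data, not code: a TSV maps (gene, alteration class,
origin constraint, framework) to a level and therapy label.  The shipped
table is a synthetic approximation of public prostate-cancer content —
HRR-gene loss of function at OncoKB level 1/ESCAT tier I (BRCA1/2) or
tier II (other HRR), MSI at the top of both scales, PI3K/AKT-pathway
alterations lower, plus level-4 (preclinical-only) entries — because both
knowledge bases evolve and any snapshot dates quickly.  LOF rules match
only (likely) pathogenic or high-impact SNVs/indels; heterozygous
deletions match nothing.  OncoKB level-4 matches are recorded but never
actionable; the per-patient highest level is taken over actionable
matches only.

## Synthetic cohort: what it emulates, and what it does not

Defaults describe a ctDNA-selected first-line mCRPC cohort: tumor
fraction uniform on [0.03, 0.75] (cohorts selected at ctDNA% ≥ 3%),
plasma depth 1000×, buffy 300×, CH in 13% of patients, per-gene event
probabilities shaped after the frequent alterations of such cohorts
(AR/AR-enhancer amplification ~45%, TP53 ~40%, PTEN ~35% including
deletions, TMPRSS2 fusions ~35%, scattered HRR hits), PFS/OS baselines of
8/22 months median, and gene-set hazard multipliers echoing reported
effect sizes (PI3K 3.9/4.9, cell cycle 2.7/4.1, chromatin 8.8/4.0 for
PFS/OS, BRAF 6.0/3.0).  Caller sensitivity is logistic in the expected
alt-read count (midpoint 8 reads, published per-caller sensitivities not
being available); false positives land uniformly on the panel at low VAF.
Primary-resistance truth is *derived* from the hazard model
(event ≤ 3 months) rather than drawn independently, so enrichment
planting (BRAF/CHD1 carriers have elevated hazards) and endpoint
derivation stay mutually consistent; PSA series are synthesized to
reproduce each patient's progression time on a 0.5-month sampling grid.
For simulation studies of the survival estimators,
`simulate_outcomes(..., derive_pfs_from_psa=False)` keeps the continuous
event times, avoiding grid-quantization ties.

The generator runs on a toy reference (16 contigs of 60 Mb, one gene
locus per 18 Mb, exported to BED via `panel.write_bed`), with one
alteration per gene per patient, no mutational signatures, no read-level
errors, no germline contamination of the plasma somatic call sets
(callers are modeled as matched-normal-subtracted), and segment noise
that is Gaussian and independent across segments.  Passing tests
therefore demonstrate the correctness and calibration of the analysis
logic under the stated models — not robustness to alignment artifacts,
GC waves, panel dropout or subclonal architecture in real plasma data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to give stable
statistics: 1000 random segment profiles for the brute-force CNV
equivalence, 200 patients for tumor-fraction recovery (TF ∈ [0.05, 0.5],
where binomial noise at depth 1000 gives estimate SDs well inside the
±0.05 band), 100 replicates of n = 500 for hazard-ratio CI coverage and
500 replicates of n = 150 for the null type-I error (judged against a
±3-SE binomial band around 0.05).  Seeds derive per-patient substreams
from one global seed, so partial re-simulation is deterministic and a
fixed seed yields byte-identical cohorts.  Weighted medians use exact
integer bin arithmetic; probabilities are validated into [0, 1]; Cox
fits run on float64 throughout.
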