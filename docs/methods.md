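# Methods

This note documents the models and procedures implemented in `chd4var`, the
parameters that matter, the choices made where the design was genuinely
open, and what the packaged tests do and do not establish.

## Variant model and fixture

Variants are protein-level records over the 1912-residue CHD4 sequence
(UniProt Q14839); residue coordinates are 1-based inclusive and no genomic
coordinates or transcript mapping are modeled. The protein-HGVS grammar
accepts substitutions and single-residue or span in-frame duplications and
deletions, in one- or three-letter form, normalizing to one-letter
(`p.Leu1009_Val1011dup` → `p.L1009_V1011dup`). Identity substitutions are
flagged synonymous rather than rejected. Splice variants are carried by
cDNA notation only and have no protein span.

The packaged fixture (`src/chd4var/data/chd4_table1.tsv`) transcribes the
36 published CHD4 variants with their predictor scores, curated evidence
strings, ClinVar labels and published per-row calls. Two editorial points:

- **Heart-anomaly flags.** The source reports only group counts (19 of 20
  motor-region variants with heart anomalies; 9 of the 15 informative
  other-domain variants, with the printed statistics implying one
  additional variant was uninformative). It does not identify which single
  motor-region variant lacks an anomaly; the fixture assigns that "no" to
  p.A1178V, and flags the splice variant "unknown", so that the
  fixture-derived 2×2 table equals the published group counts with exactly
  one exclusion. Because these per-variant flags are editorial, the group
  table itself is also shipped as `enrichment_stats.STUDY_TABLE`, and the
  statistical validation runs on that table, not on the flags.
- **Duplicate positions** (M954I/M954V, R1183H/R1183C) are independent rows
  keyed by full notation.

The frequency filter removes variants with gnomAD allele frequency
strictly above 0.001 (the study's cutoff); absent frequencies are kept, so
all 36 fixture variants pass.

## Score calibration

Each tool's score in [0, 1] maps to a three-way call. Pathogenic bounds
are the published, inclusive thresholds: MetaRNN ≥ 0.85, PolyPhen-2
≥ 0.978, AlphaMissense ≥ 0.9, REVEL ≥ 0.644. Benign bounds: PolyPhen-2
≤ 0.113 and REVEL ≤ 0.290 (published, inclusive); MetaRNN and AlphaMissense
publish no benign bound, so the package uses a strict midpoint fallback
(< 0.5) for concordance accounting — a reporting convention, not a
calibration claim.

Only REVEL generates classification evidence. The tier boundaries follow
the interval calibration of Pejaver and colleagues for PP3/BP4 strength:
PP3 supporting/moderate/strong at ≥ 0.644/0.773/0.932, BP4
supporting/moderate at ≤ 0.290/0.183, with an undetermined gap in
(0.290, 0.644) that contributes no evidence. Inclusive bounds are forced
by the published per-row labels (0.773 → moderate; 0.239 ≤ 0.290 →
supporting), and the mapping reproduces all 33 published REVEL labels
(golden test).

**Full concordance** is defined as all four tools making the same
*determinate* call — all pathogenic or all benign. A row on which every
tool is undetermined agrees only in the absence of a prediction and is not
counted as concordance (it is reported separately as `identical_calls`).
Under this rule the fixture yields 14/33 fully concordant rows, matching
the published 42.4 %; counting literal call identity would add the one
all-undetermined row (p.I1741V) for 15.

## Evidence combination

The categorical mode implements the classical ACMG/AMP rule table over
counts of very-strong/strong/moderate/supporting pathogenic criteria and
stand-alone/strong/supporting benign criteria. The points mode uses the
Tavtigian-style refinement: weights 8/4/2/1 (benign negated, BA1 weighed
as very strong) and bands P ≥ 10, LP 6–9, VUS 0–5, LB −6…−1, B ≤ −7.

Three configuration decisions reproduce the published per-row verdicts and
remain overridable:

- **PP3 tier collapse** (`collapse_to_supporting`, default): in
  combination, PP3/BP4 count at supporting level regardless of the REVEL
  strength modifier. Honoring the tier would promote rows like
  PS2+PM2+PP3_strong from LP to P, which the published table does not do;
  `honor_tier` is available as an option.
- **Conflict policy** (`dominant_side_by_points`, default): evidence sets
  mixing pathogenic and benign criteria drop the side with the smaller
  point mass before rule application (ties → VUS). This reproduces both
  published mixed rows (PS2+PM2+BP4 → LP; PM2+BS2+BP4 → LB). The strict
  policy (`richards_vus`: any mixed set → VUS) is selectable.
- **PM2 at moderate strength** (no supporting downgrade), required to
  reproduce PS2+PM2 → LP.

Non-missense variants are classified from their curated codes only; no
PVS1 auto-assignment is attempted for the splice variant (its published
assessment is a qualitative consequence-prediction narrative, not a
criteria string).

The two modes agree on 32 of the 33 missense rows; the single divergence
is p.V1608I (PS2+PM2+BP4 = 5 points → VUS in points mode, LP
categorically), asserted exactly in the tests.

ClinVar comparison maps our verdict against the prior label under the
class order, with NP → first classification, CS compared as
VUS-equivalent, and P/LP unchanged when our call falls in {LP, P}. The
fixture recounts to 12 unchanged / 10 first classifications / 11 changed
(4 upgrades + 7 downgrades). The source prose reports a 12/9/12 split that
is inconsistent with its own table; the package reports the recount and
does not force the prose numbers.

## Domain architecture

The CHD4 map ships as an interval TSV: top-level domains (N-terminal
1–354, PHD1 363–410, PHD2 442–482, CD1 522–579, CD2 615–676, ATPase
731–915, helicase 1047–1192, C-terminal 1230–1912), nested subdomains
(C1a, C1b, two disordered segments, C2a, C2b, APR2 1735–1742), and the
composite **ATPase motor region 731–1192** — the contiguous ATPase +
inter-lobe linker + helicase span used as the enrichment grouping, which
contains exactly 20 fixture variants (18 missense plus the duplication and
deletion at 1009–1012). The HMG box interval (161–242) is an editorial
placement: only its length (82 aa) and its containing region are
established, and it is marked approximate in the TSV. Localisation
returns all intersecting intervals, smallest first (ties by start);
overlapping sibling subdomains (C1a vs. the first disordered segment) are
both reported. A span touching no interval is labelled
`interdomain(left,right)` by its flanking top-level domains — the
inter-lobe linker (916–1046) is such a gap, inside the composite motor
region. The combined motor + C-terminal share of missense variants
recomputes to 27/33 = 81.8 % under these coordinates (the source rounds
this to 79 %); the intervals are not tuned to match the rounded figure.

## Enrichment statistics

Implemented from first principles because the exact test is the analysis'
core statistic. The hypergeometric pmf is computed via log-gamma
(`exp(lnC(c1,a) + lnC(c2,r1−a) − lnC(N,r1))`); the two-sided Fisher
p-value sums all margin-fixed tables with probability ≤ the observed
table's, with a relative tie tolerance of 1e-12 so the observed table is
never excluded by round-off (a double-one-sided variant is provided,
non-default). The odds ratio is the sample cross-product estimate with the
Katz log-normal CI; zero cells make OR/CI undefined (NaN) unless the
Haldane–Anscombe 0.5 correction is enabled. Reverse-derivation fixed the
estimator choice: (19·6)/(1·9) = 12.67 with Katz CI 1.32–121.47 equals the
published values exactly, so the conditional-MLE estimator is out of
scope.

Validation: the implementation equals exact integer-arithmetic enumeration
for **every** margin set with N ≤ 60 and every feasible observed cell, and
matches an independent mainstream implementation on sampled tables; the
pmf normalizes over its feasible range; under a simulated null (equal
anomaly rates, groups of 20 and 15, 2000 seeded replicates) the rejection
rate at α = 0.05 stays below 5 % (Fisher conservatism); the Katz 95 % CI
covers the true OR in ≥ 90 % of all-positive tables at the study's cell
sizes (coverage is assessed among all-positive tables because a zero cell
— which occurs in roughly a third of replicates at these sizes — leaves
the interval undefined without the continuity correction).

## Synthetic cohorts

The generator emulates the study conditions: residues uniform over the
protein; a configurable pathogenic fraction; class-conditional scores
drawn per tool from Beta(8, 2) for pathogenic and Beta(2, 8) for benign
variants (invented configuration — the study publishes no score
distributions); de novo evidence (PS2) at probability 0.9, mirroring the
reported > 90 % de novo prevalence; allele frequency absent for pathogenic
variants and log-uniform on [1e-6, 1e-2] for benign ones, with PM2
assigned exactly by the ≤ 0.001 frequency rule; PP3/BP4 derived from the
simulated REVEL score through the calibration module; heart-anomaly
probability 0.95 inside the ATPase motor region and 0.60 elsewhere,
mirroring the observed 19/20 and 9/15 group rates.

Randomness is a single `numpy.random.default_rng(seed)` stream per cohort
(NumPy PCG64), drawing per variant in the fixed order class → residue →
ref/alt residues → four scores → allele frequency → de novo status →
heart anomaly; Monte-Carlo replicates use `SeedSequence(seed).spawn`.
Power estimation can fix the two group sizes (the study design is 20 vs.
15) or let membership follow the region's share of the protein.

What the generator does **not** emulate: realistic gnomAD site-frequency
spectra, per-domain mutation-rate heterogeneity, correlated scores between
tools, or recurrent positions. Tests passing on synthetic cohorts
establish the pipeline's internal consistency under the stated model, not
calibration on real cohorts.

## Problem sizes and numerical choices

The exhaustive Fisher-vs-enumeration sweep covers all margins with total
N ≤ 60 (~70 000 margin sets, every feasible observed cell); the null
rejection check uses 2000 replicates and the CI coverage check 1000, both
seeded. Empirical score-mean checks use cohorts of 5000. These sizes make
the full suite run in well under a minute while leaving the statistical
assertions sharp. Degenerate inputs are defined rather than erroneous
wherever a convention exists: an empty evidence set is VUS; a zero-margin
2×2 table has p = 1 and undefined OR; an all-zero table is an error; an
empty cohort is an empty table.

## Known limitations

- Curated evidence (PS2/PS3/PM6/PP2/BS2...) is consumed as input; the
  package does not generate it from segregation or functional data.
- Computational evidence comes from REVEL only, per the source protocol;
  the other three tools are descriptive.
- The per-variant heart-anomaly flags in the fixture are editorial
  reconstructions of group-level counts (see above); analyses that depend
  on individual flags beyond the group table should treat them as
  provisional.
- No VCF/genomic support, no HGVS cDNA validation beyond pattern capture,
  no structural-effect prediction, and no multiple-testing machinery (the
  analysis contains a single test).
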