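# Methods

## Model and procedure

A loss-of-function screen assigns each (cell line, gene target) pair a
quantitative sensitivity score; scoring schemes differ between datasets
(zGARP, ATARiS phenotype scores, robust Z, CRISPR CS scores), but all
follow the convention that more negative means greater growth inhibition.
Because no common distributional form can be assumed across schemes, the
dependency test is rank-based: for each driver × target × context, the
one-sided Mann–Whitney U test of whether the altered group's scores are
stochastically smaller than the wild-type group's, with

U = #{altered < wild-type pairs} + ½·#tied pairs,  CLES = U/(n₁n₂).

CLES is the probability of superiority / AUROC; it is invariant under any
strictly increasing transformation of the scores, so it is comparable
across datasets with different scoring schemes. Retention requires
p < 0.05 (strict) **and** CLES ≥ 0.65 (inclusive). These are nominal
thresholds by design — the result set is an exploratory resource, not a
family-wise discovery claim — so no multiple-testing correction is
applied by default; Benjamini–Hochberg q-values per (dataset, context)
family are available opt-in and never modify the stored p-values.

### p-value computation

The exact null distribution of U is used when the pooled sample is
tie-free and n₁ + n₂ ≤ 30; otherwise the normal approximation with tie
correction and continuity correction. The switch is logged per
comparison at debug level. If every score in both groups is identical the
comparison is degenerate: p = 1 with a runtime warning. Exactness was
verified against an enumeration oracle over every tie-free rank pattern
with n₁ + n₂ ≤ 10 (agreement to 1e-12); the corrected normal
approximation stays within 0.02 of the exact value down to n₁ + n₂ ≈ 12,
which motivates the cut-over at 30 — comfortably inside the regime where
the approximation error is negligible relative to the 0.05 threshold.

### Genotype calling

Mutation side: oncogenes require a recurrent missense or in-frame indel,
recurrence meaning ≥ 3 prior COSMIC mutations at the site
(`recurrence_threshold`, default 3); tumor suppressors accept any
nonsense, frameshift or splice-site mutation unconditionally, plus
recurrent missense/indels. Copy-number side operates on precomputed
gene-level minimum/maximum segment copy number over the coding sequence:
amplification requires min_cn ≥ 8 (`amp_threshold` — "entire coding
sequence at 8 or more copies" is the minimum over segments), deletion
requires min_cn = 0 ("any part at copy number 0"). Tumor suppressors
combine deletion OR qualifying mutation; most oncogenes amplification OR
recurrent mutation; ERBB2/MYC/MYCN are amplification-only and
KRAS/BRAF/NRAS/HRAS mutation-only (the built-in driver set — all other
drivers are user-configured, mode `both`). Every true call records its
provenance ({mutation, amplification, deletion} branches fired), and
raising either threshold can only remove calls (monotonicity, property-
tested).

A driver is testable in a context when altered in ≥ 3 screened cell
lines there (`min_altered`); the rule is applied per dataset and per
context, since a driver can be well-powered pan-cancer but not within a
single tissue.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `p_max` | 0.05 | probability | nominal significance threshold, strict `<` |
| `cles_min` | 0.65 | probability | moderate effect size, inclusive `≥` |
| `amp_threshold` | 8 | copies | amplification over the whole CDS |
| `recurrence_threshold` | 3 | COSMIC site count | recurrent-mutation definition |
| `min_altered` | 3 | cell lines | smallest altered group tested |
| `min_wildtype` | 3 | cell lines | symmetric choice so group medians are meaningful; only the altered-side minimum is externally prescribed |
| `min_cell_lines` | 10 | cell lines | minimum panel size for a screen |
| STRING tiers | 0.4 / 0.7 / 0.9 | combined score | the conventional medium/high/highest cut-offs; configurable |

## Open design choices, as resolved here

- **Z-normalization axis.** zGARP-style screens are standardized to mean
  0, sample SD 1 (n−1 denominator). The axis is exposed; the default is
  per cell line, which puts every cell line's score vector on a common
  scale and so makes scores comparable *between* cell lines — the stated
  purpose of the normalization. Per-gene normalization is available as
  `per_target`.
- **Non-functional alterations.** Cell lines carrying an alteration that
  fails the functional rules (e.g. a non-recurrent missense in an
  oncogene) are pooled with wild-type, because the alteration matrix is
  binary. `scan(exclude_nonfunctional=True)` instead drops such carriers
  from the wild-type group, for users who consider them contaminating.
- **Multi-score resolution order.** When a gene has several score
  variants (ATARiS solutions), the variant with the lowest p-value is
  kept — resolution runs *before* filtering, so a gene is represented by
  its best-supported solution rather than silently dropped when a weaker
  solution fails the filter. Ties break to higher CLES, then smallest
  suffix.
- **Multiple Hit granularity.** A (driver, target) pair is flagged when
  retained after filtering in ≥ 2 distinct datasets, matching on Entrez
  IDs only — any context, any reagent suffix. Merely being *tested* in
  two datasets does not count.
- **Self-dependencies.** A driver that is its own target (oncogene
  addiction) is annotated with interaction tier `none`: self-edges are
  dropped at load time rather than reported as trivially "highest".
- **Target-label grammar.** `SYMBOL_ENTREZ[_SUFFIX]`; when the final two
  segments are both numeric, the second-to-last is the Entrez ID and the
  last the suffix; labels with no numeric Entrez segment fail loudly.
  Symbols containing underscores are supported as long as the segment
  before the Entrez ID is non-numeric.

## Synthetic data: what it does and does not emulate

`synth` generates screens with i.i.d. background noise (standard normal
scaled by `noise_sd`; optionally Student t with 3 df for heavy tails) and
planted dependencies as additive location shifts (effect ≤ 0) applied to
the altered lines of a driver, optionally restricted to one tissue.
Genotype tables are generated to *invert exactly* through the calling
rules — each altered (line, driver) gets a qualifying record for a rule
branch consistent with the driver's mode, and unaltered lines get decoy
records that sit just outside each rule boundary (recurrence 2, min_cn 7,
min_cn 1), so any threshold regression flips calls and is caught.

Deliberately not modeled: inter-gene correlation structure, batch and
off-target reagent artifacts, tissue-specific score distributions and
missingness mechanisms of real screens. Passing the synthetic benchmarks
therefore demonstrates the statistical machinery (calibration, power,
rule fidelity, format integrity) under the stated noise model, not
biological discovery performance on any real dataset.

## Benchmark problem sizes

The calibration and recovery suites use 30-line panels (10 altered / 20
wild-type), 100 targets and 200 replicate screens (100 in the acceptance
script), with planted shift −2 at noise SD 1. Under the exact tie-free
null at (10, 20), the joint p < 0.05 ∧ CLES ≥ 0.65 event has probability
≈ 0.049, so observed null retention rates near 5% are the calibrated
expectation, and the −2 shift (population CLES ≈ 0.92) is recovered in
effectively every replicate.

## Numerical notes and limitations

- Scores are written with shortest-round-trip decimal text; blank cells
  (also `NA`/`NaN` on read) denote missing values, which are dropped
  pairwise per target, never imputed.
- Scan output order is fixed (context, driver Entrez, target Entrez,
  suffix; pan-cancer first), so repeated runs are byte-identical.
- Zero-variance vectors make z-normalization undefined and raise, naming
  the offending cell line or target.
- Gene matching across screens, genotypes and annotation sources is by
  Entrez ID where available and by (optionally synonym-canonicalized)
  symbol for interaction/inhibitor lookups; a gene index built from an
  HGNC-style extract resolves synonym spellings, with primary symbols
  taking precedence over synonym collisions and genuine ambiguity raised
  as an error.
- COSMIC-numbered cell lines are supported only through a user-supplied
  rename map to CCLE-style names; there is no live identifier lookup,
  and no parsing of the original per-dataset supplementary file formats
  — screens are converted to the tab-delimited submission dialect first.
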