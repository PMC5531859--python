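# cgdscan

Detection of **cancer genetic dependencies (CGDs)** — associations in which
tumor cell lines carrying an alteration in a driver gene are selectively
sensitive to inhibition of a target gene — from loss-of-function screens
(siRNA, shRNA or CRISPR) integrated with genotype calls.

It is written for computational biologists who have a screen matrix
(cell lines × gene reagents, quantitative sensitivity scores where more
negative means more growth inhibition) and mutation / copy-number tables
for the same cell-line panel, and want the full pipeline: functional
alteration calling, the dependency test, the published filtering
thresholds, and annotation with functional-interaction, inhibitor and
cross-dataset evidence — all reproducible from a single config file.

## The statistic

For each driver gene *D*, target gene *T* and context (pan-cancer or a
single primary site), the panel is split into cell lines with a likely
functional alteration in *D* (group sizes n₁) and wild-type lines (n₂).
The alternative hypothesis — altered lines are *more sensitive* to
knockdown of *T* — is tested with a one-sided Mann–Whitney U test, where

U = #{(a, w) : score(a) < score(w)} + ½·#ties,  a ∈ altered, w ∈ wild-type.

The **common-language effect size** is CLES = U / (n₁n₂): the probability
that a randomly chosen altered line is more sensitive than a randomly
chosen wild-type line, identical to the area under the ROC curve. A
dependency is retained when p < 0.05 and CLES ≥ 0.65. The median
difference Δmedian = median(altered) − median(wild-type) reports the
effect in score units (negative = altered group more sensitive).

Genotype rules: an oncogene is altered by a recurrent missense/in-frame
indel (≥ 3 prior COSMIC mutations at the site) or amplification (entire
coding sequence at ≥ 8 copies); a tumor suppressor by any nonsense,
frameshift or splice-site mutation, a recurrent missense/indel, or a
deletion (any part of the coding sequence at copy number 0). ERBB2, MYC
and MYCN count only amplifications; KRAS, BRAF, NRAS and HRAS only
recurrent mutations.

## Worked example

Generate a self-contained demo workspace (two synthetic screens sharing a
planted dependency: tumor suppressor `DRV1` → target `TGT1`, mean shift
−2 score units in 10 altered vs 20 wild-type lines) and scan it:

```sh
cgdscan fixtures --out demo --seed 3
cd demo && cgdscan scan --config config.yaml
head -4 results/cgd_results.tsv | cut -f1-5,8-13
```

```
dataset      context  driver_symbol  driver_entrez  target_symbol  n_altered  n_wildtype  U    p            cles    delta_median
screen_DS1   PANCAN   DRV1           9001           TGT1           10         20          174  0.000307838  0.8700  -1.76213
screen_DS1   PANCAN   DRV1           9001           BG0002         10         20          142  0.0336497    0.7100  -1.12403
screen_DS1   OVARY    DRV1           9001           TGT1           5          5           22   0.0277778    0.8800  -0.969139
```

Reading the first row: in dataset `screen_DS1`, across all tissues,
`DRV1`-altered lines beat wild-type lines on `TGT1` sensitivity in 174 of
200 possible pairs (CLES 0.87 — an altered line is more sensitive 87% of
the time), one-sided p ≈ 3×10⁻⁴, and the altered group's median score is
1.76 units lower. The planted `TGT1` dependency recurs in `screen_DS2`
and is therefore flagged `yes` in the Multiple Hit column; `BG0002` is a
background target that passed the nominal filter by chance in one dataset
only. Per-CGD boxplot CSVs and a per-driver interaction-network export
are written alongside the results table, with a `manifest.json` recording
thresholds and input checksums.

## Layout

- `src/cgdscan/screen_io.py` — screen parsing/writing, CCLE-style name
  harmonization, validation, z-score normalization
- `src/cgdscan/genotype.py` — functional-alteration calling and the
  cell-line × driver alteration matrix
- `src/cgdscan/depstats.py` — Mann–Whitney/CLES testing, scanning,
  filtering, multi-score resolution, optional BH q-values
- `src/cgdscan/annotate.py` — STRING-tier, inhibitor, Multiple Hit and
  gene-synonym annotation
- `src/cgdscan/synth.py` — synthetic screens/genotypes with planted truth
- `src/cgdscan/cli.py` — the `cgdscan` command

See `docs/methods.md` for the model, parameter defaults and limitations.
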