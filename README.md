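# rhizosip

DNA stable-isotope-probing (SIP) analysis of root-exudate metabolizers, with
a full synthetic-study simulator so every stage is testable at desk scale.

A ¹³CO₂ SIP experiment feeds plants heavy CO₂; bacteria that metabolize
root exudates incorporate ¹³C into their DNA, which then bands at a higher
buoyant density in a CsCl gradient. This package implements the downstream
computational pipeline:

1. **`rhizosip.synthetic`** — simulates the whole study: a soil community
   with known ecological roles (exudate metabolizers, autotrophs,
   bystanders including an unlabeled *Streptomyces*-like minority clade),
   isotopic labeling per treatment, Gaussian banding of each taxon's DNA on
   a discretized CsCl gradient, per-fraction qPCR copy numbers with
   lognormal noise, multinomial amplicon read counts, and CFU colonization
   assays. Replicate endosphere DNA is pooled into a single gradient per
   isotope, mirroring the study design.
2. **`rhizosip.fractions`** — qPCR standard curves (CT → copy number),
   selection of heavy/light fraction windows from the copy-number profile
   (peak + density-offset rule, with a manual density-window override), and
   equal-quantity pooling of fractions into H/L class counts.
3. **`rhizosip.enrichment`** — relative-abundance conversion with
   singleton/plastid filtering, autotroph detection from unplanted ¹³CO₂
   controls, and the dual two-fold criterion: a genus is a labeled exudate
   metabolizer when its mean ¹³C-heavy abundance is ≥ 2× both its ¹³C-light
   and its ¹²C-heavy abundance and it is not an autotroph. Fold ratios use
   the ratio-of-means convention; printed integer folds are truncated.
4. **`rhizosip.ecology`** — Shannon diversity, Bray–Curtis dissimilarity,
   principal coordinates analysis, PERMANOVA.
5. **`rhizosip.colonization`** — CFU → cfu g⁻¹ conversion, log transform,
   two-way ANOVA (genotype × strain) and Tukey HSD post-hoc tests.
6. **`rhizosip.pipeline` / CLI** — end-to-end orchestration from a single
   YAML config, with seeded reproducibility and a JSON summary that, in
   synthetic mode, includes a confusion matrix against the simulated truth.

## CLI

```bash
# full pipeline from a config file
sip run --config run.yaml

# or stage by stage (every stage is re-runnable from its persisted outputs)
sip simulate --seed 1 --out sim/
sip fractions --counts sim/fraction_counts.tsv --meta sim/fraction_metadata.tsv \
    --delta-density 0.015 --out pooled.tsv
sip enrich --counts pooled.tsv --threshold 2 --pseudo 1e-6 --out enrich/
sip ecology --counts pooled.tsv --groups isotope_class --permutations 999 \
    --seed 1 --out eco/
sip cfu-stats --table cfu.tsv --out stats/
```

Minimal `run.yaml`:

```yaml
mode: synthetic     # or "real" with counts_path/metadata_path
seed: 1
out_dir: sip_out
threshold: 2.0
delta_density: 0.015
include_cfu: true
```

All tables are plain tab-delimited text. Pooled sample columns are keyed
`<isotope>_<compartment>_<replicate>_<fraction_class>` (e.g.
`13C_rhizosphere_1_H`, `13C_endosphere_pooled_L`).

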