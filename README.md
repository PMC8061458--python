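# methcompass

Cross-study quality control and variability analysis for Illumina Infinium
HumanMethylation450K (HM450K) DNA-methylation arrays.

Public repositories hold tens of thousands of HM450K samples, but their
metadata are free text, their quality is uneven, and study batch effects
dominate naive cross-study comparisons. `methcompass` packages the full
workflow needed to make such compilations analyzable:

* the **17 BeadArray control metrics** (signal ratios with manufacturer
  thresholds; extension-green background, +1 zero-denominator offset), the
  binary pass/fail outcome matrix, and a PCA + sequential-ANOVA analysis of
  which controls actually carry the quality signal;
* **array-wide signal QC** — log2 median methylated/unmethylated intensity,
  the combined failure rule (any failed control, or both medians < 11),
  per-study failure fractions f_st with a >60% flag, FFPE vs fresh-frozen
  comparisons, and binomial label-enrichment among failed samples;
* **noob background correction** — normal-exponential deconvolution using
  out-of-band probes: intensities are replaced by E[signal | observed] under
  X = S + B, S ~ Exp(α), B ~ N(μ, σ²) — plus Beta/M conversions
  (M = logit₂ Beta), per-study location adjustment of M-values, and
  per-sample median imputation;
* **metadata harmonization** — a controlled vocabulary learned from
  GEO SOFT-style free text via an editable table of prioritized regular
  expressions, with unit-normalized age capture;
* **model-based predictions** — a pluggable sparse linear epigenetic clock
  with the piecewise log-linear age calibration, median X/Y-intensity sex
  calls, constrained-least-squares cell deconvolution (w ≥ 0, Σw ≤ 1), and
  SNP-probe replicate detection;
* **age reliability** — mined vs predicted age concordance (MAD, R²,
  Spearman ρ), a ≤10-year study-wise MAD filter, epigenetic-age imputation,
  ±15-year acceleration outliers, and sequential-ANOVA variance attribution;
* the **two-step quantile-variance probe selection** — per tissue, the
  intersection of the extreme decile of probe variance and the extreme
  decile within each 0.1-wide mean-Beta bin — combined across tissues into
  shared low-variance probes (low everywhere, cross-tissue mean range
  < 0.01) and tissue-specific high-variance probes (high in exactly one
  tissue, top 2000 per tissue), with genome-context enrichment tests;
* **feature-hashing PCA** — signed hashing of probe ids into 1000 buckets
  (inner products preserved in expectation) before PCA, with group
  variance-ratio F-tests along components.

A first-class synthetic-data module generates every input with planted
ground truth (control failures, low-signal samples, replicate donors,
low-variance / tissue-specific / covariate-driven probes, messy metadata
text), so the whole pipeline is testable without downloading array data.

## Worked example

Run the seven-tissue variability workflow on a desk-scale synthetic cohort
(7 tissues × 3 studies × 8–12 samples, 2000 probes):

```python
from methcompass.pipeline import RunConfig, run_variance_analysis

cfg = RunConfig(seed=7, scenario_overrides=dict(
    n_probes=2000, n_low_var_probes=25, n_tissue_specific_per_tissue=30,
    n_shared_high_probes=190, n_age_probes=120, n_sex_probes=60,
    n_cell_probes=120, n_x_probes=120, n_y_probes=100,
    samples_per_study=(8, 12)))
res = run_variance_analysis(cfg, "demo_run")

print("samples after QC filtering:", res["panel"].samples.shape[0])
print("covariate-dropped probes (blood):", res["drop_counts"]["blood"])
print("shared low-variance probes:", int(res["shared_low"]["selected"].sum()))
print("tissue-specific probes (sperm):", len(res["tissue_specific"]["sperm"]))
mined = res["age_pairs"].query("age_provenance == 'mined'")
print("age MAD (mined pairs, years): %.2f"
      % (mined["epigenetic_age"] - mined["chronological_age"]).abs().mean())
print("eligible studies:", len(res["eligible_studies"]), "of",
      res["mad_table"].shape[0])
rec = res["recovery"]
print("planted recovery: shared-low P=%.2f R=%.2f; tissue-specific P=%.2f R=%.2f"
      % (rec["shared_low_precision"], rec["shared_low_recall"],
         rec["tissue_specific_precision"], rec["tissue_specific_recall"]))
```

which prints:

```
samples after QC filtering: 210
covariate-dropped probes (blood): 193
shared low-variance probes: 17
tissue-specific probes (sperm): 36
age MAD (mined pairs, years): 1.31
eligible studies: 21 of 21
planted recovery: shared-low P=1.00 R=0.68; tissue-specific P=0.68 R=0.86
```

Reading this: 210 samples survive the control/signal/replicate filters; the
covariate filter drops 193 of 1750 autosomal blood probes (~11%, matching the
planted 12% covariate-driven fraction); 17 probes are uninformative in every
tissue (low variance everywhere, tissue means within 0.01); sperm carries 36
probes variable there and nowhere else; predicted ages track the planted ages
with a 1.3-year mean absolute difference, so all 21 studies pass the
≤10-year reliability filter and missing ages are imputed from epigenetic
age. At this small scale, planted-probe recovery is capacity-limited by the
per-bin decile (precision/recall well below the full-scale values); at the
shipped full scenario (7 × ~150 samples × 20 000 probes) both precision and
recall exceed 0.9 — `tests/test_acceptance.py` asserts exactly that, and the
run directory's `recovery.tsv` records the numbers. All outputs embed the
config hash and seed; reruns are byte-identical.

The same workflows are available from the shell:

```bash
methcompass simulate --seed 1 --out sim/
methcompass qc --seed 1 --out qc_run/
methcompass variance --seed 1 --out var_run/
```

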