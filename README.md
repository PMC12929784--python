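# dnarna

Concordance analysis of paired tumor DNA and RNA profiling, and tumor
transcriptional burden (TTB) survival analysis, for gene-panel oncology
cohorts.

Precision-oncology programs routinely profile tumor DNA; RNA profiling on
the same specimen is still investigational, and a central question is how
the two layers relate. Given call-level tables — per patient, the genes
with genomic alterations (classed as frameshift/stop-gain, copy number,
missense, fusion, splice site) and the genes with altered expression
(over/under) — this package answers four questions:

- **Same-gene concordance** — which (patient, gene) pairs are altered by
  both assays, what alteration classes drive them, how strongly copy
  number tracks expression (Spearman ρ over concordant events), and
  whether detection depends on tumor purity (Mann-Whitney U).
- **Exhaustive pair screen** — for every DNA gene *g* × RNA gene *h*, a
  patient-level 2×2 table (presence/absence of alteration in *g* crossed
  with presence/absence of altered expression in *h*) tested by the
  two-sided Fisher exact test, with Benjamini-Hochberg FDR correction
  across all |G_DNA|·|G_RNA| pairs, partitioned into *concordant* (g = h)
  and *discordant* significant pairs.
- **Annotation** — one-sided hypergeometric over-representation of
  significant-pair genes against a GMT collection (sets of ≥10 and <250
  genes; reported at overlap ≥10 and adjusted p < 0.05), TF→target
  annotation from a TRRUST-style edge list, and directed association
  networks weighted by −log10(adjusted p).
- **TTB and survival** — TTB = per-patient count of distinct genes with
  altered expression; treated patients stratified at TTB 0–2 / 3–5 / ≥6
  (configurable) and compared with Kaplan-Meier curves and the k-sample
  log-rank test, plus a TTB vs PD-L1-status rank test and Yates-corrected
  chi-squared baseline comparisons.

Because patient-level data of this kind are generally not deposited, the
package includes a seeded synthetic cohort generator
(`dnarna.synthetic`) calibrated to realistic summaries — 253 patients,
242 DNA / 52 RNA genes with Zipf-like frequencies, per-patient medians of
4 DNA-altered and 2 expression-altered genes, a 42.9/30.4/23.8/2.9% class
mixture, 87.7/12.3% over/under split, purity-modulated copy-number→
expression coupling (concordant-event Spearman ≈ 0.72), stratum-specific
survival (median OS 9.8/11.9/6.7 months), and plantable cross-gene
associations — so every pipeline stage is testable end to end without any
downloads. See `docs/methods.md` for the model and calibration details.

## Worked example

Simulate a cohort with a planted TP53→VEGFA association (odds multiplier
8) and run the full pipeline:

```
dnarna simulate --seed 7 --out-dir cohort \
    --config planted.yaml     # planted_pairs: [[TP53, VEGFA, 8.0]]
dnarna report --patients cohort/patients.tsv --dna cohort/dna_calls.tsv \
    --rna cohort/rna_calls.tsv --out-dir results
```

or equivalently in Python:

```python
from dnarna import (SimulationConfig, PlantedPair, generate_cohort,
                    detect_concordant_events, run_screen,
                    partition_significant, ttb_survival_analysis)

cfg = SimulationConfig(seed=7, planted_pairs=(PlantedPair("TP53", "VEGFA", 8.0),))
cohort = generate_cohort(cfg)                  # 253 patients, 1157 DNA / 828 RNA calls
events = detect_concordant_events(cohort)      # 68 events in 58 patients
results = run_screen(cohort)                   # 200 x 52 = 10,400 pairs
_, _, counts = partition_significant(results)  # 1 significant pair
top = results[0]
surv = ttb_survival_analysis(cohort)
```

With this seed the screen tests 10,400 gene pairs (200 DNA genes realized
at least once × 52 RNA genes) and exactly one survives BH at 0.05 — the
planted pair:

```
top pair : TP53 -> VEGFA   n11 = 56   p = 4.1e-08   adjusted p = 4.3e-04
```

meaning 56 patients carry both a TP53 genomic alteration and altered
VEGFA expression, far above the ~36 expected under independence. The
treated-subset survival analysis recovers the configured stratum
structure:

```
KM median OS (months):  TTB 0-2: 12.5   TTB 3-5: 12.2   TTB >=6: 8.8
log-rank p = 0.0064   (n = 109 / 61 / 46)
```

— patients with ≥6 dysregulated genes have visibly shorter survival,
while the two lower-burden strata are close, as configured. Single-seed
medians scatter around the configured 9.8/11.9/6.7 by a couple of months
at these stratum sizes; the calibration tests quantify this across seeds.

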