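# crossfactor

Analysis pipeline for **2×2 factorial perturbation expression experiments**
— the design in which cells receive a genetic perturbation (e.g. knock-down
of a transcription factor such as HNF4α), a physiological stimulus (e.g. an
IL-1β/IL-6/TNF-α cytokine mixture), both, or neither, with replicated
expression profiling of all four groups.

Given a normalized probeset × sample intensity matrix, crossfactor:

1. **Classifies** every probeset by two-way fixed-effects ANOVA on the log2
   scale into four response categories (or none), at a per-effect
   Benjamini–Hochberg FDR cut-off (default q < 0.01):
   - **A** — responds to factor 1 (perturbation) only,
   - **B** — responds to factor 2 (stimulus) only,
   - **C** — *additive*: both main effects, no interaction,
   - **D** — *interactive*: significant interaction (dominates any main
     effects, since additivity is defined by its absence);
2. **Collapses** probesets to genes, conservatively dropping genes whose
   probesets disagree in category;
3. **Clusters** each category's z-scored group-mean profiles with K-means
   (default k = {A: 2, B: 2, C: 4, D: 8});
4. **Tests enrichment** of gene sets (GMT) in categories and clusters, of an
   external bound-gene list (e.g. ChIP targets) against the responsive set,
   and of promoter motifs (JASPAR PFMs, log2-ratio PWM scan, site score
   ≥ 8.0) in responsive-gene promoters versus a background promoter set —
   all with one-tailed Fisher exact tests computed in log space and
   Bonferroni control.

A first-class **synthetic-data generator** emulates the whole experiment
with known truth — planted categories and interaction archetypes, an
inflammatory-response gene set routed into focal interactive archetypes, a
bound list drawn at a configurable odds ratio, and an ETS-like consensus
motif (CCGGAAG/A) planted into responsive promoters — so every stage has a
parameter-recovery and calibration test surface.

## The statistics

For a balanced 2×2 layout with r replicates per cell the log2 intensities
decompose as

```
SS_total = SS_1 + SS_2 + SS_12 + SS_E,    F_eff = MS_eff / MS_E ~ F(1, 4(r-1))
```

with q-values per effect family by Benjamini–Hochberg. Over-representation
of a set of size K within a target of size n drawn from a universe of N
genes is the hypergeometric upper tail

```
p = P(X >= a),  X ~ Hypergeom(N, K, n),   fold = (a/n) / (K/N)
```

accumulated via log-gamma + logsumexp so p-values far below 1e-300 stay
finite. Promoter windows default to −1000/+500 around the TSS; a PWM entry
is log2(p_motif(b,i)/p_background(b)) with pseudocounts spread by the
background composition.

## Worked example

Generate a 2,000-gene synthetic experiment and run every stage:

```yaml
# demo.yaml
out_dir: demo_report
seed: 11
synth: {n_genes: 2000, seed: 11, n_inflammatory: 40, n_metabolic: 400, bound_size: 160}
```

```
$ crossfactor run-all --config demo.yaml
report written to demo_report
```

`demo_report/summary.tsv` counts probesets per category at the FDR-only and
FDR + 2-fold cut-offs:

```
cutoff    n_A  n_B  n_C  n_D  factor1_responsive  factor2_responsive  both_responsive
fdr       606  101  165   78                 849                 344              243
fdr+fold  600   99  165   78                 843                 342              243
```

`overlap_shares.tsv` reports that 243/344 = **70.6%** of stimulus-responsive
probesets also respond to the perturbation — the overlap statistic that
quantifies how strongly the two response axes intertwine. The planted
inflammatory set comes out 10.1-fold enriched in the interactive category
(p = 1.6 × 10⁻¹²) and ~30-fold in its focal cluster; the bound list overlaps
the responsive set at 60% versus a 12.9% background rate
(p = 1.6 × 10⁻⁸); and the planted ELK1-like motif ranks first in
`motif_enrichment.tsv` at p = 3.5 × 10⁻¹⁴ while every decoy stays
non-significant:

```
motif      consensus    target_fraction  background_fraction  p            significant
ELK1_like  CCGGAAG      0.720            0.552                3.53e-14     True
decoy06    CCAGCCATCCC  0.336            0.309                0.121        False
```

All numbers above are deterministic under the config's seed; a rerun
produces byte-identical reports.

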