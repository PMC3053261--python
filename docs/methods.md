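# Methods

## Design and model

crossfactor analyzes a balanced 2×2 factorial expression experiment: factor
1 is a genetic perturbation (knock-down vs control), factor 2 a stimulus
(treated vs control), with r ≥ 2 replicates in each of the four cells
(r = 4 throughout the defaults). Intensities arrive on the linear scale, as
produced by array summarization; all modeling happens on log2(x + 1). The
+1 offset keeps near-zero intensities finite and is negligible at typical
signal levels (baselines of 2⁶–2¹²).

Each probeset is decomposed by classical fixed-effects two-way ANOVA. For
cell means m_ij the marginal contrasts are d1 = mean(m_1·) − mean(m_0·),
d2 = mean(m_·1) − mean(m_·0), and the interaction contrast
c = m_11 − m_10 − m_01 + m_00, giving SS_1 = r·d1², SS_2 = r·d2²,
SS_12 = r·c²/4, each on 1 df, with SS_E on 4(r−1) df. F = MS_eff/MS_E and p
from F(1, 4(r−1)). Unbalanced layouts are rejected rather than silently
resolved through a sums-of-squares convention; the supported design is
balanced, where types I/II/III coincide (the test suite verifies agreement
with a generic least-squares model-comparison fit).

Degenerate inputs: when MS_E = 0 and the effect SS is also 0 (all sixteen
values equal), F = 0 and p = 1; when MS_E = 0 but the effect SS is
positive, F = +inf and p = 0. Both are deterministic conventions for data
that cannot occur under the noise model but can occur in constructed
fixtures.

## FDR and category assignment

p-values are adjusted by Benjamini–Hochberg separately within each of the
three effect families across all probesets (delegated to
`statsmodels.stats.multitest`; the field-default step-up procedure, checked
against a hand-enumerated oracle). At α (default 0.01):

- q_interaction < α → **D** (interaction dominates even when main effects
  are also significant — "additive" is defined by the absence of
  interaction, and interactive profiles routinely carry main-effect-like
  marginals);
- else both main q < α → **C**; only factor 1 → **A**; only factor 2 →
  **B**; otherwise **none**.

Direction per factor is the sign of that factor's marginal log2 contrast,
reported only when the factor is significant. The fold change is the
largest absolute *linear* ratio over the contrasts belonging to the
category: the significant marginal(s) for A/B/C, and for D the three
treatment-vs-control cell contrasts (factor 1 alone, factor 2 alone, both),
reconstructed exactly from (d1, d2, c). The 2-fold filter keeps the
FDR-significant probesets whose relevant contrast also reaches the
threshold; which contrast a historical analysis used for C/D genes is not
recoverable, so the maximum over the category's contrasts is used as the
most inclusive deterministic choice.

## Gene collapse

Genes are the probeset→gene map's equivalence classes. A gene is retained
only if all its probesets share one category label ("pattern" is
operationalized as the category call; a stricter (category, direction)
comparison is available via the `on` parameter). Dropped genes are reported
with reason `pattern-conflict`. The representative probeset is the one with
the highest mean intensity across all samples — deterministic and
conventional. Unmapped probesets pass through as flagged singleton
pseudo-genes so they can be excluded from annotation-based tests.

## Profile clustering

Profiles are 4-vectors of cell means on log2 scale in the fixed order
(control, stimulus-only, perturbation-only, both), z-scored per probeset
(population sd; constant profiles map to the zero vector) so that shape,
not magnitude, drives the clustering. K-means uses Euclidean distance,
k-means++ seeding, 50 restarts with the best inertia kept, then a Lloyd
polish to a strict assignment fixed point (so one further iteration changes
nothing). Cluster indices are relabeled by descending size with a
lexicographic centroid tie-break; absolute labels of any historical run are
not reproducible, so all tests match clusters by archetype shape, never by
label. Default k per category: {A: 2, B: 2, C: 4, D: 8}.

## Enrichment statistics

One-tailed (over-representation) Fisher exact tests throughout, as the
hypergeometric upper tail P(X ≥ a), computed from the log-gamma
representation of the log-pmf and accumulated with logsumexp — exact to
~1e-13 relative error (verified against integer enumeration over all small
tables) and finite for p far below the smallest normal double when reported
as log10 p. Fold enrichment is (a/n)/(K/N) with expected count n·K/N.
Bonferroni thresholds α/m are reported at full precision and rounded to one
significant digit for display. Depletion tails exist behind a flag; the
default direction is enrichment.

The gene-set universe is all genes represented on the array after collapse;
annotation sets are intersected with the universe before testing, which is
why an annotation's nominal size shrinks to its on-array count.

**Bound-list overlap conditioning.** When asking whether the rate of
responsiveness *within* an external bound-gene list exceeds the array-wide
rate, the package compares the list against the whole universe (table
a, b, |set2|, N − |set2|): this is the construction under which both
conditional shares and their printed significance levels in the motivating
study are reproduced. The classical partitioned table
(a, b, |set2∖set1|, N − |set1∪set2|) — which conditions on the
non-overlapping remainder and yields smaller p-values — is available with
`disjoint=True`.

**Motif enrichment.** PWM entries are log2(p_motif/p_background) with a
per-column pseudocount total of 4 spread by the background composition (one
count per base under a uniform background). Background frequencies default
to uniform and can be estimated from the background promoter set. Every
window on both strands is scored as the PWM sum; windows overlapping an N
score −inf; a promoter "contains" the motif when any window reaches the
score threshold (default 8.0 log2 units — a per-site cut-off, chosen over a
sequence-level averaged statistic because the downstream test is
presence-based, which keeps the site definition deterministic and the 2×2
table exact). The target promoter set is tested against
background-minus-target so cells stay disjoint. Promoter windows default to
−1000/+500 around the TSS (0-based, half-open, strand-aware; minus-strand
windows are reverse-complemented), clipped at contig ends with a warning;
an extended −5000/+2500 variant is a spec-level parameter change.

## Synthetic data generator

The generator emulates the study conditions end to end:

- **Scale**: 14,220 genes by default (scaled down explicitly in tests);
  ~10% of genes carry 2–3 probesets sharing the gene's effects; baseline
  log2 intensities uniform on [6, 12].
- **Categories**: proportions {A: 25%, B: 4%, C: 7%, D: 4%, none: 60%},
  echoing the magnitude of a genome-wide knock-down response. Effect sizes
  |log2FC| uniform on [2, 3] with random sign; replicate noise is Normal on
  the log2 scale with σ = 0.25 (log-normal intensities — the standard
  multiplicative microarray error model; the emitted matrix is linear
  scale). A gene whose drawn effects are all zero is relabeled `none`.
- **Interaction archetypes**: eight 4-vector templates covering the
  qualitatively distinct 2×2 interaction shapes (e.g. "up only under the
  combined treatment", "down under knock-down alone, restored by the
  stimulus", synergistic amplification, mutual cancellation). Two focal
  archetypes preferentially receive genes of the planted
  inflammatory-response set (170 genes at full scale, 30% routed), making
  set-in-cluster enrichment recoverable.
- **Bound list**: 1,219 genes drawn without replacement with odds 3:1
  favoring truly factor-1-responsive genes.
- **Promoters**: i.i.d. background sequence (uniform composition, length
  1500) with an instance sampled from the planted ETS-like PFM (consensus
  CCGGAAG with a G/A final position) inserted at a random offset with
  probability 0.4 for factor-1-responsive genes and 0.1 otherwise, plus 10
  sharp random-consensus decoy PFMs of length 9–11 that are never planted
  and whose consensi avoid the planted core (and its reverse complement) so
  decoy presence stays independent of planting.
- **Determinism**: one master seed; each stage draws from a named
  deterministic substream, so identical configurations give byte-identical
  bundles.

What the generator does **not** emulate: probe-level effects, chip spatial
artifacts, normalization residue, present/absent calling, missing values,
correlated gene modules, or realistic promoter composition (no GC isochores,
no CpG islands, no repeats). Passing recovery tests therefore demonstrate
the pipeline's correctness and calibration under the declared generative
model, not performance on real arrays, where variance heterogeneity and
annotation error dominate.

## Validation studies and problem sizes

The `validation` module runs the studies reported by the reproduction
script; sizes were chosen as the smallest bundles at which the measured
rates are stable:

- Fisher tail vs exact integer enumeration over all 2×2 tables with total
  ≤ 60 (transpose-symmetric margins tested once; symmetry itself is a
  property test).
- ANOVA F statistics vs a least-squares model-comparison oracle on 1,000
  random balanced 2×2×4 layouts, compared as |ΔF|/(1 + |F_ref|) — relative
  error for F of order ≥ 1, absolute near zero, where the oracle's
  residual-SS subtraction cancels catastrophically and plain relative error
  is uninformative.
- Null calibration: 20 all-null bundles of 5,000 probesets; mean fraction
  classified at q < 0.01.
- Recovery: one strong-effect bundle of 2,000 genes; fraction of non-null
  genes with the planted category recovered.
- Set-in-cluster recovery: 50 seeds × 2,000 genes (inflammatory set scaled
  to 2% of genes, 30% routed); success when the interactive-category
  cluster with the smallest inflammatory-set p is dominated by a focal
  archetype.
- Motif recovery: 50 seeds × 1,000 genes (≈50% factor-1 responsive, i.e.
  ~500 target vs ~500 background promoters); success when the planted
  motif ranks first by p, and separately when every decoy stays above the
  Bonferroni cut-off.

## Known limitations

- Variance is estimated per probeset with 4(r−1) df; no moderated
  (empirical-Bayes) shrinkage, so very small per-gene variances can inflate
  F on real data at small r.
- The motif score threshold treats 8.0 log2 units as a per-site cut-off;
  tools whose score is a sequence-level averaged likelihood ratio will call
  different site sets at the same nominal number.
- GO-style set relationships (graph propagation, true-path rule) are out of
  scope; sets are flat membership lists.
- K-means with fixed k inherits the usual limitations — no model selection,
  sensitivity to rare shapes at small category sizes.
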