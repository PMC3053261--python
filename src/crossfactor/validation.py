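"""Simulation studies validating calibration and power of the pipeline.

These routines run the full analysis on synthetic bundles with known truth
and summarize how well each stage behaves: exactness of the Fisher tail
against integer enumeration, agreement of the ANOVA decomposition with a
generic least-squares fit, false-positive calibration on all-null data,
category recovery under strong effects, recovery of a gene set planted into
one interactive-archetype cluster, and recovery of a planted promoter motif
against decoys.  They back both the test suite and the reproduction script,
and are useful on their own when tuning simulation parameters.

Problem sizes default to scaled-down bundles (a few thousand genes) that
keep each study in the seconds-to-minutes range while leaving the measured
rates stable.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from .classify import anova_table, classify
from .cluster import build_profiles, kmeans_cluster
from .collapse import collapse
from .enrichment import bonferroni_threshold, fisher_one_tailed
from .motifs import build_motif_model, motif_enrich
from .simulate import FOCAL_ARCHETYPES, SimConfig, simulate_expression, simulate_promoters

__all__ = [
    "fisher_enumeration_max_error",
    "anova_oracle_max_rel_error",
    "null_classification_rate",
    "category_recovery",
    "inflammatory_cluster_recovery",
    "motif_recovery",
]


def fisher_enumeration_max_error(max_total: int = 60) -> float:
    """Largest relative error of the log-space Fisher tail against exact
    integer enumeration, over every 2x2 table with grand total <= *max_total*.

    Tables share a p-value through (N, K, n, a), so each distinct margin
    combination is evaluated once; margins with n > K are transposes of
    tested tables (the tail is transpose-symmetric), so only n <= K runs.
    """
    worst = 0.0
    for N in range(1, max_total + 1):
        for K in range(0, N + 1):
            for n in range(0, K + 1):
                denom = math.comb(N, n)
                lo, hi = max(0, n - (N - K)), min(K, n)
                # exact upper tails, accumulated from the top in exact ints
                tail = 0
                exact: dict[int, Fraction] = {}
                for a in range(hi, lo - 1, -1):
                    tail += math.comb(K, a) * math.comb(N - K, n - a)
                    exact[a] = Fraction(tail, denom)
                for a in range(lo, hi + 1):
                    p = fisher_one_tailed(a, n - a, K - a, N - K - n + a)
                    ref = float(exact[a])
                    err = abs(p - ref) / ref
                    if err > worst:
                        worst = err
    return worst


def _lstsq_f_stats(arr: np.ndarray) -> tuple[float, float, float]:
    """Model-comparison oracle: SS of each effect as the drop in residual SS
    when that (centered, orthogonal) column leaves the full design."""
    r = arr.shape[2]
    y = arr.reshape(-1)
    i = np.repeat([0.0, 0, 1, 1], r)
    j = np.repeat([0.0, 1, 0, 1], r)
    ic, jc = i - i.mean(), j - j.mean()
    base = np.column_stack([np.ones_like(y), ic, jc, ic * jc])

    def sse(X: np.ndarray) -> float:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    sse_full = sse(base)
    mse = sse_full / (4 * (r - 1))
    out = []
    for keep in ([0, 2, 3], [0, 1, 3], [0, 1, 2]):
        out.append((sse(base[:, keep]) - sse_full) / mse)
    return tuple(out)


def anova_oracle_max_rel_error(n_instances: int = 1000, seed: int = 0) -> float:
    """Largest disagreement in F statistics between the closed-form
    decomposition and the least-squares oracle on random balanced 2x2x4
    layouts, as ``|F - F_ref| / (1 + |F_ref|)``.

    The mixed metric reads as relative error for F of order one or larger
    and absolute error near zero, where the oracle's residual-SS subtraction
    cancels catastrophically and plain relative error is meaningless.
    """
    from .classify import anova_two_way

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        arr = rng.normal(5.0, 2.0, size=(2, 2, 4))
        rec = anova_two_way(arr)
        ours = (rec["F_factor1"], rec["F_factor2"], rec["F_interaction"])
        ref = _lstsq_f_stats(arr)
        for x, y in zip(ours, ref):
            err = abs(x - y) / (1.0 + abs(y))
            if err > worst:
                worst = err
    return worst


def _null_config(n_genes: int, seed: int) -> SimConfig:
    return SimConfig(
        n_genes=n_genes,
        category_proportions={},
        n_inflammatory=0,
        n_metabolic=0,
        bound_size=0,
        seed=seed,
    )


def null_classification_rate(
    n_genes: int = 5000, n_seeds: int = 20, base_seed: int = 0
) -> float:
    """Mean fraction of probesets assigned any category on all-null bundles
    at the default FDR 0.01 cut-off."""
    fracs = []
    for k in range(n_seeds):
        bundle, _, _ = simulate_expression(_null_config(n_genes, base_seed + k))
        calls = classify(anova_table(bundle))
        fracs.append(float((calls["category"] != "none").mean()))
    return float(np.mean(fracs))


def category_recovery(n_genes: int = 2000, seed: int = 42) -> float:
    """Fraction of non-null genes whose planted category is recovered on a
    strong-effect bundle (|log2FC| in [2, 3], sigma 0.25, 4 replicates)."""
    cfg = SimConfig(
        n_genes=n_genes,
        effect_range=(2.0, 3.0),
        sigma=0.25,
        replicates=4,
        n_inflammatory=max(10, int(0.012 * n_genes)),
        n_metabolic=int(0.2 * n_genes),
        bound_size=int(0.08 * n_genes),
        seed=seed,
    )
    bundle, gene_map, truth = simulate_expression(cfg)
    calls = classify(anova_table(bundle))
    gene_calls, _ = collapse(calls, gene_map, bundle.values.mean(axis=1))
    merged = gene_calls.set_index("gene_id").join(
        truth, how="inner", lsuffix="_call", rsuffix="_true"
    )
    nonnull = merged[merged["category_true"] != "none"]
    return float((nonnull["category_call"] == nonnull["category_true"]).mean())


def inflammatory_cluster_recovery(
    n_seeds: int = 50, base_seed: int = 0, n_genes: int = 2000
) -> float:
    """Fraction of seeded runs in which the interactive-category cluster most
    enriched for the planted inflammatory set is a cluster dominated by one
    of the focal archetypes the set was routed into.

    Mirrors the set-in-cluster analysis: classify, collapse, K-means with
    k = 8 on the interactive category, then a one-tailed Fisher test of the
    inflammatory set in each cluster against the whole gene universe.
    """
    successes = []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes,
            n_inflammatory=int(0.02 * n_genes),
            inflam_route_frac=0.3,
            n_metabolic=0,
            bound_size=0,
            seed=base_seed + k,
        )
        bundle, gene_map, truth = simulate_expression(cfg)
        calls = classify(anova_table(bundle))
        gene_calls, _ = collapse(calls, gene_map, bundle.values.mean(axis=1))
        profiles = build_profiles(bundle, gene_calls, "D", id_column="gene_id")
        if len(profiles) < 8:
            successes.append(False)
            continue
        model = kmeans_cluster(profiles, k=8, seed=base_seed + k)
        inflam = set(truth.index[truth["inflammatory"]])
        universe = set(gene_calls["gene_id"])
        best_p, best_cluster = 1.1, None
        for cl in range(8):
            members = set(model.assignments.index[model.assignments == cl])
            a = len(members & inflam)
            b = len(members) - a
            c = len(inflam & universe) - a
            d = len(universe) - a - b - c
            p = fisher_one_tailed(a, b, c, d)
            if p < best_p:
                best_p, best_cluster = p, cl
        members = model.assignments.index[model.assignments == best_cluster]
        archetypes = truth.loc[truth.index.intersection(members), "archetype"]
        plurality = archetypes.value_counts().idxmax() if len(archetypes) else 0
        successes.append(plurality in FOCAL_ARCHETYPES)
    return float(np.mean(successes))


def motif_recovery(
    n_seeds: int = 50, base_seed: int = 0, n_genes: int = 1000
) -> dict[str, float]:
    """Planted-motif power and decoy calibration of promoter enrichment.

    For each seed, promoters of truly factor-1-responsive genes (planting
    rate 0.4) are tested against all remaining promoters (rate 0.1) with the
    planted matrix and the decoy library.  Returns the fraction of runs in
    which the planted motif ranks first by p-value, and the fraction in
    which every decoy stays above the Bonferroni cut-off.
    """
    first, decoys_null = [], []
    for k in range(n_seeds):
        cfg = SimConfig(
            n_genes=n_genes,
            category_proportions={"A": 0.30, "B": 0.05, "C": 0.10, "D": 0.05},
            n_inflammatory=0,
            n_metabolic=0,
            bound_size=0,
            seed=base_seed + k,
        )
        _, _, truth = simulate_expression(cfg)
        promoters, pfms = simulate_promoters(cfg, truth)
        models = [build_motif_model(p, threshold=8.0) for p in pfms]
        responsive = [
            g for g in truth.index if truth.loc[g, "category"] in ("A", "C", "D")
        ]
        res = motif_enrich(promoters.subset(responsive), promoters, models)
        first.append(res["motif"].iloc[0] == pfms[0].name)
        thr = bonferroni_threshold(0.05, len(models))
        decoy_rows = res[res["motif"] != pfms[0].name]
        decoys_null.append(bool((decoy_rows["p"] > thr).all()))
    return {
        "planted_first_rate": float(np.mean(first)),
        "decoys_nonsignificant_rate": float(np.mean(decoys_null)),
    }
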