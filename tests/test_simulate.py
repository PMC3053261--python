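import numpy as np
import pandas as pd
import pytest

from crossfactor.classify import anova_table, classify
from crossfactor.collapse import collapse
from crossfactor.io import read_expression, read_fasta_promoters, read_gmt, read_jaspar_pfm
from crossfactor.simulate import (
    D_ARCHETYPES,
    ELK1_LIKE_PFM,
    SimConfig,
    simulate_bound_list,
    simulate_expression,
    simulate_promoters,
    write_bundle,
)


def small_config(**kw):
    defaults = dict(n_genes=300, n_inflammatory=20, n_metabolic=50,
                    bound_size=40, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateExpression:
    def test_zero_effects_make_every_gene_null(self):
        cfg = small_config(effect_range=(0.0, 0.0))
        _, _, truth = simulate_expression(cfg)
        assert (truth["category"] == "none").all()

    def test_same_seed_gives_identical_bundles(self):
        cfg = small_config()
        b1, m1, t1 = simulate_expression(cfg)
        b2, m2, t2 = simulate_expression(small_config())
        pd.testing.assert_frame_equal(b1.values, b2.values)
        assert m1.mapping == m2.mapping
        pd.testing.assert_frame_equal(t1, t2)

    def test_effects_consistent_with_categories(self):
        _, _, truth = simulate_expression(small_config())
        a = truth[truth["category"] == "A"]
        assert (a["beta_factor2"] == 0).all() and (a["beta_interaction"] == 0).all()
        assert (a["beta_factor1"] != 0).all()
        b = truth[truth["category"] == "B"]
        assert (b["beta_factor1"] == 0).all() and (b["beta_interaction"] == 0).all()
        c = truth[truth["category"] == "C"]
        assert (c["beta_interaction"] == 0).all()
        assert (c["beta_factor1"] != 0).all() and (c["beta_factor2"] != 0).all()
        d = truth[truth["category"] == "D"]
        assert (d["beta_interaction"] != 0).all()
        assert set(d["archetype"]) <= set(D_ARCHETYPES)
        assert (truth.loc[truth["category"] != "D", "archetype"] == 0).all()

    def test_matrix_is_linear_scale_and_positive(self):
        bundle, _, _ = simulate_expression(small_config())
        assert (bundle.values.to_numpy() > 0).all()
        # baselines of 6-12 log2 units put typical intensities well above 1
        assert bundle.values.to_numpy().mean() > 50

    def test_some_genes_get_multiple_probesets(self):
        bundle, gene_map, truth = simulate_expression(small_config())
        per_gene = pd.Series(gene_map.mapping).value_counts()
        assert per_gene.max() >= 2
        assert per_gene.min() == 1
        assert len(bundle.probeset_ids) == len(gene_map)

    def test_null_gene_guard(self):
        cfg = small_config(
            category_proportions={"A": 0.5, "B": 0.2, "C": 0.2, "D": 0.1},
            require_null_genes=True,
        )
        with pytest.raises(ValueError, match="null"):
            simulate_expression(cfg)

    def test_recovery_on_strong_effects(self):
        """Planted categories are recovered for >= 95% of non-null genes."""
        cfg = SimConfig(n_genes=2000, effect_range=(2.0, 3.0), sigma=0.25,
                        replicates=4, n_inflammatory=50, n_metabolic=200,
                        bound_size=200, seed=42)
        bundle, gene_map, truth = simulate_expression(cfg)
        calls = classify(anova_table(bundle))
        gene_calls, _ = collapse(calls, gene_map, bundle.values.mean(axis=1))
        merged = gene_calls.set_index("gene_id").join(
            truth, how="inner", lsuffix="_call", rsuffix="_true"
        )
        nonnull = merged[merged["category_true"] != "none"]
        accuracy = (nonnull["category_call"] == nonnull["category_true"]).mean()
        assert accuracy >= 0.95

    def test_noise_monotonically_degrades_recovery(self):
        """Mean recovery accuracy never improves as sigma rises (10 seeds)."""
        def mean_recovery(sigma):
            accs = []
            for seed in range(10):
                cfg = SimConfig(n_genes=150, sigma=sigma, effect_range=(0.6, 1.0),
                                n_inflammatory=0, n_metabolic=0, bound_size=0,
                                seed=seed)
                bundle, gene_map, truth = simulate_expression(cfg)
                calls = classify(anova_table(bundle))
                gene_calls, _ = collapse(calls, gene_map,
                                         bundle.values.mean(axis=1))
                merged = gene_calls.set_index("gene_id").join(
                    truth, how="inner", lsuffix="_call", rsuffix="_true"
                )
                nonnull = merged[merged["category_true"] != "none"]
                accs.append((nonnull["category_call"] == nonnull["category_true"]).mean())
            return np.mean(accs)

        recoveries = [mean_recovery(s) for s in (0.25, 0.8, 2.5)]
        assert recoveries[0] >= recoveries[1] >= recoveries[2]


class TestSimulatePromoters:
    def test_every_responsive_promoter_scores_at_limit_planting(self):
        from crossfactor.motifs import build_motif_model, motif_presence

        cfg = small_config(p_motif_responsive=1.0, p_motif_background=0.0,
                           promoter_length=300)
        _, _, truth = simulate_expression(cfg)
        promoters, pfms = simulate_promoters(cfg, truth)
        model = build_motif_model(pfms[0], threshold=8.0)
        responsive = truth.index[truth["category"].isin(["A", "C", "D"])]
        presence = motif_presence(promoters.subset(responsive), model)
        # instances are sampled from the PFM; the sharp planted matrix keeps
        # nearly all of them at or above the score cut-off
        assert presence.mean() > 0.9

    def test_decoys_never_planted_and_distinct(self):
        cfg = small_config()
        _, _, truth = simulate_expression(cfg)
        _, pfms = simulate_promoters(cfg, truth)
        assert pfms[0].name == "ELK1_like"
        assert len(pfms) == 1 + cfg.n_decoy_motifs
        assert len({p.name for p in pfms}) == len(pfms)

    def test_motif_longer_than_promoter_rejected(self):
        cfg = small_config(promoter_length=5)
        _, _, truth = simulate_expression(cfg)
        with pytest.raises(ValueError, match="longer"):
            simulate_promoters(cfg, truth)

    def test_deterministic_under_seed(self):
        cfg = small_config(promoter_length=200)
        _, _, t1 = simulate_expression(cfg)
        p1, _ = simulate_promoters(cfg, t1)
        _, _, t2 = simulate_expression(small_config(promoter_length=200))
        p2, _ = simulate_promoters(small_config(promoter_length=200), t2)
        assert p1.sequences == p2.sequences


class TestSimulateBoundList:
    def test_enrichment_toward_responsive_genes(self):
        hits = []
        for seed in range(10):
            cfg = small_config(seed=seed, bound_odds=3.0, bound_size=60)
            _, _, truth = simulate_expression(cfg)
            bound = simulate_bound_list(cfg, truth)
            resp = truth["category"].isin(["A", "C", "D"])
            bound_mask = truth.index.isin(bound)
            frac_bound = resp[bound_mask].mean()
            frac_bg = resp[~bound_mask].mean()
            hits.append(frac_bound > frac_bg)
        assert np.mean(hits) >= 0.95

    def test_size_zero_gives_empty_list(self):
        cfg = small_config(bound_size=0)
        _, _, truth = simulate_expression(cfg)
        assert simulate_bound_list(cfg, truth) == []

    def test_oversized_request_rejected(self):
        cfg = small_config(bound_size=10_000)
        _, _, truth = simulate_expression(cfg)
        with pytest.raises(ValueError, match="exceeds"):
            simulate_bound_list(cfg, truth)


class TestWriteBundle:
    def test_bundle_files_round_trip(self, tmp_path):
        cfg = small_config(promoter_length=200)
        out = write_bundle(cfg, tmp_path / "bundle")
        bundle = read_expression(out / "matrix.tsv", out / "samples.tsv")
        assert len(bundle.sample_ids) == 16
        promoters = read_fasta_promoters(out / "promoters.fasta")
        assert len(promoters) == cfg.n_genes
        pfms = read_jaspar_pfm(out / "motifs.pfm")
        np.testing.assert_array_equal(pfms[0].counts, ELK1_LIKE_PFM.counts)
        sets = read_gmt(out / "genesets.gmt")
        assert sets.n_top_level == 26
        truth = pd.read_csv(out / "truth.tsv", sep="\t")
        assert len(truth) == cfg.n_genes
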