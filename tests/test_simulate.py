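import numpy as np
import pandas as pd
import pytest

from straindiff import atlas as atlas_mod
from straindiff import molevo, simulate
from straindiff.config import AnalysisConfig


class TestProbeExperiment:
    def test_zero_noise_shift_is_exact(self, config):
        table, sheet, truth = simulate.simulate_probe_experiment(
            config, n_genes=1, probes_per_gene=11, sfp_fraction=0.0,
            de_fraction=1.0, de_shift=2.0, noise_sd=0.0)
        a_cols = sheet.arrays_for("A", "t1")
        b_cols = sheet.arrays_for("B", "t1")
        diff = (table.values[b_cols].mean(axis=1)
                - table.values[a_cols].mean(axis=1))
        assert np.allclose(np.abs(diff), 2.0, atol=1e-12)

    def test_same_seed_identical_output(self, config):
        t1, s1, _ = simulate.simulate_probe_experiment(config, n_genes=20)
        t2, s2, _ = simulate.simulate_probe_experiment(config, n_genes=20)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(s1.frame, s2.frame)

    def test_sfp_count_binomial(self, config):
        """Planted SFP count within 3 binomial sd of n*p."""
        table, _, truth = simulate.simulate_probe_experiment(
            config, n_genes=1000, probes_per_gene=10, sfp_fraction=0.2)
        n = 10000
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(len(truth.sfp_probes) - 2000) <= 3 * sd
        planted = {p for p, _ in truth.sfp_probes}
        assert planted <= set(table.values.index)

    def test_probes_minimum_enforced(self, config):
        with pytest.raises(ValueError, match="probes_per_gene"):
            simulate.simulate_probe_experiment(config, probes_per_gene=2)

    def test_truth_covers_emitted_entities(self, config):
        table, sheet, truth = simulate.simulate_probe_experiment(
            config, n_genes=50, de_fraction=0.5)
        genes = set(table.transcripts)
        assert {g for (g, _, _) in truth.de_genes} <= genes
        assert {g for (g, _, _s) in truth.true_expr} <= genes


class TestAtlas:
    def test_no_silent_planted_none_detected(self, config):
        atlases, _ = simulate.simulate_atlas(config, silent_fraction=0.0,
                                             changed_tissue_fraction=0.0)
        assert atlas_mod.detect_silent(atlases["A"], atlases["B"], config) == set()
        assert atlas_mod.detect_silent(atlases["B"], atlases["A"], config) == set()

    def test_planted_silent_recovered_exactly(self, config):
        atlases, truth = simulate.simulate_atlas(config, silent_fraction=0.2)
        got_a = atlas_mod.detect_silent(atlases["A"], atlases["B"], config)
        assert truth.silent_genes["A"] <= got_a

    def test_silent_invariant_holds(self, config):
        atlases, truth = simulate.simulate_atlas(config, silent_fraction=0.2)
        for s, genes in truth.silent_genes.items():
            assert (atlases[s].loc[sorted(genes)].max(axis=1)
                    <= config.expr_threshold).all()

    def test_tau_targets_separate(self, config):
        atlases, truth = simulate.simulate_atlas(
            config, silent_fraction=0.0, changed_tissue_fraction=0.0,
            noise_sd=0.0, n_genes=200)
        taus = atlas_mod.compute_tau_table(atlases["A"], config)["tau"]
        spec = [g for g, k in truth.tau_targets.items() if k == "specific"]
        broad = [g for g, k in truth.tau_targets.items() if k == "broad"]
        assert (taus.loc[spec] >= 0.8).all()
        assert (taus.loc[broad] <= 0.3).all()

    def test_fraction_budget_validated(self, config):
        with pytest.raises(ValueError, match="<= 1"):
            simulate.simulate_atlas(config, silent_fraction=0.7,
                                    changed_tissue_fraction=0.7)

    def test_tissue_sets_differ_across_strains(self, config):
        atlases, _ = simulate.simulate_atlas(
            config, n_tissues={"A": 8, "B": 6}, n_homologous=5)
        shared = set(atlases["A"].columns) & set(atlases["B"].columns)
        assert shared == {f"h{i+1}" for i in range(5)}


class TestOrthologs:
    def test_same_protein_zero_substitutions(self, config):
        rec_a, rec_b, _ = simulate.simulate_ortholog_pairs(
            config, n_pairs=3, class_mix={"same_protein_sequence": 1.0},
            syn_prop=0.0)
        for (g, a), (_, b) in zip(rec_a, rec_b):
            assert a == b
            ka, ks, ratio, _ = molevo.compute_ka_ks(a[3:-3], b[3:-3])
            assert ka == 0.0 and ks == 0.0 and ratio is None

    def test_same_protein_synonymous_only(self, config):
        rec_a, rec_b, _ = simulate.simulate_ortholog_pairs(
            config, n_pairs=5, class_mix={"same_protein_sequence": 1.0})
        ev = molevo.classify_pairs(list(zip(
            [g for g, _ in rec_a], [s for _, s in rec_a],
            [s for _, s in rec_b])), config)
        assert (ev["structural_class"] == "same_protein_sequence").all()
        assert (ev["ka"] == 0.0).all()

    def test_frameshift_classified_different_length(self, config):
        rec_a, rec_b, _ = simulate.simulate_ortholog_pairs(
            config, n_pairs=6, class_mix={"different_protein_length": 1.0})
        ev = molevo.classify_pairs(list(zip(
            [g for g, _ in rec_a], [s for _, s in rec_a],
            [s for _, s in rec_b])), config)
        assert (ev["structural_class"] == "different_protein_length").all()

    def test_all_planted_classes_recovered(self, config):
        rec_a, rec_b, truth = simulate.simulate_ortholog_pairs(
            config, n_pairs=60)
        ev = molevo.classify_pairs(list(zip(
            [g for g, _ in rec_a], [s for _, s in rec_a],
            [s for _, s in rec_b])), config).set_index("gene_id")
        agree = np.mean([ev.at[g, "structural_class"] == c
                         for g, c in truth.ortholog_classes.items()])
        assert agree == 1.0

    def test_kaks_target_recovered(self, config):
        """500-codon pairs tuned to 1.5: mean NG86 estimate within 0.3."""
        estimates = []
        for seed in range(25):
            cfg = AnalysisConfig(seed=seed)
            rec_a, rec_b, _ = simulate.simulate_ortholog_pairs(
                cfg, n_pairs=4, class_mix={"amino_acid_substitution": 1.0},
                target_kaks=(1.5,), cds_len_codons=500)
            for (_, a), (_, b) in zip(rec_a, rec_b):
                _, _, ratio, _ = molevo.compute_ka_ks(a[3:-3], b[3:-3])
                estimates.append(ratio)
        assert abs(np.mean(estimates) - 1.5) <= 0.3

    def test_short_cds_rejected(self, config):
        with pytest.raises(ValueError, match="100"):
            simulate.simulate_ortholog_pairs(config, cds_len_codons=50)

    def test_nonpositive_target_rejected(self, config):
        with pytest.raises(ValueError, match="positive"):
            simulate.simulate_ortholog_pairs(config, target_kaks=(0.0,))


class TestGenomeGoEqtl:
    def test_cluster_window_outside_chrom_rejected(self, config):
        with pytest.raises(ValueError, match="outside"):
            simulate.simulate_genome(
                config, cluster_spec=[("chr1", 0, 99_000_000, 0.5)])

    def test_flags_subset_of_highly_expressed(self, config):
        _, he, fl, _ = simulate.simulate_genome(config, n_genes=500)
        assert fl <= he

    def test_planted_enrichment_detected(self, config):
        """Odds-ratio-10 term is significant in >= 90% of seeds."""
        from straindiff.stats import fisher_enrichment
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = AnalysisConfig(seed=seed)
            ann, flagged, background, truth = simulate.simulate_go(
                cfg, n_genes=2000, n_terms=20, term_size=(40, 80),
                enriched=[("TERM:0000", 10.0)], n_flagged=50)
            results = {r.term: r for r in fisher_enrichment(
                flagged, background, ann, cfg)}
            r = results.get("TERM:0000")
            if r is not None and r.p < 0.01:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_eqtl_groups_by_construction(self, config):
        from straindiff.stats import summarize_eqtl
        records, loci, truth = simulate.simulate_eqtl_records(config,
                                                              n_genes=100)
        summary, _ = summarize_eqtl(records, loci, None, config)
        summary = summary.set_index("gene_id")
        for gene, (cis, fractions) in truth.eqtl_truth.items():
            row = summary.loc[gene]
            if cis:
                assert row["has_cis"] and row["sum_explained"] > 80
                assert row["group"] == "well_explained"
            else:
                assert not row["has_cis"] and row["sum_explained"] < 40
                assert row["group"] == "unexplained"


class TestDataset:
    def test_write_dataset_deterministic(self, config, tmp_path):
        import filecmp
        simulate.write_dataset(config, tmp_path / "d1", n_genes=60)
        simulate.write_dataset(config, tmp_path / "d2", n_genes=60)
        for f in sorted((tmp_path / "d1").glob("*.tsv")):
            assert filecmp.cmp(f, tmp_path / "d2" / f.name, shallow=False), f.name
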