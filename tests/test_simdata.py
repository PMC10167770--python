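import numpy as np
import pandas as pd
import pytest

from hybridgp import (
    SimConfig,
    hybrid_means,
    make_mating_design,
    simulate_effects,
    simulate_parents,
    simulate_phenotypes,
    simulate_study,
    subpopulation_labels,
)


class TestSimulateParents:
    def test_degenerate_frequency_gives_all_alt_homozygotes(self):
        config = SimConfig(allele_freq_range=(1.0, 1.0), n_markers=50,
                           n_qtl=10)
        geno = simulate_parents(config)
        assert (geno.codes == 1.0).all()

    def test_lines_are_fully_homozygous(self):
        geno = simulate_parents(SimConfig(n_markers=100, n_qtl=20, seed=2))
        assert set(np.unique(geno.codes)) <= {-1.0, 1.0}

    def test_same_seed_reproduces_identical_matrix(self):
        a = simulate_parents(SimConfig(n_markers=100, n_qtl=20, seed=7))
        b = simulate_parents(SimConfig(n_markers=100, n_qtl=20, seed=7))
        np.testing.assert_array_equal(a.codes, b.codes)
        assert a.lines == b.lines and a.markers == b.markers

    def test_markers_assigned_contiguously_to_chromosomes(self):
        geno = simulate_parents(
            SimConfig(n_markers=95, n_qtl=10, n_chromosomes=10)
        )
        chrom = geno.marker_map["chrom"].to_numpy()
        changes = sum(chrom[i] != chrom[i + 1] for i in range(len(chrom) - 1))
        assert changes == 9  # each chromosome forms one contiguous block

    def test_diverged_subpopulations_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        config = SimConfig(
            n_pollinators=47, n_testers=3, group_sizes=(5, 5, 5),
            n_shared_pollinators=2, n_markers=500, n_subpopulations=2,
            allele_freq_range=(0.05, 0.95), seed=3,
        )
        geno = simulate_parents(config)
        labels = subpopulation_labels(config)
        centered = geno.codes - geno.codes.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)  # direct oracle
        pc1 = (u * s)[:, :1]
        assert silhouette_score(pc1, labels) > 0

    def test_too_many_subpopulations_rejected(self):
        with pytest.raises(ValueError, match="subpopulations"):
            simulate_parents(
                SimConfig(n_pollinators=2, n_testers=1, group_sizes=(1,),
                          n_shared_pollinators=1, n_subpopulations=5)
            )


class TestMatingDesign:
    def test_reference_design_has_204_hybrids(self):
        design = make_mating_design(SimConfig.reference_design())
        assert design.n_hybrids == 204
        sizes = design.table.groupby("group")["hybrid"].count()
        assert sorted(sizes) == [59, 68, 77]

    def test_reference_design_shares_44_pollinators(self):
        design = make_mating_design(SimConfig.reference_design())
        per_male = design.table.groupby("male")["female"].nunique()
        assert (per_male == 3).sum() == 44
        assert design.table["male"].nunique() == 99  # whole panel used

    def test_disjoint_groups_are_additive(self):
        config = SimConfig(
            n_pollinators=5, n_testers=2, group_sizes=(2, 3),
            n_shared_pollinators=0, n_markers=20, n_qtl=5,
            n_subpopulations=1,
        )
        design = make_mating_design(config)
        assert design.n_hybrids == 5
        per_male = design.table.groupby("male")["female"].nunique()
        assert (per_male == 1).all()

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValueError, match="group size"):
            SimConfig(n_pollinators=5, n_testers=2, group_sizes=(2, 3),
                      n_shared_pollinators=3)


class TestSimulateEffects:
    def _setup(self, **overrides):
        params = dict(n_markers=200, n_qtl=40, seed=19)
        params.update(overrides)
        config = SimConfig(**params)
        geno = simulate_parents(config)
        design = make_mating_design(config)
        return config, geno, design

    def test_zero_dominance_target_gives_zero_effects(self):
        config, geno, design = self._setup(var_dominance=0.0)
        values = simulate_effects(config, geno, design)
        assert (values.marker_effects["d"] == 0).all()
        assert (values.dominance_value == 0).all()

    def test_only_qtl_markers_carry_effects(self):
        config, geno, design = self._setup()
        values = simulate_effects(config, geno, design)
        nonzero = values.marker_effects.index[values.marker_effects["a"] != 0]
        assert set(nonzero) <= set(values.qtl)
        assert len(values.qtl) == config.n_qtl

    def test_all_marker_qtl_hits_target_variance(self):
        config, geno, design = self._setup(n_qtl=200)
        values = simulate_effects(config, geno, design)
        assert (values.marker_effects["a"] != 0).all()
        realized = float(np.var(values.additive_value, ddof=1))
        assert realized == pytest.approx(config.var_additive, rel=1e-10)
        realized_d = float(np.var(values.dominance_value, ddof=1))
        assert realized_d == pytest.approx(config.var_dominance, rel=1e-10)

    def test_single_qtl_additive_values_take_three_levels(self):
        config, geno, design = self._setup(n_qtl=1, var_dominance=0.0)
        values = simulate_effects(config, geno, design)
        levels = np.unique(np.round(values.additive_value, 9))
        assert len(levels) <= 3


class TestSimulatePhenotypes:
    def test_noise_free_limit_reproduces_genetic_values(self):
        config = SimConfig(
            n_markers=100, n_qtl=20, var_gxe=0.0, var_residual=0.0,
            env_effect_sd=0.0, rep_effect_sd=0.0, mu=7.0, seed=23,
        )
        study = simulate_study(config)
        g = study.values.value_series()
        merged = study.phenotypes.assign(
            expected=lambda t: config.mu + g.reindex(t["hybrid"]).to_numpy()
        )
        np.testing.assert_allclose(merged["value"], merged["expected"],
                                   atol=1e-12)

    def test_record_cardinality(self):
        config = SimConfig(
            n_pollinators=10, n_testers=2, group_sizes=(5, 5),
            n_shared_pollinators=0, n_markers=50, n_qtl=10,
            n_environments=2, n_replicates=3, n_subpopulations=2,
        )
        study = simulate_study(config)
        assert len(study.phenotypes) == 10 * 2 * 3

    def test_table_is_balanced(self, desk_study):
        counts = desk_study.phenotypes.groupby(
            ["hybrid", "environment", "replicate"]
        )["value"].count()
        assert (counts == 1).all()
        n_h = desk_study.design.n_hybrids
        cfg = desk_study.config
        assert len(counts) == n_h * cfg.n_environments * cfg.n_replicates

    def test_missing_hybrid_value_rejected(self):
        config = SimConfig(n_markers=50, n_qtl=10, seed=1)
        geno = simulate_parents(config)
        design = make_mating_design(config)
        values = simulate_effects(config, geno, design)
        truncated = design.table.iloc[: design.n_hybrids - 1]
        values_short = type(values)(
            hybrids=values.hybrids[:-1],
            additive_value=values.additive_value[:-1],
            dominance_value=values.dominance_value[:-1],
            marker_effects=values.marker_effects,
            qtl=values.qtl,
        )
        with pytest.raises(ValueError, match="no genetic value"):
            simulate_phenotypes(design, values_short, config)


class TestReproducibilityAndHeritability:
    def test_full_study_is_bit_reproducible(self):
        a = simulate_study(SimConfig(n_markers=100, n_qtl=20, seed=77))
        b = simulate_study(SimConfig(n_markers=100, n_qtl=20, seed=77))
        np.testing.assert_array_equal(a.genotypes.codes, b.genotypes.codes)
        pd.testing.assert_frame_equal(a.design.table, b.design.table)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_realized_heritability_matches_formula_at_large_n(self):
        # ~500 hybrids: entry-mean variance should match
        # var_g + var_gxe/e + var_e/(e r) closely
        config = SimConfig(
            n_pollinators=170, n_testers=3, group_sizes=(167, 167, 166),
            n_shared_pollinators=150, n_markers=200, n_qtl=50,
            var_additive=10.0, var_dominance=0.0, var_gxe=4.0,
            var_residual=7.0, seed=29,
        )
        study = simulate_study(config)
        e, r = config.n_environments, config.n_replicates
        expected_h = 10.0 / (10.0 + 4.0 / e + 7.0 / (e * r))
        means = hybrid_means(study.phenotypes, "simtrait")
        genetic_var = float(np.var(study.values.total, ddof=1))
        realized_h = genetic_var / float(np.var(means, ddof=1))
        assert realized_h == pytest.approx(expected_h, abs=0.05)
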