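import itertools

import numpy as np
import pandas as pd
import pytest

from hybridgp import (
    SimConfig,
    VarianceComponents,
    broad_sense_heritability,
    estimate_components,
    hybrid_means,
    simulate_study,
)


def long_table(values):
    """Build a long-format table from values[hybrid][environment][replicate]."""
    rows = []
    for i, envs in values.items():
        for j, reps in envs.items():
            for k, v in reps.items():
                rows.append(
                    {"hybrid": i, "environment": j, "replicate": k,
                     "trait": "t", "value": float(v)}
                )
    return pd.DataFrame(rows)


def anova_oracle(values):
    """Hand expected-mean-squares solution computed with explicit loops."""
    hybrids = sorted(values)
    envs = sorted(values[hybrids[0]])
    reps = sorted(values[hybrids[0]][envs[0]])
    g, e, r = len(hybrids), len(envs), len(reps)
    y = {(i, j, k): values[i][j][k] for i in hybrids for j in envs for k in reps}
    grand = sum(y.values()) / len(y)
    hyb_mean = {i: sum(y[i, j, k] for j in envs for k in reps) / (e * r)
                for i in hybrids}
    env_mean = {j: sum(y[i, j, k] for i in hybrids for k in reps) / (g * r)
                for j in envs}
    cell_mean = {(i, j): sum(y[i, j, k] for k in reps) / r
                 for i in hybrids for j in envs}
    rep_mean = {(j, k): sum(y[i, j, k] for i in hybrids) / g
                for j in envs for k in reps}
    ms_g = e * r * sum((hyb_mean[i] - grand) ** 2 for i in hybrids) / (g - 1)
    ms_ge = r * sum(
        (cell_mean[i, j] - hyb_mean[i] - env_mean[j] + grand) ** 2
        for i in hybrids for j in envs
    ) / ((g - 1) * (e - 1))
    ms_r = sum(
        (y[i, j, k] - cell_mean[i, j] - rep_mean[j, k] + env_mean[j]) ** 2
        for i in hybrids for j in envs for k in reps
    ) / (e * (g - 1) * (r - 1))
    return (
        max((ms_g - ms_ge) / (e * r), 0.0),
        max((ms_ge - ms_r) / r, 0.0),
        max(ms_r, 0.0),
    )


class TestEstimateComponents:
    def test_noise_free_data_gives_zero_gxe_and_residual(self):
        config = SimConfig(
            n_markers=200, n_qtl=40, var_gxe=0.0, var_residual=0.0,
            env_effect_sd=0.0, rep_effect_sd=0.0, seed=5,
        )
        study = simulate_study(config)
        vc = estimate_components(study.phenotypes, "simtrait")
        assert vc.var_ge <= 1e-8
        assert vc.var_e <= 1e-8
        # with no noise the genetic component is exactly the variance of the
        # true genetic values among hybrids
        assert vc.var_g == pytest.approx(
            float(np.var(study.values.total, ddof=1)), abs=1e-8
        )

    def test_tiny_balanced_table_matches_hand_anova(self):
        rng = np.random.default_rng(9)
        values = {
            i: {j: {k: rng.normal() for k in ("R1", "R2")}
                for j in ("E1", "E2")}
            for i in ("H1", "H2", "H3")
        }
        vc = estimate_components(long_table(values), "t")
        exp_g, exp_ge, exp_e = anova_oracle(values)
        assert vc.var_g == pytest.approx(exp_g, abs=1e-10)
        assert vc.var_ge == pytest.approx(exp_ge, abs=1e-10)
        assert vc.var_e == pytest.approx(exp_e, abs=1e-10)
        assert (vc.n_envs, vc.n_reps) == (2, 2)

    def test_unbalanced_table_errors_on_moment_path(self):
        rng = np.random.default_rng(1)
        values = {
            i: {j: {k: rng.normal() for k in ("R1", "R2")}
                for j in ("E1", "E2")}
            for i in ("H1", "H2", "H3")
        }
        table = long_table(values).iloc[:-1]  # drop one observation
        with pytest.raises(ValueError, match="reml"):
            estimate_components(table, "t", method="moments")

    def test_reml_agrees_with_moments_on_balanced_data(self):
        study = simulate_study(
            SimConfig(n_markers=200, n_qtl=40, var_gxe=0.4,
                      var_residual=0.8, seed=13)
        )
        mom = estimate_components(study.phenotypes, "simtrait",
                                  method="moments")
        reml = estimate_components(study.phenotypes, "simtrait",
                                   method="reml")
        assert reml.var_g == pytest.approx(mom.var_g, rel=0.15, abs=0.05)
        assert reml.var_e == pytest.approx(mom.var_e, rel=0.15, abs=0.05)

    def test_reml_handles_unbalanced_data(self):
        study = simulate_study(
            SimConfig(n_markers=150, n_qtl=30, seed=21)
        )
        table = study.phenotypes.sample(frac=0.9, random_state=0)
        vc = estimate_components(table, "simtrait")
        assert vc.method == "reml"
        assert vc.var_g > 0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        values = {
            i: {j: {k: rng.normal() for k in ("R1", "R2", "R3")}
                for j in ("E1", "E2")}
            for i in ("H1", "H2", "H3", "H4")
        }
        table = long_table(values)
        scaled = table.assign(value=table["value"] * 3.0)
        vc1 = estimate_components(table, "t")
        vc2 = estimate_components(scaled, "t")
        assert vc2.var_g == pytest.approx(9 * vc1.var_g, abs=1e-9)
        assert vc2.var_ge == pytest.approx(9 * vc1.var_ge, abs=1e-9)
        assert vc2.var_e == pytest.approx(9 * vc1.var_e, abs=1e-9)


class TestHeritability:
    @pytest.mark.parametrize(
        "vg, vge, ve, e, r, expected",
        [
            (5.0, 0.0, 0.0, 4, 3, 1.0),
            (0.0, 0.0, 2.0, 4, 3, 0.0),
            (10.2, 3.93, 6.8, 4, 3, 10.2 / (10.2 + 3.93 / 4 + 6.8 / 12)),
        ],
    )
    def test_entry_mean_formula(self, vg, vge, ve, e, r, expected):
        vc = VarianceComponents(var_g=vg, var_ge=vge, var_e=ve,
                                n_reps=r, n_envs=e)
        assert broad_sense_heritability(vc) == pytest.approx(expected, abs=1e-6)

    def test_all_zero_variances_error(self):
        vc = VarianceComponents(var_g=0, var_ge=0, var_e=0, n_reps=3, n_envs=4)
        with pytest.raises(ValueError, match="undefined"):
            broad_sense_heritability(vc)

    def test_monotone_in_genetic_variance_and_noise(self):
        grid = [0.5, 1.0, 2.0, 4.0]
        for vge, ve in itertools.product(grid, grid):
            hs = [
                broad_sense_heritability(
                    VarianceComponents(var_g=vg, var_ge=vge, var_e=ve,
                                       n_reps=3, n_envs=4)
                )
                for vg in grid
            ]
            assert hs == sorted(hs)
        for vg, ve in itertools.product(grid, grid):
            hs = [
                broad_sense_heritability(
                    VarianceComponents(var_g=vg, var_ge=vge, var_e=ve,
                                       n_reps=3, n_envs=4)
                )
                for vge in grid
            ]
            assert hs == sorted(hs, reverse=True)


class TestHybridMeans:
    def test_means_equal_brute_force_group_means(self):
        rng = np.random.default_rng(17)
        values = {
            i: {j: {k: rng.normal() for k in ("R1", "R2")}
                for j in ("E1", "E2", "E3")}
            for i in ("H1", "H2")
        }
        table = long_table(values)
        means = hybrid_means(table, "t")
        for i in ("H1", "H2"):
            manual = np.mean(
                [values[i][j][k] for j in values[i] for k in values[i][j]]
            )
            assert means.loc[i] == pytest.approx(manual)

    def test_simple_values(self):
        table = pd.DataFrame(
            {
                "hybrid": ["H1"] * 3,
                "environment": ["E1", "E1", "E2"],
                "replicate": ["R1", "R2", "R1"],
                "trait": ["t"] * 3,
                "value": [2.0, 4.0, 6.0],
            }
        )
        assert hybrid_means(table, "t").loc["H1"] == 4.0

    def test_missing_trait_errors(self):
        table = pd.DataFrame(
            {"hybrid": ["H1"], "environment": ["E1"], "replicate": ["R1"],
             "trait": ["t"], "value": [1.0]}
        )
        with pytest.raises(KeyError):
            hybrid_means(table, "other")
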