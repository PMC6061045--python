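"""Tests for the synthetic cohort generators and their planted ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthoprio import (
    GroundTruth,
    InvalidDesignError,
    InvalidParameterError,
    SimulationConfig,
    abeta_correlation,
    make_ortholog_table,
    simulate_case_control_study,
    simulate_genotype_panel,
    simulate_strain_expression,
    simulate_tg_cohort,
    snp_association,
    strain_differential_test,
)
from orthoprio.synthetic import latent_rho_for_target
from scipy.stats import norm


NULL_KW = dict(strain_shift_sd=0.0, abeta_corr_effects=(0.0,), causal_snp_or=1.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_causal": 10, "n_genes": 5},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"within_block_rho": 1.0},
            {"within_block_rho": -0.1},
            {"case_fraction": 0.0},
            {"abeta_corr_effects": (1.0,)},
            {"n_snps": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(**kw)


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_config):
        outs = []
        for _ in range(2):
            e1, t1 = simulate_strain_expression(small_config)
            e2, ab = simulate_tg_cohort(small_config, t1)
            panel = simulate_genotype_panel(small_config)
            ph = simulate_case_control_study(panel, small_config, t1)
            outs.append((e1.values, e2.values, ab, panel.dosages, ph))
        assert outs[0][0].equals(outs[1][0])
        assert outs[0][1].equals(outs[1][1])
        assert (outs[0][2] == outs[1][2]).all()
        assert np.array_equal(outs[0][3], outs[1][3])
        assert outs[0][4].equals(outs[1][4])

    def test_different_seed_differs(self, small_config):
        a, _ = simulate_strain_expression(small_config)
        b, _ = simulate_strain_expression(small_config.with_seed(999))
        assert not a.values.equals(b.values)


class TestStrainExpression:
    def test_null_design_selects_alpha_fraction(self):
        """With zero planted shift the pooled screen selects ~alpha of genes."""
        cfg = SimulationConfig(seed=41, n_genes=4_000, **NULL_KW)
        expr, _ = simulate_strain_expression(cfg)
        diff = strain_differential_test(expr, "DBA", ["B6", "SJL"],
                                        mode="pooled", alpha=0.05)
        frac = diff["selected"].mean()
        se = np.sqrt(0.05 * 0.95 / 4_000)
        assert abs(frac - 0.05) < 3 * se
        # uniformity of the full null p stream (>= 1,000 draws)
        assert stats.kstest(diff["p_summary"], "uniform").pvalue > 0.01
        # mode=either takes a minimum of two p-values, so it selects >= alpha
        diff_e = strain_differential_test(expr, "DBA", ["B6", "SJL"],
                                          mode="either", alpha=0.05)
        assert diff_e["selected"].mean() >= 0.05

    def test_nonplanted_gene_means_equal_across_strains(self):
        # planted shift is strain_shift_sd * noise_sd = 0.06; with noise
        # 0.01 the null between-strain spread stays well below it
        cfg = SimulationConfig(seed=42, n_genes=10, n_causal=1, noise_sd=0.01)
        expr, truth = simulate_strain_expression(cfg)
        gmeans = expr.values.T.groupby(expr.sample_labels).mean().T
        planted = sorted(truth.causal_gene_indices)
        spread = gmeans.max(axis=1) - gmeans.min(axis=1)
        null_rows = [i for i in range(10) if i not in planted]
        assert spread.iloc[null_rows].max() < 0.04
        assert spread.iloc[planted].min() > 0.045

    def test_recovery_rate_matches_noncentral_t_oracle(self):
        """Monte-Carlo recovery of a 3-noise-SD shift (4 samples/strain)
        agrees with the analytic noncentral-t power for the pooled screen."""
        crit = stats.t.isf(0.0005, 10)
        ncp = 3.0 / np.sqrt(1 / 4 + 1 / 8)
        power = stats.nct.sf(crit, 10, ncp) + stats.nct.cdf(-crit, 10, ncp)
        hits, n_rep = 0, 200
        for s in range(n_rep):
            cfg = SimulationConfig(seed=50_000 + s, n_genes=2, n_causal=1,
                                   strain_shift_sd=3.0)
            expr, truth = simulate_strain_expression(cfg)
            diff = strain_differential_test(expr, "DBA", ["B6", "SJL"], mode="pooled")
            hits += bool(diff["selected"].iloc[list(truth.causal_gene_indices)].all())
        rate = hits / n_rep
        se = np.sqrt(power * (1 - power) / n_rep)
        assert abs(rate - power) < 4 * se

    def test_small_strain_raises(self):
        cfg = SimulationConfig(seed=1, strain_sizes={"DBA": 1, "B6": 4, "SJL": 4})
        with pytest.raises(InvalidDesignError):
            simulate_strain_expression(cfg)


class TestTgCohort:
    def test_null_gene_exceedance_at_5pct(self):
        """|r| > 0.374 (the two-tailed 5% point of the null correlation at
        n = 28, t with 26 df) for ~5% of unplanted genes."""
        t_crit = stats.t.isf(0.025, 26)
        r_crit = t_crit / np.sqrt(t_crit**2 + 26)
        assert r_crit == pytest.approx(0.374, abs=0.001)
        cfg = SimulationConfig(seed=43, n_genes=4_000, **NULL_KW)
        _, truth = simulate_strain_expression(cfg)
        expr, ab = simulate_tg_cohort(cfg, truth)
        corr = abeta_correlation(expr, ab)
        frac = (corr["r"].abs() > r_crit).mean()
        se = np.sqrt(0.05 * 0.95 / 4_000)
        assert abs(frac - 0.05) < 4 * se
        assert stats.kstest(corr["p"], "uniform").pvalue > 0.01

    def test_mean_sample_r_near_target(self):
        """Mean sample correlation within +-0.1 of the -0.7 target, 500 reps."""
        vals = []
        for s in range(500):
            cfg = SimulationConfig(seed=60_000 + s, n_genes=5, n_causal=1,
                                   abeta_corr_effects=(-0.7,))
            _, truth = simulate_strain_expression(cfg)
            expr, ab = simulate_tg_cohort(cfg, truth)
            gi = truth.causal_gene_indices[0]
            x = expr.values.iloc[gi].to_numpy()
            vals.append(np.corrcoef(x, ab.to_numpy())[0, 1])
        assert abs(np.mean(vals) - (-0.7)) < 0.1

    def test_degenerate_cohort_and_effect_errors(self):
        cfg = SimulationConfig(seed=1, n_tg_animals=2)
        _, truth = simulate_strain_expression(cfg)
        with pytest.raises(InvalidDesignError):
            simulate_tg_cohort(cfg, truth)
        with pytest.raises(InvalidParameterError):
            SimulationConfig(abeta_corr_effects=(-1.2,))


class TestGenotypePanel:
    def test_zero_rho_gives_independent_snps(self):
        cfg = SimulationConfig(seed=44, n_snps=50, n_individuals=2_000,
                               within_block_rho=0.0)
        panel = simulate_genotype_panel(cfg)
        R = np.corrcoef(panel.dosages.T)
        off = np.abs(R[np.triu_indices(50, 1)])
        assert off.mean() < 0.05

    def test_high_rho_gives_high_adjacent_r2(self):
        cfg = SimulationConfig(seed=45, n_snps=400, n_individuals=2_000,
                               within_block_rho=0.95, maf_range=(0.3, 0.3))
        panel = simulate_genotype_panel(cfg)
        D, blk = panel.dosages, panel.snp_map["block"].to_numpy()
        r2 = [
            np.corrcoef(D[:, j], D[:, j - 1])[0, 1] ** 2
            for j in range(1, 400) if blk[j] == blk[j - 1]
        ]
        assert np.median(r2) > 0.8

    def test_sample_maf_close_to_target(self):
        cfg = SimulationConfig(seed=46, n_snps=300, n_individuals=2_000)
        panel = simulate_genotype_panel(cfg)
        maf_hat = panel.dosages.mean(axis=0) / 2
        assert np.abs(maf_hat - panel.snp_map["maf"]).max() < 0.03

    def test_tetrachoric_inversion_identity(self):
        """Latent rho from the inversion reproduces the requested allelic
        correlation through the forward orthant-probability formula."""
        from orthoprio.synthetic import _allelic_corr

        q1, q2 = norm.ppf(0.2), norm.ppf(0.4)
        rho_l = latent_rho_for_target(np.array([0.6]), q1, q2)
        assert _allelic_corr(q1, q2, rho_l)[0] == pytest.approx(0.6, abs=1e-6)


class TestCaseControl:
    def test_realized_case_fraction_calibrated(self, small_config):
        _, truth = simulate_strain_expression(small_config)
        cfg = SimulationConfig(seed=123, n_genes=40, n_causal=3, n_snps=200,
                               n_individuals=2_000)
        panel = simulate_genotype_panel(cfg)
        pheno = simulate_case_control_study(panel, cfg, truth)
        assert 0.48 <= pheno["status"].mean() <= 0.52
        assert set(pheno["sex"].unique()) <= {0, 1}
        assert pheno["age"].std() > 0

    def test_causal_snp_power_oracle(self):
        """OR 1.5, MAF 0.3, 1,000/1,000: causal-SNP median p < 1e-4 over
        100 replicates."""
        pvals = []
        for s in range(100):
            cfg = SimulationConfig(seed=70_000 + s, n_genes=1, n_causal=1,
                                   n_snps=5, n_individuals=2_000,
                                   maf_range=(0.3, 0.3), causal_snp_or=1.5)
            truth = GroundTruth({"Gene0000"}, {"Gene0000": "Up"}, set(), (0,))
            panel = simulate_genotype_panel(cfg)
            pheno = simulate_case_control_study(panel, cfg, truth)
            snp = sorted(truth.causal_snp_ids)[0]
            res = snp_association(panel, pheno).set_index("snp_id")
            pvals.append(res.loc[snp, "p"])
        assert np.median(pvals) < 1e-4

    def test_causal_snps_filled_from_gene_blocks(self, small_config):
        _, truth = simulate_strain_expression(small_config)
        panel = simulate_genotype_panel(small_config)
        assert not truth.causal_snp_ids
        simulate_case_control_study(panel, small_config, truth)
        assert len(truth.causal_snp_ids) == small_config.n_causal
        blocks = panel.snp_map.set_index("snp_id").loc[sorted(truth.causal_snp_ids), "block"]
        assert set(blocks) == set(truth.causal_gene_indices)

    def test_empty_panel_raises(self, small_config):
        panel = simulate_genotype_panel(small_config)
        empty = pd.DataFrame(columns=panel.snp_map.columns)
        with pytest.raises(InvalidParameterError):
            simulate_case_control_study(
                type(panel)(np.empty((0, 0)), empty, []), small_config,
                GroundTruth(set(), {}, set(), ()),
            )


class TestOrthologTable:
    def test_bijective_without_scrambling(self):
        t = make_ortholog_table(["GENEA", "GENEB"], ["Genea", "Geneb"])
        assert len(t) == 2 and not t["is_multi"].any()

    def test_duplicate_mouse_symbol_flags_family(self):
        t = make_ortholog_table(["GA", "GB"], ["Shared", "Shared"])
        assert t["is_multi"].all()

    def test_duplicate_human_symbol_raises(self):
        with pytest.raises(InvalidParameterError):
            make_ortholog_table(["GA", "GA"], ["Ma", "Mb"])

    def test_scramble_injects_flagged_rows(self):
        t = make_ortholog_table([f"G{i}" for i in range(20)],
                                [f"g{i}" for i in range(20)],
                                scramble_fraction=0.2, seed=7)
        assert len(t) > 20 and t["is_multi"].sum() >= 4

    def test_tsv_round_trip(self, tmp_path):
        t = make_ortholog_table(["GENEA", "GENEB"], ["Genea", "Geneb"])
        path = tmp_path / "orth.tsv"
        t.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(t, back)
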