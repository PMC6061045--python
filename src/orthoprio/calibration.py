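"""Calibration experiments: null behavior of each statistic in the pipeline.

These drivers quantify, by simulation, the operating characteristics the
pipeline's statistics are expected to have under the null: type-I error of
the extended-Simes gene test under blocked LD, genomic inflation and
p-value uniformity of the per-SNP association stream, the (deliberately
anti-conservative) null rejection rate of the inverse-normal combination, and
end-to-end recovery of planted genes at the study's default effect sizes.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, norm

from .genebased import gates_p_batch
from .gwas import genomic_inflation, snp_association
from .integrate import combine_p
from .pipeline import planted_rank_fraction, run_study
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    simulate_case_control_study,
    simulate_genotype_panel,
)


def gates_null_calibration(
    seed: int = 0,
    n_snps: int = 10,
    adjacent_r: float = 0.8,
    n_individuals: int = 1_000,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the gene-based test on one null gene.

    Simulates a single LD block (adjacent-SNP allelic correlation
    ``adjacent_r``), then permutes a balanced case/control label
    ``n_permutations`` times.  Per permutation the SNP p-values come from
    the 1-df trend (score) test z = r*sqrt(n), and the extended-Simes gene
    p is computed against the LD matrix estimated from the genotypes.
    Returns the rejection rate at ``alpha`` (and the gene p quantiles).
    """
    cfg = SimulationConfig(
        seed=seed, n_genes=1, n_causal=1, n_snps=n_snps, block_size=n_snps,
        n_individuals=n_individuals, within_block_rho=adjacent_r,
        maf_range=(0.1, 0.5), causal_snp_or=1.0,
    )
    panel = simulate_genotype_panel(cfg)
    G = panel.dosages
    n = G.shape[0]
    R = np.corrcoef(G.T)
    Gn = (G - G.mean(0)) / G.std(0)

    status = np.zeros(n)
    status[: n // 2] = 1.0
    rng = np.random.default_rng([seed, 101])
    S = np.array([rng.permutation(status) for _ in range(n_permutations)])
    Sn = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    z = (Sn @ Gn / n) * np.sqrt(n)
    P = np.clip(2 * norm.sf(np.abs(z)), 5e-324, 1.0)
    gene_p = gates_p_batch(P, R)
    return {
        "rejection_rate": float((gene_p < alpha).mean()),
        "alpha": alpha,
        "n_permutations": n_permutations,
        "median_gene_p": float(np.median(gene_p)),
    }


def gwas_null_calibration(
    seed: int = 0, n_snps: int = 50_000, n_individuals: int = 1_000
) -> dict:
    """Genomic inflation and KS uniformity of the null association stream.

    SNPs are simulated without LD so the median-lambda and KS sampling
    distributions are the independent-test ones; no causal effect is
    planted (per-allele OR 1).
    """
    cfg = SimulationConfig(
        seed=seed, n_genes=1, n_causal=1, n_snps=n_snps, block_size=5,
        n_individuals=n_individuals, within_block_rho=0.0, causal_snp_or=1.0,
    )
    panel = simulate_genotype_panel(cfg)
    truth = GroundTruth(set(), {}, set(), ())
    pheno = simulate_case_control_study(panel, cfg, truth)
    assoc = snp_association(panel, pheno)
    p = assoc["p"].dropna().to_numpy()
    ks = kstest(p, "uniform")
    return {
        "lambda": genomic_inflation(p),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_snps_tested": int(p.size),
    }


def stouffer_null_calibration(
    seed: int = 0, n_draws: int = 100_000, alpha: float = 0.05
) -> dict:
    """Null rejection rate of the two-stream inverse-normal combination.

    With independent uniform inputs the combined two-tailed p is *not*
    uniform (the statistic sums two folded-normal z-scores): the rate at
    0.05 is ~0.096, i.e. the recipe over-rejects under the null.
    Reported, not corrected, for fidelity to the combination rule.
    """
    rng = np.random.default_rng([seed, 102])
    u = rng.uniform(size=(n_draws, 2))
    _, pc = combine_p(u[:, 0], u[:, 1])
    return {
        "rejection_rate": float((pc < alpha).mean()),
        "alpha": alpha,
        "n_draws": n_draws,
    }


def planted_recovery_experiment(
    seed: int = 0,
    n_replicates: int = 50,
    rank_fraction: float = 0.95,
    config: SimulationConfig | None = None,
) -> dict:
    """End-to-end recovery of planted genes over seeded study replicates.

    Each replicate simulates a full study at the default conditions
    (200 genes, 3 planted with |r| = 0.7 amyloid correlation and a causal
    SNP at OR 1.5, 1,000/1,000 case/control) and checks whether every
    planted gene attains a smaller combined p than ``rank_fraction`` of
    the null genes.  Returns the success rate across replicates.
    """
    base = config if config is not None else SimulationConfig()
    fractions = []
    for i in range(n_replicates):
        res = run_study(base.with_seed(seed + 7919 * i))
        fractions.append(planted_rank_fraction(res))
    fr = np.asarray(fractions)
    return {
        "success_rate": float((fr >= rank_fraction).mean()),
        "mean_rank_fraction": float(fr.mean()),
        "n_replicates": n_replicates,
        "rank_fraction_required": rank_fraction,
    }
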