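"""End-to-end study driver on synthetic cohorts.

Runs the full prioritization once for a :class:`SimulationConfig`:
strain screen -> amyloid correlation -> per-SNP GWAS -> gene-based
extended-Simes statistics -> ortholog join and inverse-normal combination.
Used by the recovery tests and the acceptance script; real-data analyses
call the stage functions directly on tables read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import genebased, gwas, integrate, mouse, synthetic


@dataclass
class StudyResult:
    """Everything one synthetic study produced, stage by stage."""

    truth: synthetic.GroundTruth
    differential: pd.DataFrame
    candidates: mouse.CandidateSet
    fdr_at_alpha: float
    correlation: pd.DataFrame  # per-gene mouse evidence (all genes)
    association: pd.DataFrame  # per-SNP GWAS
    lambda_gc: float
    gene_stats: pd.DataFrame  # per-gene GATES table
    combined: pd.DataFrame  # ranked cross-species table
    threshold: float


def run_study(
    config: synthetic.SimulationConfig,
    mode: str = "either",
    alpha: float = 0.001,
) -> StudyResult:
    """Simulate one study and run every pipeline stage on it.

    The mouse correlation stage is evaluated for *all* genes (not only the
    screen's candidates) so null genes carry a combined p-value too; the
    candidate set and its FDR estimate are still reported for the screen.
    """
    pmap = synthetic.probe_gene_map(config)

    expr_nt, truth = synthetic.simulate_strain_expression(config)
    others = [s for s in config.strain_sizes if s != config.low_susceptibility_strain]
    diff = mouse.strain_differential_test(
        expr_nt, config.low_susceptibility_strain, others, mode=mode, alpha=alpha
    )
    candidates = mouse.select_candidate_genes(diff, pmap, alpha=alpha)
    fdr = mouse.fdr_at_threshold(diff["p_summary"], alpha)

    expr_tg, abeta = synthetic.simulate_tg_cohort(config, truth)
    corr = mouse.abeta_correlation(expr_tg, abeta)
    corr_gene = mouse.collapse_probes(corr, pmap)

    panel = synthetic.simulate_genotype_panel(config)
    pheno = synthetic.simulate_case_control_study(panel, config, truth)
    assoc = gwas.snp_association(panel, pheno)
    lam = gwas.genomic_inflation(assoc["p"].dropna())

    regions = synthetic.gene_regions(config, panel)
    gstats = genebased.gene_statistics(panel, regions, assoc)

    orthologs = synthetic.default_ortholog_table(config)
    combined = integrate.ortholog_join(corr_gene, gstats, orthologs)

    return StudyResult(
        truth=truth,
        differential=diff,
        candidates=candidates,
        fdr_at_alpha=fdr,
        correlation=corr_gene,
        association=assoc,
        lambda_gc=lam,
        gene_stats=gstats,
        combined=combined,
        threshold=combined.attrs["threshold"],
    )


def planted_rank_fraction(result: StudyResult) -> float:
    """Fraction of null genes that every planted gene outranks.

    Returns the minimum, over planted genes, of the fraction of non-causal
    genes with a strictly larger combined p-value; 1.0 means every planted
    gene beat every null gene.
    """
    df = result.combined
    causal_h = {synthetic.human_gene_symbol(i) for i in result.truth.causal_gene_indices}
    is_causal = df["human_symbol"].isin(causal_h)
    null_p = df.loc[~is_causal, "p_combined"].to_numpy()
    if null_p.size == 0 or not is_causal.any():
        return float("nan")
    worst = df.loc[is_causal, "p_combined"].max()
    return float((null_p > worst).mean())
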