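"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV for expression matrices, phenotypes,
dosages, association results and ortholog tables; VCF (written
uncompressed, read via cyvcf2) for genotypes; JSON for ground truth.
Gene annotations are accepted as BED (0-based half-open) or 1-based
inclusive TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .genebased import GeneRegion
from .gwas import GenotypePanel
from .mouse import ExpressionMatrix
from .synthetic import GroundTruth


# -- expression -------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, values_path, metadata_path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="probe_id")
    meta = pd.DataFrame(
        {"sample_id": expr.sample_ids,
         "label": [expr.sample_labels[s] for s in expr.sample_ids]}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_expression(values_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    values.index.name = None
    meta = pd.read_csv(metadata_path, sep="\t")
    labels = pd.Series(meta["label"].to_numpy(), index=meta["sample_id"])
    return ExpressionMatrix(values=values, sample_labels=labels)


def write_series(series: pd.Series, path, id_name: str = "sample_id") -> None:
    series.rename_axis(id_name).to_csv(path, sep="\t", header=True)


def read_abeta(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="abeta")


# -- genotypes --------------------------------------------------------------

def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    """SNP map columns then one column per individual (dosage 0/1/2)."""
    df = panel.snp_map[["snp_id", "chrom", "pos", "a0", "a1"]].copy()
    dos = pd.DataFrame(
        panel.dosages.T, columns=panel.individual_ids, index=df.index
    )
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    fixed = ["snp_id", "chrom", "pos", "a0", "a1"]
    ids = [c for c in df.columns if c not in fixed]
    dosages = df[ids].to_numpy(float).T
    snp_map = df[fixed].copy()
    snp_map["chrom"] = snp_map["chrom"].astype(str)
    return GenotypePanel(dosages=dosages, snp_map=snp_map, individual_ids=ids)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal uncompressed VCF 4.2 with GT fields (unphased, from dosage)."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in panel.snp_map["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for j, row in enumerate(panel.snp_map.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else gt[int(d)] for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.a0}\t{row.a1}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        rows.append((var.ID, var.CHROM, var.POS, var.REF, var.ALT[0]))
        gts = var.genotype.array()[:, :2]
        col = gts.sum(axis=1).astype(float)
        col[(gts < 0).any(axis=1)] = np.nan
        dosage_cols.append(col)
    if not rows:
        raise InvalidParameterError(f"no variants in {path}")
    snp_map = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a0", "a1"])
    return GenotypePanel(
        dosages=np.column_stack(dosage_cols),
        snp_map=snp_map,
        individual_ids=ids,
    )


# -- annotations ------------------------------------------------------------

def read_gene_annotation(path, coords: str = "one_based", flank: int = 3_000) -> list[GeneRegion]:
    """Gene regions from BED (0-based half-open) or 1-based inclusive TSV.

    TSV columns: symbol, chrom, start, end.  BED columns: chrom, start, end,
    name (standard order).
    """
    df = pd.read_csv(path, sep="\t", header=None if coords == "bed" else 0)
    regions = []
    if coords == "bed":
        for _, r in df.iterrows():
            regions.append(GeneRegion(str(r[3]), str(r[0]), int(r[1]) + 1, int(r[2]), flank))
    elif coords == "one_based":
        for _, r in df.iterrows():
            regions.append(
                GeneRegion(str(r["symbol"]), str(r["chrom"]), int(r["start"]), int(r["end"]), flank)
            )
    else:
        raise InvalidParameterError("coords must be 'bed' or 'one_based'")
    return regions


def write_gene_annotation(regions: list[GeneRegion], path) -> None:
    pd.DataFrame(
        [(g.symbol, g.chrom, g.start, g.end) for g in regions],
        columns=["symbol", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


# -- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "causal_gene_ids": sorted(truth.causal_gene_ids),
                "causal_directions": truth.causal_directions,
                "causal_snp_ids": sorted(truth.causal_snp_ids),
                "causal_gene_indices": list(truth.causal_gene_indices),
            },
            fh,
            indent=2,
        )


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        causal_gene_ids=set(d["causal_gene_ids"]),
        causal_directions=d["causal_directions"],
        causal_snp_ids=set(d["causal_snp_ids"]),
        causal_gene_indices=tuple(d["causal_gene_indices"]),
    )


# -- simple tables ----------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def study_outputs(outdir, config, truth, panel, pheno, expr_nt, expr_tg, abeta, orthologs) -> None:
    """Write every simulated input the downstream stages consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(expr_nt, out / "expression_strains.tsv", out / "samples_strains.tsv")
    write_expression(expr_tg, out / "expression_tg.tsv", out / "samples_tg.tsv")
    write_series(abeta, out / "abeta.tsv")
    write_dosage_tsv(panel, out / "genotypes.tsv")
    write_vcf(panel, out / "genotypes.vcf")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    write_ground_truth(truth, out / "ground_truth.json")

    from .synthetic import gene_regions, probe_gene_map

    write_gene_annotation(gene_regions(config, panel), out / "genes.tsv")
    pd.DataFrame(
        sorted(probe_gene_map(config).items()), columns=["probe_id", "gene"]
    ).to_csv(out / "probe_gene_map.tsv", sep="\t", index=False)
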