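import numpy as np
import pandas as pd
import pytest

from orthoprio import GenotypePanel, SimulationConfig
from orthoprio.mouse import ExpressionMatrix

# (r, p_mouse printed, p_human printed, combined printed) rows of the
# published integrated-analysis table (28 transgenic animals)
TABLE2 = [
    ("Lbh", "LBH", -0.6941, 0.000042, 0.046239, 1.66e-05),
    ("St6galnac4", "ST6GALNAC4", 0.5970, 0.000797, 0.011877, 3.32e-05),
    ("Arsj", "ARSJ", 0.6609, 0.000129, 0.045099, 3.73e-05),
    ("AW549877", "C5orf51", -0.6009, 0.000722, 0.019214, 5.20e-05),
    ("Shf", "SHF", -0.6455, 0.000208, 0.044829, 5.31e-05),
]


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=123, n_genes=40, n_causal=3, n_snps=200, n_individuals=600
    )


def toy_panel(dosage_columns: dict[str, np.ndarray], positions=None, chrom="1") -> GenotypePanel:
    """Hand-built panel from named dosage columns (individuals x SNPs)."""
    ids = list(dosage_columns)
    D = np.column_stack([np.asarray(dosage_columns[s], float) for s in ids])
    pos = positions if positions is not None else [100 * (i + 1) for i in range(len(ids))]
    snp_map = pd.DataFrame(
        {"snp_id": ids, "chrom": chrom, "pos": pos, "a0": "A", "a1": "G"}
    )
    return GenotypePanel(
        dosages=D,
        snp_map=snp_map,
        individual_ids=[f"i{k}" for k in range(D.shape[0])],
    )


def expr_from_groups(groups: dict[str, np.ndarray], probe_ids) -> ExpressionMatrix:
    """Expression matrix whose columns are grouped samples (one label each)."""
    cols, labels, mats = [], [], []
    for label, mat in groups.items():
        mat = np.atleast_2d(np.asarray(mat, float))
        for k in range(mat.shape[1]):
            cols.append(f"{label}_{k + 1}")
            labels.append(label)
        mats.append(mat)
    values = pd.DataFrame(np.hstack(mats), index=probe_ids, columns=cols)
    return ExpressionMatrix(values=values, sample_labels=pd.Series(labels, index=cols))
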