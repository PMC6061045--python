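"""Per-SNP case-control association and genomic-inflation diagnostics.

Each SNP is tested by additive-coding logistic regression of disease status
on allele dosage with age and sex as covariates (Wald two-tailed p on the
dosage coefficient).  The genomic inflation factor lambda — the median of
the per-SNP 1-df chi-square statistics divided by the null median — is the
standard check that the p-value stream is not confounded by structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import InvalidDesignError, InvalidParameterError

# exact median of the 1-df chi-square (0.4549 to four decimals)
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class GenotypePanel:
    """Diploid dosage matrix (individual x SNP) plus a sorted SNP map.

    ``dosages`` holds values in {0, 1, 2} (minor-allele counts) or NaN for
    missing.  ``snp_map`` is a DataFrame with columns ``snp_id``, ``chrom``,
    ``pos`` (1-based), ``a0``, ``a1``; positions must be strictly increasing
    within each chromosome.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    individual_ids: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, float)
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_map)):
            raise InvalidParameterError("dosage shape does not match ids/snp_map")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise InvalidParameterError("dosages must be in {0, 1, 2} or NaN")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise InvalidParameterError(
                    "SNP positions must be strictly increasing within chromosome"
                )
        self._index = {s: i for i, s in enumerate(self.snp_map["snp_id"])}

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP id."""
        return self.dosages[:, self._index[snp_id]]

    def columns(self, snp_ids: list[str]) -> np.ndarray:
        return self.dosages[:, [self._index[s] for s in snp_ids]]


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype/covariate table (individual_id, status, age, sex)."""
    required = {"individual_id", "status", "age", "sex"}
    if not required <= set(pheno.columns):
        raise InvalidParameterError(f"phenotype table needs columns {sorted(required)}")
    if pheno["individual_id"].duplicated().any():
        raise InvalidParameterError("duplicate individual ids")
    statuses = set(pheno["status"].unique())
    if not statuses <= {0, 1} or len(statuses) != 2:
        raise InvalidDesignError("need both cases (1) and controls (0)")
    return pheno


def snp_association(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Covariate-adjusted logistic association for every SNP in the panel.

    Model per SNP: ``status ~ dosage + age + sex`` (additive coding), with a
    Wald two-tailed p-value on the dosage log-odds.  Missing dosages are
    dropped per SNP (complete-case).  Age is standardized and sex encoded 0/1
    before fitting, for numerical stability.  Monomorphic SNPs and fits with
    (quasi-)separation are reported with a NaN p and a reason in ``note``.
    """
    pheno = validate_phenotypes(pheno)
    pheno = pheno.set_index("individual_id").loc[panel.individual_ids]
    n_case = int(pheno["status"].sum())
    n_ctrl = len(pheno) - n_case
    if min(n_case, n_ctrl) < 10:
        raise InvalidDesignError("need >= 10 individuals per status group")

    y = pheno["status"].to_numpy(float)
    cov_cols = []
    if "age" in covariates:
        age = pheno["age"].to_numpy(float)
        sd = age.std()
        cov_cols.append((age - age.mean()) / sd if sd > 0 else age * 0.0)
    if "sex" in covariates:
        sex = pheno["sex"]
        if sex.dtype == object:
            sex = sex.map({"male": 0, "female": 1})
        cov_cols.append(sex.to_numpy(float))
    covs = np.column_stack(cov_cols) if cov_cols else np.empty((len(y), 0))

    records = []
    design = np.empty((len(y), 2 + covs.shape[1]))
    design[:, 0] = 1.0
    design[:, 2:] = covs
    for j, snp_id in enumerate(panel.snp_map["snp_id"]):
        g = panel.dosages[:, j]
        keep = ~np.isnan(g)
        effect, p, note = np.nan, np.nan, ""
        gk = g[keep]
        if gk.size == 0 or gk.min() == gk.max():
            note = "monomorphic"
        else:
            X = design[keep] if keep.all() else design[keep].copy()
            X[:, 1] = gk
            try:
                res = sm.Logit(y[keep], X).fit(disp=0, method="newton", maxiter=50)
                if res.mle_retvals.get("converged", False) and np.isfinite(
                    res.bse[1]
                ) and res.bse[1] < 50:
                    effect = float(res.params[1])
                    p = float(res.pvalues[1])
                    p = min(max(p, 5e-324), 1.0)
                else:
                    note = "separation"
            except (PerfectSeparationError, np.linalg.LinAlgError):
                note = "separation"
        records.append((snp_id, effect, p, note))
    out = pd.DataFrame(records, columns=["snp_id", "effect", "p", "note"])
    return out.merge(panel.snp_map[["snp_id", "chrom", "pos"]], on="snp_id")


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda from a vector of two-tailed p-values.

    lambda = median(qchisq(1-p, 1)) / median(chi2_1); ~1 under the null.
    """
    p = np.asarray(p_values, float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise InvalidParameterError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def qq_coordinates(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) coordinates for a QQ plot."""
    p = np.sort(np.asarray(p_values, float))
    p = p[~np.isnan(p)]
    n = p.size
    if n == 0:
        raise InvalidParameterError("no p-values")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return pd.DataFrame({"expected": expected, "observed": observed})
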