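"""Gene-based association statistics via the extended Simes (GATES) procedure.

A gene's SNP-level p-values are combined into one gene-level p-value that
accounts for local linkage disequilibrium.  SNPs are assigned to a gene if
they fall inside the transcript region extended by a 3 kb flank, or if they
are in high LD (r^2 > 0.8) with an in-region SNP.  The effective number of
independent tests Me is derived from the eigenvalues of the SNP p-value
correlation matrix, and the gene p-value is

    P_gene = min_j  Me * p_(j) / Me(j),

over the ascending-sorted p-values, where Me(j) is the effective number for
the top-j SNPs.  With independent SNPs this reduces exactly to the Simes
combination; with perfectly correlated SNPs it reduces to min p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, MonomorphicSnpError
from .gwas import GenotypePanel

#: coefficients of the 6th-degree polynomial approximating the correlation of
#: two two-tailed p-values as a function of the genotype correlation |r|
#: (highest degree first), as published for the extended Simes test.
GATES_POLY = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0)

DEFAULT_FLANK = 3_000
DEFAULT_R2_THRESHOLD = 0.8
PROXY_WINDOW = 1_000_000  # bp searched either side of a gene for LD proxies


@dataclass
class GeneRegion:
    """A gene's genomic span (1-based, inclusive) with a symmetric flank."""

    symbol: str
    chrom: str
    start: int
    end: int
    flank: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidParameterError(f"{self.symbol}: start > end")
        if self.flank < 0:
            raise InvalidParameterError("flank must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneSnpSet:
    """SNPs assigned to one gene plus their genotype correlation matrix.

    ``snp_ids`` are position-ordered, in-region SNPs first then LD proxies;
    ``source`` tags each SNP as ``in_region`` or ``ld_proxy``.
    """

    symbol: str
    snp_ids: list[str]
    r_matrix: np.ndarray
    source: dict[str, str]
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if len(set(self.snp_ids)) != m:
            raise InvalidParameterError("duplicate SNP ids in gene set")
        if m:
            R = np.asarray(self.r_matrix, float)
            if R.shape != (m, m) or not np.allclose(R, R.T, atol=1e-8):
                raise InvalidParameterError("r_matrix must be symmetric m x m")
            self.r_matrix = R

    def __len__(self) -> int:
        return len(self.snp_ids)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_correlation(panel: GenotypePanel, snp_ids: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation of dosages (signed r; square for r^2).

    Missing genotypes are handled pairwise (complete pairs).  Raises for
    monomorphic SNPs, fewer than 2 SNPs or fewer than 20 individuals.
    """
    if len(snp_ids) < 2:
        raise InvalidParameterError("need >= 2 SNPs for an LD matrix")
    if panel.n_individuals < 20:
        raise InvalidParameterError("need >= 20 individuals for LD estimation")
    G = pd.DataFrame(panel.columns(snp_ids), columns=snp_ids)
    sds = G.std(ddof=0)
    mono = sds.index[sds == 0].tolist()
    if mono:
        raise MonomorphicSnpError(f"monomorphic SNP(s): {mono}")
    return G.corr(method="pearson")


def assign_snps(
    gene: GeneRegion,
    panel: GenotypePanel,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    proxy_window: int = PROXY_WINDOW,
) -> GeneSnpSet:
    """Assign panel SNPs to a gene by position and LD proxy rules.

    A SNP is assigned when its position lies in ``[start - flank, end + flank]``
    on the gene's chromosome, or when its r^2 with any in-region SNP strictly
    exceeds ``r2_threshold`` (searched within ``proxy_window`` bp of the
    flanked region).  A gene with no in-region SNP yields an empty set.
    """
    sm_ = panel.snp_map
    on_chrom = sm_["chrom"] == gene.chrom
    lo, hi = gene.start - gene.flank, gene.end + gene.flank
    in_region = on_chrom & (sm_["pos"] >= lo) & (sm_["pos"] <= hi)
    region_ids = sm_.loc[in_region, "snp_id"].tolist()
    if not region_ids:
        return GeneSnpSet(gene.symbol, [], np.empty((0, 0)), {})

    near = on_chrom & ~in_region
    near &= (sm_["pos"] >= lo - proxy_window) & (sm_["pos"] <= hi + proxy_window)
    candidate_ids = sm_.loc[near, "snp_id"].tolist()

    proxy_ids: list[str] = []
    if candidate_ids:
        all_ids = region_ids + candidate_ids
        R = ld_correlation(panel, all_ids) if len(all_ids) >= 2 else None
        if R is not None:
            r2 = R.loc[candidate_ids, region_ids].to_numpy() ** 2
            keep = r2.max(axis=1) > r2_threshold
            proxy_ids = [s for s, k in zip(candidate_ids, keep) if k]

    pos = sm_.set_index("snp_id")["pos"]
    region_ids.sort(key=lambda s: pos[s])
    proxy_ids.sort(key=lambda s: pos[s])
    ids = region_ids + proxy_ids
    if len(ids) >= 2:
        Rm = ld_correlation(panel, ids).to_numpy()
    else:
        Rm = np.ones((1, 1))
    source = {s: "in_region" for s in region_ids}
    source.update({s: "ld_proxy" for s in proxy_ids})
    return GeneSnpSet(gene.symbol, ids, Rm, source, [int(pos[s]) for s in ids])


# ---------------------------------------------------------------------------
# extended Simes machinery
# ---------------------------------------------------------------------------

def pvalue_correlation_approx(r, method: str = "gates_poly"):
    """Approximate correlation of two two-tailed p-values from genotype r.

    ``gates_poly`` (default) evaluates the published 6th-degree polynomial at
    |r|, clipped to [0, 1] with |r| = 1 mapped exactly to 1 so that duplicated
    SNPs collapse cleanly; ``r2`` is the simple f(r) = r^2 fallback.  Both are
    even functions with f(0) = 0 and f(+-1) = 1.
    """
    a = np.abs(np.asarray(r, float))
    if (a > 1 + 1e-12).any():
        raise InvalidParameterError("|r| must be <= 1")
    a = np.minimum(a, 1.0)
    if method == "gates_poly":
        out = np.clip(np.polyval(GATES_POLY, a), 0.0, 1.0)
        out = np.where(a >= 1.0 - 1e-12, 1.0, out)
    elif method == "r2":
        out = a**2
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return float(out) if np.isscalar(r) else out


def effective_number(corr_matrix) -> float:
    """Effective number of independent tests Me from a correlation matrix.

    Me = M - sum over eigenvalues > 1 of (eigenvalue - 1), clamped to [1, M].
    Negative eigenvalues arising from approximate (non-PSD) matrices are
    truncated at 0 before the sum (they do not enter it anyway).
    """
    C = np.asarray(corr_matrix, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise InvalidParameterError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise InvalidParameterError("correlation matrix must be symmetric")
    m = C.shape[0]
    lam = np.linalg.eigvalsh((C + C.T) / 2.0)
    lam = np.maximum(lam, 0.0)
    me = m - np.sum(np.maximum(lam - 1.0, 0.0))
    # snap away eigendecomposition round-off so exact limiting cases
    # (identity -> M, all-ones -> 1) are hit exactly
    return float(np.clip(round(me, 10), 1.0, m))


@dataclass
class GateResult:
    """Gene-level extended-Simes outcome."""

    symbol: str
    n_snps: int
    me: float
    me_partial: np.ndarray
    gene_p: float
    note: str = ""
    pcorr_method: str = "gates_poly"


def _sort_order(p, positions, ids):
    """Ascending p; ties broken by genomic position then SNP id."""
    n = len(p)
    pos = positions if positions is not None else [0] * n
    idx = ids if ids is not None else [""] * n
    return sorted(range(n), key=lambda i: (p[i], pos[i], idx[i]))


def gates_p(
    snp_pvals,
    r_matrix,
    positions=None,
    snp_ids=None,
    symbol: str = "",
    pcorr: str = "gates_poly",
) -> GateResult:
    """Extended Simes gene p-value from SNP p-values and genotype LD.

    Missing (NaN) p-values are dropped along with their matrix rows; an
    all-missing gene returns NaN with a reason.  The p-value correlation
    matrix is built with :func:`pvalue_correlation_approx`; Me(j) values are
    made monotone non-decreasing in j (they are in exact arithmetic).
    """
    p = np.asarray(snp_pvals, float)
    R = np.atleast_2d(np.asarray(r_matrix, float))
    if p.size == 0 or np.isnan(p).all():
        return GateResult(symbol, 0, np.nan, np.empty(0), np.nan, "no valid p-values", pcorr)
    valid = ~np.isnan(p)
    if not valid.all():
        keep = np.flatnonzero(valid)
        p = p[keep]
        R = R[np.ix_(keep, keep)]
        if positions is not None:
            positions = [positions[i] for i in keep]
        if snp_ids is not None:
            snp_ids = [snp_ids[i] for i in keep]
    if ((p <= 0) | (p > 1)).any():
        raise InvalidParameterError("p-values must lie in (0, 1]")

    order = _sort_order(p.tolist(), positions, snp_ids)
    p_sorted = p[order]
    C = pvalue_correlation_approx(R[np.ix_(order, order)], method=pcorr)
    np.fill_diagonal(C, 1.0)
    m = p_sorted.size
    me_partial = np.array([effective_number(C[:j, :j]) for j in range(1, m + 1)])
    me_partial = np.maximum.accumulate(me_partial)
    me = me_partial[-1]
    gene_p = float(np.min(me * p_sorted / me_partial))
    gene_p = min(max(gene_p, 5e-324), 1.0)
    return GateResult(symbol, m, float(me), me_partial, gene_p, "", pcorr)


def gates_p_batch(pvals: np.ndarray, r_matrix: np.ndarray, pcorr: str = "gates_poly") -> np.ndarray:
    """Vectorized :func:`gates_p` over replicates sharing one LD matrix.

    ``pvals`` is (n_replicates, m); ties in the per-replicate sort fall back
    to column order.  Used for permutation-based calibration, where the same
    gene (hence the same LD matrix) is scored for thousands of null p-value
    vectors; returns an array of gene p-values identical to looping
    :func:`gates_p` over rows.
    """
    P = np.asarray(pvals, float)
    nrep, m = P.shape
    C = pvalue_correlation_approx(np.asarray(r_matrix, float), method=pcorr)
    np.fill_diagonal(C, 1.0)
    order = np.argsort(P, axis=1, kind="stable")
    P_sorted = np.take_along_axis(P, order, axis=1)
    me_partial = np.empty((nrep, m))
    for j in range(1, m + 1):
        sub = C[order[:, :j, None], order[:, None, :j]]
        lam = np.linalg.eigvalsh(sub)
        lam = np.maximum(lam, 0.0)
        me_j = j - np.sum(np.maximum(lam - 1.0, 0.0), axis=1)
        me_partial[:, j - 1] = np.clip(me_j, 1.0, j)
    me_partial = np.maximum.accumulate(me_partial, axis=1)
    me = me_partial[:, -1:]
    return np.clip(np.min(me * P_sorted / me_partial, axis=1), 5e-324, 1.0)


# ---------------------------------------------------------------------------
# per-study driver
# ---------------------------------------------------------------------------

def gene_statistics(
    panel: GenotypePanel,
    genes: list[GeneRegion],
    assoc: pd.DataFrame,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    pcorr: str = "gates_poly",
) -> pd.DataFrame:
    """Gene-based p-values for a list of genes from per-SNP association results.

    Mirrors a per-gene summary table: symbol, chrom, start, length, n_snps,
    Me and the extended-Simes gene p.  Genes with no assigned SNP, or whose
    assigned SNPs all lack a valid p, are flagged and carry NaN.
    """
    pmap = assoc.set_index("snp_id")["p"]
    rows = []
    for gene in genes:
        gset = assign_snps(gene, panel, r2_threshold=r2_threshold)
        if len(gset) == 0:
            rows.append((gene.symbol, gene.chrom, gene.start, gene.length,
                         0, np.nan, np.nan, "no snps"))
            continue
        pv = pmap.reindex(gset.snp_ids).to_numpy(float)
        res = gates_p(pv, gset.r_matrix, positions=gset.positions,
                      snp_ids=gset.snp_ids, symbol=gene.symbol, pcorr=pcorr)
        rows.append((gene.symbol, gene.chrom, gene.start, gene.length,
                     len(gset), res.me, res.gene_p, res.note))
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "start", "length_bp", "n_snps", "me",
                 "gates_p", "note"],
    )
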