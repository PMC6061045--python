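"""Synthetic cohorts with planted ground truth for the whole pipeline.

Emulates the three data sources the integration consumes:

* a 12-array non-transgenic expression experiment (three inbred strains,
  one of low AD susceptibility) with a planted strain-differential subset;
* a 28-animal APP-transgenic cohort in which designated genes' expression
  correlates (positively or negatively) with a log-normal amyloid-beta
  level;
* an LD-blocked diploid genotype panel with case/control status driven by
  causal SNPs inside designated genes plus small age and sex effects.

Haplotypes come from a latent-Gaussian threshold model: within each LD
block the latent variables follow an AR-1 chain whose coefficients are
obtained by inverting the tetrachoric relation, so that
``within_block_rho`` is the *allelic* (dosage) correlation of adjacent
SNPs, not the latent one.  All randomness derives from one root seed via
named substreams, so each stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, owens_t
from scipy.stats import norm

from .exceptions import InvalidDesignError, InvalidParameterError
from .gwas import GenotypePanel
from .genebased import GeneRegion
from .mouse import ExpressionMatrix

_STREAMS = {"truth": 1, "strain": 2, "tg": 3, "panel": 4, "pheno": 5, "ortholog": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the root seed (independent per pipeline stage)."""
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """All sizes, effect sizes, seeds and LD parameters for one study.

    Defaults mirror the emulated study conditions: 3 strains x 4 arrays for
    the non-Tg screen, 28 transgenic animals, |r| = 0.7 amyloid correlation
    for planted genes, 5-SNP LD blocks and a per-allele odds ratio of 1.5
    for causal SNPs.
    """

    seed: int = 0
    n_genes: int = 200
    n_causal: int = 3
    strain_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"DBA": 4, "B6": 4, "SJL": 4}
    )
    low_susceptibility_strain: str = "DBA"
    n_tg_animals: int = 28
    abeta_corr_effects: tuple[float, ...] = (-0.7, 0.7, -0.7)
    strain_shift_sd: float = 6.0  # planted shift, in units of noise SD
    noise_sd: float = 1.0
    abeta_log_mean: float = np.log(50.0)  # log pmol/g, ELISA-like
    abeta_log_sd: float = 0.5
    n_individuals: int = 2_000
    n_snps: int = 1_000
    block_size: int = 5
    within_block_rho: float = 0.8  # target adjacent-SNP allelic correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snp_or: float = 1.5
    case_fraction: float = 0.5
    age_effect: float = 0.02  # log-odds per year from age 70
    sex_effect: float = 0.25  # log-odds, female vs male

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_causal, self.n_tg_animals,
                  self.n_individuals, self.n_snps, self.block_size]
        if any(c < 1 for c in counts):
            raise InvalidParameterError("all counts must be >= 1")
        if self.n_causal > self.n_genes:
            raise InvalidParameterError("n_causal must be <= n_genes")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.within_block_rho < 1:
            raise InvalidParameterError("within_block_rho must be in [0, 1)")
        if not 0 < self.case_fraction < 1:
            raise InvalidParameterError("case_fraction must be in (0, 1)")
        if self.causal_snp_or <= 0:
            raise InvalidParameterError("causal_snp_or must be > 0")
        if any(abs(e) >= 1 for e in self.abeta_corr_effects):
            raise InvalidParameterError(
                "amyloid correlation effects are correlations; |effect| must be < 1"
            )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted signal: which genes/SNPs are causal and in which direction."""

    causal_gene_ids: set[str]
    causal_directions: dict[str, str]
    causal_snp_ids: set[str] = field(default_factory=set)
    causal_gene_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if set(self.causal_directions) != set(self.causal_gene_ids):
            raise InvalidParameterError(
                "directions must be defined exactly for the causal genes"
            )


def mouse_gene_symbol(i: int) -> str:
    return f"Gene{i:04d}"


def human_gene_symbol(i: int) -> str:
    return f"GENE{i:04d}"


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    rng = _rng(config.seed, "truth")
    # causal genes need genotype support: one LD block exists per gene only
    # for the first ceil(n_snps / block_size) genes
    n_blocks = -(-config.n_snps // config.block_size)
    pool = min(config.n_genes, n_blocks)
    if config.n_causal > pool:
        raise InvalidParameterError(
            f"n_causal={config.n_causal} exceeds the {pool} genes with LD blocks"
        )
    idx = np.sort(rng.choice(pool, size=config.n_causal, replace=False))
    effects = [config.abeta_corr_effects[i % len(config.abeta_corr_effects)]
               for i in range(config.n_causal)]
    genes = [mouse_gene_symbol(i) for i in idx]
    directions = {g: ("Up" if e > 0 else "Down") for g, e in zip(genes, effects)}
    return GroundTruth(
        causal_gene_ids=set(genes),
        causal_directions=directions,
        causal_gene_indices=tuple(int(i) for i in idx),
    )


def _causal_effects(config: SimulationConfig) -> list[float]:
    return [config.abeta_corr_effects[i % len(config.abeta_corr_effects)]
            for i in range(config.n_causal)]


def probe_gene_map(config: SimulationConfig) -> dict[str, str]:
    """One probe per gene: probe0007 -> Gene0007."""
    return {f"probe{i:04d}": mouse_gene_symbol(i) for i in range(config.n_genes)}


# ---------------------------------------------------------------------------
# non-transgenic strain expression (screen step 1 input)
# ---------------------------------------------------------------------------

def simulate_strain_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Strain-panel expression with a planted differential subset.

    Values are gene baseline + strain shift + i.i.d. Gaussian noise; the
    shift applies only to planted genes and only in the designated
    low-susceptibility strain (positive for genes planted as "Down", i.e.
    negatively amyloid-correlated genes are higher in the resistant strain).
    Non-planted genes share one mean across strains.
    """
    if len(config.strain_sizes) < 3:
        raise InvalidDesignError("need three strains")
    if config.low_susceptibility_strain not in config.strain_sizes:
        raise InvalidDesignError("low-susceptibility strain missing from strain_sizes")
    if any(n < 2 for n in config.strain_sizes.values()):
        raise InvalidDesignError("every strain needs >= 2 samples")

    truth = _ground_truth(config)
    rng = _rng(config.seed, "strain")
    baseline = rng.normal(8.0, 1.0, size=config.n_genes)

    sample_ids, labels = [], []
    for strain, n in config.strain_sizes.items():
        for i in range(n):
            sample_ids.append(f"{strain}_{i + 1}")
            labels.append(strain)
    n_samples = len(sample_ids)

    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_samples)
    )
    shift = config.strain_shift_sd * config.noise_sd
    low_cols = [j for j, lab in enumerate(labels) if lab == config.low_susceptibility_strain]
    for gi, g in zip(truth.causal_gene_indices, sorted(truth.causal_gene_ids)):
        sgn = 1.0 if truth.causal_directions[g] == "Down" else -1.0
        values[gi, low_cols] += sgn * shift

    probes = list(probe_gene_map(config))
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=sample_ids),
        sample_labels=pd.Series(labels, index=sample_ids),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# transgenic cohort (screen step 2 input)
# ---------------------------------------------------------------------------

def simulate_tg_cohort(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, pd.Series]:
    """Transgenic-cohort expression plus per-animal amyloid-beta levels.

    Amyloid is log-normal (positive, right-skewed, as ELISA measurements
    are).  For each causal gene, expression = baseline + beta * A-beta +
    noise, with beta chosen so the *population* correlation equals the
    configured signed effect; other genes are independent of amyloid.
    """
    if config.n_tg_animals < 4:
        raise InvalidDesignError("need >= 4 transgenic animals")
    rng = _rng(config.seed, "tg")
    n = config.n_tg_animals
    abeta = np.exp(rng.normal(config.abeta_log_mean, config.abeta_log_sd, size=n))
    sample_ids = [f"Tg_{i + 1}" for i in range(n)]

    baseline = rng.normal(8.0, 1.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n)
    )

    # population SD of the log-normal amyloid level
    s2 = config.abeta_log_sd**2
    sd_abeta = np.exp(config.abeta_log_mean + s2 / 2.0) * np.sqrt(np.expm1(s2))
    effects = _causal_effects(config)
    for gi, rho in zip(truth.causal_gene_indices, effects):
        beta = (rho / np.sqrt(1.0 - rho**2)) * config.noise_sd / sd_abeta
        values[gi, :] += beta * (abeta - abeta.mean())

    probes = list(probe_gene_map(config))
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=sample_ids),
        sample_labels=pd.Series(["Tg"] * n, index=sample_ids),
    )
    return expr, pd.Series(abeta, index=sample_ids, name="abeta")


# ---------------------------------------------------------------------------
# genotype panel: latent-Gaussian threshold haplotypes in LD blocks
# ---------------------------------------------------------------------------

def _bvn_lower_cdf(q1: np.ndarray, q2: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(X <= q1, Y <= q2) for standard bivariate normals, via Owen's T.

    Valid for q1, q2 < 0 (MAF thresholds; MAF = 0.5 is nudged off zero).
    """
    q1 = np.where(q1 == 0, -1e-9, q1)
    q2 = np.where(q2 == 0, -1e-9, q2)
    denom = np.sqrt(np.maximum(1.0 - rho**2, 1e-12))
    a1 = (q2 - rho * q1) / (q1 * denom)
    a2 = (q1 - rho * q2) / (q2 * denom)
    return (
        0.5 * (norm.cdf(q1) + norm.cdf(q2))
        - owens_t(q1, a1)
        - owens_t(q2, a2)
    )


def _allelic_corr(q1, q2, rho_latent):
    """Correlation of the two thresholded (minor-allele) indicators."""
    p1, p2 = norm.cdf(q1), norm.cdf(q2)
    p11 = _bvn_lower_cdf(q1, q2, rho_latent)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def latent_rho_for_target(target_r: np.ndarray, q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Latent-Gaussian correlation achieving a target allelic correlation.

    Inverts the tetrachoric relation by bisection (vectorized over SNP
    pairs).  Targets above the attainable maximum (unequal MAFs bound the
    binary correlation below 1) are capped at the maximum.
    """
    target = np.asarray(target_r, float)
    lo = np.zeros_like(target)
    hi = np.full_like(target, 0.999999)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        too_low = _allelic_corr(q1, q2, mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def simulate_genotype_panel(config: SimulationConfig) -> GenotypePanel:
    """Diploid dosages from two thresholded latent-AR-1 haplotypes.

    SNPs are grouped into blocks of ``block_size`` (the last block may be
    short); blocks are mutually independent and widely separated on the
    coordinate axis (one block per gene, 2 Mb apart, 1 kb between SNPs).
    Each haplotype's latent vector follows an AR-1 chain whose coefficient
    per adjacent pair is tetrachorically matched to ``within_block_rho``;
    thresholding at each SNP's MAF quantile gives minor-allele indicators,
    and dosage is the sum over the two haplotypes.
    """
    rng = _rng(config.seed, "panel")
    n_snps, bs = config.n_snps, config.block_size
    n_hap = 2 * config.n_individuals

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    q = norm.ppf(maf)

    block_of = np.arange(n_snps) // bs
    n_blocks = int(block_of[-1]) + 1
    pos = np.empty(n_snps, int)
    for b in range(n_blocks):
        j = np.flatnonzero(block_of == b)
        pos[j] = 1 + b * 2_000_000 + np.arange(j.size) * 1_000

    # latent AR-1 coefficient for each adjacent within-block pair
    rho_lat = np.zeros(n_snps)  # rho_lat[j] links SNP j-1 -> j
    if config.within_block_rho > 0:
        adj = np.flatnonzero((block_of[1:] == block_of[:-1]))
        if adj.size:
            j = adj + 1
            rho_lat[j] = latent_rho_for_target(
                np.full(j.size, config.within_block_rho), q[j - 1], q[j]
            )

    # generate latent chains chunk-wise (chunks aligned to block boundaries)
    # to bound memory at large n_snps; blocks are mutually independent
    alleles = np.empty((n_hap, n_snps), dtype=np.int8)
    chunk_target = max(bs, 4096)
    start = 0
    while start < n_snps:
        stop = min(start + chunk_target, n_snps)
        stop = n_snps if stop >= n_snps else int(block_of.searchsorted(block_of[stop], "left"))
        z = rng.standard_normal((n_hap, stop - start))
        prev = z[:, 0].copy()
        for jj in range(start, stop):
            r = rho_lat[jj]
            col = z[:, jj - start]
            if r > 0 and jj > start and block_of[jj] == block_of[jj - 1]:
                prev = r * prev + np.sqrt(1.0 - r * r) * col
            else:
                prev = col
            alleles[:, jj] = prev < q[jj]
        start = stop

    dosages = (alleles[0::2] + alleles[1::2]).astype(float)

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1:06d}" for j in range(n_snps)],
            "chrom": "1",
            "pos": pos,
            "a0": "A",
            "a1": "G",
            "maf": maf,
            "block": block_of,
        }
    )
    ids = [f"ind{i + 1:05d}" for i in range(config.n_individuals)]
    return GenotypePanel(dosages=dosages, snp_map=snp_map, individual_ids=ids)


def gene_regions(config: SimulationConfig, panel: GenotypePanel) -> list[GeneRegion]:
    """One human gene per LD block, spanning exactly its block's SNPs."""
    regions = []
    for b, grp in panel.snp_map.groupby("block", sort=True):
        regions.append(
            GeneRegion(
                symbol=human_gene_symbol(int(b)),
                chrom=str(grp["chrom"].iloc[0]),
                start=int(grp["pos"].min()),
                end=int(grp["pos"].max()),
            )
        )
    return regions


# ---------------------------------------------------------------------------
# case/control phenotypes
# ---------------------------------------------------------------------------

def simulate_case_control_study(
    panel: GenotypePanel, config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Case/control status from a logistic model on causal-SNP dosages.

    logit P(case) = b0 + sum log(OR) * dosage_causal + age and sex effects;
    the intercept b0 is calibrated by bisection so the expected case
    fraction matches ``case_fraction``.  When ``truth.causal_snp_ids`` is
    empty, the middle SNP of each causal gene's block is designated causal
    (and recorded back into the ground truth).
    """
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise InvalidParameterError("empty genotype panel")
    if not truth.causal_snp_ids:
        sm_ = panel.snp_map
        for b in truth.causal_gene_indices:
            grp = sm_[sm_["block"] == b]
            if grp.empty:
                raise InvalidParameterError(f"causal gene block {b} has no SNPs")
            truth.causal_snp_ids.add(grp["snp_id"].iloc[len(grp) // 2])
    missing = truth.causal_snp_ids - set(panel.snp_map["snp_id"])
    if missing:
        raise InvalidParameterError(f"causal SNPs absent from panel: {sorted(missing)}")

    rng = _rng(config.seed, "pheno")
    n = panel.n_individuals
    age = rng.normal(70.0, 8.0, size=n)
    sex = rng.integers(0, 2, size=n)

    eta = config.age_effect * (age - 70.0) + config.sex_effect * sex
    log_or = np.log(config.causal_snp_or)
    if log_or != 0.0:
        G = panel.columns(sorted(truth.causal_snp_ids))
        eta = eta + log_or * np.nansum(G, axis=1)

    lo, hi = -25.0, 25.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < config.case_fraction:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    status = (rng.random(n) < expit(b0 + eta)).astype(int)

    return pd.DataFrame(
        {
            "individual_id": panel.individual_ids,
            "status": status,
            "age": age,
            "sex": sex,
        }
    )


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------

def make_ortholog_table(
    human_symbols: Sequence[str],
    mouse_symbols: Sequence[str],
    scramble_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """1:1 human-mouse symbol pairs, optionally with many-to-many rows.

    ``scramble_fraction`` injects that fraction of extra rows pairing an
    existing human symbol with a second mouse partner (for join-policy
    tests); every row of such a family is flagged ``is_multi``.  Input
    duplicates among the mouse symbols are likewise flagged; duplicated
    human symbols in the base input are an error.
    """
    if len(human_symbols) != len(mouse_symbols):
        raise InvalidParameterError("symbol lists must have equal length")
    hs = list(human_symbols)
    if len(set(hs)) != len(hs):
        raise InvalidParameterError("duplicate human symbols in base table")
    df = pd.DataFrame({"human_symbol": hs, "mouse_symbol": list(mouse_symbols)})

    if not 0 <= scramble_fraction < 1:
        raise InvalidParameterError("scramble_fraction must be in [0, 1)")
    n_extra = round(scramble_fraction * len(df))
    if n_extra:
        rng = _rng(seed, "ortholog")
        pick_h = rng.choice(len(df), size=n_extra, replace=False)
        pick_m = rng.choice(len(df), size=n_extra, replace=False)
        extra = pd.DataFrame(
            {
                "human_symbol": df["human_symbol"].iloc[pick_h].to_numpy(),
                "mouse_symbol": df["mouse_symbol"].iloc[pick_m].to_numpy(),
            }
        )
        df = pd.concat([df, extra], ignore_index=True)
        df = df.drop_duplicates(ignore_index=True)

    df["is_multi"] = df.duplicated("human_symbol", keep=False) | df.duplicated(
        "mouse_symbol", keep=False
    )
    return df


def default_ortholog_table(config: SimulationConfig) -> pd.DataFrame:
    return make_ortholog_table(
        [human_gene_symbol(i) for i in range(config.n_genes)],
        [mouse_gene_symbol(i) for i in range(config.n_genes)],
        seed=config.seed,
    )
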