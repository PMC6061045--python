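"""Two-step mouse transcriptome screen.

Step 1 selects candidate genes that are differentially expressed in a
low-AD-susceptibility inbred strain relative to two susceptible strains,
using non-transgenic animals so that expression differences reflect genetic
background rather than amyloid pathology.  Step 2 scores each candidate by
the Pearson correlation between its expression and per-animal amyloid-beta
(ELISA) levels in an APP-transgenic cohort of mixed genetic background.
The per-gene two-tailed correlation p-value and the sign of the correlation
are the mouse evidence stream handed to the cross-species integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidDesignError, InvalidParameterError

logger = logging.getLogger(__name__)

_TINY_P = 5e-324  # smallest subnormal double; keeps p in (0, 1]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe x sample log-intensity matrix with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, columns are sample ids.  Values are
        log-scale intensities; missing values are rejected (imputation or
        filtering is an upstream preprocessing concern).
    sample_labels
        Series mapping sample id -> strain or disease-group label.
    """

    values: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.sample_labels = pd.Series(self.sample_labels)
        if self.values.isna().any().any():
            raise InvalidParameterError(
                "expression matrix contains missing values; handle upstream"
            )
        missing = set(self.values.columns) - set(self.sample_labels.index)
        if missing:
            raise InvalidParameterError(f"samples without a label: {sorted(missing)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, label: str) -> list[str]:
        """Sample ids carrying the given strain/group label."""
        lab = self.sample_labels
        return [s for s in self.values.columns if lab[s] == label]


@dataclass
class CandidateSet:
    """Outcome of the differential-expression candidate selection."""

    genes: set[str]
    probes: list[str]
    n_genes: int = field(init=False)
    n_probes: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_genes = len(self.genes)
        self.n_probes = len(self.probes)


# ---------------------------------------------------------------------------
# step 1: strain-differential screen
# ---------------------------------------------------------------------------

def _equal_variance_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical (pooled-variance) two-sample t test, rowwise.

    Rows with zero pooled variance get t=0, p=1 when the means agree, and a
    formally infinite t (p = smallest positive double) when they differ.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero = denom == 0
    t = np.where(zero & (diff == 0), 0.0, t)
    t = np.where(zero & (diff != 0), np.sign(diff) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, _TINY_P, 1.0)
    return t, p


def strain_differential_test(
    expr: ExpressionMatrix,
    target_strain: str,
    other_strains: Sequence[str],
    mode: str = "either",
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-probe differential expression of ``target_strain`` vs the others.

    For each comparison strain an equal-variance two-tailed Student t test is
    run per probe.  The summary p-value per probe is

    * ``either`` (default) -- the minimum over the pairwise comparisons
      (a probe counts as differential if it differs from *either* strain);
    * ``both``   -- the maximum (must differ from every comparison strain);
    * ``pooled`` -- a single comparison against all other strains pooled.

    Returns a DataFrame indexed by probe id with per-comparison ``t_*`` and
    ``p_*`` columns, ``p_summary`` and a boolean ``selected`` column
    (``p_summary < alpha``).
    """
    if mode not in {"either", "both", "pooled"}:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    tgt_cols = expr.samples_in(target_strain)
    if len(tgt_cols) < 2:
        raise InvalidDesignError(
            f"strain {target_strain!r} has {len(tgt_cols)} samples; need >= 2"
        )
    a = expr.values[tgt_cols].to_numpy(float)

    out = pd.DataFrame(index=expr.values.index)
    if mode == "pooled":
        pool_cols: list[str] = []
        for s in other_strains:
            cols = expr.samples_in(s)
            if len(cols) < 2:
                raise InvalidDesignError(f"strain {s!r} has {len(cols)} samples")
            pool_cols += cols
        t, p = _equal_variance_t(a, expr.values[pool_cols].to_numpy(float))
        out["t_pooled"], out["p_pooled"] = t, p
        out["p_summary"] = p
    else:
        pcols = []
        for s in other_strains:
            cols = expr.samples_in(s)
            if len(cols) < 2:
                raise InvalidDesignError(f"strain {s!r} has {len(cols)} samples")
            t, p = _equal_variance_t(a, expr.values[cols].to_numpy(float))
            out[f"t_{s}"], out[f"p_{s}"] = t, p
            pcols.append(f"p_{s}")
        agg = out[pcols].min(axis=1) if mode == "either" else out[pcols].max(axis=1)
        out["p_summary"] = agg
    out["selected"] = out["p_summary"] < alpha
    return out


def fdr_at_threshold(p_values: Iterable[float], alpha: float) -> float:
    """Expected-false-positives FDR estimate at a fixed p cutoff.

    Returns ``m * alpha / k`` (capped at 1) where ``m`` is the number of tests
    and ``k`` the number with p < alpha; NaN when nothing is selected.
    """
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        raise InvalidParameterError("empty p-value list")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    k = int((p < alpha).sum())
    if k == 0:
        return float("nan")
    return min(1.0, p.size * alpha / k)


def select_candidate_genes(
    diff: pd.DataFrame,
    probe_gene_map: Mapping[str, str],
    alpha: float = 0.001,
) -> CandidateSet:
    """Collapse selected probes to the candidate gene set.

    A gene is a candidate if *any* of its probes passes the summary-p
    threshold.  Selected probes absent from the probe->gene map are excluded
    with a logged warning.
    """
    sel = diff.index[diff["p_summary"] < alpha]
    probes, genes = [], set()
    for probe in sel:
        gene = probe_gene_map.get(probe)
        if gene is None:
            logger.warning("selected probe %s has no gene mapping; excluded", probe)
            continue
        probes.append(probe)
        genes.add(gene)
    return CandidateSet(genes=genes, probes=probes)


# ---------------------------------------------------------------------------
# step 2: amyloid-beta correlation in the transgenic cohort
# ---------------------------------------------------------------------------

def correlation_pvalue(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-tailed p for a Pearson correlation via t = r sqrt((n-2)/(1-r^2)).

    The statistic has n-2 degrees of freedom under the null of zero
    correlation.  |r| = 1 maps to the smallest positive double.
    """
    r_arr = np.asarray(r, float)
    if n < 3:
        raise InvalidDesignError("need n >= 3 for a correlation p-value")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt((n - 2) / (1.0 - r_arr**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r_arr) >= 1.0, _TINY_P, p)
    p = np.clip(p, _TINY_P, 1.0)
    return float(p) if np.isscalar(r) else p


def abeta_correlation(
    expr_tg: ExpressionMatrix,
    abeta: pd.Series,
    probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each probe's expression with amyloid-beta level.

    ``abeta`` is aligned to the expression samples by id.  Returns a DataFrame
    indexed by probe with ``r``, ``p`` (two-tailed, from the t transform),
    ``direction`` ("Up" for r > 0, "Down" otherwise) and a ``note`` column;
    probes with zero expression variance get NaN and note ``zero_variance``.
    """
    samples = expr_tg.sample_ids
    n = len(samples)
    if n < 4:
        raise InvalidDesignError(f"need >= 4 animals, got {n}")
    missing = set(samples) - set(abeta.index)
    if missing:
        raise InvalidParameterError(f"A-beta level missing for samples {sorted(missing)}")
    y = abeta.loc[samples].to_numpy(float)
    if np.std(y) == 0:
        raise InvalidParameterError("A-beta vector has zero variance")

    vals = expr_tg.values if probes is None else expr_tg.values.loc[list(probes)]
    x = vals.to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    ok = sx > 0
    p = np.full(r.shape, np.nan)
    p[ok] = correlation_pvalue(r[ok], n)
    out = pd.DataFrame(
        {
            "r": np.where(ok, r, np.nan),
            "p": p,
            "direction": np.where(r > 0, "Up", "Down"),
            "note": np.where(ok, "", "zero_variance"),
        },
        index=vals.index,
    )
    out.loc[~ok, "direction"] = ""
    return out


def collapse_probes(
    corr: pd.DataFrame, probe_gene_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene correlation result: keep each gene's smallest-p probe.

    Ties on p are broken by larger |r|, then lexicographically smaller probe
    id, so the collapse is deterministic.  Probes must all be mapped.
    """
    unmapped = [pr for pr in corr.index if pr not in probe_gene_map]
    if unmapped:
        raise InvalidParameterError(f"unmapped probes: {unmapped[:5]}")
    df = corr.copy()
    df["gene"] = [probe_gene_map[pr] for pr in df.index]
    df["probe"] = df.index
    df = df[df["p"].notna()]
    df = df.sort_values(
        by=["gene", "p", "r", "probe"],
        key=lambda c: -c.abs() if c.name == "r" else c,
    )
    best = df.groupby("gene", sort=True).head(1).set_index("gene")
    return best[["probe", "r", "p", "direction"]]
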