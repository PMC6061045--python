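"""Cross-species evidence integration by the unweighted inverse-normal method.

Each gene carries two two-tailed p-values: the mouse expression/amyloid
correlation p and the human gene-based GWAS p.  Both are halved to one-tailed
p-values, mapped to z-scores through the standard normal quantile function,
and averaged (Stouffer's method without weights):

    Z_C = (Z_MEXP + Z_HGWAS) / sqrt(2)

The combined one-tailed p = 1 - Phi(Z_C) is then doubled to a two-tailed
p-value.  Significance is declared at a Bonferroni-style cutoff of
0.05 / n_tested / 2, the extra factor of two matching the doubling of the
combined p.  Note the combined statistic is not calibrated under the null:
both z-scores are folded (non-negative), so their sum over-rejects
(empirically ~0.10 at nominal 0.05 for independent uniform inputs); the
calibration is characterized empirically rather than corrected, for
fidelity to the published recipe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import EmptyJoinError, InvalidParameterError

logger = logging.getLogger(__name__)

#: z cap used when a p-value is too small for the quantile function (p < 1e-300)
Z_MAX = float(norm.isf(0.5e-300))


def one_tailed_z(p_two_tailed) -> float | np.ndarray:
    """One-tailed z-score from a two-tailed p: z = Phi^-1(1 - p/2) >= 0.

    The two-tailed p is halved before inversion; p-values below 1e-300 are
    capped at ``Z_MAX`` with a logged warning.
    """
    p = np.asarray(p_two_tailed, float)
    if (p <= 0).any() or (p > 1).any():
        raise InvalidParameterError("p must lie in (0, 1]")
    tiny = p < 1e-300
    if tiny.any():
        logger.warning("%d p-value(s) below 1e-300; z capped at %.2f", tiny.sum(), Z_MAX)
    z = np.where(tiny, Z_MAX, norm.isf(np.maximum(p, 1e-300) / 2.0))
    return float(z) if np.isscalar(p_two_tailed) else z


def combine_p(p_mouse, p_human) -> tuple:
    """Unweighted Stouffer combination of two two-tailed p-values.

    Returns ``(Z_C, p_combined)`` with Z_C = (z_mouse + z_human)/sqrt(2) and
    p_combined = min(1, 2 * (1 - Phi(Z_C))), two-tailed.
    """
    z1 = one_tailed_z(p_mouse)
    z2 = one_tailed_z(p_human)
    zc = (np.asarray(z1) + np.asarray(z2)) / np.sqrt(2.0)
    pc = np.minimum(1.0, 2.0 * norm.sf(zc))
    pc = np.maximum(pc, 5e-324)
    if np.isscalar(p_mouse) and np.isscalar(p_human):
        return float(zc), float(pc)
    return zc, pc


def significance_threshold(n_tested: int) -> float:
    """Study-wide cutoff 0.05 / n_tested / 2 on the combined two-tailed p."""
    if n_tested < 1:
        raise InvalidParameterError("n_tested must be >= 1")
    return 0.05 / n_tested / 2.0


def ortholog_join(
    mouse_stats: pd.DataFrame,
    human_stats: pd.DataFrame,
    orthologs: pd.DataFrame,
    n_tested: int | None = None,
) -> pd.DataFrame:
    """Join the two evidence streams through human-mouse ortholog pairs.

    ``mouse_stats`` is the per-gene correlation table (index mouse gene
    symbol; columns r, p, direction, probe), ``human_stats`` the gene-based
    table (column ``gene`` with human symbols, ``gates_p``), ``orthologs`` a
    two-column table (human_symbol, mouse_symbol).  Matching is
    case-insensitive; pairs missing either p are dropped with a logged count.
    When several mouse genes map to one human gene the smallest-p mouse
    partner is kept and the row flagged ``multi_ortholog``.  Returns the
    ranked combined table with z-scores, combined two-tailed p and the
    significance flag at 0.05 / n_tested / 2 (n_tested defaults to the number
    of genes with both p-values).
    """
    mo = mouse_stats.copy()
    mo.index = mo.index.str.upper()
    hu = human_stats.set_index(human_stats["gene"].str.upper())

    rows = []
    n_dropped = 0
    for _, pair in orthologs.iterrows():
        hkey = str(pair["human_symbol"]).upper()
        mkey = str(pair["mouse_symbol"]).upper()
        if hkey not in hu.index or mkey not in mo.index:
            n_dropped += 1
            continue
        p_h = hu.at[hkey, "gates_p"]
        p_m = mo.at[mkey, "p"]
        if pd.isna(p_h) or pd.isna(p_m):
            n_dropped += 1
            continue
        rows.append(
            {
                "human_symbol": pair["human_symbol"],
                "mouse_symbol": pair["mouse_symbol"],
                "r": mo.at[mkey, "r"],
                "direction": mo.at[mkey, "direction"],
                "p_mouse": float(p_m),
                "p_human": float(p_h),
            }
        )
    if n_dropped:
        logger.info("ortholog join dropped %d pair(s) lacking a p-value", n_dropped)
    if not rows:
        raise EmptyJoinError("no ortholog pair with both evidence streams")
    df = pd.DataFrame(rows)

    # many-to-many: per human gene keep the smallest mouse p, flag the family
    df["multi_ortholog"] = df.duplicated("human_symbol", keep=False)
    df = (
        df.sort_values(["human_symbol", "p_mouse", "mouse_symbol"])
        .groupby("human_symbol", sort=False)
        .head(1)
        .reset_index(drop=True)
    )

    z_m = one_tailed_z(df["p_mouse"].to_numpy())
    z_h = one_tailed_z(df["p_human"].to_numpy())
    df["z_mexp"] = z_m
    df["z_hgwas"] = z_h
    df["z_c"] = (z_m + z_h) / np.sqrt(2.0)
    df["p_combined"] = np.maximum(np.minimum(1.0, 2.0 * norm.sf(df["z_c"])), 5e-324)

    if n_tested is None:
        n_tested = len(df)
    cutoff = significance_threshold(n_tested)
    df["significant"] = df["p_combined"] < cutoff
    df.attrs["n_tested"] = n_tested
    df.attrs["threshold"] = cutoff
    return df.sort_values("p_combined", kind="mergesort").reset_index(drop=True)
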