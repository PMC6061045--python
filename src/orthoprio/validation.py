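"""Independent-cohort expression check for prioritized genes.

Mirrors a qPCR validation stage: target-gene expression is normalized to a
stable reference gene (GUSB in the original assays), compared between
disease and control groups with a two-tailed Student t test, and the
per-gene p-values are adjusted by Benjamini-Hochberg FDR.  A direction
concordance flag records whether the disease-vs-control sign agrees with
the mouse correlation direction (Down = lower in disease).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidDesignError, InvalidParameterError


def normalize_to_reference(target_level, reference_level, scale: str = "linear"):
    """Express a target-gene measurement relative to the reference gene.

    ``linear``: ratio target/reference (reference must be > 0).
    ``ct``: qPCR cycle-threshold scale, 2^-(Ct_target - Ct_reference); one
    extra cycle for the target means half the abundance.
    """
    t = np.asarray(target_level, float)
    r = np.asarray(reference_level, float)
    if np.isnan(t).any() or np.isnan(r).any():
        raise InvalidParameterError("missing target or reference measurement")
    if scale == "linear":
        if (r <= 0).any():
            raise InvalidParameterError("reference level must be > 0 on linear scale")
        out = t / r
    elif scale == "ct":
        out = 2.0 ** (-(t - r))
    else:
        raise InvalidParameterError(f"unknown scale {scale!r}")
    return float(out) if np.isscalar(target_level) else out


def group_difference(values, groups, case_label: str = "AD", control_label: str = "control"):
    """Equal-variance two-tailed t test of case vs control normalized levels.

    Returns ``(t, p, mean_diff)`` with the sign convention case minus control.
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    a = v[g == case_label]
    b = v[g == control_label]
    if len(a) < 2 or len(b) < 2:
        raise InvalidDesignError("need >= 2 samples per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero variance in both groups
        t, p = 0.0, 1.0
    return float(t), float(min(max(p, 5e-324), 1.0)), float(a.mean() - b.mean())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise InvalidParameterError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise InvalidParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_genes(
    data: pd.DataFrame,
    mouse_directions: dict[str, str] | None = None,
    scale: str = "linear",
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Run the whole validation stage on a long-format measurement table.

    ``data`` columns: sample, group (AD/control), gene, target_level,
    reference_level.  Returns a per-gene table with t, p, BH q, the
    case-minus-control mean difference, a significance flag at q < 0.05 and,
    when mouse directions are supplied, ``direction_concordant`` (True when a
    "Down" gene is indeed lower in the disease group, and vice versa).
    """
    rows = []
    for gene, sub in data.groupby("gene", sort=True):
        norm = normalize_to_reference(
            sub["target_level"].to_numpy(), sub["reference_level"].to_numpy(), scale
        )
        t, p, diff = group_difference(norm, sub["group"].to_numpy())
        rows.append({"gene": gene, "t": t, "p": p, "mean_diff": diff})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_cutoff
    if mouse_directions is not None:
        conc = []
        for _, row in out.iterrows():
            d = mouse_directions.get(row["gene"])
            if d is None:
                conc.append(pd.NA)
            else:
                conc.append(row["mean_diff"] < 0 if d == "Down" else row["mean_diff"] > 0)
        out["direction_concordant"] = conc
    return out
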