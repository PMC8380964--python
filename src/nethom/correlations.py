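"""Pearson correlation of region-mean NH with clinical variables.

Correlations are computed within one group (patients, by default),
with pairwise-complete deletion of missing phenotype values and the
per-test n recorded. No multiple-testing adjustment is applied by
default; Benjamini-Hochberg q-values can be appended on request.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import NethomError

__all__ = ["pearson_with_pvalue", "correlate_regions_with_clinical"]


def pearson_with_pvalue(x, y) -> dict:
    """Sample Pearson r with the two-sided t-based p-value.

    Missing values are dropped pairwise; returns
    ``{"r": ..., "p": ..., "n": ...}``. A perfect fit's p underflows
    to the smallest positive float rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise NethomError("x and y must be equal-length 1D vectors")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise NethomError(f"need at least 3 complete pairs, got {n}")
    if x.std() < 1e-14 or y.std() < 1e-14:
        raise NethomError("zero variance input to correlation")
    res = stats.pearsonr(x, y)
    p = float(res.pvalue)
    if p <= 0.0:
        p = float(np.nextafter(0.0, 1.0))
    return {"r": float(res.statistic), "p": p, "n": n}


def correlate_regions_with_clinical(
    features: pd.DataFrame,
    pheno: pd.DataFrame,
    variables: list[str],
    group_filter: str = "patient",
    adjust: str | None = None,
) -> pd.DataFrame:
    """One row of (region, variable, n, r, p) per pair.

    ``features``: subjects x region columns (indexed by subject_id).
    ``pheno``: phenotype table indexed by subject_id with a ``group``
    column. ``adjust='bh'`` appends Benjamini-Hochberg q-values.
    """
    missing = [v for v in variables if v not in pheno.columns]
    if missing:
        raise NethomError(
            f"unknown variable(s) {missing}; available: "
            f"{sorted(c for c in pheno.columns if c != 'group')}"
        )
    joined = features.join(pheno, how="inner")
    if group_filter is not None:
        joined = joined[joined["group"] == group_filter]
    if joined.shape[0] < 3:
        raise NethomError("fewer than 3 subjects after group filtering")
    rows = []
    for region in features.columns:
        for var in variables:
            r = pearson_with_pvalue(joined[region], joined[var])
            rows.append(
                {"region": region, "variable": var, "n": r["n"], "r": r["r"], "p": r["p"]}
            )
    out = pd.DataFrame(rows, columns=["region", "variable", "n", "r", "p"])
    if adjust == "bh":
        out["q_bh"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    elif adjust is not None:
        raise NethomError(f"unknown adjustment {adjust!r} (use 'bh' or None)")
    return out
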