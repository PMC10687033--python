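"""Response-stratified comparisons along supplied pseudotime.

Pseudotime is consumed as an input column (any trajectory tool's output can be
fed in); this module never infers trajectories. Distribution contrasts use the
two-sample Kolmogorov-Smirnov test on raw pseudotime values; binned profiles
of cell density, TCR richness and Gini index support the corresponding
along-trajectory plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .repertoire import ClonotypeTable, gini_index


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    D: float
    p_value: float
    n1: int
    n2: int


def ks_compare(pseudotimes_a, pseudotimes_b) -> KSResult:
    """Exact two-sample KS statistic with the asymptotic two-sided p-value.

    D is the supremum of |ECDF_a - ECDF_b| over the pooled observed points
    (ECDFs right-continuous, so ties are handled by evaluating after each
    distinct value); the p-value uses the Kolmogorov distribution at
    ``sqrt(n1 n2 / (n1 + n2)) * D``.
    """
    a = np.sort(np.asarray(pseudotimes_a, dtype=float))
    b = np.sort(np.asarray(pseudotimes_b, dtype=float))
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.union1d(a, b)
    cdf_a = np.searchsorted(a, grid, side="right") / n1
    cdf_b = np.searchsorted(b, grid, side="right") / n2
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = math.sqrt(n1 * n2 / (n1 + n2))
    p = float(special.kolmogorov(en * d))
    return KSResult(D=d, p_value=min(max(p, 0.0), 1.0), n1=n1, n2=n2)


def binned_profile(
    cells: pd.DataFrame,
    n_bins: int,
    metric: str = "density",
    shared_keys: set[str] | None = None,
    min_cells: int = 5,
) -> pd.DataFrame:
    """Profile a metric along pseudotime in equal-width bins.

    ``metric`` is one of ``density`` (bin cell count / total), ``richness``
    and ``gini`` (computed on the bin's clone-size table), or
    ``shared_density`` (density restricted to cells whose clonotype key is in
    ``shared_keys``). Bins holding fewer than ``min_cells`` cells are reported
    with value NaN (absent, not zero). Returns columns
    ``bin_mid, value, n_cells``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if metric not in ("density", "richness", "gini", "shared_density"):
        raise ValueError(f"unknown metric: {metric!r}")
    pt = pd.to_numeric(cells["pseudotime"], errors="coerce")
    if pt.isna().any():
        raise ValueError("all cells must carry a pseudotime value")
    if metric in ("richness", "gini", "shared_density") and (
        "clonotype_key" not in cells or cells["clonotype_key"].eq("").any()
    ):
        raise ValueError(f"metric {metric!r} requires clonotype keys on every cell")
    if metric == "shared_density" and shared_keys is None:
        raise ValueError("shared_density requires shared_keys")

    lo, hi = float(pt.min()), float(pt.max())
    if hi == lo:
        hi = lo + 1.0  # all mass in one bin; keep edges valid
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(pt, edges[1:-1], right=False), 0, n_bins - 1)
    total = len(cells)
    rows = []
    for b in range(n_bins):
        in_bin = cells.loc[idx == b]
        n = len(in_bin)
        mid = 0.5 * (edges[b] + edges[b + 1])
        if n < min_cells:
            rows.append({"bin_mid": mid, "value": float("nan"), "n_cells": n})
            continue
        if metric == "density":
            value = n / total
        elif metric == "shared_density":
            value = in_bin["clonotype_key"].isin(shared_keys).sum() / total
        else:
            counts = in_bin["clonotype_key"].value_counts()
            table = ClonotypeTable(sample_id=f"bin{b}", counts=dict(counts.items()))
            if metric == "richness":
                value = table.n_clonotypes / table.n_cells
            else:
                value = gini_index(table)
        rows.append({"bin_mid": mid, "value": float(value), "n_cells": n})
    return pd.DataFrame(rows)


def smoothed_density(values, grid=None, n_points: int = 200):
    """Gaussian-kernel density (Silverman bandwidth) for plotting only.

    Statistics always use the raw values via :func:`ks_compare`; this helper
    exists so plotted curves match the binned profiles' smoothed rendering.
    Returns ``(grid, density)``.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 values for a density estimate")
    if grid is None:
        grid = np.linspace(values.min(), values.max(), n_points)
    kde = gaussian_kde(values, bw_method="silverman")
    return grid, kde(grid)


def response_ks(
    cells: pd.DataFrame,
    lineage: str,
    shared_keys: set[str] | None = None,
) -> KSResult:
    """KS comparison of responder vs non-responder pseudotime on one lineage.

    When ``shared_keys`` is given, only cells carrying a shared clonotype are
    compared (shared-cell density contrast).
    """
    sel = cells.loc[cells["lineage"] == lineage]
    if shared_keys is not None:
        sel = sel.loc[sel["clonotype_key"].isin(shared_keys)]
    a = sel.loc[sel["response"] == "responder", "pseudotime"]
    b = sel.loc[sel["response"] == "non_responder", "pseudotime"]
    return ks_compare(a.to_numpy(float), b.to_numpy(float))
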