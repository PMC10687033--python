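"""Per-sample and per-phenotype TCR repertoire diversity statistics.

Given clonotype-annotated cells, each (sample, optional phenotype) stratum is
summarised by:

* **evenness** — Shannon entropy of clonotype frequencies normalised by
  ``ln(S)`` (Pielou's J); 1 for a perfectly even repertoire;
* **clonality** — ``1 - evenness``; high values indicate clonal expansion;
* **richness** — unique clonotypes per cell carrying a productive TCR, S/N;
* **Gini index** — inequality of the clone-size distribution (0 = all clones
  the same size), computed with the uncorrected estimator so that values are
  comparable with R's ``ineq::Gini`` default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClonotypeTable:
    """Clone-size table for one (sample x optional phenotype) stratum."""

    sample_id: str
    counts: dict[str, int]
    phenotype: str | None = None

    def __post_init__(self):
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("clonotype counts must be >= 1")

    @property
    def n_cells(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clonotypes(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> np.ndarray:
        n = np.fromiter(self.counts.values(), dtype=float, count=len(self.counts))
        return n / n.sum()

    @property
    def keys(self) -> set[str]:
        return set(self.counts)


@dataclass(frozen=True)
class RepertoireMetrics:
    clonality: float
    evenness: float
    richness: float
    gini: float
    n_cells: int
    n_clonotypes: int


def build_tables(cells: pd.DataFrame, by_phenotype: bool = False) -> list[ClonotypeTable]:
    """Tally cells into one clone-size table per sample (x phenotype).

    Empty strata are omitted; within a sample-phenotype stratum, counts sum to
    the stratum's cell count.
    """
    keys = ["sample_id", "phenotype"] if by_phenotype else ["sample_id"]
    tables = []
    for name, grp in cells.groupby(keys, sort=True):
        if not isinstance(name, tuple):
            name = (name,)
        counts = grp["clonotype_key"].value_counts().sort_index()
        tables.append(
            ClonotypeTable(
                sample_id=name[0],
                phenotype=name[1] if by_phenotype else None,
                counts=dict(counts.items()),
            )
        )
    return tables


def shannon_evenness(table: ClonotypeTable) -> float:
    """Normalised Shannon entropy H/ln(S) of the clonotype frequencies.

    A single-clonotype repertoire (S = 1) has evenness 0 by convention: it is
    the limit of a two-clone table as one frequency tends to 1, and makes
    clonality 1 for a maximally clonal sample.
    """
    if table.n_clonotypes == 0:
        raise ValueError("empty clonotype table")
    if table.n_clonotypes == 1:
        return 0.0
    p = table.frequencies
    h = -np.sum(p * np.log(p))
    return float(min(max(h / math.log(table.n_clonotypes), 0.0), 1.0))


def gini_index(table: ClonotypeTable, corrected: bool = False) -> float:
    """Gini index of the clone-size vector.

    Uncorrected estimator ``G = sum_ij |n_i - n_j| / (2 S^2 nbar)`` (the
    ``ineq::Gini`` default); ``corrected=True`` applies the small-sample
    factor S/(S-1). 0 when all clones are the same size.
    """
    if table.n_clonotypes == 0:
        raise ValueError("empty clonotype table")
    n = np.sort(np.fromiter(table.counts.values(), dtype=float))
    s = len(n)
    if s == 1:
        return 0.0
    i = np.arange(1, s + 1)
    g = (2.0 * np.sum(i * n) / (s * n.sum())) - (s + 1.0) / s
    if corrected:
        g *= s / (s - 1.0)
    return float(max(g, 0.0))


def richness(table: ClonotypeTable, denominator: str = "all_cells") -> float:
    """Unique clonotypes per cell.

    ``all_cells`` (default): S divided by every cell carrying a productive
    TCR. ``singleton_cells``: S divided by the number of cells whose
    clonotype is a singleton — an alternative reading of "cells with a
    unique TCR" that penalises expanded repertoires harder (and can exceed 1,
    so it is reported unclipped).
    """
    if denominator == "all_cells":
        return table.n_clonotypes / table.n_cells
    if denominator == "singleton_cells":
        n_singleton = sum(1 for n in table.counts.values() if n == 1)
        if n_singleton == 0:
            raise ValueError("no singleton clonotypes: denominator is zero")
        return table.n_clonotypes / n_singleton
    raise ValueError(f"unknown richness denominator: {denominator!r}")


def repertoire_metrics(table: ClonotypeTable, gini_corrected: bool = False) -> RepertoireMetrics:
    """Bundle all diversity statistics for one stratum."""
    evenness = shannon_evenness(table)
    return RepertoireMetrics(
        clonality=1.0 - evenness,
        evenness=evenness,
        richness=richness(table),
        gini=gini_index(table, corrected=gini_corrected),
        n_cells=table.n_cells,
        n_clonotypes=table.n_clonotypes,
    )


def metrics_frame(cells: pd.DataFrame, by_phenotype: bool = False) -> pd.DataFrame:
    """Diversity statistics for every stratum, as one tidy DataFrame."""
    rows = []
    for t in build_tables(cells, by_phenotype=by_phenotype):
        m = repertoire_metrics(t)
        rows.append(
            {
                "sample_id": t.sample_id,
                "phenotype": t.phenotype if t.phenotype is not None else "",
                "clonality": m.clonality,
                "evenness": m.evenness,
                "richness": m.richness,
                "gini": m.gini,
                "n_cells": m.n_cells,
                "n_clonotypes": m.n_clonotypes,
            }
        )
    return pd.DataFrame(rows)


def classify_dominant(
    table: ClonotypeTable,
    rule: str = "either",
    min_cells: int = 5,
    min_fraction: float = 0.01,
) -> dict[str, bool]:
    """Flag dominant clonotypes.

    ``min_cells``: clonotypes with >= ``min_cells`` cells; ``min_fraction``:
    clonotypes holding >= ``min_fraction`` of the repertoire; ``either``: the
    union of the two rules.
    """
    if rule not in ("min_cells", "min_fraction", "either"):
        raise ValueError(f"unknown dominance rule: {rule!r}")
    if min_cells <= 0 or min_fraction <= 0:
        raise ValueError("dominance thresholds must be positive")
    total = table.n_cells
    out = {}
    for key, n in table.counts.items():
        by_cells = n >= min_cells
        by_frac = n / total >= min_fraction
        out[key] = {
            "min_cells": by_cells,
            "min_fraction": by_frac,
            "either": by_cells or by_frac,
        }[rule]
    return out
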