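"""Gene signatures and single-sample gene-set enrichment (ssGSEA) scoring.

Ships the two built-in treatment-response signatures — a 36-gene cytotoxic
effector-memory CD8 T-cell (TEMRA) signature and a 16-gene inflammatory
CXCL10+ macrophage signature — plus their 52-gene union, and scores them per
bulk sample with a rank-based single-sample enrichment statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# Signature gene lists transcribed verbatim from the source marker tables,
# including the symbols "KRLK1" (likely KLRK1) and "WARS" (now WARS1) as
# printed; SYMBOL_ALIASES can rewrite them for modern annotations.
_TEMRA_GENES = (
    "GZMH", "GNLY", "NKG7", "FGFBP2", "GZMB", "CST7", "CCL5", "PRF1",
    "CX3CR1", "CTSW", "GZMA", "KLRD1", "GZMM", "CD3D", "CD8A", "CD52",
    "PTPRC", "CD3G", "HCST", "CD3E", "PLEK", "KLRG1", "RAC2", "LCK",
    "CD247", "HOPX", "KRLK1", "BIN2", "S100A4", "CORO1A", "IL2RG", "ITGB2",
    "IFITM1", "EMP3", "TRBC1", "FLNA",
)
_MACRO_CXCL10_GENES = (
    "CXCL10", "CXCL9", "GBP1", "TYMP", "CALHM6", "CCL2", "TNFSF13B", "WARS",
    "CCL8", "IL4I1", "ICAM1", "LILRB4", "CXCL11", "SOD2", "LAP3", "STAT1",
)

#: Optional rewrites of legacy/misprinted symbols to current HGNC symbols.
SYMBOL_ALIASES = {"KRLK1": "KLRK1", "WARS": "WARS1"}


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate symbols in signature {self.name}")

    def __len__(self) -> int:
        return len(self.genes)

    def with_aliases(self, aliases: dict[str, str] | None = None) -> "GeneSignature":
        """Return a copy with legacy symbols rewritten via ``aliases``."""
        table = SYMBOL_ALIASES if aliases is None else aliases
        return GeneSignature(self.name, tuple(table.get(g, g) for g in self.genes))


def builtin_signatures(fix_symbols: bool = False) -> list[GeneSignature]:
    """The built-in TEMRA (36 genes) and Macro CXCL10 (16 genes) signatures
    and their combined 52-gene treatment-response biomarker.

    ``fix_symbols=True`` rewrites legacy/misprinted symbols through
    :data:`SYMBOL_ALIASES`; the default keeps them verbatim.
    """
    sigs = [
        GeneSignature("CD8_TEMRA", _TEMRA_GENES),
        GeneSignature("Macro_CXCL10", _MACRO_CXCL10_GENES),
        GeneSignature("combined", _TEMRA_GENES + _MACRO_CXCL10_GENES),
    ]
    if fix_symbols:
        sigs = [s.with_aliases() for s in sigs]
    return sigs


def read_signature(path) -> GeneSignature:
    """Read a signature file: one symbol per line, ``#``-prefixed name header."""
    name = "signature"
    genes = []
    for line in open(path):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            name = line.lstrip("#").strip() or name
        else:
            genes.append(line)
    return GeneSignature(name, tuple(genes))


def ssgsea_scores(
    expr: pd.DataFrame,
    signature: GeneSignature,
    weight_exponent: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample single-sample enrichment score of ``signature``.

    For each sample, genes are ranked by expression (average ranks for ties;
    the most expressed gene holds the largest rank). Walking genes from
    highest to lowest expression, the running statistic is the cumulative
    rank^``weight_exponent``-weighted ECDF of in-set genes minus the
    cumulative (unweighted) ECDF of out-of-set genes; the enrichment score is
    the sum of that running difference over all positions. With
    ``normalize=True`` all scores are divided by the score range (max - min)
    across samples.

    Signature symbols are matched case-insensitively after trimming; symbols
    absent from the matrix are dropped with a warning, and an error is raised
    if none remain. ``expr`` is genes x samples.
    """
    if expr.shape[0] < 2:
        raise ValueError("expression matrix must contain at least 2 genes")
    upper_index = pd.Index([str(g).strip().upper() for g in expr.index])
    wanted = {g.strip().upper() for g in signature.genes}
    in_set = np.asarray(upper_index.isin(wanted))
    found = set(upper_index[in_set])
    missing = sorted(wanted - found)
    if len(missing) == len(wanted):
        raise ValueError(
            f"no gene of signature {signature.name!r} present in the matrix"
        )
    if missing:
        logger.warning(
            "signature %s: %d symbol(s) absent from the matrix: %s",
            signature.name, len(missing), ", ".join(missing),
        )

    x = expr.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    n_in = int(in_set.sum())
    n_out = n_genes - n_in
    scores = np.empty(n_samples)
    for j in range(n_samples):
        col = x[:, j]
        ranks = stats.rankdata(col)  # ascending average ranks; max = highest expr
        order = np.argsort(-ranks, kind="stable")  # descending expression walk
        in_walk = in_set[order]
        w = ranks[order] ** weight_exponent
        num_in = np.cumsum(np.where(in_walk, w, 0.0))
        denom_in = num_in[-1]
        cdf_in = num_in / denom_in
        cdf_out = np.cumsum(~in_walk) / n_out
        scores[j] = np.sum(cdf_in - cdf_out)
    out = pd.Series(scores, index=expr.columns, name=signature.name)
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out
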