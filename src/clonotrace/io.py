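"""Readers, cell QC, and assembly of contigs + metadata into clonotype-annotated cells.

The pipeline's in-memory unit is a :class:`pandas.DataFrame` of cells with the
columns in :data:`CELL_COLUMNS` — one row per T cell carrying a productive TCR,
annotated with its sample/patient/compartment/timepoint/phenotype labels and a
``clonotype_key`` that identifies cells with the same CDR3 nucleotide
sequence(s).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Column schema of a cell table (``pseudotime``/``lineage`` may be NaN).
CELL_COLUMNS = [
    "barcode",
    "sample_id",
    "patient_id",
    "compartment",
    "timepoint",
    "phenotype",
    "response",
    "clonotype_key",
    "pseudotime",
    "lineage",
]

#: Metadata columns expected in the per-cell metadata TSV.
META_COLUMNS = [
    "barcode",
    "sample_id",
    "patient_id",
    "compartment",
    "timepoint",
    "phenotype",
    "response",
]

_CONTIG_REQUIRED = ["barcode", "chain", "cdr3_nt", "productive"]

# Spellings of "productive" seen in 10x contig CSVs across CellRanger versions.
_PRODUCTIVE_TRUE = {"true", "t", "yes", "1"}

#: Phenotype labels excluded from clonotype analysis: cells whose TCR locus is
#: invariant or whose receptor is not an alpha/beta TCR (NK, gamma-delta, MAIT).
RESTRICTIVE_PHENOTYPE_PATTERN = re.compile(
    r"(?:^|[\s_])NK(?:[\s_]|$)|^NK|gamma.?delta|γδ|(?:^|[\s_])GD[\s_]?T|MAIT",
    re.IGNORECASE,
)


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class QCPreset:
    """Cell-quality thresholds for droplet-based single-cell data."""

    min_genes: int = 200
    max_genes: int = 6000
    min_umi: int = 400
    max_pct_mito: float = 50.0


#: Named presets: tumour biopsies tolerate higher mitochondrial content than PBMCs.
QC_PRESETS = {
    "biopsy": QCPreset(200, 6000, 400, 50.0),
    "pbmc": QCPreset(200, 6000, 400, 15.0),
}


@dataclass
class ClonotypeCallTally:
    """Bookkeeping from :func:`call_clonotypes`."""

    n_cells_in: int = 0
    n_no_productive: int = 0
    n_missing_meta: int = 0
    n_restrictive: int = 0
    n_na_phenotype: int = 0
    n_cells_out: int = 0
    missing_barcodes: list = field(default_factory=list)


def read_contigs(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a 10x ``filtered_contig_annotations.csv``-dialect contig table.

    Parameters
    ----------
    path
        CSV with at least ``barcode, chain, cdr3_nt, productive`` columns;
        extra columns are ignored.
    sample_id
        Sample label attached to every contig.

    Returns
    -------
    DataFrame with columns ``barcode, chain, cdr3_nt, productive, sample_id``;
    ``productive`` is boolean (the dialect's True/true/TRUE spellings parse as
    true, anything else — including "None" and "False" — as false).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CONTIG_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required contig column(s): {', '.join(missing)}"
        )
    out = df[_CONTIG_REQUIRED].copy()
    out["productive"] = (
        out["productive"].str.strip().str.lower().isin(_PRODUCTIVE_TRUE)
    )
    out["chain"] = out["chain"].where(out["chain"].isin(["TRA", "TRB"]), "other")
    out["sample_id"] = sample_id
    bad = out["productive"] & (out["cdr3_nt"].str.len() == 0)
    if bad.any():
        raise FormatError(f"{path}: {int(bad.sum())} productive contig(s) with empty cdr3_nt")
    return out.reset_index(drop=True)


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata TSV (one row per barcode x sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {', '.join(missing)}")
    if "pseudotime" in df.columns:
        df["pseudotime"] = pd.to_numeric(df["pseudotime"], errors="coerce")
    else:
        df["pseudotime"] = float("nan")
    if "lineage" not in df.columns:
        df["lineage"] = ""
    dup = df.duplicated(subset=["barcode", "sample_id"])
    if dup.any():
        raise FormatError(f"{path}: duplicated (barcode, sample_id) rows")
    return df


def read_qc_table(path: str | Path) -> pd.DataFrame:
    """Read a QC TSV with columns ``barcode, n_genes, n_umi, pct_mito``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("barcode", "n_genes", "n_umi", "pct_mito") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing QC column(s): {', '.join(missing)}")
    return df


def qc_filter_cells(
    qc: pd.DataFrame,
    min_genes: int = 200,
    max_genes: int = 6000,
    min_umi: int = 400,
    max_pct_mito: float = 50.0,
) -> pd.DataFrame:
    """Filter barcodes on gene/UMI counts and mitochondrial content.

    Retains rows with ``min_genes <= n_genes <= max_genes``, ``n_umi >= min_umi``
    and ``pct_mito <= max_pct_mito``; input order is preserved. Defaults are the
    biopsy preset (droplets with <200 or >6000 genes, <400 UMIs, or >50%
    mitochondrial reads removed).
    """
    if min_genes <= 0 or max_genes <= 0 or min_umi <= 0:
        raise ValueError("QC thresholds must be positive")
    if min_genes >= max_genes:
        raise ValueError("min_genes must be < max_genes")
    keep = (
        (qc["n_genes"] >= min_genes)
        & (qc["n_genes"] <= max_genes)
        & (qc["n_umi"] >= min_umi)
        & (qc["pct_mito"] <= max_pct_mito)
    )
    return qc.loc[keep].copy()


def _paired_key(cdr3s: tuple[str, ...]) -> str:
    return "_".join(sorted(cdr3s))


def call_clonotypes(
    contigs: pd.DataFrame,
    meta: pd.DataFrame,
    identity_mode: str = "paired",
) -> tuple[pd.DataFrame, ClonotypeCallTally]:
    """Assemble contigs + metadata into clonotype-annotated cells.

    Only cells with >= 1 productive contig are kept; cells annotated as NK,
    gamma-delta T or MAIT ("restrictive TCR" phenotypes) are excluded, as are
    cells with no phenotype annotation.

    ``identity_mode`` controls clonotype identity:

    ``paired`` (default)
        the clonotype key is the lexicographically sorted, "_"-joined set of
        the cell's productive CDR3 nucleotide sequences (CellRanger-style
        strict identity);
    ``any_chain``
        cells are merged into one clonotype whenever they share any single
        productive CDR3 nucleotide sequence (single-linkage over chains); the
        key is the lexicographically smallest CDR3 of the component.

    Returns the cell DataFrame (:data:`CELL_COLUMNS`) and a tally of drops.
    """
    if identity_mode not in ("paired", "any_chain"):
        raise ValueError(f"unknown identity_mode: {identity_mode!r}")

    prod = contigs.loc[contigs["productive"] & (contigs["cdr3_nt"].str.len() > 0)]
    per_cell = (
        prod.groupby(["sample_id", "barcode"], sort=True)["cdr3_nt"]
        .apply(lambda s: tuple(sorted(set(s))))
    )
    tally = ClonotypeCallTally(
        n_cells_in=contigs.groupby(["sample_id", "barcode"]).ngroups
    )
    tally.n_no_productive = tally.n_cells_in - len(per_cell)

    meta_idx = meta.set_index(["sample_id", "barcode"])
    if meta_idx.index.has_duplicates:
        raise FormatError("metadata has duplicated (sample_id, barcode) rows")

    rows = []
    keys: list[tuple[str, ...]] = []
    for (sample_id, barcode), cdr3s in per_cell.items():
        try:
            m = meta_idx.loc[(sample_id, barcode)]
        except KeyError:
            tally.n_missing_meta += 1
            tally.missing_barcodes.append((sample_id, barcode))
            continue
        phenotype = str(m["phenotype"]).strip()
        if not phenotype or phenotype.upper() in ("NA", "NAN"):
            tally.n_na_phenotype += 1
            continue
        if RESTRICTIVE_PHENOTYPE_PATTERN.search(phenotype):
            tally.n_restrictive += 1
            continue
        rows.append(
            {
                "barcode": barcode,
                "sample_id": sample_id,
                "patient_id": m["patient_id"],
                "compartment": m["compartment"],
                "timepoint": m["timepoint"],
                "phenotype": phenotype,
                "response": m["response"],
                "pseudotime": m.get("pseudotime", float("nan")),
                "lineage": m.get("lineage", ""),
            }
        )
        keys.append(cdr3s)

    if tally.n_missing_meta:
        logger.warning(
            "%d cell(s) with productive contigs had no metadata row and were dropped",
            tally.n_missing_meta,
        )
    if tally.n_na_phenotype:
        logger.info("%d cell(s) dropped for missing phenotype annotation", tally.n_na_phenotype)

    cells = pd.DataFrame(rows, columns=[c for c in CELL_COLUMNS if c != "clonotype_key"])
    if identity_mode == "paired":
        cells["clonotype_key"] = [_paired_key(k) for k in keys]
    else:
        cells["clonotype_key"] = _any_chain_keys(keys)
    cells = cells[CELL_COLUMNS]
    tally.n_cells_out = len(cells)
    return cells.reset_index(drop=True), tally


def _any_chain_keys(cdr3_sets: list[tuple[str, ...]]) -> list[str]:
    """Single-linkage clonotype keys: cells sharing any CDR3nt merge."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic: smaller string wins as root
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    for cdr3s in cdr3_sets:
        for c in cdr3s:
            parent.setdefault(c, c)
        for c in cdr3s[1:]:
            union(cdr3s[0], c)
    # key of a component = lexicographically smallest member CDR3
    smallest: dict[str, str] = {}
    for c in parent:
        r = find(c)
        if r not in smallest or c < smallest[r]:
            smallest[r] = c
    return [smallest[find(cdr3s[0])] for cdr3s in cdr3_sets]


def drop_cross_patient_clonotypes(cells: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Remove clonotypes observed in two or more distinct patients.

    Public (cross-patient) CDR3 sequences are more likely invariant or
    artefactual than tumour-relevant, so every cell carrying such a key is
    removed. Returns the filtered cells and the removed key set.
    """
    n_patients = cells.groupby("clonotype_key")["patient_id"].nunique()
    removed = set(n_patients.index[n_patients >= 2])
    kept = cells.loc[~cells["clonotype_key"].isin(removed)].copy()
    if removed:
        logger.info(
            "%d clonotype(s) shared between >=2 patients removed (%d cells)",
            len(removed),
            len(cells) - len(kept),
        )
    return kept.reset_index(drop=True), removed


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as TSV (round-trips through :func:`read_cells`)."""
    cells.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a cell table written by :func:`write_cells`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cell column(s): {', '.join(missing)}")
    df["pseudotime"] = pd.to_numeric(df["pseudotime"], errors="coerce")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Accepts a TSV with gene symbols in the first column, or a MatrixMarket
    ``.mtx`` file accompanied by ``genes.txt`` and ``samples.txt`` in the same
    directory (one name per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = mmread(path).toarray()
        genes = (path.parent / "genes.txt").read_text().split()
        samples = (path.parent / "samples.txt").read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise FormatError(f"{path}: matrix shape {mat.shape} does not match name files")
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival CSV: ``sample_id, arm, os_time, os_event, pfs_time, pfs_event``."""
    df = pd.read_csv(path)
    required = ["sample_id", "arm", "os_time", "os_event", "pfs_time", "pfs_event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing survival column(s): {', '.join(missing)}")
    return df
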