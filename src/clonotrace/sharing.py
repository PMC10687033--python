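"""Tumour-blood clonotype sharing and longitudinal clonotype tracking.

Sharing is exact clonotype-key intersection between a patient's tumour
repertoire and a peripheral-blood repertoire. The "tumour-specific shared"
designation is always anchored at pre-treatment blood (week 0); later
timepoints are tracked separately so that treatment-induced clones never feed
the baseline shared set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .repertoire import ClonotypeTable, build_tables

logger = logging.getLogger(__name__)

#: Blood timepoints, in sampling order.
TIMEPOINTS = ("W0", "W3", "W6")


@dataclass
class SharingResult:
    """Clonotype sharing between one patient's tumour and one blood sample."""

    patient_id: str
    timepoint: str
    shared_keys: set[str]
    prop_shared_tcrs_tumour: float
    prop_shared_tcrs_blood: float
    prop_shared_cells_blood: float
    per_phenotype_tumour: dict[str, float] = field(default_factory=dict)


@dataclass
class TrackedClonotypes:
    """Blood abundance of one tumour phenotype's clonotypes over timepoints.

    ``per_timepoint`` maps W0/W3/W6 to ``(n_matching, n_total, fraction)``;
    timepoints with no blood sample are absent from the map (not zero).
    """

    patient_id: str
    source_phenotype: str
    per_timepoint: dict[str, tuple[int, int, float]] = field(default_factory=dict)


def _merge_tables(tables: list[ClonotypeTable], sample_id: str) -> ClonotypeTable:
    counts: dict[str, int] = {}
    for t in tables:
        for k, n in t.counts.items():
            counts[k] = counts.get(k, 0) + n
    return ClonotypeTable(sample_id=sample_id, counts=counts)


def baseline_sharing(
    cells: pd.DataFrame,
    timepoint: str = "W0",
    merge_multiple_biopsies: bool = True,
) -> list[SharingResult]:
    """Per-patient clonotype sharing between tumour and blood at ``timepoint``.

    For each patient with both a tumour repertoire and a blood sample at the
    requested timepoint, computes the shared key set and four proportions:
    shared / unique tumour TCRs, shared / unique blood TCRs, blood cells
    carrying a shared TCR / blood cells with a productive TCR, and the
    per-tumour-phenotype fraction of cells carrying a shared TCR. Patients
    lacking either compartment are omitted with a logged reason.

    Multiple tumour samples of one patient are merged into one repertoire by
    default; set ``merge_multiple_biopsies=False`` to raise instead.
    """
    results = []
    for patient_id, grp in cells.groupby("patient_id", sort=True):
        tumour = grp.loc[grp["compartment"] == "tumour"]
        blood = grp.loc[
            (grp["compartment"] == "pbmc") & (grp["timepoint"] == timepoint)
        ]
        if tumour.empty or blood.empty:
            logger.info(
                "patient %s omitted from sharing: missing %s",
                patient_id,
                "tumour" if tumour.empty else f"blood {timepoint}",
            )
            continue
        if tumour["sample_id"].nunique() > 1 and not merge_multiple_biopsies:
            raise ValueError(
                f"patient {patient_id}: multiple tumour samples and merging disabled"
            )
        if blood["sample_id"].nunique() > 1 and not merge_multiple_biopsies:
            raise ValueError(
                f"patient {patient_id}: multiple blood samples at {timepoint}"
            )
        t_tab = _merge_tables(build_tables(tumour), f"{patient_id}_tumour")
        b_tab = _merge_tables(build_tables(blood), f"{patient_id}_{timepoint}")
        shared = t_tab.keys & b_tab.keys
        n_shared_blood_cells = sum(b_tab.counts[k] for k in shared)
        results.append(
            SharingResult(
                patient_id=patient_id,
                timepoint=timepoint,
                shared_keys=shared,
                prop_shared_tcrs_tumour=len(shared) / t_tab.n_clonotypes,
                prop_shared_tcrs_blood=len(shared) / b_tab.n_clonotypes,
                prop_shared_cells_blood=n_shared_blood_cells / b_tab.n_cells,
                per_phenotype_tumour=phenotype_shared_fraction(tumour, shared),
            )
        )
    return results


def phenotype_shared_fraction(
    cells: pd.DataFrame, shared_keys: set[str]
) -> dict[str, float]:
    """Per phenotype, fraction of cells whose clonotype is in ``shared_keys``.

    Phenotypes with zero cells are omitted.
    """
    out = {}
    for phenotype, grp in cells.groupby("phenotype", sort=True):
        out[phenotype] = float(grp["clonotype_key"].isin(shared_keys).mean())
    return out


def pooled_phenotype_shared_fraction(
    cells: pd.DataFrame, results: list[SharingResult]
) -> tuple[dict[str, float], dict[str, float]]:
    """Cohort-level per-phenotype shared fractions.

    Returns ``(pooled, per_patient_mean)``: *pooled* counts shared cells over
    all patients' tumour cells of each phenotype; *per_patient_mean* averages
    each patient's own fraction. Both reductions are reported because cohort
    summaries of per-phenotype sharing depend on this choice.
    """
    shared_by_patient = {r.patient_id: r.shared_keys for r in results}
    tumour = cells.loc[
        (cells["compartment"] == "tumour")
        & cells["patient_id"].isin(shared_by_patient)
    ].copy()
    tumour["is_shared"] = [
        key in shared_by_patient[pat]
        for pat, key in zip(tumour["patient_id"], tumour["clonotype_key"])
    ]
    pooled = tumour.groupby("phenotype")["is_shared"].mean().to_dict()
    per_pat = (
        tumour.groupby(["patient_id", "phenotype"])["is_shared"]
        .mean()
        .groupby("phenotype")
        .mean()
        .to_dict()
    )
    return pooled, per_pat


def track_clonotypes(
    tumour_cells: pd.DataFrame,
    blood_cells: pd.DataFrame,
    source_phenotype: str,
    denominator_phenotypes: set[str] | None = None,
) -> TrackedClonotypes:
    """Track one tumour phenotype's clonotypes through blood timepoints.

    Collects the unique clonotype keys of tumour cells with phenotype
    ``source_phenotype``; at each blood timepoint with a sample, counts blood
    cells (restricted to ``denominator_phenotypes``; default: all phenotypes
    present in blood) carrying those keys, over the timepoint's denominator
    cell count.
    """
    valid = sorted(set(tumour_cells["phenotype"]))
    if source_phenotype not in valid:
        raise ValueError(
            f"unknown source phenotype {source_phenotype!r}; tumour has: {valid}"
        )
    patients = set(tumour_cells["patient_id"].unique())
    patient_id = patients.pop() if len(patients) == 1 else "(pooled)"
    source_keys = set(
        tumour_cells.loc[
            tumour_cells["phenotype"] == source_phenotype, "clonotype_key"
        ]
    )
    if denominator_phenotypes is not None:
        unknown = denominator_phenotypes - set(blood_cells["phenotype"])
        if unknown:
            raise ValueError(
                f"unknown denominator phenotype(s) {sorted(unknown)}; "
                f"blood has: {sorted(set(blood_cells['phenotype']))}"
            )
        blood_cells = blood_cells.loc[
            blood_cells["phenotype"].isin(denominator_phenotypes)
        ]
    tracked = TrackedClonotypes(patient_id=patient_id, source_phenotype=source_phenotype)
    for tp in TIMEPOINTS:
        at_tp = blood_cells.loc[blood_cells["timepoint"] == tp]
        if at_tp.empty:
            continue  # no sample at this timepoint: absent, not zero
        n_total = len(at_tp)
        n_match = int(at_tp["clonotype_key"].isin(source_keys).sum())
        tracked.per_timepoint[tp] = (n_match, n_total, n_match / n_total)
    return tracked


def shared_tcr_weight(pheno_a: ClonotypeTable, pheno_b: ClonotypeTable) -> float:
    """Clonotype-overlap weight between two phenotypes along a trajectory.

    ``|keys(a) & keys(b)| / S_a`` where ``pheno_a`` is the phenotype located
    first on the trajectory; asymmetric by construction.
    """
    if pheno_a.n_clonotypes == 0:
        raise ValueError("upstream phenotype has no clonotypes")
    return len(pheno_a.keys & pheno_b.keys) / pheno_a.n_clonotypes


def sharing_frame(results: list[SharingResult]) -> pd.DataFrame:
    """Flatten sharing results into a tidy DataFrame (one row per patient)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "timepoint": r.timepoint,
                "n_shared": len(r.shared_keys),
                "prop_shared_tcrs_tumour": r.prop_shared_tcrs_tumour,
                "prop_shared_tcrs_blood": r.prop_shared_tcrs_blood,
                "prop_shared_cells_blood": r.prop_shared_cells_blood,
            }
            for r in results
        ]
    )
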