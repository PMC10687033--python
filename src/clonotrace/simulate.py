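"""Seeded synthetic cohort generator.

Emulates the data shape of a paired tumour / peripheral-blood single-cell TCR
study of checkpoint-inhibitor-treated liver cancer: per-patient tumour and
week 0/3/6 blood clonotype tables with skewed (power-law) clone sizes,
response-dependent tumour-to-blood sharing, phenotype-specific expansion,
clonotype persistence across timepoints and three-lineage pseudotime, plus a
bulk expression matrix in which signature genes are shifted in a planted
"biomarker-high" stratum with correspondingly longer exponential survival.

Everything is deterministic given ``CohortConfig.seed``, and the generating
choices are recorded in a ``truth`` dict so downstream modules can be tested
against exact ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarker import builtin_signatures
from .io import CELL_COLUMNS

PHENOTYPES = ("CD8 TN", "CD8 TEM", "CD8 TEMRA", "CD8 TEX", "CD8 TRM")
LINEAGES = ("TEMRA", "TEX", "TRM")
_TERMINAL = {"CD8 TEMRA": "TEMRA", "CD8 TEX": "TEX", "CD8 TRM": "TRM"}
_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Defaults mirror the treated cohort the generator emulates: 20 patients
    (60% responders), a few hundred T cells with a productive TCR per tumour
    biopsy, ~1500 per blood sample, ~2% of tumour clonotypes re-found in
    responder blood versus ~0.5% in non-responders, TEMRA-skewed phenotype
    composition in responders, and a bulk validation set of 311 samples
    (253 treated, 58 control) whose planted biomarker-high half survives with
    exponential median ~12 months versus ~2 months.
    """

    n_patients: int = 20
    frac_responders: float = 0.6
    cells_per_tumour: int = 500
    cells_per_pbmc: int = 1500
    clone_size_alpha: float = 2.5
    sharing_rate_resp: float = 0.02
    sharing_rate_nonresp: float = 0.005
    phenotype_mix_resp: dict = dc_field(
        default_factory=lambda: {
            "CD8 TN": 0.15, "CD8 TEM": 0.20, "CD8 TEMRA": 0.30,
            "CD8 TEX": 0.20, "CD8 TRM": 0.15,
        }
    )
    phenotype_mix_nonresp: dict = dc_field(
        default_factory=lambda: {
            "CD8 TN": 0.15, "CD8 TEM": 0.35, "CD8 TEMRA": 0.10,
            "CD8 TEX": 0.25, "CD8 TRM": 0.15,
        }
    )
    shared_temra_bias: float = 0.6
    phenotype_mirror_prob: float = 0.8
    persistence: float = 0.8
    n_genes_bulk: int = 2000
    n_samples_bulk: int = 311
    frac_bulk_treated: float = 253 / 311
    frac_biomarker_high: float = 0.5
    signature_shift: float = 1.0
    survival_scale_high: float = 17.3
    survival_scale_low: float = 2.9
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_responders", "sharing_rate_resp", "sharing_rate_nonresp",
            "shared_temra_bias", "phenotype_mirror_prob", "persistence",
            "frac_biomarker_high", "censor_rate", "frac_bulk_treated",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_patients", "cells_per_tumour", "cells_per_pbmc",
            "n_genes_bulk", "n_samples_bulk",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clone_size_alpha <= 1.0:
            raise ValueError("clone_size_alpha must be > 1")
        if self.survival_scale_high <= 0 or self.survival_scale_low <= 0:
            raise ValueError("survival scales must be positive")
        for mix in (self.phenotype_mix_resp, self.phenotype_mix_nonresp):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("phenotype mix must sum to 1")
            if set(mix) != set(PHENOTYPES):
                raise ValueError(f"phenotype mix must cover {PHENOTYPES}")
        if self.cells_per_tumour < len(PHENOTYPES):
            raise ValueError("cells_per_tumour smaller than the number of phenotypes")
        if self.n_genes_bulk < 60:
            raise ValueError("n_genes_bulk must exceed the signature sizes")


@dataclass
class SyntheticCohort:
    cells: pd.DataFrame
    bulk_expr: pd.DataFrame
    survival: pd.DataFrame
    truth: dict
    config: CohortConfig


class _ClonotypeFactory:
    """Globally unique CDR3 nucleotide pairs, deterministic given the rng.

    A base-4 encoding of a global counter is appended to a random prefix so
    that no two clonotypes anywhere in the cohort collide, which makes the
    planted sharing/persistence structure exact set membership.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.counter = 0

    def new_keys(self, n: int) -> tuple[list[str], list[tuple[str, str]]]:
        """Return n (clonotype_key, (cdr3_tra, cdr3_trb)) in paired-key form."""
        keys, pairs = [], []
        for _ in range(n):
            suffix = _encode_id(self.counter)
            self.counter += 1
            tra = "".join(self.rng.choice(_NT, size=21)) + "A" + suffix
            trb = "".join(self.rng.choice(_NT, size=21)) + "C" + suffix
            pairs.append((tra, trb))
            keys.append("_".join(sorted((tra, trb))))
        return keys, pairs


def _encode_id(i: int, width: int = 12) -> str:
    out = []
    for _ in range(width):
        out.append("ACGT"[i % 4])
        i //= 4
    return "".join(out)


def _zipf_sizes(rng: np.random.Generator, alpha: float, total: int) -> np.ndarray:
    """Clone sizes from a discrete power law P(k) ∝ k^-alpha, k = 1..total,
    drawn until they cover ``total`` cells (last clone trimmed to fit)."""
    k = np.arange(1, total + 1, dtype=float)
    p = k ** (-alpha)
    p /= p.sum()
    sizes: list[int] = []
    covered = 0
    while covered < total:
        batch = rng.choice(len(k), size=max(16, (total - covered) // 2), p=p) + 1
        for s in batch:
            s = int(min(s, total - covered))
            if s <= 0:
                break
            sizes.append(s)
            covered += s
            if covered >= total:
                break
    return np.asarray(sizes, dtype=int)


def _choose_mix(rng, mix: dict, n: int) -> np.ndarray:
    labels = list(PHENOTYPES)
    probs = np.array([mix[l] for l in labels])
    return np.asarray(labels, dtype=object)[rng.choice(len(labels), size=n, p=probs)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (cells + bulk + survival + truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    factory = _ClonotypeFactory(rng)
    n_resp = int(round(config.n_patients * config.frac_responders))

    frames: list[pd.DataFrame] = []
    truth_patients: dict[str, dict] = {}
    cdr3_pairs: dict[str, tuple[str, str]] = {}

    for p in range(config.n_patients):
        patient_id = f"P{p + 1:03d}"
        responder = p < n_resp
        response = "responder" if responder else "non_responder"
        mix = config.phenotype_mix_resp if responder else config.phenotype_mix_nonresp
        share_rate = (
            config.sharing_rate_resp if responder else config.sharing_rate_nonresp
        )

        # --- tumour repertoire -------------------------------------------------
        t_sizes = _zipf_sizes(rng, config.clone_size_alpha, config.cells_per_tumour)
        t_keys, t_pairs = factory.new_keys(len(t_sizes))
        cdr3_pairs.update(dict(zip(t_keys, t_pairs)))
        shared_mask = rng.random(len(t_keys)) < share_rate
        phenos = _choose_mix(rng, mix, len(t_keys))
        if responder and config.shared_temra_bias > 0:
            # planted shared clones in responders lean TEMRA in both compartments
            to_temra = shared_mask & (rng.random(len(t_keys)) < config.shared_temra_bias)
            phenos[to_temra] = "CD8 TEMRA"
        tumour_pheno_of = dict(zip(t_keys, phenos))
        shared_keys = [k for k, m in zip(t_keys, shared_mask) if m]

        frames.append(
            _cells_frame(
                sample_id=f"{patient_id}_T",
                patient_id=patient_id,
                compartment="tumour",
                timepoint="W0",
                response=response,
                keys=np.repeat(t_keys, t_sizes),
                phenotypes=np.repeat(phenos, t_sizes),
            )
        )

        # --- blood, week 0 then persistence to W3/W6 ---------------------------
        blood_tables: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = {}
        prev_keys: list[str] = []
        for tp in ("W0", "W3", "W6"):
            if tp == "W0":
                base_keys = list(shared_keys)
            else:
                keep = rng.random(len(prev_keys)) < config.persistence
                base_keys = [k for k, m in zip(prev_keys, keep) if m]
            base_sizes = 1 + rng.geometric(0.6, size=len(base_keys))
            n_base = int(base_sizes.sum()) if len(base_keys) else 0
            # trim planted clones if they alone exceed the sample size
            while n_base > config.cells_per_pbmc and len(base_keys) > 0:
                base_keys, base_sizes = base_keys[:-1], base_sizes[:-1]
                n_base = int(base_sizes.sum())
            n_fill = config.cells_per_pbmc - n_base
            fill_sizes = (
                _zipf_sizes(rng, config.clone_size_alpha, n_fill)
                if n_fill > 0
                else np.empty(0, dtype=int)
            )
            fill_keys, fill_pairs = factory.new_keys(len(fill_sizes))
            cdr3_pairs.update(dict(zip(fill_keys, fill_pairs)))

            base_phenos = np.empty(len(base_keys), dtype=object)
            for i, k in enumerate(base_keys):
                if k in tumour_pheno_of and rng.random() < config.phenotype_mirror_prob:
                    base_phenos[i] = tumour_pheno_of[k]
                else:
                    base_phenos[i] = _choose_mix(rng, mix, 1)[0]
            fill_phenos = _choose_mix(rng, mix, len(fill_keys))

            keys = list(base_keys) + list(fill_keys)
            sizes = np.concatenate([base_sizes[: len(base_keys)], fill_sizes]).astype(int)
            phenos_b = np.concatenate([base_phenos, fill_phenos])
            blood_tables[tp] = (keys, sizes, phenos_b)
            prev_keys = keys
            frames.append(
                _cells_frame(
                    sample_id=f"{patient_id}_PBMC_{tp}",
                    patient_id=patient_id,
                    compartment="pbmc",
                    timepoint=tp,
                    response=response,
                    keys=np.repeat(keys, sizes),
                    phenotypes=np.repeat(phenos_b, sizes),
                )
            )

        truth_patients[patient_id] = {
            "response": response,
            "shared_keys": sorted(shared_keys),
            "n_tumour_clonotypes": len(t_keys),
            "realized_sharing_rate": len(shared_keys) / len(t_keys),
            "blood_keys_w0": sorted(blood_tables["W0"][0]),
        }

    cells = pd.concat(frames, ignore_index=True)
    cells = _assign_pseudotime(cells, rng)

    bulk_expr, survival, bulk_truth = _generate_bulk(config, rng)
    truth = {
        "patients": truth_patients,
        "bulk": bulk_truth,
        "cdr3_pairs": {k: list(v) for k, v in sorted(cdr3_pairs.items())},
    }
    return SyntheticCohort(
        cells=cells, bulk_expr=bulk_expr, survival=survival, truth=truth, config=config
    )


def _cells_frame(sample_id, patient_id, compartment, timepoint, response, keys, phenotypes):
    n = len(keys)
    return pd.DataFrame(
        {
            "barcode": [f"CELL{i:06d}-1" for i in range(n)],
            "sample_id": sample_id,
            "patient_id": patient_id,
            "compartment": compartment,
            "timepoint": timepoint,
            "phenotype": phenotypes,
            "response": response,
            "clonotype_key": keys,
            "pseudotime": np.nan,
            "lineage": "",
        },
        columns=CELL_COLUMNS,
    )


# pseudotime stage windows per phenotype along a lineage
_STAGE = {"CD8 TN": (0.0, 0.25), "CD8 TEM": (0.2, 0.5)}
_TERMINAL_WINDOW = (0.4, 1.0)


def _assign_pseudotime(cells: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Three-lineage pseudotime for tumour cells.

    Terminal phenotypes sit on their own lineage; naive/effector-memory cells
    are spread across the three lineages. Cells draw uniform pseudotime within
    a phenotype stage window; responder cells on the TEMRA lineage are pushed
    toward the lineage end (square-root warp), emulating responders' capacity
    to reach the differentiated end state.
    """
    cells = cells.copy()
    n = len(cells)
    tum = (cells["compartment"] == "tumour").to_numpy()
    phen = cells["phenotype"].to_numpy()
    resp = (cells["response"] == "responder").to_numpy()

    lineage = np.full(n, "", dtype=object)
    lo = np.zeros(n)
    hi = np.zeros(n)
    on_traj = np.zeros(n, dtype=bool)
    for ph, lin in _TERMINAL.items():
        m = tum & (phen == ph)
        lineage[m] = lin
        lo[m], hi[m] = _TERMINAL_WINDOW
        on_traj |= m
    random_lin = np.asarray(LINEAGES, dtype=object)[rng.integers(0, len(LINEAGES), size=n)]
    for ph, (s_lo, s_hi) in _STAGE.items():
        m = tum & (phen == ph)
        lineage[m] = random_lin[m]
        lo[m], hi[m] = s_lo, s_hi
        on_traj |= m

    u = rng.uniform(size=n)
    warp = on_traj & resp & (lineage == "TEMRA")
    u = np.where(warp, np.sqrt(u), u)  # push toward the lineage end
    pt = np.where(on_traj, lo + (hi - lo) * u, np.nan)
    lineage[~on_traj] = ""
    cells["lineage"] = lineage
    cells["pseudotime"] = pt
    return cells


def _generate_bulk(config: CohortConfig, rng: np.random.Generator):
    """Bulk expression + survival with a planted biomarker-high stratum."""
    sig_genes = list(builtin_signatures()[2].genes)  # the 52-gene union
    n_fill = config.n_genes_bulk - len(sig_genes)
    genes = sig_genes + [f"GENE{i:05d}" for i in range(n_fill)]
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples_bulk)]

    n_high = int(round(config.n_samples_bulk * config.frac_biomarker_high))
    high = np.zeros(config.n_samples_bulk, dtype=bool)
    high[:n_high] = True
    rng.shuffle(high)
    n_treated = int(round(config.n_samples_bulk * config.frac_bulk_treated))
    arm = np.where(
        rng.permutation(config.n_samples_bulk) < n_treated, "atezo_bev", "control"
    )

    mu = rng.normal(3.0, 1.0, size=config.n_genes_bulk)  # per-gene log-mean
    log_x = mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes_bulk, len(samples)))
    log_x[: len(sig_genes), high] += config.signature_shift
    bulk = pd.DataFrame(np.exp(log_x), index=genes, columns=samples)

    scale = np.where(high, config.survival_scale_high, config.survival_scale_low)
    os_t = rng.exponential(scale)
    pfs_t = rng.exponential(scale * 0.6)
    os_cens = rng.random(len(samples)) < config.censor_rate
    pfs_cens = rng.random(len(samples)) < config.censor_rate
    os_time = np.where(os_cens, os_t * rng.random(len(samples)), os_t)
    pfs_time = np.where(pfs_cens, pfs_t * rng.random(len(samples)), pfs_t)
    survival = pd.DataFrame(
        {
            "sample_id": samples,
            "arm": arm,
            "os_time": np.maximum(os_time, 1e-6),
            "os_event": (~os_cens).astype(int),
            "pfs_time": np.maximum(pfs_time, 1e-6),
            "pfs_event": (~pfs_cens).astype(int),
        }
    )
    bulk_truth = {
        "stratum": {s: ("high" if h else "low") for s, h in zip(samples, high)},
        "n_high": int(high.sum()),
    }
    return bulk, survival, bulk_truth


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> list[str]:
    """Write a cohort to disk in the pipeline's input formats.

    Emits one contig CSV per sample, a cell-metadata TSV, the bulk expression
    TSV, the survival CSV and the truth JSON; returns the manifest (relative
    file names, sorted). The files round-trip losslessly through the readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    pairs = cohort.truth["cdr3_pairs"]
    for sample_id, grp in cohort.cells.groupby("sample_id", sort=True):
        rows = []
        for barcode, key in zip(grp["barcode"], grp["clonotype_key"]):
            tra, trb = pairs[key]
            rows.append((barcode, "TRA", "None", tra, "True", key))
            rows.append((barcode, "TRB", "None", trb, "True", key))
        contigs = pd.DataFrame(
            rows,
            columns=["barcode", "chain", "cdr3", "cdr3_nt", "productive", "raw_clonotype_id"],
        )
        name = f"{sample_id}_contigs.csv"
        contigs.to_csv(out / name, index=False)
        manifest.append(name)

    meta = cohort.cells.drop(columns=["clonotype_key"])
    meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False, float_format="%.10g")
    cohort.bulk_expr.to_csv(out / "bulk_expr.tsv", sep="\t", float_format="%.10g")
    cohort.survival.to_csv(out / "survival.csv", index=False, float_format="%.10g")
    truth = dict(cohort.truth)
    truth["config"] = dataclasses.asdict(cohort.config)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest += ["cell_meta.tsv", "bulk_expr.tsv", "survival.csv", "truth.json"]
    return sorted(manifest)
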