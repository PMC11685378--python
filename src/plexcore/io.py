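"""Cohort, parcellation and matrix I/O.

All on-disk formats are tab-delimited text: ``cohort.tsv`` (one row per
subject), ``volumes.tsv`` (subjects x regions, in ml), ``parcellation.tsv``
(node label + system label), and per-subject square matrices named
``<subject_id>_<layer>.tsv`` with a node-label header row and index column.
Missing clinical values are encoded as ``NA``.  Node identity is always
carried by label, never by position, in outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "Parcellation",
    "CohortData",
    "make_parcellation",
    "validate_cohort_table",
    "read_cohort",
    "write_cohort",
    "read_matrix",
    "write_matrix",
    "write_results",
]

GROUPS = ("HC", "MS")
PHENOTYPES = ("CIS", "RRMS", "SPMS", "PPMS", "NA")
SEXES = ("F", "M")

COHORT_COLUMNS = [
    "subject_id", "group", "phenotype", "site", "age", "sex", "tiv",
    "edss", "sdmt_z", "bpf", "tlv",
]

_SYSTEMS = (
    "visual", "somatomotor", "dorsal_attention", "ventral_attention",
    "limbic", "control", "default_mode",
)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    phenotype: str
    site: str
    age: float
    sex: str
    tiv: float
    edss: float | None = None
    sdmt_z: float | None = None
    bpf: float | None = None
    tlv: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.group == "HC":
            if self.phenotype != "NA":
                raise ValueError("HC records must have phenotype NA")
            for name in ("edss", "sdmt_z", "tlv"):
                if getattr(self, name) is not None:
                    raise ValueError(f"HC records must have missing {name}")
        if self.edss is not None:
            if not (0.0 <= self.edss <= 10.0) or (self.edss * 2) % 1 != 0:
                raise ValueError(f"EDSS must be in [0, 10] in 0.5 steps, got {self.edss}")
        if self.bpf is not None and not (0.0 < self.bpf < 1.0):
            raise ValueError(f"BPF must be in (0, 1), got {self.bpf}")
        if self.tlv is not None and self.tlv < 0:
            raise ValueError(f"TLV must be nonnegative, got {self.tlv}")


@dataclass
class Parcellation:
    node_labels: list[str]
    system_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.node_labels) != len(self.system_labels):
            raise ValueError("node and system label lists differ in length")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError("node labels must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def make_parcellation(n_nodes: int = 114) -> Parcellation:
    """Default parcellation: cortical nodes over 7 systems + subcortical.

    For the default 114 nodes this is 100 cortical + 14 subcortical regions;
    other sizes keep the same cortical/subcortical proportion.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    n_sub = int(round(n_nodes * 14 / 114))
    n_ctx = n_nodes - n_sub
    labels, systems = [], []
    for k in range(n_ctx):
        sysname = _SYSTEMS[k % len(_SYSTEMS)]
        labels.append(f"ctx-{sysname}-{k:03d}")
        systems.append(sysname)
    for k in range(n_sub):
        labels.append(f"sub-subcortical-{k:03d}")
        systems.append("subcortical")
    return Parcellation(node_labels=labels, system_labels=systems)


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Row-wise validation with row numbers in error messages."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    for rownum, row in enumerate(table.itertuples(index=False)):
        def opt(v):
            return None if pd.isna(v) else float(v)
        try:
            SubjectRecord(
                subject_id=str(row.subject_id), group=str(row.group),
                phenotype=str(row.phenotype), site=str(row.site),
                age=float(row.age), sex=str(row.sex), tiv=float(row.tiv),
                edss=opt(row.edss), sdmt_z=opt(row.sdmt_z),
                bpf=opt(row.bpf), tlv=opt(row.tlv),
            )
        except ValueError as exc:
            raise ValueError(f"cohort row {rownum}: {exc}") from exc


@dataclass
class CohortData:
    """In-memory cohort: table, volumes, per-subject SC/FC, parcellation."""

    cohort: pd.DataFrame
    volumes: pd.DataFrame
    sc: dict[str, np.ndarray]
    fc: dict[str, np.ndarray]
    parcellation: Parcellation

    def __post_init__(self) -> None:
        n = self.parcellation.n_nodes
        if list(self.volumes.columns) != self.parcellation.node_labels:
            raise ValueError("volume columns do not match parcellation labels")
        ids = list(self.cohort["subject_id"])
        if list(self.volumes.index) != ids:
            raise ValueError("volume rows do not match cohort subject order")
        for name, mats in (("sc", self.sc), ("fc", self.fc)):
            for sid in ids:
                if sid not in mats:
                    raise ValueError(f"missing {name} matrix for subject {sid}")
                m = mats[sid]
                if m.shape != (n, n):
                    raise ValueError(
                        f"{name} matrix for {sid} has shape {m.shape}, expected {(n, n)}"
                    )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.cohort["subject_id"])

    @property
    def hc_mask(self) -> np.ndarray:
        return (self.cohort["group"] == "HC").to_numpy()


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(path, weights: np.ndarray, node_labels) -> Path:
    path = Path(path)
    pd.DataFrame(weights, index=node_labels, columns=node_labels).to_csv(path, sep="\t")
    return path


def read_matrix(path, node_labels=None, *, symmetrize: bool = True) -> np.ndarray:
    """Read a square TSV matrix; symmetrize as (M + M^T)/2 and zero the diagonal."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path.name}: non-square matrix {m.shape}")
    if node_labels is not None:
        if len(node_labels) != m.shape[0]:
            raise ValueError(
                f"{path.name}: {m.shape[1]} columns for a "
                f"{len(node_labels)}-node parcellation"
            )
        if list(df.columns) != list(node_labels):
            raise ValueError(f"{path.name}: column labels do not match the parcellation")
    if symmetrize:
        asym = float(np.max(np.abs(m - m.T))) if m.size else 0.0
        if asym > 1e-6:
            logger.warning("%s: max asymmetry %.3g; storing (M + M^T)/2", path.name, asym)
        m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


# ---------------------------------------------------------------------------
# cohort round-trip
# ---------------------------------------------------------------------------

def write_cohort(out_dir, data: CohortData) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    paths = {}
    cohort = data.cohort[COHORT_COLUMNS]
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False, na_rep="NA")
    paths["cohort"] = out / "cohort.tsv"
    data.volumes.to_csv(out / "volumes.tsv", sep="\t", index_label="subject_id")
    paths["volumes"] = out / "volumes.tsv"
    parc = pd.DataFrame(
        {"node_label": data.parcellation.node_labels,
         "system_label": data.parcellation.system_labels}
    )
    parc.to_csv(out / "parcellation.tsv", sep="\t", index=False)
    paths["parcellation"] = out / "parcellation.tsv"
    labels = data.parcellation.node_labels
    for sid in data.subject_ids:
        write_matrix(mat_dir / f"{sid}_sc.tsv", data.sc[sid], labels)
        write_matrix(mat_dir / f"{sid}_fc.tsv", data.fc[sid], labels)
    paths["matrix_dir"] = mat_dir
    return paths


def read_cohort(cohort_path, volumes_path, matrix_dir, parcellation_path) -> CohortData:
    """Load a cohort from disk, validating every invariant on the way in."""
    parc_df = pd.read_csv(parcellation_path, sep="\t")
    parcellation = Parcellation(
        node_labels=list(parc_df["node_label"].astype(str)),
        system_labels=list(parc_df["system_label"].astype(str)),
    )
    # "NA" means missing only in numeric columns; in phenotype it is the
    # legitimate healthy-control level, so parse everything as text first.
    table = pd.read_csv(cohort_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("age", "tiv", "edss", "sdmt_z", "bpf", "tlv"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col].replace("NA", np.nan))
    validate_cohort_table(table)
    volumes = pd.read_csv(volumes_path, sep="\t", index_col="subject_id")
    volumes.index = volumes.index.astype(str)
    mat_dir = Path(matrix_dir)
    sc, fc = {}, {}
    for sid in table["subject_id"]:
        for layer, store in (("sc", sc), ("fc", fc)):
            path = mat_dir / f"{sid}_{layer}.tsv"
            if not path.exists():
                raise FileNotFoundError(
                    f"missing {layer.upper()} matrix for subject {sid}: {path}"
                )
            store[sid] = read_matrix(path, parcellation.node_labels)
    return CohortData(
        cohort=table, volumes=volumes, sc=sc, fc=fc, parcellation=parcellation
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_results(
    out_dir,
    coreness_table: pd.DataFrame | None = None,
    kappa_table: pd.DataFrame | None = None,
    stats_report: dict | None = None,
    prediction_report: dict | None = None,
) -> dict[str, Path]:
    """Write coreness/kappa TSVs and the JSON report with deterministic layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if coreness_table is not None:
        p = out / "coreness.tsv"
        coreness_table.to_csv(p, sep="\t", index_label="subject_id")
        paths["coreness"] = p
    if kappa_table is not None:
        p = out / "kappa.tsv"
        cols = [c for c in ("multiplex", "MC", "SC", "FC") if c in kappa_table.columns]
        kappa_table[cols].to_csv(p, sep="\t", index_label="subject_id")
        paths["kappa"] = p
    report = {"stats": stats_report or {}, "prediction": prediction_report or {}}
    p = out / "report.json"
    with open(p, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    paths["report"] = p
    return paths
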