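"""Core containers and I/O for two-color skin-biopsy expression compendia.

Expression values are log2(sample/reference) ratios throughout; readers never
re-log.  The central objects are:

* :class:`ExpressionCompendium` — a probe-level genes × arrays matrix with
  probe annotations (probe_id, gene_symbol, entrez_id).
* a *sample table* — a plain :class:`pandas.DataFrame` of per-array clinical
  and batch metadata (see :data:`SAMPLE_TABLE_COLUMNS`).
* :class:`GeneMatrix` — a matrix keyed by a single identifier space (probe or
  Entrez), produced by :func:`collapse_probes` or alignment operations.

Missing cells are permitted everywhere and represented as NaN; all means and
correlations downstream are computed pairwise-complete.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import reduce
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .signatures import PathwaySignature

logger = logging.getLogger(__name__)

#: Diagnoses recognised in sample tables.
DIAGNOSES = ("dSSc", "lSSc", "control", "morphea", "eos_fasciitis")

#: Biopsy sites recognised in sample tables.
BIOPSY_SITES = ("forearm_lesional", "back_nonlesional", "other")

#: Required column order of a metadata TSV / sample table.
SAMPLE_TABLE_COLUMNS = (
    "array_id",
    "patient_id",
    "batch",
    "diagnosis",
    "biopsy_site",
    "timepoint_label",
    "mrss",
    "age",
    "sex",
    "disease_duration_years",
    "original_subset_label",
)

#: Annotation columns that precede the per-array columns in an expression TSV.
FEATURE_COLUMNS = ("probe_id", "gene_symbol", "entrez_id")

#: Minimum fraction of non-missing values a feature needs to survive reading.
DEFAULT_MIN_PRESENT_FRACTION = 0.7


class SigscoreError(ValueError):
    """Base class for hard errors raised by the pipeline."""


@dataclass
class ExpressionCompendium:
    """Probe-level log2-ratio expression matrix with annotations.

    Parameters
    ----------
    values
        genes × arrays matrix, indexed by ``probe_id`` with ``array_id``
        columns.  NaN marks missing spots.
    features
        per-probe annotation frame indexed by ``probe_id`` with columns
        ``gene_symbol`` and ``entrez_id`` (empty string = unannotated).
    cohort
        optional cohort/batch label for a single-source compendium; set by
        readers and consumed by :func:`merge_compendia`.
    batches
        per-array cohort label (indexed by ``array_id``); populated on merged
        compendia.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    cohort: str | None = None
    batches: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise SigscoreError(f"duplicate probe_id(s): {list(dupes[:5])}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise SigscoreError(f"duplicate array_id(s): {list(dupes[:5])}")
        if not self.features.index.equals(self.values.index):
            self.features = self.features.reindex(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_arrays(self, array_ids: Sequence[str]) -> "ExpressionCompendium":
        sub = self.values.loc[:, list(array_ids)]
        batches = self.batches.loc[list(array_ids)] if self.batches is not None else None
        return ExpressionCompendium(sub, self.features.copy(), self.cohort, batches)


@dataclass
class GeneMatrix:
    """Expression matrix keyed by a single identifier space."""

    values: pd.DataFrame
    id_space: Literal["probe", "entrez"]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise SigscoreError("GeneMatrix index must be unique")

    @property
    def ids(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class OverlapReport:
    """Bookkeeping for signature ↔ compendium alignment."""

    n_signature_ids: int
    n_matched: int

    @property
    def percent_overlap(self) -> float:
        return round(100.0 * self.n_matched / self.n_signature_ids, 1)


@dataclass(frozen=True)
class CohortSummary:
    """Counts describing a biopsy compendium's sample table."""

    n_arrays: int
    n_unique_biopsies: int
    n_patients: int
    patients_per_diagnosis: Mapping[str, int]
    conflicting_diagnosis_patients: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    format: Literal["tsv", "gct"] = "tsv",
    min_present_fraction: float = DEFAULT_MIN_PRESENT_FRACTION,
    cohort: str | None = None,
) -> ExpressionCompendium:
    """Read a log2-ratio expression matrix.

    The TSV dialect has header ``probe_id  gene_symbol  entrez_id  <array_id>…``
    with empty strings marking missing cells.  GCT 1.2 is supported as a
    degenerate dialect (Name → probe_id, Description → gene_symbol, no Entrez).
    Features present in fewer than ``min_present_fraction`` of arrays are
    dropped (a stand-in spot-quality filter; set to 0 to disable).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gct":
        df = pd.read_csv(path, sep="\t", skiprows=2, dtype={"Name": str, "Description": str})
        df = df.rename(columns={"Name": "probe_id", "Description": "gene_symbol"})
        df.insert(2, "entrez_id", "")
    else:
        df = pd.read_csv(
            path, sep="\t", dtype={c: str for c in FEATURE_COLUMNS}, keep_default_na=False
        )
        if tuple(df.columns[:3]) != FEATURE_COLUMNS:
            raise SigscoreError(
                f"expected leading columns {FEATURE_COLUMNS}, got {tuple(df.columns[:3])}"
            )
    probe_ids = df["probe_id"]
    if probe_ids.duplicated().any():
        dupes = probe_ids[probe_ids.duplicated()].unique()
        raise SigscoreError(f"duplicate probe_id(s) in {path.name}: {list(dupes[:5])}")
    value_cols = [c for c in df.columns if c not in FEATURE_COLUMNS]
    raw = df[value_cols].replace("", np.nan)
    try:
        values = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in value_cols:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SigscoreError(
                    f"non-numeric value {raw[col].iloc[row]!r} at probe "
                    f"{probe_ids.iloc[row]!r}, array {col!r} in {path.name}"
                )
        raise  # pragma: no cover - unreachable
    values.index = pd.Index(probe_ids, name="probe_id")
    values.columns.name = "array_id"
    features = df[["gene_symbol", "entrez_id"]].fillna("").astype(str)
    features.index = values.index

    if min_present_fraction > 0 and values.shape[1] > 0:
        present = values.notna().mean(axis=1)
        keep = present >= min_present_fraction
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("read_expression: dropped %d/%d low-coverage features", n_dropped, len(keep))
        values, features = values.loc[keep], features.loc[keep]

    logger.info("read_expression: %s -> %d features x %d arrays", path.name, *values.shape)
    return ExpressionCompendium(values, features, cohort=cohort)


def write_expression(c: ExpressionCompendium, path: str | Path) -> None:
    """Write a compendium in the expression TSV dialect (empty cell = missing)."""
    out = pd.concat([c.features, c.values], axis=1)
    out.insert(0, "probe_id", c.values.index)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a metadata TSV with exactly the sample-table columns."""
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "patient_id": str, "batch": str})
    return validate_sample_table(df)


def write_sample_table(s: pd.DataFrame, path: str | Path) -> None:
    s.to_csv(path, sep="\t", index=False, na_rep="")


def validate_sample_table(s: pd.DataFrame) -> pd.DataFrame:
    """Check sample-table invariants; returns the frame with canonical columns."""
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in s.columns]
    if missing:
        raise SigscoreError(f"sample table missing columns: {missing}")
    s = s.loc[:, list(SAMPLE_TABLE_COLUMNS)].copy()
    if s["array_id"].duplicated().any():
        dupes = s.loc[s["array_id"].duplicated(), "array_id"].unique()
        raise SigscoreError(f"duplicate array_id(s) in sample table: {list(dupes[:5])}")
    bad_dx = set(s["diagnosis"].dropna()) - set(DIAGNOSES)
    if bad_dx:
        raise SigscoreError(f"unknown diagnosis value(s): {sorted(bad_dx)}")
    mrss = pd.to_numeric(s["mrss"], errors="coerce")
    if (mrss.dropna() < 0).any():
        raise SigscoreError("mrss must be >= 0 or missing")
    dur = pd.to_numeric(s["disease_duration_years"], errors="coerce")
    if (dur.dropna() < 0).any():
        raise SigscoreError("disease_duration_years must be >= 0 or missing")
    return s


# ---------------------------------------------------------------------------
# probe collapsing and alignment
# ---------------------------------------------------------------------------

def collapse_probes(
    c: ExpressionCompendium, id_space: Literal["entrez"] = "entrez"
) -> GeneMatrix:
    """Collapse a probe-level compendium to one row per Entrez gene.

    Probes lacking an Entrez annotation are dropped; each retained gene's row
    is the arithmetic mean over that gene's probes, computed per array over
    non-missing values only.
    """
    if id_space != "entrez":
        raise SigscoreError(f"unsupported id_space for collapsing: {id_space}")
    entrez = c.features["entrez_id"].astype(str)
    keep = (entrez != "") & (entrez != "nan")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unannotated probes", n_dropped)
    if not keep.any():
        raise SigscoreError("collapse_probes: no probes carry an entrez_id")
    collapsed = c.values.loc[keep].groupby(entrez[keep].astype(str)).mean()
    collapsed.index.name = "entrez_id"
    return GeneMatrix(collapsed, id_space="entrez")


def as_gene_matrix(obj: ExpressionCompendium | GeneMatrix) -> GeneMatrix:
    """View a compendium as a probe-space GeneMatrix (no copy of semantics)."""
    if isinstance(obj, GeneMatrix):
        return obj
    return GeneMatrix(obj.values, id_space="probe")


def align_to_signature(
    g: ExpressionCompendium | GeneMatrix, sig: "PathwaySignature"
) -> tuple[GeneMatrix, "PathwaySignature", OverlapReport]:
    """Restrict a matrix and a signature to their shared identifiers.

    The output rows follow the signature's member order on both sides so that
    centroid vectors and matrix rows can be correlated positionally.
    """
    gm = as_gene_matrix(g)
    if sig.id_space != gm.id_space:
        if gm.id_space == "probe" and sig.id_space == "entrez" and isinstance(g, ExpressionCompendium):
            gm = collapse_probes(g)
        else:
            raise SigscoreError(
                f"signature id_space {sig.id_space!r} incompatible with matrix {gm.id_space!r}"
            )
    matched = [i for i in sig.member_ids if i in gm.ids]
    report = OverlapReport(n_signature_ids=len(sig.member_ids), n_matched=len(matched))
    if not matched:
        raise SigscoreError(f"signature {sig.name!r} shares no identifiers with the matrix")
    sub = GeneMatrix(gm.values.loc[matched], id_space=gm.id_space)
    return sub, sig.subset(matched), report


def merge_compendia(
    cs: Sequence[ExpressionCompendium],
    join: Literal["probe", "entrez"] = "probe",
) -> ExpressionCompendium:
    """Inner-join ≥ 2 compendia on shared features; columns concatenate.

    Each source's ``cohort`` label (or ``batch{i}``) becomes the batch label of
    its arrays, recorded in the merged compendium's ``batches`` series.  Only
    features present in every source survive — the compendium intersection
    semantics of multi-platform merges.
    """
    if len(cs) < 2:
        raise SigscoreError("merge_compendia requires >= 2 compendia")
    all_ids = [a for c in cs for a in c.array_ids]
    if len(set(all_ids)) != len(all_ids):
        seen: set[str] = set()
        dupes = []
        for a in all_ids:
            if a in seen:
                dupes.append(a)
            seen.add(a)
        raise SigscoreError(f"overlapping array_ids across compendia: {sorted(set(dupes))[:5]}")

    if join == "entrez":
        mats = [collapse_probes(c).values for c in cs]
        feats = None
    else:
        mats = [c.values for c in cs]
        feats = [c.features for c in cs]

    shared = reduce(lambda a, b: a.intersection(b), (m.index for m in mats))
    shared = mats[0].index[mats[0].index.isin(shared)]  # keep first source's order
    for i, m in enumerate(mats):
        logger.info("merge_compendia: source %d drops %d features", i, m.shape[0] - len(shared))
    values = pd.concat([m.loc[shared] for m in mats], axis=1)
    batch_labels = []
    for i, c in enumerate(cs):
        label = c.cohort if c.cohort is not None else f"batch{i + 1}"
        batch_labels.extend([label] * c.n_arrays)
    batches = pd.Series(batch_labels, index=values.columns, name="batch")
    if feats is not None:
        features = feats[0].loc[shared]
    else:
        features = pd.DataFrame(
            {"gene_symbol": "", "entrez_id": shared}, index=shared
        )
    return ExpressionCompendium(values, features, batches=batches)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

def summarize_cohort(s: pd.DataFrame) -> CohortSummary:
    """Count arrays, unique biopsies and patients, with per-diagnosis splits.

    A biopsy is identified by (patient, site, time point); technical replicates
    of one biopsy therefore count once.  A patient whose diagnosis differs
    across arrays is flagged and counted once under the last-recorded
    diagnosis (table order stands in for chronology).
    """
    if len(s) == 0:
        return CohortSummary(0, 0, 0, {})
    s = validate_sample_table(s)
    biopsy_key = s[["patient_id", "biopsy_site", "timepoint_label"]].astype(str).agg("|".join, axis=1)
    per_patient = s.groupby("patient_id", sort=False)["diagnosis"]
    conflicts = tuple(pid for pid, dx in per_patient if dx.nunique() > 1)
    final_dx = per_patient.last()
    counts = final_dx.value_counts().to_dict()
    return CohortSummary(
        n_arrays=len(s),
        n_unique_biopsies=int(biopsy_key.nunique()),
        n_patients=int(s["patient_id"].nunique()),
        patients_per_diagnosis=counts,
        conflicting_diagnosis_patients=conflicts,
    )
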