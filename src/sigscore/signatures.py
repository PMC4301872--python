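"""Pathway gene signatures from agonist time courses in dermal fibroblasts.

A signature is the set of genes durably induced or repressed by one agonist:
membership requires a ≥ fold_threshold mean change at BOTH the 12 h and 24 h
time points, plus an average trajectory correlation > pattern_r against an
idealized sustained-induction pattern (0 at baselines, full induction from
2 h on).  Each member carries a centroid value — the mean of its 12 h and
24 h log2 fold changes across replicates — which is the reference vector for
correlation scoring of biopsies.

Externally defined gene lists (e.g. an in-vivo drug response signature) are
imported as-is with ±1 weights; the fold/pattern gates do not apply to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SigscoreError

logger = logging.getLogger(__name__)

HOURS_DEFAULT = (0.0, 0.0, 0.0, 2.0, 4.0, 8.0, 12.0, 24.0)


@dataclass
class TimeCourseSet:
    """Replicate agonist time courses over a common gene set.

    Each replicate course is a genes × timepoints frame whose columns align
    positionally with ``hours``; hour 0 columns are the (triplicate) baseline.
    """

    courses: list[pd.DataFrame]
    hours: tuple[float, ...] = HOURS_DEFAULT
    agonist: str = ""
    cell_lines: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.courses:
            raise SigscoreError("TimeCourseSet needs >= 1 replicate course")
        if any(h2 < h1 for h1, h2 in zip(self.hours, self.hours[1:])):
            raise SigscoreError("hour labels must be non-decreasing")
        if 0.0 not in self.hours:
            raise SigscoreError("TimeCourseSet needs >= 1 baseline (0 h) column")
        for rep in self.courses:
            if rep.shape[1] != len(self.hours):
                raise SigscoreError("each course must have one column per hour label")

    @property
    def n_replicates(self) -> int:
        return len(self.courses)

    @property
    def baseline_mask(self) -> np.ndarray:
        return np.asarray(self.hours) == 0.0


@dataclass
class PathwaySignature:
    """A named gene set with directions and centroid values.

    ``members`` is indexed by gene identifier with columns ``direction``
    (up/down) and ``centroid`` (mean 12/24 h log2FC for derived signatures,
    ±weight for imported ones).
    """

    name: str
    id_space: Literal["probe", "entrez"]
    members: pd.DataFrame
    provenance: Literal["derived", "imported"] = "derived"
    fold_threshold: float = 2.0
    pattern_correlation_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.members.index.duplicated().any():
            dupes = self.members.index[self.members.index.duplicated()].unique()
            raise SigscoreError(f"duplicate signature IDs: {list(dupes[:5])}")
        cent = self.members["centroid"].to_numpy(dtype=float)
        direc = self.members["direction"].to_numpy()
        if ((cent > 0) & (direc == "down")).any() or ((cent < 0) & (direc == "up")).any():
            raise SigscoreError("direction inconsistent with centroid sign")
        if self.provenance == "derived" and len(self.members):
            if (np.abs(cent) < np.log2(self.fold_threshold) - 1e-12).any():
                raise SigscoreError(
                    "derived members must satisfy |centroid| >= log2(fold_threshold)"
                )

    @property
    def member_ids(self) -> list[str]:
        return list(self.members.index)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def centroid(self) -> pd.Series:
        return self.members["centroid"]

    def subset(self, ids: Sequence[str]) -> "PathwaySignature":
        return replace(self, members=self.members.loc[list(ids)])


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def baseline_normalize(tc: TimeCourseSet) -> TimeCourseSet:
    """Subtract each replicate's mean baseline (0 h) value per gene.

    Genes with no non-missing baseline in a replicate are dropped from that
    replicate (their fold changes would be undefined).
    """
    normed = []
    for i, rep in enumerate(tc.courses):
        base = rep.loc[:, tc.baseline_mask].mean(axis=1)
        missing = base.isna()
        if missing.any():
            logger.warning(
                "baseline_normalize: replicate %d drops %d genes with no baseline",
                i,
                int(missing.sum()),
            )
        rep = rep.loc[~missing]
        normed.append(rep.sub(base.loc[~missing], axis=0))
    return replace(tc, courses=normed)


def _idealized_pattern(hours: Sequence[float]) -> np.ndarray:
    """0 at each baseline column, 1 at every post-treatment column."""
    return (np.asarray(hours) > 0).astype(float)


def derive_signature(
    tc: TimeCourseSet,
    fold_threshold: float = 2.0,
    pattern_correlation_threshold: float = 0.8,
    per_replicate: bool = False,
    name: str | None = None,
    id_space: Literal["probe", "entrez"] = "probe",
) -> PathwaySignature:
    """Derive a sustained-response signature from baseline-normalized courses.

    Gates, in order:

    1. *fold gate* — the cross-replicate mean log2FC must be ≥ log2(fold) at
       both 12 h and 24 h (up) or ≤ −log2(fold) at both (down).  With
       ``per_replicate=True`` every replicate must individually pass instead.
    2. *pattern gate* — the replicate-averaged Pearson correlation between the
       gene's full trajectory and the idealized induction pattern (negated for
       down genes) must exceed ``pattern_correlation_threshold``.

    Genes passing opposite directions at 12 h vs 24 h are excluded and logged.
    The centroid is the mean over all replicate 12 h and 24 h values.
    """
    if 12.0 not in tc.hours or 24.0 not in tc.hours:
        raise SigscoreError("derive_signature needs 12 h and 24 h columns in every replicate")
    thr = np.log2(fold_threshold)
    hours = np.asarray(tc.hours)
    late_mask = (hours == 12.0) | (hours == 24.0)

    genes = tc.courses[0].index
    for rep in tc.courses[1:]:
        genes = genes.intersection(rep.index)
    reps = [rep.loc[genes] for rep in tc.courses]

    # genes × replicates arrays of the per-replicate mean 12 h / 24 h values
    v12 = np.column_stack([r.loc[:, hours == 12.0].mean(axis=1) for r in reps])
    v24 = np.column_stack([r.loc[:, hours == 24.0].mean(axis=1) for r in reps])
    if per_replicate:
        up = (v12 >= thr).all(axis=1) & (v24 >= thr).all(axis=1)
        down = (v12 <= -thr).all(axis=1) & (v24 <= -thr).all(axis=1)
    else:
        m12, m24 = np.nanmean(v12, axis=1), np.nanmean(v24, axis=1)
        up = (m12 >= thr) & (m24 >= thr)
        down = (m12 <= -thr) & (m24 <= -thr)
        mixed = ((m12 >= thr) & (m24 <= -thr)) | ((m12 <= -thr) & (m24 >= thr))
        if mixed.any():
            logger.info(
                "derive_signature(%s): %d mixed-direction genes excluded",
                tc.agonist,
                int(mixed.sum()),
            )
    candidates = genes[up | down]
    directions = pd.Series(np.where(up[up | down], "up", "down"), index=candidates)

    ideal = _idealized_pattern(tc.hours)
    keep, centroids = [], []
    for gene in candidates:
        sign = 1.0 if directions[gene] == "up" else -1.0
        rs = []
        for rep in reps:
            traj = rep.loc[gene].to_numpy(dtype=float)
            ok = np.isfinite(traj)
            if ok.sum() < 3 or np.std(traj[ok]) == 0:
                continue
            rs.append(stats.pearsonr(traj[ok], sign * ideal[ok])[0])
        if rs and float(np.mean(rs)) > pattern_correlation_threshold:
            late_vals = np.concatenate([rep.loc[gene].to_numpy()[late_mask] for rep in reps])
            keep.append(gene)
            centroids.append(float(np.nanmean(late_vals)))
    members = pd.DataFrame(
        {"direction": directions.loc[keep], "centroid": centroids}, index=pd.Index(keep)
    )
    logger.info(
        "derive_signature(%s): %d candidates, %d pass pattern gate",
        tc.agonist,
        len(candidates),
        len(members),
    )
    return PathwaySignature(
        name=name or tc.agonist or "signature",
        id_space=id_space,
        members=members,
        provenance="derived",
        fold_threshold=fold_threshold,
        pattern_correlation_threshold=pattern_correlation_threshold,
    )


def import_signature(
    records: Iterable[tuple],
    id_space: Literal["probe", "entrez"],
    name: str = "imported",
) -> PathwaySignature:
    """Build a signature from (id, direction[, weight]) records.

    Missing weights default to +1/−1 by direction; the fold/pattern invariants
    of derived signatures are not enforced.
    """
    rows = list(records)
    if not rows:
        raise SigscoreError("import_signature: empty record list")
    ids, dirs, weights = [], [], []
    for rec in rows:
        gid, direction = rec[0], rec[1]
        if direction not in ("up", "down"):
            raise SigscoreError(f"direction must be 'up' or 'down', got {direction!r}")
        w = rec[2] if len(rec) > 2 and rec[2] is not None else (1.0 if direction == "up" else -1.0)
        ids.append(str(gid))
        dirs.append(direction)
        weights.append(float(w))
    index = pd.Index(ids)
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique()
        raise SigscoreError(f"duplicate signature ID(s): {list(dupes[:5])}")
    members = pd.DataFrame({"direction": dirs, "centroid": weights}, index=index)
    return PathwaySignature(name=name, id_space=id_space, members=members, provenance="imported")


def signature_similarity(
    a: PathwaySignature, b: PathwaySignature, g: "GeneMatrix | None" = None
) -> float:
    """Pearson correlation of two signatures' centroid vectors.

    Computed over the union of member genes restricted to a shared gene space
    (``g``'s identifiers if given, else the union itself); a gene absent from
    one signature contributes 0 on that side.
    """
    if a.id_space != b.id_space:
        raise SigscoreError("signatures must share an id_space")
    union = a.members.index.union(b.members.index)
    if g is not None:
        union = union[union.isin(g.ids)]
    if len(union) < 3:
        raise SigscoreError("fewer than 3 genes in the shared space")
    va = a.centroid.reindex(union).fillna(0.0).to_numpy()
    vb = b.centroid.reindex(union).fillna(0.0).to_numpy()
    return float(stats.pearsonr(va, vb)[0])


# ---------------------------------------------------------------------------
# signature TSV I/O:  id  direction  centroid  provenance
# ---------------------------------------------------------------------------

def write_signature(sig: PathwaySignature, path: str | Path) -> None:
    out = sig.members.copy()
    out.insert(0, "id", sig.members.index)
    out["provenance"] = sig.provenance
    out.to_csv(path, sep="\t", index=False)


def read_signature(
    path: str | Path,
    id_space: Literal["probe", "entrez"] = "probe",
    name: str | None = None,
) -> PathwaySignature:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    members = pd.DataFrame(
        {"direction": df["direction"].to_numpy(), "centroid": df["centroid"].to_numpy(float)},
        index=pd.Index(df["id"]),
    )
    provenance = df["provenance"].iloc[0] if "provenance" in df and len(df) else "imported"
    return PathwaySignature(
        name=name or Path(path).stem,
        id_space=id_space,
        members=members,
        provenance=provenance,  # type: ignore[arg-type]
    )
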