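"""Hierarchical clustering of intrinsic genes and arrays into disease subsets.

Arrays are clustered with average linkage on 1 − centered Pearson correlation
(the Cluster 3.0 convention), the tree is cut into k main clusters, and
clusters smaller than ``min_cluster_size`` are relabelled *unassigned*.
Clusters are then named after intrinsic subsets by which marker-gene program
is most expressed within them, and a concordance report compares the new
labels against a prior labelling with a chi-squared test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import GeneMatrix, SigscoreError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class SubsetAssignment:
    """Per-array cluster/subset labels plus the dendrograms that produced them."""

    labels: pd.Series
    array_linkage: np.ndarray
    gene_linkage: np.ndarray | None
    params: Mapping

    @property
    def assigned(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED]


@dataclass(frozen=True)
class ConcordanceReport:
    """Original × new label agreement with per-subset retention."""

    contingency: pd.DataFrame
    per_subset: pd.DataFrame  # columns: retained, total, percent
    chi2: float
    dof: int
    p_value: float


def correlation_distance(values: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """1 − (centered) Pearson correlation between columns, pairwise-complete."""
    corr = values.corr(method="pearson", min_periods=2) if center else _uncentered_corr(values)
    return 1.0 - corr


def _uncentered_corr(values: pd.DataFrame) -> pd.DataFrame:
    X = values.to_numpy(dtype=float)
    norms = np.sqrt(np.nansum(X**2, axis=0))
    finite = np.where(np.isfinite(X), X, 0.0)
    return pd.DataFrame(
        (finite.T @ finite) / np.outer(norms, norms), index=values.columns, columns=values.columns
    )


def cluster_arrays(
    g: GeneMatrix,
    k: int = 5,
    min_cluster_size: int = 8,
    median_center_genes: bool = True,
    cluster_genes: bool = True,
) -> SubsetAssignment:
    """Average-linkage clustering of arrays (and genes) on correlation distance.

    The array tree is cut into ``k`` main clusters; clusters with fewer than
    ``min_cluster_size`` arrays become *unassigned*.  Genes are optionally
    median-centered first, and the gene tree is computed identically on the
    transposed data.  Constant (zero-variance) arrays are excluded with a
    warning and labelled unassigned.
    """
    values = g.values
    if values.shape[1] < k:
        raise SigscoreError(f"need >= k={k} arrays, have {values.shape[1]}")
    if values.isna().all(axis=1).any():
        raise SigscoreError("all-missing gene rows must be dropped before clustering")
    if median_center_genes:
        values = values.sub(values.median(axis=1), axis=0)

    variances = values.var(axis=0, ddof=0)
    constant = variances.index[variances.fillna(0.0) == 0.0]
    if len(constant):
        logger.warning("cluster_arrays: excluding %d constant arrays", len(constant))
    use = values.drop(columns=constant)
    if use.shape[1] < k:
        raise SigscoreError("too few non-constant arrays for the requested k")

    dist = correlation_distance(use)
    darr = dist.to_numpy()
    darr = np.clip((darr + darr.T) / 2.0, 0.0, None)
    np.fill_diagonal(darr, 0.0)
    Z = linkage(squareform(darr, checks=False), method="average")
    cut = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(
        [f"cluster_{c}" for c in cut], index=use.columns, name="subset"
    )
    sizes = labels.value_counts()
    small = sizes[sizes < min_cluster_size].index
    labels[labels.isin(small)] = UNASSIGNED
    labels = labels.reindex(values.columns, fill_value=UNASSIGNED)

    gene_Z = None
    if cluster_genes:
        gdist = correlation_distance(use.T)
        gd = gdist.to_numpy()
        gd = np.clip((gd + gd.T) / 2.0, 0.0, None)
        np.fill_diagonal(gd, 0.0)
        gd = np.nan_to_num(gd, nan=2.0)  # constant genes: maximal distance
        gene_Z = linkage(squareform(gd, checks=False), method="average")

    return SubsetAssignment(
        labels=labels,
        array_linkage=Z,
        gene_linkage=gene_Z,
        params={
            "distance": "1 - centered Pearson",
            "linkage": "average",
            "k": k,
            "min_cluster_size": min_cluster_size,
            "median_center_genes": median_center_genes,
        },
    )


def label_clusters(
    assign: SubsetAssignment,
    g: GeneMatrix,
    program_markers: Mapping[str, Sequence[str]],
) -> SubsetAssignment:
    """Name each cluster after the subset whose markers are most expressed in it.

    Ties break by the larger margin over the runner-up, then lexicographically
    by subset name.  Marker lists must be non-empty, disjoint, and present in
    the matrix.
    """
    names = sorted(program_markers)
    seen: set[str] = set()
    for subset in names:
        markers = list(program_markers[subset])
        if not markers:
            raise SigscoreError(f"empty marker list for {subset!r}")
        overlap = seen.intersection(markers)
        if overlap:
            raise SigscoreError(f"marker lists must be disjoint; shared: {sorted(overlap)[:5]}")
        seen.update(markers)
    missing = sorted(seen - set(map(str, g.ids)))
    if missing:
        raise SigscoreError(f"marker genes absent from matrix: {missing[:10]}")

    new = assign.labels.copy()
    for cluster in assign.labels.unique():
        if cluster == UNASSIGNED:
            continue
        arrays = assign.labels.index[assign.labels == cluster]
        means = {
            subset: float(g.values.loc[list(program_markers[subset]), arrays].mean().mean())
            for subset in names
        }
        ranked = sorted(names, key=lambda s: (-means[s], s))
        new[arrays] = ranked[0]
    return replace(assign, labels=new)


def concordance(original: pd.Series, new: pd.Series) -> ConcordanceReport:
    """Compare two labelings of the same arrays.

    Per-subset retention is reported for every original subset (whole-percent
    rounding); the chi-squared test of independence runs on the contingency
    table with *unassigned* rows/columns excluded (reported separately in the
    full table).
    """
    original, new = original.align(new, join="inner")
    if len(original) == 0:
        raise SigscoreError("no shared arrays between labelings")
    shared_vocab = set(original.unique()) & set(new.unique()) - {UNASSIGNED}
    if not shared_vocab:
        raise SigscoreError("label vocabularies are disjoint")

    table = pd.crosstab(original, new, dropna=False)
    rows = []
    for subset in sorted(set(original.unique()) - {UNASSIGNED}):
        total = int((original == subset).sum())
        retained = int(((original == subset) & (new == subset)).sum())
        rows.append(
            {
                "subset": subset,
                "retained": retained,
                "total": total,
                "percent": int(round(100.0 * retained / total)) if total else 0,
            }
        )
    per_subset = pd.DataFrame(rows).set_index("subset")

    test_table = table.drop(index=UNASSIGNED, errors="ignore").drop(
        columns=UNASSIGNED, errors="ignore"
    )
    test_table = test_table.loc[test_table.sum(axis=1) > 0, test_table.sum(axis=0) > 0]
    if test_table.shape[0] > 1 and test_table.shape[1] > 1:
        chi2, p, dof, _ = stats.chi2_contingency(test_table.to_numpy())
    else:
        chi2, p, dof = np.nan, np.nan, 0
    return ConcordanceReport(
        contingency=table, per_subset=per_subset, chi2=float(chi2), dof=int(dof), p_value=float(p)
    )


# ---------------------------------------------------------------------------
# Cluster 3.0 / Java TreeView export
# ---------------------------------------------------------------------------

def write_treeview(
    g: GeneMatrix, assign: SubsetAssignment, prefix: str
) -> None:
    """Write CDT/GTR/ATR files loadable by Java TreeView.

    Node ordering follows the scipy linkage; correlation similarities are
    written as 1 − merge distance.
    """
    values = g.values
    cdt = pd.DataFrame(values.to_numpy(), columns=values.columns)
    cdt.insert(0, "GWEIGHT", 1)
    cdt.insert(0, "NAME", values.index)
    cdt.insert(0, "GID", [f"GENE{i}X" for i in range(len(values))])
    header = ["GID", "NAME", "GWEIGHT", *values.columns]
    with open(f"{prefix}.cdt", "w") as fh:
        fh.write("\t".join(header) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * values.shape[1]) + "\n")
        cdt.to_csv(fh, sep="\t", header=False, index=False)
    _write_tree(assign.array_linkage, values.shape[1], "ARRY", f"{prefix}.atr")
    if assign.gene_linkage is not None:
        _write_tree(assign.gene_linkage, values.shape[0], "GENE", f"{prefix}.gtr")


def _write_tree(Z: np.ndarray, n_leaves: int, leaf_prefix: str, path: str) -> None:
    def node_name(i: int) -> str:
        return f"{leaf_prefix}{i}X" if i < n_leaves else f"NODE{i - n_leaves + 1}X"

    with open(path, "w") as fh:
        for i, (a, b, dist, _) in enumerate(Z):
            fh.write(
                f"NODE{i + 1}X\t{node_name(int(a))}\t{node_name(int(b))}\t{1.0 - dist:.6f}\n"
            )
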