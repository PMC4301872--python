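"""Centroid-correlation scoring of biopsies against pathway signatures.

Every array receives, for every signature, the Pearson correlation between
the signature's centroid vector and the array's expression over the aligned
genes.  Per intrinsic subset, the mean correlation r̄ is converted to an
enrichment p-value with the standard correlation t statistic,
t = r̄·√((n−2)/(1−r̄²)) with n−2 degrees of freedom, where n is the number of
signature genes present in the compendium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import UNASSIGNED, SubsetAssignment
from .core import ExpressionCompendium, GeneMatrix, SigscoreError, align_to_signature
from .signatures import PathwaySignature

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-array per-signature Pearson scores."""

    scores: pd.DataFrame  # arrays × signatures
    n_genes: pd.Series  # aligned gene count per signature


def score_arrays(
    g: GeneMatrix | ExpressionCompendium,
    sigs: list[PathwaySignature],
) -> ScoreTable:
    """Correlate every array with every signature centroid (pairwise-complete).

    Probe-space signatures align directly; Entrez-space signatures trigger
    multi-probe averaging on the compendium side.  An array whose aligned
    values have zero variance gets a missing score with a warning.
    """
    cols = {}
    n_genes = {}
    for sig in sigs:
        sub, aligned_sig, report = align_to_signature(g, sig)
        if report.n_matched < 3:
            raise SigscoreError(f"signature {sig.name!r} aligns with < 3 genes")
        n_genes[sig.name] = report.n_matched
        centroid = aligned_sig.centroid.to_numpy(dtype=float)
        X = sub.values.to_numpy(dtype=float)
        rs = np.full(X.shape[1], np.nan)
        n_degenerate = 0
        for j in range(X.shape[1]):
            ok = np.isfinite(X[:, j]) & np.isfinite(centroid)
            if ok.sum() < 3 or np.ptp(X[ok, j]) == 0 or np.ptp(centroid[ok]) == 0:
                n_degenerate += 1
                continue
            rs[j] = stats.pearsonr(X[ok, j], centroid[ok])[0]
        if n_degenerate:
            logger.warning(
                "score_arrays: %d arrays had zero-variance/empty alignment vs %s",
                n_degenerate,
                sig.name,
            )
        cols[sig.name] = pd.Series(rs, index=sub.values.columns)
    scores = pd.DataFrame(cols)
    scores.index.name = "array_id"
    return ScoreTable(scores=scores, n_genes=pd.Series(n_genes, name="n_genes"))


def enrichment_p(r_bar: float, n: int) -> float:
    """Two-sided p for a mean Pearson r treated as a correlation over n genes."""
    if n < 3 or not np.isfinite(r_bar) or abs(r_bar) >= 1.0:
        return np.nan if n < 3 or not np.isfinite(r_bar) else 0.0
    t = r_bar * np.sqrt((n - 2) / (1.0 - r_bar**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def subset_enrichment(st: ScoreTable, assign: SubsetAssignment) -> pd.DataFrame:
    """Mean score and enrichment p per (subset, signature).

    Unassigned arrays are excluded; a subset with no scored arrays is omitted
    with a warning; n < 3 leaves the p-value missing.  The output is a long
    table with columns subset, signature, mean_r, n_arrays, n_genes, t, p.
    """
    labels = assign.labels.reindex(st.scores.index)
    rows = []
    subsets = [s for s in labels.dropna().unique() if s != UNASSIGNED]
    for subset in sorted(subsets):
        arrays = labels.index[labels == subset]
        if len(arrays) == 0:
            logger.warning("subset_enrichment: subset %s has no scored arrays", subset)
            continue
        for sig_name in st.scores.columns:
            r_bar = float(st.scores.loc[arrays, sig_name].mean())
            n = int(st.n_genes[sig_name])
            if n >= 3 and np.isfinite(r_bar) and abs(r_bar) < 1.0:
                t = r_bar * np.sqrt((n - 2) / (1.0 - r_bar**2))
            else:
                t = np.nan
            rows.append(
                {
                    "subset": subset,
                    "signature": sig_name,
                    "mean_r": r_bar,
                    "n_arrays": len(arrays),
                    "n_genes": n,
                    "t": t,
                    "p": enrichment_p(r_bar, n),
                }
            )
    return pd.DataFrame(rows)
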