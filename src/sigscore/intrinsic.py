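"""Intrinsic gene selection with permutation-estimated FDR.

A gene is *intrinsic* when its expression is consistent across repeat arrays
from one patient but varies strongly between patients.  The statistic is the
variance ratio S_g = W_g / B_g, where W_g is the mean within-patient variance
(over patients contributing ≥ 2 arrays) and B_g the variance of per-patient
mean values across all patients; small S_g marks intrinsic genes.  The null
distribution of S comes from permuting the array→patient assignment while
preserving the per-patient array counts, giving an estimated FDR for any
score threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionCompendium, SigscoreError

logger = logging.getLogger(__name__)


@dataclass
class IntrinsicResult:
    """Outcome of intrinsic selection at a chosen score threshold."""

    scores: pd.Series
    threshold: float
    selected: pd.Index
    fdr_percent: float
    n_permutations: int
    seed: int

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _scores_from_groups(values: np.ndarray, patient_codes: np.ndarray) -> np.ndarray:
    """Vectorized W/B per gene for a genes × arrays matrix and patient codes."""
    n_patients = patient_codes.max() + 1
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    indicator = np.eye(n_patients)[patient_codes]  # arrays × patients
    counts = finite.astype(float) @ indicator
    sums = vals @ indicator
    sq = (vals**2) @ indicator
    if (counts == 0).any():
        raise SigscoreError("gene with an all-missing patient group; drop it first")
    means = sums / counts
    multi = counts >= 2
    if not multi.any(axis=1).all():
        # at least one gene has no multi-array patient (can only happen with
        # missingness); the statistic is undefined there
        raise SigscoreError("no multi-array patient for some gene")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        wvar = (sq - counts * means**2) / np.maximum(counts - 1, 1)
        wvar = np.where(multi, wvar, np.nan)
        W = np.nanmean(wvar, axis=1)
    B = means.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(B > 0, W / B, np.inf)
    return np.maximum(S, 0.0)  # numerical floor; W can round to -0


def intrinsic_scores(c: ExpressionCompendium, s: pd.DataFrame) -> pd.Series:
    """Per-gene intrinsic score S = W/B (small = intrinsic).

    Patients with a single array contribute to the between-patient variance
    only.  Genes whose expression is entirely missing for some patient are
    dropped beforehand by the caller (hard error here).
    """
    patient = s.set_index("array_id")["patient_id"].reindex(c.array_ids)
    if patient.isna().any():
        raise SigscoreError("arrays missing from the sample table")
    sizes = patient.value_counts()
    if (sizes >= 2).sum() < 2:
        raise SigscoreError("need >= 2 patients with >= 2 arrays each")
    codes = pd.Categorical(patient).codes.astype(int)
    S = _scores_from_groups(c.values.to_numpy(dtype=float), codes)
    return pd.Series(S, index=c.values.index, name="intrinsic_score")


def select_intrinsic(
    scores: pd.Series,
    c: ExpressionCompendium,
    s: pd.DataFrame,
    target_fdr_percent: float | None = None,
    target_n_probes: int | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> IntrinsicResult:
    """Choose a score threshold by target FDR (%) or by probe count.

    Null scores are generated by permuting which patient each array belongs
    to (group sizes preserved); FDR(t) = 100 · mean over permutations of
    #\\{null S ≤ t\\} / #\\{observed S ≤ t\\}.  If the FDR target is unattainable
    the closest attainable selection is returned with a warning.
    """
    if (target_fdr_percent is None) == (target_n_probes is None):
        raise SigscoreError("specify exactly one of target_fdr_percent / target_n_probes")
    if n_perm < 20:
        raise SigscoreError("n_perm must be >= 20")

    patient = s.set_index("array_id")["patient_id"].reindex(c.array_ids)
    codes = pd.Categorical(patient).codes.astype(int)
    values = c.values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    obs = np.sort(scores.to_numpy())
    null_sorted = []
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(len(codes))]
        null_sorted.append(np.sort(_scores_from_groups(values, perm_codes)))
    null_all = np.sort(np.concatenate(null_sorted))

    def fdr_at(t: float) -> float:
        n_obs = int(np.searchsorted(obs, t, side="right"))
        if n_obs == 0:
            return 0.0
        mean_null = np.searchsorted(null_all, t, side="right") / n_perm
        return min(100.0 * mean_null / n_obs, 100.0)

    if target_n_probes is not None:
        k = min(target_n_probes, len(obs))
        if k < target_n_probes:
            logger.warning("select_intrinsic: only %d genes available", len(obs))
        threshold = obs[k - 1] if k > 0 else -np.inf
        fdr = fdr_at(threshold)
    else:
        fdrs = np.array([fdr_at(t) for t in obs])
        ok = np.flatnonzero(fdrs <= target_fdr_percent)
        if len(ok):
            idx = ok[-1]  # largest selection meeting the target
            threshold, fdr = obs[idx], fdrs[idx]
        else:
            idx = int(np.argmin(fdrs))  # ties resolve to the smallest selection
            fdr = fdrs[idx]
            logger.warning(
                "select_intrinsic: FDR target %.2f%% unattainable; closest is %.2f%%",
                target_fdr_percent,
                fdr,
            )
            if fdr >= 95.0:
                # the scores carry no patient signal at all: every selection is
                # expected to be almost entirely false, so select nothing
                threshold = -np.inf
            else:
                threshold = obs[idx]

    selected = scores.index[scores.to_numpy() <= threshold]
    return IntrinsicResult(
        scores=scores,
        threshold=float(threshold),
        selected=selected,
        fdr_percent=float(min(fdr, 100.0)),
        n_permutations=n_perm,
        seed=seed,
    )
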