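"""Associations between pathway scores and clinical covariates.

Array selection follows the study design: general comparisons use diffuse
(dSSc) patients only, a single array per patient per time point with lesional
biopsies preferred; biopsy-site comparisons use dSSc patients who provided
paired lesional/non-lesional biopsies at the same time point, keeping both.
Continuous covariates (MRSS, age) are tested with Pearson correlation,
categorical covariates (sex, biopsy site, early/late disease duration with
early = ≤ 2 years) with one-way ANOVA.  Raw p-values are flagged at 0.05; a
Benjamini–Hochberg column is emitted for reuse but does not drive the flags.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SigscoreError, validate_sample_table
from .scoring import ScoreTable

logger = logging.getLogger(__name__)

EARLY_DISEASE_YEARS = 2.0

CONTINUOUS_COVARIATES = ("mrss", "age")
CATEGORICAL_COVARIATES = ("disease_duration_early_late", "sex", "biopsy_site")


def select_clinical_arrays(
    s: pd.DataFrame, purpose: Literal["general", "biopsy_site"] = "general"
) -> list[str]:
    """Apply the study's array-selection rules; returns array_ids.

    general
        dSSc only; one array per patient per time point, preferring the
        lesional biopsy, ties broken by array_id order (stands in for
        technical-replicate collapsing).
    biopsy_site
        dSSc patients with BOTH a lesional and a non-lesional biopsy at the
        same time point; both arrays retained (one per site, first by
        array_id on replicates).
    """
    s = validate_sample_table(s)
    d = s[s["diagnosis"] == "dSSc"].copy()
    if d.empty:
        logger.warning("select_clinical_arrays: no dSSc arrays")
        return []
    site_rank = d["biopsy_site"].map({"forearm_lesional": 0, "back_nonlesional": 1}).fillna(2)
    d = d.assign(_rank=site_rank).sort_values(["_rank", "array_id"], kind="stable")
    if purpose == "general":
        picked = d.groupby(["patient_id", "timepoint_label"], sort=False).head(1)
        return sorted(picked["array_id"])
    if purpose != "biopsy_site":
        raise SigscoreError(f"unknown purpose {purpose!r}")
    keep: list[str] = []
    for (_, _), grp in d.groupby(["patient_id", "timepoint_label"], sort=False):
        sites = set(grp["biopsy_site"])
        if {"forearm_lesional", "back_nonlesional"} <= sites:
            for site in ("forearm_lesional", "back_nonlesional"):
                keep.append(grp[grp["biopsy_site"] == site]["array_id"].iloc[0])
    return sorted(keep)


def associate(
    st: ScoreTable,
    s: pd.DataFrame,
    selection: Sequence[str],
    covariates: Sequence[str] = CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each (covariate, signature) pair on the selected arrays.

    Returns a long table with columns covariate, signature, stat_type,
    statistic, p, fdr (Benjamini–Hochberg across the whole table), n and
    significant (raw p ≤ alpha).  Constant covariates yield missing
    statistics with a warning.
    """
    meta = validate_sample_table(s).set_index("array_id")
    arrays = [a for a in selection if a in st.scores.index]
    if len(arrays) < len(selection):
        logger.warning("associate: %d selected arrays lack scores", len(selection) - len(arrays))
    rows = []
    for cov in covariates:
        if cov == "disease_duration_early_late":
            raw = pd.to_numeric(meta.loc[arrays, "disease_duration_years"], errors="coerce")
            values = pd.Series(
                np.where(raw <= EARLY_DISEASE_YEARS, "early", "late"), index=raw.index
            ).where(raw.notna())
            kind = "anova_F"
        elif cov in CONTINUOUS_COVARIATES:
            values = pd.to_numeric(meta.loc[arrays, cov], errors="coerce")
            kind = "pearson_r"
        else:
            values = meta.loc[arrays, cov].where(meta.loc[arrays, cov].notna())
            kind = "anova_F"
        for sig_name in st.scores.columns:
            scores = st.scores.loc[arrays, sig_name]
            ok = scores.notna() & values.notna()
            x, y = values[ok], scores[ok]
            stat, p = np.nan, np.nan
            if kind == "pearson_r":
                if len(x) >= 3 and x.nunique() > 1 and y.nunique() > 1:
                    stat, p = stats.pearsonr(x.astype(float), y)
                else:
                    logger.warning("associate: %s constant/degenerate for %s", cov, sig_name)
            else:
                groups = [y[x == lvl].to_numpy() for lvl in pd.unique(x.dropna())]
                groups = [grp for grp in groups if len(grp) >= 2]
                if len(groups) >= 2:
                    stat, p = stats.f_oneway(*groups)
                else:
                    logger.warning("associate: %s has < 2 usable levels for %s", cov, sig_name)
            rows.append(
                {
                    "covariate": cov,
                    "signature": sig_name,
                    "stat_type": kind,
                    "statistic": float(stat) if np.isfinite(stat) else np.nan,
                    "p": float(p) if np.isfinite(p) else np.nan,
                    "n": int(ok.sum()),
                }
            )
    out = pd.DataFrame(rows)
    fdr = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        fdr[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["significant"] = out["p"] <= alpha
    return out


def clinical_associations(st: ScoreTable, s: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the full clinical screen: general covariates plus biopsy site.

    MRSS, age, disease duration and sex use the general selection; biopsy
    site uses the paired-biopsy selection.
    """
    general = select_clinical_arrays(s, "general")
    paired = select_clinical_arrays(s, "biopsy_site")
    parts = [
        associate(
            st, s, general,
            covariates=("mrss", "age", "disease_duration_early_late", "sex"),
            alpha=alpha,
        )
    ]
    if paired:
        parts.append(associate(st, s, paired, covariates=("biopsy_site",), alpha=alpha))
    return pd.concat(parts, ignore_index=True)
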