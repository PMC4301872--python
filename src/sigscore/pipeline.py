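"""End-to-end orchestration of the analysis on a synthetic compendium.

Runs the full chain the package implements: simulate a three-cohort biopsy
compendium with planted subsets, test and remove batch bias, select intrinsic
genes, cluster arrays into subsets, name clusters by planted marker programs,
derive a signature per subset program from synthetic time courses, score all
arrays, summarize enrichment per subset, and screen clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .batch import GPCAResult, combat_fit_transform, gpca_test
from .clinical import clinical_associations
from .cluster import UNASSIGNED, SubsetAssignment, cluster_arrays, label_clusters
from .core import ExpressionCompendium, GeneMatrix
from .intrinsic import IntrinsicResult, intrinsic_scores, select_intrinsic
from .scoring import ScoreTable, score_arrays, subset_enrichment
from .signatures import PathwaySignature, import_signature
from .simulate import SUBSETS, CompendiumSimSpec, GroundTruth, simulate_compendium


@dataclass
class PipelineResult:
    compendium: ExpressionCompendium
    samples: pd.DataFrame
    truth: GroundTruth
    gpca_before: GPCAResult
    gpca_after: GPCAResult
    intrinsic: IntrinsicResult
    assignment: SubsetAssignment
    ari_vs_truth: float
    scores: ScoreTable
    enrichment: pd.DataFrame
    associations: pd.DataFrame

    def summary(self) -> str:
        lines = [
            f"arrays: {self.compendium.n_arrays}, genes: {self.compendium.n_features}",
            f"gPCA p before/after ComBat: {self.gpca_before.p_value:.4f} / "
            f"{self.gpca_after.p_value:.4f}",
            f"intrinsic genes selected: {self.intrinsic.n_selected} "
            f"(estimated FDR {self.intrinsic.fdr_percent:.2f}%)",
            f"subset recovery ARI: {self.ari_vs_truth:.3f}",
            "subset sizes: "
            + ", ".join(
                f"{k}={v}" for k, v in self.assignment.labels.value_counts().items()
            ),
        ]
        sig_hits = self.associations.query("covariate == 'mrss' and significant")
        if len(sig_hits):
            top = sig_hits.sort_values("p").iloc[0]
            lines.append(
                f"strongest MRSS association: {top['signature']} "
                f"(r = {top['statistic']:.3f}, p = {top['p']:.3g})"
            )
        return "\n".join(lines)


def program_signatures(truth: GroundTruth, effect: float = 1.5) -> list[PathwaySignature]:
    """One synthetic pathway signature per planted subset program.

    Members are the program's genes with the signed planted log2 activation
    as the centroid — the stand-in for experimentally derived agonist
    signatures with up- and down-regulated members.
    """
    sigs = []
    for subset in SUBSETS:
        genes = truth.program_of_gene.index[truth.program_of_gene == subset]
        records = [
            (g, "up" if truth.program_sign[g] > 0 else "down", effect * truth.program_sign[g])
            for g in genes
        ]
        sigs.append(import_signature(records, id_space="probe", name=f"{subset}_program"))
    return sigs


def program_markers(truth: GroundTruth, ids) -> dict[str, list[str]]:
    """Up-regulated program genes per subset, restricted to available ids."""
    out = {}
    for subset in SUBSETS:
        genes = truth.program_of_gene.index[
            (truth.program_of_gene == subset) & (truth.program_sign > 0)
        ]
        out[subset] = [g for g in genes if g in ids]
    return out


def run_synthetic_pipeline(
    seed: int = 0,
    spec: CompendiumSimSpec | None = None,
    out_dir: str | Path | None = None,
    gpca_perms: int = 200,
    intrinsic_perms: int = 50,
    target_fdr_percent: float = 5.0,
    k: int = 4,
    min_cluster_size: int = 2,
) -> PipelineResult:
    """Simulate, adjust, cluster, score and associate in one call."""
    spec = spec or CompendiumSimSpec(seed=seed)
    comp, samples, truth = simulate_compendium(spec)

    before = gpca_test(comp, samples, n_perm=gpca_perms, seed=seed + 1)
    adjusted, _ = combat_fit_transform(comp, samples)
    after = gpca_test(adjusted, samples, n_perm=gpca_perms, seed=seed + 2)

    scores = intrinsic_scores(adjusted, samples)
    intr = select_intrinsic(
        scores, adjusted, samples,
        target_fdr_percent=target_fdr_percent, n_perm=intrinsic_perms, seed=seed + 3,
    )
    gm = GeneMatrix(adjusted.values.loc[intr.selected], id_space="probe")
    assign = cluster_arrays(gm, k=k, min_cluster_size=min_cluster_size)
    markers = {k_: v for k_, v in program_markers(truth, set(gm.ids)).items() if v}
    if len(markers) == len(SUBSETS):
        assign = label_clusters(assign, gm, markers)
    assigned = assign.labels[assign.labels != UNASSIGNED]
    ari = adjusted_rand_score(
        truth.subset_of_array.loc[assigned.index], assigned
    ) if len(assigned) else 0.0

    sigs = program_signatures(truth, effect=spec.module_effect or 1.0)
    st = score_arrays(adjusted, sigs)
    enr = subset_enrichment(st, assign)
    assoc = clinical_associations(st, samples)

    result = PipelineResult(
        compendium=comp,
        samples=samples,
        truth=truth,
        gpca_before=before,
        gpca_after=after,
        intrinsic=intr,
        assignment=assign,
        ari_vs_truth=float(ari),
        scores=st,
        enrichment=enr,
        associations=assoc,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        st.scores.to_csv(out / "scores.tsv", sep="\t")
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        assign.labels.rename_axis("array_id").to_csv(out / "subsets.tsv", sep="\t")
    return result
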