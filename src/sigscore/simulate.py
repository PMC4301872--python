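"""Synthetic biopsy compendia and agonist time courses with planted truth.

The compendium generator emulates the structure the analysis assumes: three
cohorts (batches) of patients, four intrinsic subsets (fibroproliferative,
inflammatory, limited, normal-like) each driven by a disjoint gene program,
patients contributing 1–3 arrays including paired lesional/non-lesional
biopsies, per-patient random intercepts, additive and scale batch effects,
and an MRSS clinical score generated from a planted TGFβ-like activation.

The time-course generator emulates fibroblast agonist experiments sampled at
0,0,0,2,4,8,12,24 h with triplicate baselines and planted sustained,
transient and late-partial responder genes.

Both return a ``GroundTruth`` record so recovery can be tested end-to-end.
All randomness flows from one integer seed; sub-streams are spawned
deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ExpressionCompendium, SigscoreError, validate_sample_table
from .signatures import HOURS_DEFAULT, TimeCourseSet

SUBSETS = ("fibroproliferative", "inflammatory", "limited", "normal_like")


@dataclass
class CompendiumSimSpec:
    """Parameters of the synthetic biopsy compendium.

    Defaults are sized so a full pipeline run (merge → ComBat → intrinsic
    selection → clustering → scoring → clinical association) completes in
    seconds while keeping the effects at realistic magnitudes: log2 program
    shifts of 1.5, spot noise 0.5 sd, cohort offsets 0.5 sd, per-patient
    intercepts 0.3 sd.
    """

    n_genes: int = 2000
    n_patients_per_subset: int = 10
    arrays_per_patient_probs: tuple[float, float, float] = (0.3, 0.45, 0.25)
    paired_biopsy_prob: float = 0.5
    n_batches: int = 3
    batch_additive_sd: float = 0.5
    batch_scale_sd: float = 0.1
    noise_sd: float = 0.5
    patient_sd: float = 0.3
    module_size: int = 50
    module_effect: float = 1.5
    activation_sd: float = 0.3
    lesional_delta: float = 0.5
    #: subset whose program stands in for the TGFβ-like severity axis
    mrss_driver_subset: str = "fibroproliferative"
    mrss_intercept: float = 15.0
    mrss_slope: float = 8.0
    mrss_noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("batch_additive_sd", "batch_scale_sd", "noise_sd", "patient_sd",
                     "activation_sd", "mrss_noise_sd"):
            if getattr(self, name) < 0:
                raise SigscoreError(f"{name} must be >= 0")
        if self.module_effect < 0:
            raise SigscoreError("module_effect must be >= 0 (0 = null simulation)")
        if self.module_size * len(SUBSETS) > self.n_genes:
            raise SigscoreError("subset programs exceed n_genes; programs must be disjoint")
        if abs(sum(self.arrays_per_patient_probs) - 1.0) > 1e-9:
            raise SigscoreError("arrays_per_patient_probs must sum to 1")
        if self.mrss_driver_subset not in SUBSETS:
            raise SigscoreError(f"mrss_driver_subset must be one of {SUBSETS}")


@dataclass
class TimeCourseSimSpec:
    """Parameters of the synthetic agonist time course."""

    n_genes: int = 1000
    hours: tuple[float, ...] = HOURS_DEFAULT
    n_replicate_courses: int = 2
    n_sustained_up: int = 60
    n_sustained_down: int = 40
    n_transient: int = 30
    n_late_partial: int = 20
    min_effect: float = 1.2
    max_effect: float = 3.0
    noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        planted = (
            self.n_sustained_up + self.n_sustained_down + self.n_transient + self.n_late_partial
        )
        if planted > self.n_genes:
            raise SigscoreError("planted classes exceed n_genes; classes must be disjoint")
        if self.noise_sd < 0:
            raise SigscoreError("noise_sd must be >= 0")
        if self.min_effect < 1.0:
            raise SigscoreError("min_effect below the 2-fold gate makes recovery ill-posed")
        if 0.0 not in self.hours:
            raise SigscoreError("hours must include baseline columns")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    subset_of_array: pd.Series | None = None
    program_of_gene: pd.Series | None = None
    program_sign: pd.Series | None = None
    batch_additive: pd.DataFrame | None = None
    batch_scale: pd.Series | None = None
    activations: pd.DataFrame | None = None
    gene_class: pd.Series | None = None
    planted_effects: pd.Series | None = None
    params: Mapping | None = None


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:05d}" for i in range(n)], name="probe_id")


def simulate_compendium(
    spec: CompendiumSimSpec,
) -> tuple[ExpressionCompendium, pd.DataFrame, GroundTruth]:
    """Generate a three-cohort biopsy compendium with planted subsets.

    The value of gene g on array a is::

        sign_g * activation[a, s]   for g in program_s
        + patient_intercept[patient(a)]
        + batch_additive[batch(a), g]
        + noise,   noise ~ N(0, noise_sd * batch_scale[batch(a)])

    Each program is half induced (sign +1) and half repressed (sign −1),
    mirroring agonist signatures with up- and down-regulated members.
    Pathway activation is a *patient-level* latent — intrinsic subsets are
    stable across a patient's serial biopsies —
    ``activation[a, s] = module_effect * 1[subset(patient) = s]
    + N(0, activation_sd) + lesional_delta * 1[s = mrss_driver and lesional]``
    with the patient draw shared by all of the patient's arrays and only the
    lesional term varying per biopsy.  MRSS is generated for SSc samples from
    the TGFβ-like (mrss_driver) activation:
    ``mrss = intercept + slope * activation + N(0, mrss_noise_sd)``,
    rounded and clipped at 0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)

    # disjoint subset programs at the head of the gene list; each half up/down
    program_of_gene = pd.Series("background", index=genes, name="program")
    program_sign = pd.Series(0.0, index=genes, name="program_sign")
    for i, subset in enumerate(SUBSETS):
        block = genes[i * spec.module_size : (i + 1) * spec.module_size]
        program_of_gene.loc[block] = subset
        signs = np.ones(len(block))
        signs[len(block) // 2 :] = -1.0
        program_sign.loc[block] = signs

    # patients: subset and batch assignment (patients nested within cohorts)
    records = []
    patient_rows = []
    array_counter = 0
    for si, subset in enumerate(SUBSETS):
        for p in range(spec.n_patients_per_subset):
            pid = f"P{si * spec.n_patients_per_subset + p:03d}"
            batch = f"cohort{rng.integers(spec.n_batches) + 1}"
            diagnosis = {
                "fibroproliferative": "dSSc",
                "inflammatory": "dSSc",
                "limited": "lSSc" if rng.random() < 0.5 else "dSSc",
                "normal_like": "control",
            }[subset]
            n_arrays = int(rng.choice([1, 2, 3], p=spec.arrays_per_patient_probs))
            # controls have no lesional/non-lesional contrast to pair
            paired = (
                n_arrays >= 2 and diagnosis != "control" and rng.random() < spec.paired_biopsy_prob
            )
            patient_rows.append((pid, subset, batch, diagnosis))
            for j in range(n_arrays):
                if paired and j == 1:
                    site, tp = "back_nonlesional", "t0"
                else:
                    site = "forearm_lesional" if diagnosis != "control" else "other"
                    tp = f"t{j * 6}mo" if not (paired and j == 0) else "t0"
                records.append(
                    {
                        "array_id": f"A{array_counter:04d}",
                        "patient_id": pid,
                        "batch": batch,
                        "diagnosis": diagnosis,
                        "biopsy_site": site,
                        "timepoint_label": tp,
                        "subset": subset,
                    }
                )
                array_counter += 1
    samples = pd.DataFrame(records)
    arrays = pd.Index(samples["array_id"], name="array_id")
    n_arrays = len(arrays)

    # latent pathway activations: patient-level draw, broadcast to arrays
    patient_ids = [r[0] for r in patient_rows]
    patient_activ = pd.DataFrame(
        rng.normal(0.0, spec.activation_sd, size=(len(patient_rows), len(SUBSETS))),
        index=patient_ids,
        columns=list(SUBSETS),
    )
    for pid, subset, _, _ in patient_rows:
        patient_activ.loc[pid, subset] += spec.module_effect
    activ = patient_activ.loc[samples["patient_id"]].set_axis(arrays, axis=0)
    lesional = (samples["biopsy_site"] == "forearm_lesional").to_numpy()
    activ.loc[lesional, spec.mrss_driver_subset] += spec.lesional_delta

    # assemble expression
    values = np.zeros((spec.n_genes, n_arrays))
    for si, subset in enumerate(SUBSETS):
        in_prog = (program_of_gene == subset).to_numpy()
        values[in_prog, :] += (
            program_sign.to_numpy()[in_prog, None] * activ[subset].to_numpy()[None, :]
        )

    patient_intercept = pd.Series(
        rng.normal(0.0, spec.patient_sd, size=len(patient_rows)),
        index=[r[0] for r in patient_rows],
    )
    values += patient_intercept.loc[samples["patient_id"]].to_numpy()[None, :]

    batch_names = [f"cohort{i + 1}" for i in range(spec.n_batches)]
    batch_additive = pd.DataFrame(
        rng.normal(0.0, spec.batch_additive_sd, size=(spec.n_batches, spec.n_genes)),
        index=batch_names,
        columns=genes,
    )
    batch_scale = pd.Series(
        np.exp(rng.normal(0.0, spec.batch_scale_sd, size=spec.n_batches)), index=batch_names
    )
    batch_of_array = samples.set_index("array_id")["batch"]
    values += batch_additive.loc[batch_of_array].to_numpy().T
    noise_scale = spec.noise_sd * batch_scale.loc[batch_of_array].to_numpy()
    values += rng.normal(0.0, 1.0, size=values.shape) * noise_scale[None, :]

    compendium = ExpressionCompendium(
        values=pd.DataFrame(values, index=genes, columns=arrays),
        features=pd.DataFrame(
            {
                "gene_symbol": [f"SYM{i:05d}" for i in range(spec.n_genes)],
                "entrez_id": [str(10000 + i) for i in range(spec.n_genes)],
            },
            index=genes,
        ),
        batches=batch_of_array.copy(),
    )

    # clinical covariates
    driver = activ[spec.mrss_driver_subset].to_numpy()
    is_ssc = samples["diagnosis"].isin(["dSSc", "lSSc"]).to_numpy()
    mrss_raw = spec.mrss_intercept + spec.mrss_slope * driver + rng.normal(
        0.0, spec.mrss_noise_sd, size=n_arrays
    )
    mrss = np.clip(np.round(mrss_raw), 0, None)
    samples["mrss"] = np.where(is_ssc, mrss, np.nan)
    per_patient_age = pd.Series(
        np.clip(rng.normal(50, 12, size=len(patient_rows)), 18, 85).round(),
        index=[r[0] for r in patient_rows],
    )
    per_patient_sex = pd.Series(
        rng.choice(["F", "M"], p=[0.8, 0.2], size=len(patient_rows)),
        index=[r[0] for r in patient_rows],
    )
    per_patient_dur = pd.Series(
        rng.exponential(4.0, size=len(patient_rows)).round(1),
        index=[r[0] for r in patient_rows],
    )
    samples["age"] = per_patient_age.loc[samples["patient_id"]].to_numpy()
    samples["sex"] = per_patient_sex.loc[samples["patient_id"]].to_numpy()
    samples["disease_duration_years"] = np.where(
        is_ssc, per_patient_dur.loc[samples["patient_id"]].to_numpy(), np.nan
    )
    samples["original_subset_label"] = samples["subset"]
    sample_table = validate_sample_table(samples.drop(columns=["subset"]))

    truth = GroundTruth(
        subset_of_array=samples.set_index("array_id")["subset"].rename("subset"),
        program_of_gene=program_of_gene,
        program_sign=program_sign,
        batch_additive=batch_additive,
        batch_scale=batch_scale,
        activations=activ,
        params={"spec": spec},
    )
    return compendium, sample_table, truth


def simulate_timecourse(spec: TimeCourseSimSpec) -> tuple[TimeCourseSet, GroundTruth]:
    """Generate replicate agonist time courses with planted responder classes.

    Sustained genes follow the idealized step (0 at baselines, a plateau of
    |log2FC| ≥ min_effect from 2 h on); transient genes return to baseline by
    12 h; late-partial genes pass the 2-fold gate at 12 h only and therefore
    must not enter a derived signature.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    hours = np.asarray(spec.hours)
    post = hours > 0
    early = (hours >= 2) & (hours <= 8)
    h12 = hours == 12.0

    classes = np.array(["background"] * spec.n_genes, dtype=object)
    bounds = np.cumsum(
        [spec.n_sustained_up, spec.n_sustained_down, spec.n_transient, spec.n_late_partial]
    )
    classes[: bounds[0]] = "sustained_up"
    classes[bounds[0] : bounds[1]] = "sustained_down"
    classes[bounds[1] : bounds[2]] = "transient"
    classes[bounds[2] : bounds[3]] = "late_partial"
    gene_class = pd.Series(classes, index=genes, name="gene_class")

    amps = rng.uniform(spec.min_effect, spec.max_effect, size=spec.n_genes)
    sign = np.ones(spec.n_genes)
    sign[bounds[0] : bounds[1]] = -1.0
    sign[bounds[1] : bounds[2]] = np.where(rng.random(bounds[2] - bounds[1]) < 0.5, 1.0, -1.0)
    sign[bounds[2] : bounds[3]] = np.where(rng.random(bounds[3] - bounds[2]) < 0.5, 1.0, -1.0)
    effects = amps * sign
    effects[classes == "background"] = 0.0
    planted_effects = pd.Series(effects, index=genes, name="planted_log2fc")

    template = np.zeros((spec.n_genes, len(hours)))
    sustained = (classes == "sustained_up") | (classes == "sustained_down")
    template[np.ix_(sustained, post)] = effects[sustained, None]
    transient = classes == "transient"
    template[np.ix_(transient, early)] = effects[transient, None]
    late = classes == "late_partial"
    template[np.ix_(late, h12)] = effects[late, None]
    # 24 h value of late-partial genes sits well inside the 2-fold gate
    template[np.ix_(late, hours == 24.0)] = 0.4 * np.sign(effects[late, None])

    courses = []
    for _ in range(spec.n_replicate_courses):
        noise = rng.normal(0.0, spec.noise_sd, size=template.shape) if spec.noise_sd > 0 else 0.0
        courses.append(
            pd.DataFrame(
                template + noise,
                index=genes,
                columns=[f"h{h:g}_{i}" for i, h in enumerate(hours)],
            )
        )
    tc = TimeCourseSet(courses=courses, hours=spec.hours, agonist="synthetic")
    truth = GroundTruth(gene_class=gene_class, planted_effects=planted_effects,
                        params={"spec": spec})
    return tc, truth
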