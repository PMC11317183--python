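"""End-to-end orchestration of the two-phase screening workflow.

Phase I runs on a small early-disease discovery subset (by default 5
ACPA-positive and 5 ACPA-negative early RA cases against 3 healthy controls,
plus the blank / secondary-only / pooled-control reference arrays): array QC,
duplicate-concordant hit calling and candidate-antigen selection.  Phase II
evaluates the candidates on the full cohort: per-antibody cutoffs, ROC,
subgroup prevalence, clinical correlation and a 2-D embedding.  Finally the
candidate panel feeds the RBF-SVM classifier with RFE feature selection and
a specificity-anchored decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .array_io import (
    ArrayScan,
    CohortManifest,
    IntensityMatrix,
    NET_FLOOR,
    aggregate_duplicates,
    build_matrix,
)
from .diagnostics import (
    compare_prevalence,
    correlate_clinical,
    diagnostic_table,
    embed_cohort,
    prevalence,
    round_half_up,
)
from .errors import ConfigurationError
from .model import (
    ModelConfig,
    TrainingReport,
    compare_single_markers,
    evaluate,
    split_cohort,
    train_classifier,
)
from .screening import CandidateSet, QCReport, build_hit_table, qc_array, select_candidates
from .simulate import (
    EARLY_DURATION_YEARS,
    SimulatedCohort,
    SimulationConfig,
    simulate_cohort,
    simulate_qc_profile,
)

CLINICAL_VARIABLES = ["ESR", "CRP", "RF", "IgG", "DAS28", "SJC", "TJC", "SHS", "anti_ccp"]


@dataclass
class PipelineSettings:
    """Stage thresholds; defaults follow the screening protocol."""

    phase1_n_acpa_pos: int = 5
    phase1_n_acpa_neg: int = 5
    phase1_n_controls: int = 3
    presence_z: float = 3.0
    snr_min: float = 13.0
    fold_min: float = 2.5
    min_case_positive: int = 2
    max_control_positive: int = 0
    range_lo: float = 1000.0
    range_hi: float = 24000.0
    rpd_max: float = 30.0
    pass_fraction: float = 0.90
    control_pool: str = "all"
    n_case_train: int = 120
    n_control_train: int = 120


@dataclass
class PipelineResult:
    cohort: SimulatedCohort
    qc_report: QCReport
    hit_table: pd.DataFrame
    candidates: CandidateSet
    phase1_sample_ids: list[str]
    diagnostics: pd.DataFrame
    prevalence_comparisons: pd.DataFrame
    correlations: pd.DataFrame
    embedding: pd.DataFrame
    split: "object"
    training: TrainingReport
    eval_report: "object"
    marker_comparison: pd.DataFrame
    features: pd.DataFrame  # log10 intensities used by the classifier

    def informative_recall(self) -> float:
        """Fraction of planted informative antigens among the candidates."""
        truth = set(self.cohort.ground_truth.informative_probe_ids)
        if not truth:
            return float("nan")
        return len(truth & set(self.candidates.probe_ids)) / len(truth)

    def model_feature_recall(self) -> float:
        """Fraction of planted antigens in the model input kept by selection."""
        truth = set(self.cohort.ground_truth.informative_probe_ids)
        available = truth & set(self.features.columns)
        if not available:
            return float("nan")
        return len(available & set(self.training.model.feature_ids)) / len(available)


def phase1_sample_ids(
    manifest: CohortManifest, settings: PipelineSettings
) -> list[str]:
    """Pick the early-disease discovery subset for Phase I, deterministically.

    Early ACPA-positive and ACPA-negative cases (disease duration < 2 years,
    duration known) are taken in manifest order.
    """
    df = manifest.frame
    dur = pd.to_numeric(df["disease_duration"], errors="coerce")
    early = (df["role"] == "case") & dur.notna() & (dur < EARLY_DURATION_YEARS)
    pos = list(df.loc[early & (df["acpa_status"] == "positive"), "sample_id"])
    neg = list(df.loc[early & (df["acpa_status"] == "negative"), "sample_id"])
    if len(pos) < settings.phase1_n_acpa_pos or len(neg) < settings.phase1_n_acpa_neg:
        raise ConfigurationError(
            f"not enough early cases for Phase I "
            f"(ACPA+ {len(pos)}/{settings.phase1_n_acpa_pos}, "
            f"ACPA- {len(neg)}/{settings.phase1_n_acpa_neg})"
        )
    hc = manifest.hc_ids
    if len(hc) < settings.phase1_n_controls:
        raise ConfigurationError("not enough healthy controls for Phase I")
    return (
        pos[: settings.phase1_n_acpa_pos]
        + neg[: settings.phase1_n_acpa_neg]
        + hc[: settings.phase1_n_controls]
    )


def _scan_by_role(cohort: SimulatedCohort, role: str) -> ArrayScan:
    ids = cohort.manifest.ids_where(role=role)
    if not ids:
        raise ConfigurationError(f"cohort carries no {role!r} array")
    return cohort.scan(ids[0])


def classifier_features(matrix: IntensityMatrix, probe_ids: Sequence[str]) -> pd.DataFrame:
    """Log10 floored net intensities, the classifier's input representation."""
    x = matrix.net[list(probe_ids)].clip(lower=NET_FLOOR)
    x = x.fillna(x.median(axis=0))
    return np.log10(x)


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    settings: PipelineSettings | None = None,
    model_config: ModelConfig | None = None,
) -> PipelineResult:
    """Simulate a cohort and run screening, validation and modelling on it."""
    sim_config = sim_config or SimulationConfig()
    settings = settings or PipelineSettings()
    model_config = model_config or ModelConfig(seed=sim_config.seed)

    cohort = simulate_cohort(sim_config)
    manifest = cohort.manifest
    layout = cohort.layout

    # --- Phase I ---------------------------------------------------------
    qc_scan = simulate_qc_profile(sim_config)[0]
    qc_report = qc_array(
        qc_scan, layout,
        range_lo=settings.range_lo, range_hi=settings.range_hi,
        rpd_max=settings.rpd_max, pass_fraction=settings.pass_fraction,
    )
    p1_ids = phase1_sample_ids(manifest, settings)
    p1_scans = [cohort.scan(sid) for sid in p1_ids]
    blank = _scan_by_role(cohort, "blank")
    secondary = _scan_by_role(cohort, "secondary-only")
    pooled = _scan_by_role(cohort, "pooled-control")

    hit_table = build_hit_table(p1_scans, blank, secondary, layout,
                                presence_z=settings.presence_z)
    p1_matrix = build_matrix(p1_scans, layout, manifest)
    pooled_profile = aggregate_duplicates(pooled, layout)["net"]
    candidates = select_candidates(
        hit_table, p1_matrix, pooled_profile, manifest,
        snr_min=settings.snr_min, fold_min=settings.fold_min,
        min_case_positive=settings.min_case_positive,
        max_control_positive=settings.max_control_positive,
    )

    # --- Phase II --------------------------------------------------------
    serum_ids = manifest.case_ids + manifest.control_ids
    serum_scans = [cohort.scan(sid) for sid in serum_ids]
    matrix = build_matrix(serum_scans, layout, manifest)
    probe_ids = candidates.probe_ids
    diagnostics = diagnostic_table(matrix, manifest, probe_ids,
                                   control_pool=settings.control_pool)
    prevalences = _prevalence_comparisons(matrix, manifest, diagnostics)
    correlations = correlate_clinical(matrix, manifest, probe_ids, CLINICAL_VARIABLES)
    embedding = embed_cohort(
        IntensityMatrix(matrix.net[probe_ids], matrix.rpd[probe_ids],
                        matrix.snr[probe_ids]),
        seed=sim_config.seed,
    )

    # --- diagnostic model -------------------------------------------------
    features = classifier_features(matrix, probe_ids)
    split = split_cohort(
        manifest.case_ids, manifest.control_ids,
        settings.n_case_train, settings.n_control_train, seed=model_config.seed,
    )
    y_train = np.array([1] * len(split.train_cases) + [0] * len(split.train_controls))
    y_test = np.array([1] * len(split.test_cases) + [0] * len(split.test_controls))
    training = train_classifier(features.loc[split.train_ids], y_train, model_config)
    meta = manifest.frame.set_index("sample_id")
    eval_report = evaluate(
        training.model,
        features.loc[split.test_ids],
        y_test,
        acpa_status=meta.loc[split.test_ids, "acpa_status"],
    )
    markers = meta[["CH28", "NH26"]].astype(float)
    marker_comparison = compare_single_markers(
        markers.loc[split.train_ids], y_train,
        markers.loc[split.test_ids], y_test,
        target_specificity=model_config.target_specificity,
        combinations=[("CH28", "NH26")],
        model_sensitivity=eval_report.sensitivity,
    )

    return PipelineResult(
        cohort=cohort,
        qc_report=qc_report,
        hit_table=hit_table,
        candidates=candidates,
        phase1_sample_ids=p1_ids,
        diagnostics=diagnostics,
        prevalence_comparisons=prevalences,
        correlations=correlations,
        embedding=embedding,
        split=split,
        training=training,
        eval_report=eval_report,
        marker_comparison=marker_comparison,
        features=features,
    )


def _prevalence_comparisons(
    matrix: IntensityMatrix, manifest: CohortManifest, diagnostics: pd.DataFrame
) -> pd.DataFrame:
    """Early- vs established-stage positivity per antibody, overall and ACPA-negative.

    Cases with unknown disease duration are excluded from the comparison.
    """
    df = manifest.frame
    dur = pd.to_numeric(df["disease_duration"], errors="coerce")
    case = df["role"] == "case"
    early_ids = list(df.loc[case & dur.notna() & (dur < EARLY_DURATION_YEARS), "sample_id"])
    est_ids = list(df.loc[case & dur.notna() & (dur >= EARLY_DURATION_YEARS), "sample_id"])
    neg = set(df.loc[df["acpa_status"] == "negative", "sample_id"])

    records = []
    for pid, row in diagnostics.iterrows():
        cutoff = row["cutoff"]
        for subset, e_ids, s_ids in (
            ("all-RA", early_ids, est_ids),
            ("acpa-negative", [s for s in early_ids if s in neg],
             [s for s in est_ids if s in neg]),
        ):
            if not e_ids or not s_ids:
                continue
            pe = prevalence(matrix.net.loc[e_ids, pid], cutoff)
            ps = prevalence(matrix.net.loc[s_ids, pid], cutoff)
            test = compare_prevalence(
                (pe["n_positive"], pe["n_total"]), (ps["n_positive"], ps["n_total"])
            )
            records.append(
                {
                    "probe_id": pid,
                    "subset": subset,
                    "early_positive": pe["n_positive"],
                    "early_total": pe["n_total"],
                    "early_percent": pe["percent"],
                    "established_positive": ps["n_positive"],
                    "established_total": ps["n_total"],
                    "established_percent": ps["percent"],
                    "test_used": test["test_used"],
                    "p": test["p"],
                }
            )
    return pd.DataFrame(records)
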