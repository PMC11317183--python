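"""Synthetic serum-array cohorts with planted autoantibody signal.

The generator emulates the statistical structure a two-phase autoantibody
screen assumes: a duplicate-printed protein array, log-normal per-antigen
background reactivity, a small informative antigen subset whose reactivity is
elevated in cases (attenuated in ACPA-negative cases, boosted in early
disease), pooled-control / blank / secondary-antibody-only reference arrays,
and clinical covariates coupled to the informative antibodies through a
shared disease-activity factor.

Model for the latent serum reactivity of sample *s* on antigen *a* (log10
fluorescence units)::

    log10 L[s, a] = mu_a + sigma * z[s, a]                    (all samples)
                  + R[s, a] * (effect_a + boost_a + kappa * act_s)   (cases)

where ``mu_a`` is drawn uniformly from ``baseline_log_mean_range``, ``sigma``
is ``baseline_log_sd``, ``R`` is a Bernoulli responder indicator (not every
patient mounts a response against every informative antigen), ``effect_a`` is
``effect_size`` (times ``acpa_neg_attenuation`` for ACPA-negative cases),
``boost_a`` adds ``early_boost`` for early-disease cases (duration < 2 y) on
the designated early antigen subset, and ``act_s`` is a standard-normal
disease-activity factor shared with the clinical covariates at strength
``clinical_coupling``.  Each probe is rendered as two duplicate spots with
multiplicative log-normal technical noise of coefficient of variation
``duplicate_cv`` on top of a Gaussian local background.

Everything is drawn from a single seeded generator, so equal configurations
produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_io import (
    ArrayLayout,
    ArrayScan,
    CohortManifest,
    MANIFEST_COLUMNS,
    ProbeAnnotation,
    SpotRecord,
    write_layout,
    write_manifest,
    write_scan,
)
from .errors import ConfigurationError

#: disease duration (years) below which a patient counts as early-stage
EARLY_DURATION_YEARS = 2.0

#: log10-decades of antibody shift per unit disease-activity factor at
#: clinical_coupling = 1
_COUPLING_LOG_SCALE = 0.6

#: loadings of the clinical covariates on the disease-activity factor, with
#: (mean, sd, low, high) on their natural scales (means/sds follow typical
#: active-RA cohort values)
_CLINICAL_VARS: dict[str, tuple[float, float, float, float, float]] = {
    # name: (loading, mean, sd, lo, hi)
    "ESR": (0.6, 50.0, 32.0, 2.0, 140.0),
    "CRP": (0.5, 35.0, 40.0, 0.1, 200.0),
    "RF": (0.5, 120.0, 150.0, 5.0, 1500.0),
    "IgG": (0.45, 13.0, 4.0, 5.0, 30.0),
    "DAS28": (0.6, 4.3, 1.5, 0.5, 9.4),
    "SJC": (0.45, 7.0, 8.6, 0.0, 40.0),
    "TJC": (0.45, 8.0, 9.0, 0.0, 40.0),
    "SHS": (0.2, 74.0, 51.0, 0.0, 300.0),
}

_CONTROL_PROBES = [
    ("CTRL-buffer", "buffer", "buffer", 0.0),
    ("CTRL-hIgG", "Human IgG", "human-IgG", 20000.0),
    ("CTRL-hIgM", "Human IgM", "human-IgM", 8000.0),
    ("CTRL-bBSA", "Biotin-BSA", "biotin-BSA", 15000.0),
    ("CTRL-BSA", "BSA", "BSA", 0.0),
    ("CTRL-GST", "GST", "GST-control", 3000.0),
]


@dataclass
class SimulationConfig:
    """All tunable parameters of the cohort generator.

    Default group sizes mirror a two-phase RA screening cohort: 182 RA cases
    of which 48 ACPA-negative, 103 healthy controls and 158 disease controls
    (48 AS, 47 SLE, 31 SS, 32 OA).
    """

    seed: int = 0
    n_probes: int = 200
    n_informative: int = 15
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"RA": 182, "HC": 103, "AS": 48, "SLE": 47, "SS": 31, "OA": 32}
    )
    n_acpa_negative: int = 48
    effect_size: float = 0.6
    acpa_neg_attenuation: float = 0.5
    early_boost: float = 1.4
    early_subset_fraction: float = 1.0
    responder_rate: float = 0.5
    duplicate_cv: float = 0.08
    background_mean: float = 300.0
    background_sd: float = 60.0
    baseline_log_mean_range: tuple[float, float] = (1.3, 1.4)
    baseline_log_sd: float = 0.4
    clinical_coupling: float = 0.4
    duration_scale_years: float = 5.0
    duration_missing_rate: float = 0.16
    ch28_responder_rate: float = 0.5
    nh26_responder_rate: float = 0.2
    marker_shift: float = 1.0
    qc_log_mean: float = 3.65
    qc_log_sd: float = 0.35
    block_rows: int = 25
    block_cols: int = 32

    def __post_init__(self) -> None:
        if self.n_informative > self.n_probes:
            raise ConfigurationError("n_informative must be <= n_probes")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be >= 0")
        if sum(self.group_sizes.values()) == 0:
            raise ConfigurationError("empty cohort: group sizes sum to 0")
        if self.duplicate_cv < 0:
            raise ConfigurationError("duplicate_cv must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: informative antigens, effects and latent intensities."""

    informative_probe_ids: list[str]
    effects: pd.Series  # log10 shift per probe for an ACPA-positive case
    early_subset_ids: list[str]
    latent: pd.DataFrame  # serum samples x probes, log10 latent intensity
    responders: pd.DataFrame  # case samples x informative probes, bool


@dataclass
class SimulatedCohort:
    layout: ArrayLayout
    scans: list[ArrayScan]
    manifest: CohortManifest
    ground_truth: GroundTruth

    def scan(self, sample_id: str) -> ArrayScan:
        for s in self.scans:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# layout construction
# ---------------------------------------------------------------------------


def build_layout(
    n_probes: int, block_rows: int = 25, block_cols: int = 32
) -> ArrayLayout:
    """A duplicate-printed layout with the six standard control probes.

    Protein probes are placed at consecutive positions in duplicate, filling
    blocks of ``block_rows x block_cols`` spots; controls are appended after
    the proteins, also in duplicate.
    """
    probes: dict[str, ProbeAnnotation] = {}
    order: list[str] = []
    for i in range(1, n_probes + 1):
        pid = f"P{i:05d}"
        probes[pid] = ProbeAnnotation(pid, f"AG{i:05d}", f"NM_{900000 + i:06d}", "protein")
        order.append(pid)
    for pid, name, category, _level in _CONTROL_PROBES:
        probes[pid] = ProbeAnnotation(pid, name, "", category)
        order.append(pid)

    per_block = block_rows * block_cols
    total_spots = 2 * len(order)
    n_blocks = max(1, math.ceil(total_spots / per_block))
    placements: dict[tuple[int, int, int], str] = {}
    idx = 0
    for pid in order:
        for _ in range(2):
            block = idx // per_block + 1
            within = idx % per_block
            placements[(block, within // block_cols + 1, within % block_cols + 1)] = pid
            idx += 1
    return ArrayLayout(n_blocks, block_rows, block_cols, placements, probes)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _render_scan(
    rng: np.random.Generator,
    layout: ArrayLayout,
    signal_by_probe: Mapping[str, float],
    scan_id: str,
    sample_id: str,
    cfg: SimulationConfig,
) -> ArrayScan:
    """Render per-probe latent signals as duplicate spots over background."""
    sln = math.sqrt(math.log1p(cfg.duplicate_cv**2)) if cfg.duplicate_cv > 0 else 0.0
    coords = list(layout.placements)
    n = len(coords)
    bg = cfg.background_mean + cfg.background_sd * rng.standard_normal(n)
    # quantise to 1/64 fluorescence units (dyadic rationals), so fg - bg
    # recovers the rendered signal exactly in binary floating point
    bg = np.round(np.maximum(bg, 1.0) * 64.0) / 64.0
    eta = np.exp(sln * rng.standard_normal(n)) if sln > 0 else np.ones(n)
    spots = []
    for i, coord in enumerate(coords):
        pid = layout.placements[coord]
        signal = np.round(signal_by_probe.get(pid, 0.0) * eta[i] * 64.0) / 64.0
        spots.append(
            SpotRecord(
                *coord,
                fg={532: bg[i] + signal},
                bg={532: bg[i]},
                bg_sd={532: cfg.background_sd},
                flag=0,
            )
        )
    return ArrayScan(scan_id=scan_id, sample_id=sample_id, spots=spots)


def _control_signal_map(blank: bool = False) -> dict[str, float]:
    if blank:
        return {pid: 0.0 for pid, _, _, _ in _CONTROL_PROBES}
    return {pid: level for pid, _, _, level in _CONTROL_PROBES}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort: layout, per-sample scans, manifest, truth.

    Reference arrays included besides the serum samples: a pooled-control
    array (per-probe geometric mean of the healthy-control latent intensities
    with fresh technical noise) and blank / secondary-antibody-only arrays
    carrying background-only signal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    layout = build_layout(cfg.n_probes, cfg.block_rows, cfg.block_cols)
    probe_ids = layout.protein_probe_ids

    # --- sample bookkeeping -------------------------------------------------
    sample_ids: list[str] = []
    groups: list[str] = []
    roles: list[str] = []
    for group, size in cfg.group_sizes.items():
        for i in range(1, size + 1):
            sample_ids.append(f"{group}{i:04d}")
            groups.append(group)
            roles.append("case" if group == "RA" else "control")
    n_serum = len(sample_ids)
    case_mask = np.array([r == "case" for r in roles])
    hc_mask = np.array([g == "HC" for g in groups])
    n_cases = int(case_mask.sum())

    # --- planted truth ------------------------------------------------------
    mu = rng.uniform(*cfg.baseline_log_mean_range, size=cfg.n_probes)
    informative_idx = np.sort(
        rng.choice(cfg.n_probes, size=cfg.n_informative, replace=False)
    )
    informative_ids = [probe_ids[i] for i in informative_idx]
    n_early_subset = int(round(cfg.early_subset_fraction * cfg.n_informative))
    early_subset_idx = informative_idx[:n_early_subset]
    early_subset_ids = [probe_ids[i] for i in early_subset_idx]

    # --- case phenotypes ----------------------------------------------------
    n_neg = min(cfg.n_acpa_negative, n_cases)
    acpa_negative_case = np.zeros(n_cases, dtype=bool)
    acpa_negative_case[rng.choice(n_cases, size=n_neg, replace=False)] = True
    duration = np.round(rng.exponential(cfg.duration_scale_years, size=n_cases), 2)
    duration_missing = rng.random(n_cases) < cfg.duration_missing_rate
    early = (duration < EARLY_DURATION_YEARS) & ~duration_missing
    activity = rng.standard_normal(n_cases)

    # --- latent intensities -------------------------------------------------
    z = rng.standard_normal((n_serum, cfg.n_probes))
    latent_log = mu[None, :] + cfg.baseline_log_sd * z

    responders = rng.random((n_cases, cfg.n_informative)) < cfg.responder_rate
    effect_per_case = np.where(
        acpa_negative_case,
        cfg.effect_size * cfg.acpa_neg_attenuation,
        cfg.effect_size,
    )
    kappa = _COUPLING_LOG_SCALE * cfg.clinical_coupling
    in_early_subset = np.isin(informative_idx, early_subset_idx)
    case_rows = np.nonzero(case_mask)[0]
    for ci, row in enumerate(case_rows):
        if effect_per_case[ci] <= 0:
            continue  # no planted effect, hence no response to boost or couple
        shift = effect_per_case[ci] + kappa * activity[ci]
        boosts = np.where(early[ci] & in_early_subset, cfg.early_boost, 0.0)
        latent_log[row, informative_idx] += responders[ci] * np.maximum(shift + boosts, 0.0)

    effects = pd.Series(0.0, index=probe_ids, name="effect")
    effects.iloc[informative_idx] = cfg.effect_size

    # --- manifest -----------------------------------------------------------
    anti_ccp = np.full(n_serum, np.nan)
    ccp_cases_pos = np.maximum(26.0, 10 ** (1.7 + 0.45 * rng.standard_normal(n_cases)))
    ccp_cases_neg = rng.uniform(2.0, 20.0, size=n_cases)
    anti_ccp[case_mask] = np.where(acpa_negative_case, ccp_cases_neg, ccp_cases_pos)
    anti_ccp[~case_mask] = rng.uniform(1.0, 15.0, size=n_serum - n_cases)
    anti_ccp = np.round(anti_ccp, 1)

    clinical: dict[str, np.ndarray] = {}
    for name, (loading, mean, sd, lo, hi) in _CLINICAL_VARS.items():
        eps = rng.standard_normal(n_cases)
        vals = mean + sd * (loading * activity + math.sqrt(1 - loading**2) * eps)
        col = np.full(n_serum, np.nan)
        col[case_mask] = np.round(np.clip(vals, lo, hi), 1)
        clinical[name] = col

    def _marker(responder_rate: float) -> np.ndarray:
        base = 1.35 + 0.25 * rng.standard_normal(n_serum)
        resp = rng.random(n_serum) < responder_rate
        reacts = case_mask & ~np.isin(np.arange(n_serum), case_rows[acpa_negative_case]) & resp
        return np.round(10 ** (base + np.where(reacts, cfg.marker_shift, 0.0)), 2)

    ch28 = _marker(cfg.ch28_responder_rate)
    nh26 = _marker(cfg.nh26_responder_rate)

    dur_col = np.full(n_serum, np.nan)
    dur_case = duration.astype(float).copy()
    dur_case[duration_missing] = np.nan
    dur_col[case_mask] = dur_case

    rows = []
    for i, sid in enumerate(sample_ids):
        status = "negative"
        if case_mask[i]:
            ci = int(np.searchsorted(case_rows, i))
            status = "negative" if acpa_negative_case[ci] else "positive"
        rows.append(
            {
                "sample_id": sid,
                "group": groups[i],
                "role": roles[i],
                "acpa_status": status,
                "anti_ccp": anti_ccp[i],
                "disease_duration": dur_col[i],
                **{k: clinical[k][i] for k in _CLINICAL_VARS},
                "CH28": ch28[i],
                "NH26": nh26[i],
            }
        )
    for sid, group, role in (
        ("POOL0001", "HC", "pooled-control"),
        ("BLANK001", "HC", "blank"),
        ("SECOND01", "HC", "secondary-only"),
    ):
        rows.append(
            {
                "sample_id": sid,
                "group": group,
                "role": role,
                "acpa_status": "unknown",
                **{k: np.nan for k in MANIFEST_COLUMNS if k not in
                   ("sample_id", "group", "role", "acpa_status")},
            }
        )
    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))

    # --- render scans -------------------------------------------------------
    control_signals = _control_signal_map()
    scans: list[ArrayScan] = []
    for i, sid in enumerate(sample_ids):
        signals = dict(zip(probe_ids, 10 ** latent_log[i]))
        signals.update(control_signals)
        scans.append(_render_scan(rng, layout, signals, f"scan-{sid}", sid, cfg))

    pooled_log = latent_log[hc_mask].mean(axis=0) if hc_mask.any() else np.zeros(cfg.n_probes)
    pooled_signals = dict(zip(probe_ids, 10 ** pooled_log))
    pooled_signals.update(control_signals)
    scans.append(_render_scan(rng, layout, pooled_signals, "scan-POOL0001", "POOL0001", cfg))
    scans.append(_render_scan(rng, layout, _control_signal_map(blank=True),
                              "scan-BLANK001", "BLANK001", cfg))
    scans.append(_render_scan(rng, layout, _control_signal_map(blank=True),
                              "scan-SECOND01", "SECOND01", cfg))

    truth = GroundTruth(
        informative_probe_ids=informative_ids,
        effects=effects,
        early_subset_ids=early_subset_ids,
        latent=pd.DataFrame(latent_log, index=sample_ids, columns=probe_ids),
        responders=pd.DataFrame(
            responders, index=[sample_ids[r] for r in case_rows], columns=informative_ids
        ),
    )
    return SimulatedCohort(layout, scans, manifest, truth)


def simulate_qc_profile(config: SimulationConfig, n_scans: int = 1) -> list[ArrayScan]:
    """Anti-GST-style quality-control scans where every protein spot lights up.

    Per-probe intensities are drawn log10-normal with ``qc_log_mean`` and
    ``qc_log_sd``, calibrated so that roughly 95% of protein spots fall in the
    canonical [1000, 24000] fluorescence window and duplicate agreement
    reflects ``duplicate_cv``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    layout = build_layout(cfg.n_probes, cfg.block_rows, cfg.block_cols)
    probe_ids = layout.protein_probe_ids
    scans = []
    for k in range(n_scans):
        levels = 10 ** (cfg.qc_log_mean + cfg.qc_log_sd * rng.standard_normal(cfg.n_probes))
        signals = dict(zip(probe_ids, levels))
        signals.update(_control_signal_map())
        signals["CTRL-GST"] = 20000.0
        sid = f"QC{k + 1:04d}"
        scans.append(_render_scan(rng, layout, signals, f"scan-{sid}", sid, cfg))
    return scans


# ---------------------------------------------------------------------------
# on-disk rendering
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write layout, manifest, all scans and the ground truth under a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_layout(cohort.layout, out / "layout.gal")
    write_manifest(cohort.manifest, out / "manifest.tsv")
    scan_dir = out / "scans"
    scan_dir.mkdir(exist_ok=True)
    for scan in cohort.scans:
        write_scan(scan, cohort.layout, scan_dir / f"{scan.sample_id}.gpr")
    truth = {
        "informative_probe_ids": cohort.ground_truth.informative_probe_ids,
        "early_subset_ids": cohort.ground_truth.early_subset_ids,
        "effects": {
            k: v for k, v in cohort.ground_truth.effects.items() if v != 0.0
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["group_sizes"] = dict(config.group_sizes)
    d["baseline_log_mean_range"] = list(config.baseline_log_mean_range)
    return d
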