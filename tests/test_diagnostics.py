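"""Cutoffs, ROC arithmetic, prevalence tests, correlation grid and embedding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seroscreen.array_io import IntensityMatrix
from seroscreen.diagnostics import (
    auc_score,
    compare_prevalence,
    correlate_clinical,
    diagnostic_table,
    embed_cohort,
    prevalence,
    roc_auc,
    round_half_up,
    sens_spec,
    seropositivity_cutoff,
)
from seroscreen.errors import InsufficientDataError


# ---------------------------------------------------------------------------
# seropositivity cutoff
# ---------------------------------------------------------------------------


def test_cutoff_is_mean_plus_two_sd():
    # mean 100, sample SD 20 -> cutoff 140
    assert seropositivity_cutoff([80.0, 100.0, 120.0]) == pytest.approx(140.0)


def test_cutoff_of_constant_controls():
    cutoff = seropositivity_cutoff([55.0, 55.0, 55.0])
    assert cutoff == 55.0
    assert sens_spec([55.1], [55.0], cutoff)["sensitivity"] == 1.0


def test_cutoff_needs_two_values():
    with pytest.raises(InsufficientDataError):
        seropositivity_cutoff([1.0])


def test_gaussian_cutoff_specificity_matches_normal_tail():
    rng = np.random.default_rng(42)
    draws = rng.standard_normal(50_000)
    cutoff = seropositivity_cutoff(draws)
    specificity = np.mean(draws <= cutoff)
    assert specificity == pytest.approx(0.9772, abs=0.003)


# ---------------------------------------------------------------------------
# sensitivity / specificity
# ---------------------------------------------------------------------------


def test_sens_spec_extremes_and_hand_count():
    assert sens_spec([2, 3], [0, 1], 1.5) == pytest.approx(
        {"sensitivity": 1.0, "specificity": 1.0, "n_case": 2, "n_control": 2,
         "n_case_positive": 2, "n_control_positive": 0}
    )
    assert sens_spec([2, 3], [0, 1], 99.0)["sensitivity"] == 0.0
    assert sens_spec([2, 3], [0, 1], 99.0)["specificity"] == 1.0
    cases = [1, 2, 3, 6, 6, 6, 6, 7, 8, 9]  # 7 above cutoff 5
    controls = [1, 2, 3, 4, 4, 4, 5, 5, 6, 7]  # 2 above cutoff 5
    out = sens_spec(cases, controls, 5.0)
    assert (out["sensitivity"], out["specificity"]) == (0.7, 0.8)


def test_sens_spec_monotone_in_cutoff():
    rng = np.random.default_rng(0)
    cases, controls = rng.normal(1, 1, 40), rng.normal(0, 1, 40)
    cuts = np.linspace(-4, 4, 30)
    sens = [sens_spec(cases, controls, c)["sensitivity"] for c in cuts]
    spec = [sens_spec(cases, controls, c)["specificity"] for c in cuts]
    assert all(a >= b for a, b in zip(sens, sens[1:]))
    assert all(a <= b for a, b in zip(spec, spec[1:]))
    assert sens_spec(cases, controls, -np.inf)["sensitivity"] == 1.0
    assert sens_spec(cases, controls, np.inf)["specificity"] == 1.0


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_auc_trivial_cases():
    assert roc_auc([10, 11], [1, 2]).auc == 1.0
    assert roc_auc([5, 5, 5], [5, 5]).auc == 0.5


def test_auc_equals_pairwise_concordance_with_ties():
    rng = np.random.default_rng(1)
    for _ in range(25):
        m, n = rng.integers(1, 30, 2)
        cases = rng.integers(0, 6, m).astype(float)
        controls = rng.integers(0, 6, n).astype(float)
        brute = np.mean(
            [1.0 if c > d else 0.5 if c == d else 0.0 for c in cases for d in controls]
        )
        assert auc_score(cases, controls) == brute


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 9), min_size=1, max_size=15),
    st.lists(st.integers(0, 9), min_size=1, max_size=15),
)
def test_auc_complement_symmetry(a, b):
    assert auc_score(a, b) + auc_score(b, a) == pytest.approx(1.0)


def test_delong_interval_brackets_auc_and_tightens():
    rng = np.random.default_rng(2)
    small = roc_auc(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
    large = roc_auc(rng.normal(1, 1, 500), rng.normal(0, 1, 500))
    for res in (small, large):
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
    assert (large.ci_high - large.ci_low) < (small.ci_high - small.ci_low)


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_pos,total,pct", [(10, 48, 20.8), (13, 48, 27.1), (0, 31, 0.0)])
def test_prevalence_percent_rendering(n_pos, total, pct):
    values = np.r_[np.full(n_pos, 2.0), np.full(total - n_pos, 0.0)]
    out = prevalence(values, 1.0)
    assert out == {"n_positive": n_pos, "n_total": total, "percent": pct}


def test_round_half_up_matches_table_rendering():
    assert round_half_up(20.83333, 1) == 20.8
    assert round_half_up(27.0833, 1) == 27.1
    assert round_half_up(0.25, 1) == 0.3  # half rounds up, not to even


def test_compare_prevalence_test_choice():
    equal_small = compare_prevalence((2, 4), (2, 4))
    assert equal_small["test_used"] == "fisher"
    assert equal_small["p"] == 1.0
    fisher = compare_prevalence((6, 13), (2, 35))
    assert fisher["test_used"] == "fisher"
    chi = compare_prevalence((50, 100), (50, 100))
    assert chi["test_used"] == "chi-square"
    assert chi["p"] == 1.0


# ---------------------------------------------------------------------------
# diagnostic table
# ---------------------------------------------------------------------------


def test_diagnostic_table_recovers_planted_separation(small_cohort):
    from seroscreen.array_io import build_matrix

    manifest = small_cohort.manifest
    serum = manifest.case_ids + manifest.control_ids
    matrix = build_matrix([small_cohort.scan(s) for s in serum],
                          small_cohort.layout, manifest)
    info = small_cohort.ground_truth.informative_probe_ids
    table = diagnostic_table(matrix, manifest, probe_ids=list(matrix.probe_ids))
    null_probes = [p for p in matrix.probe_ids if p not in info]
    assert table.loc[info, "auc"].mean() > table.loc[null_probes, "auc"].mean() + 0.1
    assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()
    # ACPA-negative prevalence columns render consistently
    pct = 100 * table["acpa_neg_n_positive"] / table["acpa_neg_n_total"]
    assert all(round_half_up(v, 1) == w for v, w in zip(pct, table["acpa_neg_percent"]))


# ---------------------------------------------------------------------------
# clinical correlation
# ---------------------------------------------------------------------------


def _matrix_from_frame(net: pd.DataFrame) -> IntensityMatrix:
    shape = pd.DataFrame(0.0, index=net.index, columns=net.columns)
    return IntensityMatrix(net=net, rpd=shape, snr=shape)


def test_antibody_correlated_with_itself():
    rng = np.random.default_rng(3)
    from conftest import make_manifest

    ids = [f"RA{i}" for i in range(20)]
    manifest = make_manifest([(s, "RA", "case") for s in ids])
    vals = rng.lognormal(3, 1, 20)
    manifest.frame["ESR"] = vals
    net = pd.DataFrame({"P1": vals}, index=ids)
    grid = correlate_clinical(_matrix_from_frame(net), manifest, ["P1"], ["ESR"])
    assert grid.loc[0, "r"] == pytest.approx(1.0)


def test_independent_variable_survives_bonferroni():
    rng = np.random.default_rng(4)
    from conftest import make_manifest

    ids = [f"RA{i}" for i in range(150)]
    manifest = make_manifest([(s, "RA", "case") for s in ids])
    for var in ("ESR", "CRP", "RF"):
        manifest.frame[var] = rng.normal(50, 10, 150)
    net = pd.DataFrame(rng.lognormal(3, 0.5, (150, 5)),
                       index=ids, columns=[f"P{i}" for i in range(5)])
    grid = correlate_clinical(_matrix_from_frame(net), manifest,
                              list(net.columns), ["ESR", "CRP", "RF"])
    assert grid["n_tests"].iloc[0] == 15
    assert (grid["p_bonferroni"] > 0.05).all()


def test_sparse_cells_excluded_from_bonferroni():
    from conftest import make_manifest

    ids = [f"RA{i}" for i in range(10)]
    manifest = make_manifest([(s, "RA", "case") for s in ids])
    manifest.frame["ESR"] = np.r_[[50.0, 60.0], [math.nan] * 8]  # only 2 pairs
    manifest.frame["CRP"] = np.linspace(1, 10, 10)
    net = pd.DataFrame({"P1": np.linspace(100, 200, 10)}, index=ids)
    grid = correlate_clinical(_matrix_from_frame(net), manifest, ["P1"], ["ESR", "CRP"])
    esr = grid[grid["variable"] == "ESR"].iloc[0]
    assert esr["method"] == "none" and math.isnan(esr["r"])
    assert grid["n_tests"].iloc[0] == 1


def test_planted_clinical_coupling_recovered(small_cohort):
    from seroscreen.array_io import build_matrix

    manifest = small_cohort.manifest
    serum = manifest.case_ids + manifest.control_ids
    matrix = build_matrix([small_cohort.scan(s) for s in serum],
                          small_cohort.layout, manifest)
    info = small_cohort.ground_truth.informative_probe_ids
    grid = correlate_clinical(matrix, manifest, info, ["ESR", "RF", "IgG"])
    assert grid["r"].mean() > 0.05


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def test_embedding_deterministic_and_finite():
    rng = np.random.default_rng(5)
    net = pd.DataFrame(rng.lognormal(3, 0.5, (30, 8)),
                       index=[f"S{i}" for i in range(30)],
                       columns=[f"P{i}" for i in range(8)])
    a = embed_cohort(_matrix_from_frame(net), seed=9)
    b = embed_cohort(_matrix_from_frame(net), seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert np.isfinite(a.to_numpy()).all()


def test_embedding_of_identical_samples_is_finite():
    net = pd.DataFrame(100.0, index=[f"S{i}" for i in range(5)], columns=["P1", "P2"])
    coords = embed_cohort(_matrix_from_frame(net), seed=0)
    assert np.isfinite(coords.to_numpy()).all()


def test_embedding_too_few_samples():
    net = pd.DataFrame(100.0, index=["S1", "S2"], columns=["P1"])
    with pytest.raises(InsufficientDataError):
        embed_cohort(_matrix_from_frame(net), seed=0)


def test_embedding_separates_two_clusters():
    rng = np.random.default_rng(6)
    a = rng.normal(0, 0.2, (20, 6)) + 3.0
    b = rng.normal(0, 0.2, (20, 6)) + 5.0
    net = pd.DataFrame(10 ** np.vstack([a, b]),
                       index=[f"S{i}" for i in range(40)],
                       columns=[f"P{i}" for i in range(6)])
    coords = embed_cohort(_matrix_from_frame(net), seed=1).to_numpy()
    intra = np.mean([np.linalg.norm(coords[i] - coords[j])
                     for grp in (range(20), range(20, 40))
                     for i in grp for j in grp if i < j])
    inter = np.mean([np.linalg.norm(coords[i] - coords[j])
                     for i in range(20) for j in range(20, 40)])
    assert inter > intra
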