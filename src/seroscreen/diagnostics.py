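"""Per-antibody diagnostic evaluation and cohort-level statistics.

Seropositivity is defined against a cutoff set 2 standard deviations above
the healthy-control mean; a sample is positive when its intensity is
strictly above the cutoff.  Discrimination is summarised by the
nonparametric (Mann-Whitney) area under the ROC curve with a DeLong 95%
confidence interval.  Subgroup prevalences are compared by chi-square with
continuity correction, or Fisher's exact test when any expected cell count
falls below 5.  Antibody / clinical-variable association uses Spearman rank
correlation by default, switching to Pearson only when both variables pass a
Shapiro-Wilk normality screen, with Bonferroni correction over the number of
tests actually performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .array_io import CohortManifest, IntensityMatrix, NET_FLOOR
from .errors import InsufficientDataError


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, matching how report tables render percents."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# cutoffs, sensitivity/specificity, ROC
# ---------------------------------------------------------------------------


def seropositivity_cutoff(hc_values) -> float:
    """Cutoff = mean + 2 SD of the healthy-control intensities (SD with n-1).

    Downstream positivity means a value strictly above the cutoff.
    """
    vals = np.asarray(hc_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise InsufficientDataError("need >= 2 healthy-control values for a cutoff")
    return float(vals.mean() + 2.0 * vals.std(ddof=1))


def sens_spec(case_values, control_values, cutoff: float) -> dict:
    """Sensitivity and specificity of a strict-> cutoff on two groups."""
    cases = np.asarray(case_values, dtype=float)
    cases = cases[~np.isnan(cases)]
    controls = np.asarray(control_values, dtype=float)
    controls = controls[~np.isnan(controls)]
    if cases.size == 0 or controls.size == 0:
        raise InsufficientDataError("sens_spec requires non-empty case and control groups")
    tp = int((cases > cutoff).sum())
    tn = int((controls <= cutoff).sum())
    return {
        "sensitivity": tp / cases.size,
        "specificity": tn / controls.size,
        "n_case": int(cases.size),
        "n_control": int(controls.size),
        "n_case_positive": tp,
        "n_control_positive": int(controls.size - tn),
    }


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def auc_score(case_values, control_values) -> float:
    """Mann-Whitney concordance: P(case > control) + 0.5 P(tie).

    Computed with midranks, which equals the exhaustive all-pairs count
    exactly (ties contribute 1/2).
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    m, n = cases.size, controls.size
    if m == 0 or n == 0:
        raise InsufficientDataError("roc_auc requires non-empty case and control groups")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    r_case = ranks[:m].sum()
    return float((r_case - m * (m + 1) / 2.0) / (m * n))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def roc_auc(case_values, control_values) -> RocResult:
    """Nonparametric AUC with a DeLong 95% confidence interval.

    The variance uses the DeLong structural components; with fewer than two
    observations in either arm the interval is undefined (NaN bounds).
    """
    cases = np.asarray(case_values, dtype=float)
    cases = cases[~np.isnan(cases)]
    controls = np.asarray(control_values, dtype=float)
    controls = controls[~np.isnan(controls)]
    m, n = cases.size, controls.size
    if m == 0 or n == 0:
        raise InsufficientDataError("roc_auc requires non-empty case and control groups")

    tx = _midrank(cases)
    ty = _midrank(controls)
    tz = _midrank(np.concatenate([cases, controls]))
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v10 = (tz[:m] - tx) / n  # per-case placement
    v01 = 1.0 - (tz[m:] - ty) / m  # per-control placement
    if m >= 2 and n >= 2:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
        half = 1.959963984540054 * math.sqrt(max(var, 0.0))
        lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    else:
        lo = hi = math.nan
    return RocResult(auc, lo, hi)


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def prevalence(values, cutoff: float, n_total: int | None = None) -> dict:
    """Count of values strictly above the cutoff and the percent (1 decimal)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    n_pos = int((vals > cutoff).sum())
    total = int(n_total) if n_total is not None else int(vals.size)
    if total < 1:
        raise InsufficientDataError("prevalence requires n_total >= 1")
    return {
        "n_positive": n_pos,
        "n_total": total,
        "percent": round_half_up(100.0 * n_pos / total, 1),
    }


def compare_prevalence(group_a: tuple[int, int], group_b: tuple[int, int]) -> dict:
    """Compare two positivity proportions with chi-square or Fisher's exact.

    ``group_a`` / ``group_b`` are ``(n_positive, n_total)`` pairs.  Fisher's
    exact test is used when any expected cell count is below 5, otherwise
    chi-square with continuity correction.
    """
    a_pos, a_tot = group_a
    b_pos, b_tot = group_b
    if a_tot < 1 or b_tot < 1:
        raise InsufficientDataError("compare_prevalence requires totals >= 1")
    table = np.array([[a_pos, a_tot - a_pos], [b_pos, b_tot - b_pos]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 5).any():
        stat, p = stats.fisher_exact(table)
        test_used = "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=True)
        test_used = "chi-square"
    return {"test_used": test_used, "statistic": float(stat), "p": float(p)}


# ---------------------------------------------------------------------------
# per-antibody report
# ---------------------------------------------------------------------------


def diagnostic_table(
    matrix: IntensityMatrix,
    manifest: CohortManifest,
    probe_ids: list[str] | None = None,
    control_pool: str = "all",
) -> pd.DataFrame:
    """Per-antibody cutoff, ROC and subgroup prevalence over a cohort.

    Cutoffs come from healthy controls only; sensitivity/specificity and the
    AUC compare cases against either all control-role samples
    (``control_pool="all"``, the default) or healthy controls only
    (``control_pool="hc"``).  The ACPA-negative columns report prevalence
    within ACPA-negative cases.
    """
    if control_pool not in ("all", "hc"):
        raise ValueError("control_pool must be 'all' or 'hc'")
    case_ids = manifest.case_ids
    hc_ids = manifest.hc_ids
    ctrl_ids = manifest.control_ids if control_pool == "all" else hc_ids
    acpa_neg_ids = manifest.ids_where(role="case", acpa_status="negative")
    probes = probe_ids if probe_ids is not None else matrix.probe_ids

    records = []
    for pid in probes:
        col = matrix.net[pid]
        cutoff = seropositivity_cutoff(col.loc[hc_ids])
        cases = col.loc[case_ids].to_numpy(dtype=float)
        controls = col.loc[ctrl_ids].to_numpy(dtype=float)
        ss = sens_spec(cases, controls, cutoff)
        roc = roc_auc(cases, controls)
        neg = prevalence(col.loc[acpa_neg_ids], cutoff) if acpa_neg_ids else {
            "n_positive": 0, "n_total": 0, "percent": math.nan}
        records.append(
            {
                "probe_id": pid,
                "cutoff": cutoff,
                "auc": roc.auc,
                "auc_ci_low": roc.ci_low,
                "auc_ci_high": roc.ci_high,
                "sensitivity_pct": round_half_up(100 * ss["sensitivity"], 1),
                "specificity_pct": round_half_up(100 * ss["specificity"], 1),
                "acpa_neg_n_positive": neg["n_positive"],
                "acpa_neg_n_total": neg["n_total"],
                "acpa_neg_percent": neg["percent"],
            }
        )
    return (
        pd.DataFrame(records)
        .set_index("probe_id")
        .sort_values(by=["auc", "probe_id"], ascending=[False, True], kind="mergesort")
    )


# ---------------------------------------------------------------------------
# clinical correlation
# ---------------------------------------------------------------------------


def correlate_clinical(
    matrix: IntensityMatrix,
    manifest: CohortManifest,
    antibodies: list[str],
    variables: list[str],
    normality_alpha: float = 0.05,
    min_pairs: int = 3,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Antibody x clinical-variable correlation grid with Bonferroni correction.

    Each cell uses pairwise-complete observations restricted to case samples.
    Cells with fewer than ``min_pairs`` pairs are reported with NaN and are
    excluded from the Bonferroni factor, which multiplies each raw p by the
    number of tests actually performed.
    """
    case_ids = [s for s in manifest.case_ids if s in matrix.net.index]
    meta = manifest.frame.set_index("sample_id").loc[case_ids]
    records = []
    for pid in antibodies:
        x_all = matrix.net[pid].loc[case_ids].astype(float)
        if log_transform:
            x_all = np.log10(x_all.clip(lower=NET_FLOOR))
        for var in variables:
            y_all = pd.to_numeric(meta[var], errors="coerce")
            ok = x_all.notna() & y_all.notna()
            n = int(ok.sum())
            if n < min_pairs:
                records.append((pid, var, n, "none", math.nan, math.nan))
                continue
            x = x_all[ok].to_numpy()
            y = y_all[ok].to_numpy()
            use_pearson = (
                n >= 3
                and np.ptp(x) > 0
                and np.ptp(y) > 0
                and stats.shapiro(x).pvalue > normality_alpha
                and stats.shapiro(y).pvalue > normality_alpha
            )
            if use_pearson:
                r, p = stats.pearsonr(x, y)
                method = "pearson"
            else:
                r, p = stats.spearmanr(x, y)
                method = "spearman"
            records.append((pid, var, n, method, float(r), float(p)))
    grid = pd.DataFrame(
        records, columns=["probe_id", "variable", "n", "method", "r", "p"]
    )
    n_tests = int(grid["p"].notna().sum())
    grid["p_bonferroni"] = (grid["p"] * n_tests).clip(upper=1.0)
    grid["n_tests"] = n_tests
    return grid


# ---------------------------------------------------------------------------
# cohort embedding
# ---------------------------------------------------------------------------


def embed_cohort(
    matrix: IntensityMatrix | pd.DataFrame,
    seed: int = 0,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """Two-dimensional t-SNE embedding of samples by antibody profile.

    Intensities are log10 transformed and column-standardised first.  The
    output is deterministic for a fixed seed and carries no scale guarantee,
    only neighbourhood structure.
    """
    net = matrix.net if isinstance(matrix, IntensityMatrix) else matrix
    n = len(net.index)
    if n < 5:
        raise InsufficientDataError("embedding requires at least 5 samples")
    x = np.log10(net.to_numpy(dtype=float).clip(min=NET_FLOOR))
    col_med = np.nanmedian(x, axis=0)
    col_med = np.where(np.isnan(col_med), 0.0, col_med)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = col_med[nan_c]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="random",
        random_state=seed,
    ).fit_transform(x)
    return pd.DataFrame(coords, index=net.index, columns=["tsne1", "tsne2"])
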