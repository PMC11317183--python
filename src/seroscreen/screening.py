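"""Phase-I screening: array QC, per-sample hit calling, candidate selection.

Hit calling follows the duplicate-concordance rule used on proteome arrays:
a probe is positive for a sample only when both duplicate spots are present
on the sample's array and no duplicate of that probe is present on either the
blank or the secondary-antibody-only reference array.  "Present" means the
net signal exceeds ``presence_z`` local background standard deviations
(default 3, a common array-positivity heuristic).

Candidate antigens for the focused array must, in at least
``min_case_positive`` hit-positive case samples, show a signal-to-noise ratio
strictly above ``snr_min`` (default 13) and a net signal strictly above
``fold_min`` (default 2.5) times the pooled-control net, while being
hit-positive in at most ``max_control_positive`` healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .array_io import (
    ArrayLayout,
    ArrayScan,
    CohortManifest,
    IntensityMatrix,
    NET_FLOOR,
    SpotRecord,
    aggregate_duplicates,
    net_signal,
)
from .errors import ConfigurationError, ValidationError


@dataclass
class QCReport:
    """Outcome of the fluorescence-range and duplicate-agreement checks."""

    scan_id: str
    fraction_in_range: float
    fraction_rpd_ok: float
    n_spots: int
    n_pairs: int
    range_lo: float
    range_hi: float
    rpd_max: float
    pass_fraction: float

    @property
    def passed(self) -> bool:
        return (
            self.fraction_in_range >= self.pass_fraction
            and self.fraction_rpd_ok >= self.pass_fraction
        )

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["passed"] = self.passed
        return d


@dataclass
class CandidateSet:
    """Probes passing the focused-array selection criteria, with evidence."""

    table: pd.DataFrame  # indexed by probe_id, sorted by descending n_case_positive
    snr_min: float
    fold_min: float
    min_case_positive: int
    max_control_positive: int

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def qc_array(
    scan: ArrayScan,
    layout: ArrayLayout,
    range_lo: float = 1000.0,
    range_hi: float = 24000.0,
    rpd_max: float = 30.0,
    pass_fraction: float = 0.90,
    channel: int = 532,
) -> QCReport:
    """Quality-control an array scan over its protein-category spots.

    ``fraction_in_range`` is the proportion of unflagged protein spots whose
    foreground median lies in ``[range_lo, range_hi]``; ``fraction_rpd_ok``
    the proportion of complete duplicate pairs with relative percentage
    difference below ``rpd_max``.  The scan passes when both fractions reach
    ``pass_fraction``.  Control probes are excluded throughout.
    """
    protein = set(layout.protein_probe_ids)
    spots = [
        s
        for s in scan.spots
        if not s.excluded and layout.placements.get(s.coord) in protein
    ]
    if not spots:
        raise ValidationError(f"scan {scan.scan_id}: no usable protein spots")
    fg = np.array([s.fg[channel] for s in spots])
    frac_range = float(np.mean((fg >= range_lo) & (fg <= range_hi)))

    agg = aggregate_duplicates(scan, layout, channel)
    rpd = agg.loc[agg["status"] == "ok", "rpd"]
    if rpd.empty:
        raise ValidationError(f"scan {scan.scan_id}: no complete duplicate pairs")
    frac_rpd = float(np.mean(rpd < rpd_max))
    return QCReport(
        scan_id=scan.scan_id,
        fraction_in_range=frac_range,
        fraction_rpd_ok=frac_rpd,
        n_spots=len(spots),
        n_pairs=int(len(rpd)),
        range_lo=range_lo,
        range_hi=range_hi,
        rpd_max=rpd_max,
        pass_fraction=pass_fraction,
    )


def _default_presence(presence_z: float, channel: int) -> Callable[[SpotRecord], bool]:
    def present(spot: SpotRecord) -> bool:
        sd = spot.bg_sd.get(channel)
        if sd is None:
            raise ValidationError(
                f"spot {spot.coord}: background SD required by the presence rule"
            )
        return (spot.fg[channel] - spot.bg[channel]) >= presence_z * sd

    return present


def call_hits(
    sample_scan: ArrayScan,
    blank_scan: ArrayScan | None,
    secondary_scan: ArrayScan | None,
    layout: ArrayLayout,
    presence_z: float = 3.0,
    presence_rule: Callable[[SpotRecord], bool] | None = None,
    channel: int = 532,
) -> pd.DataFrame:
    """Call per-probe hits for one sample against both negative controls.

    A probe is positive iff the presence rule holds for *both* sample
    duplicates and for *no* duplicate of that probe on the blank or the
    secondary-antibody-only scan.  Flagged spots never count as present.
    Returns a frame indexed by probe id with the positivity call and its
    evidence columns.
    """
    if blank_scan is None or secondary_scan is None:
        raise ConfigurationError(
            "hit calling requires both a blank and a secondary-antibody-only scan"
        )
    present = presence_rule or _default_presence(presence_z, channel)

    def spot_present(spot_map, coord) -> bool:
        spot = spot_map.get(coord)
        return spot is not None and not spot.excluded and present(spot)

    sample_map = sample_scan.spot_map()
    blank_map = blank_scan.spot_map()
    secondary_map = secondary_scan.spot_map()

    records = []
    for pid in layout.protein_probe_ids:
        coords = layout.positions(pid)
        sample_both = all(spot_present(sample_map, c) for c in coords)
        blank_any = any(spot_present(blank_map, c) for c in coords)
        secondary_any = any(spot_present(secondary_map, c) for c in coords)
        records.append(
            (pid, sample_both, blank_any, secondary_any,
             sample_both and not blank_any and not secondary_any)
        )
    return pd.DataFrame(
        records,
        columns=["probe_id", "sample_present", "blank_present", "secondary_present", "positive"],
    ).set_index("probe_id")


def build_hit_table(
    sample_scans: Sequence[ArrayScan],
    blank_scan: ArrayScan,
    secondary_scan: ArrayScan,
    layout: ArrayLayout,
    presence_z: float = 3.0,
    channel: int = 532,
) -> pd.DataFrame:
    """Stack :func:`call_hits` over samples into one long hit table."""
    frames = []
    for scan in sample_scans:
        hits = call_hits(scan, blank_scan, secondary_scan, layout,
                         presence_z=presence_z, channel=channel)
        hits = hits.reset_index()
        hits.insert(0, "sample_id", scan.sample_id)
        frames.append(hits)
    return pd.concat(frames, ignore_index=True)


def select_candidates(
    hits: pd.DataFrame,
    matrix: IntensityMatrix,
    pooled_control_profile: pd.Series,
    manifest: CohortManifest,
    snr_min: float = 13.0,
    fold_min: float = 2.5,
    min_case_positive: int = 2,
    max_control_positive: int = 0,
) -> CandidateSet:
    """Select candidate antigens from the hit table and intensity evidence.

    Both intensity thresholds are strict inequalities ("higher than" /
    "more than").  The output is sorted by descending number of qualifying
    case samples, ties broken by probe id.
    """
    probe_ids = sorted(hits["probe_id"].unique())
    missing = [p for p in probe_ids if p not in pooled_control_profile.index]
    if missing:
        raise ValidationError(
            f"pooled-control profile missing probe(s): {missing[:5]}"
        )
    pooled = pooled_control_profile.clip(lower=NET_FLOOR)

    case_ids = set(manifest.case_ids)
    hc_ids = set(manifest.hc_ids)
    pos = hits[hits["positive"]]

    records = []
    for pid in probe_ids:
        rows = pos[pos["probe_id"] == pid]
        n_control_positive = int(rows["sample_id"].isin(hc_ids).sum())
        case_rows = rows[rows["sample_id"].isin(case_ids)]
        n_case_positive = 0
        max_snr = np.nan
        max_fold = np.nan
        for sid in case_rows["sample_id"]:
            snr = matrix.snr.at[sid, pid]
            net = matrix.net.at[sid, pid]
            fold = net / pooled[pid]
            if not np.isnan(snr):
                max_snr = snr if np.isnan(max_snr) else max(max_snr, snr)
            if not np.isnan(fold):
                max_fold = fold if np.isnan(max_fold) else max(max_fold, fold)
            if snr > snr_min and fold > fold_min:
                n_case_positive += 1
        records.append((pid, n_case_positive, n_control_positive, max_snr, max_fold))

    table = pd.DataFrame(
        records,
        columns=["probe_id", "n_case_positive", "n_control_positive", "max_snr", "max_fold"],
    ).set_index("probe_id")
    keep = (table["n_case_positive"] >= min_case_positive) & (
        table["n_control_positive"] <= max_control_positive
    )
    table = table[keep].sort_values(
        by=["n_case_positive", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    return CandidateSet(table, snr_min, fold_min, min_case_positive, max_control_positive)
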