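"""Reading, writing and aggregation of GenePix-style microarray data.

Three plain-text dialects are used throughout the package:

* a GAL-style layout file (``Block/Row/Column/ID/Name`` plus ``Accession`` and
  ``Category`` columns) describing the printed geometry and probe identity;
* a GPR-style scan file carrying per-spot foreground/background medians,
  background SD and GenePix flags for one scanned sample;
* a tab-delimited cohort manifest with one row per subject.

All writers emit exactly the dialect the readers accept, so a write -> read
round trip is lossless.  Coordinates are 1-based, following the GenePix
convention, and channel 532 is the default analysis channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    MissingChannelError,
    ValidationError,
)

#: closed set of probe categories; everything except "protein" is a control
CONTROL_CATEGORIES = frozenset(
    {"buffer", "human-IgG", "human-IgM", "biotin-BSA", "BSA", "GST-control"}
)
PROBE_CATEGORIES = CONTROL_CATEGORIES | {"protein"}

#: display names that identify control probes when no Category column is given
_CONTROL_NAME_MAP = {
    "buffer": "buffer",
    "printing buffer": "buffer",
    "human igg": "human-IgG",
    "human-igg": "human-IgG",
    "human igm": "human-IgM",
    "human-igm": "human-IgM",
    "biotin-bsa": "biotin-BSA",
    "bsa": "BSA",
    "gst": "GST-control",
    "gst-control": "GST-control",
}

GROUPS = frozenset({"RA", "HC", "OA", "SLE", "SS", "AS"})
ROLES = frozenset({"case", "control", "pooled-control", "blank", "secondary-only"})
ACPA_STATUS = frozenset({"positive", "negative", "unknown"})

#: anti-CCP ELISA positivity threshold, U/mL
ANTI_CCP_CUTOFF = 25.0

#: default floor for net signal so downstream log transforms are defined
NET_FLOOR = 1.0

MANIFEST_COLUMNS = [
    "sample_id",
    "group",
    "role",
    "acpa_status",
    "anti_ccp",
    "disease_duration",
    "ESR",
    "CRP",
    "RF",
    "IgG",
    "DAS28",
    "SJC",
    "TJC",
    "SHS",
    "CH28",
    "NH26",
]
_MANIFEST_STR_COLUMNS = {"sample_id", "group", "role", "acpa_status"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAnnotation:
    """Identity and category of one printed probe."""

    probe_id: str
    display_name: str
    accession: str = ""
    category: str = "protein"

    def __post_init__(self) -> None:
        if self.category not in PROBE_CATEGORIES:
            raise ValidationError(
                f"probe {self.probe_id!r}: unknown category {self.category!r}"
            )


@dataclass
class ArrayLayout:
    """Printed geometry of an array: block grid plus probe placements.

    ``placements`` maps 1-based ``(block, row, col)`` coordinates to probe ids.
    Every protein-category probe must occupy exactly two placements (the
    duplicate pair); control probes may occupy any number.
    """

    n_blocks: int
    block_rows: int
    block_cols: int
    placements: dict[tuple[int, int, int], str]
    probes: dict[str, ProbeAnnotation]
    _positions: dict[str, list[tuple[int, int, int]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positions: dict[str, list[tuple[int, int, int]]] = {}
        for coord, probe_id in self.placements.items():
            b, r, c = coord
            if not (1 <= b <= self.n_blocks and 1 <= r <= self.block_rows and 1 <= c <= self.block_cols):
                raise ValidationError(
                    f"placement {coord} outside layout "
                    f"[1..{self.n_blocks}]x[1..{self.block_rows}]x[1..{self.block_cols}]"
                )
            if probe_id not in self.probes:
                raise ValidationError(f"placement {coord} refers to unknown probe {probe_id!r}")
            positions.setdefault(probe_id, []).append(coord)
        for probe_id, ann in self.probes.items():
            if ann.category == "protein" and len(positions.get(probe_id, [])) != 2:
                n = len(positions.get(probe_id, []))
                raise ValidationError(
                    f"protein probe {probe_id!r} occupies {n} placements; expected 2"
                )
        self._positions = positions

    def positions(self, probe_id: str) -> list[tuple[int, int, int]]:
        """Placement coordinates of one probe, in layout order."""
        return list(self._positions[probe_id])

    @property
    def protein_probe_ids(self) -> list[str]:
        return [p for p, a in self.probes.items() if a.category == "protein"]

    @property
    def n_placements(self) -> int:
        return len(self.placements)


@dataclass
class SpotRecord:
    """One scanned spot: per-channel medians plus the GenePix flag.

    ``flag`` follows the GPR convention: 0 is a good spot, negative values
    mark spots excluded from aggregation.
    """

    block: int
    row: int
    col: int
    fg: dict[int, float]
    bg: dict[int, float]
    bg_sd: dict[int, float] = field(default_factory=dict)
    flag: int = 0

    def __post_init__(self) -> None:
        for ch, v in self.fg.items():
            if v < 0:
                raise ValidationError(f"spot {(self.block, self.row, self.col)}: fg[{ch}] < 0")
        for ch, v in self.bg.items():
            if v < 0:
                raise ValidationError(f"spot {(self.block, self.row, self.col)}: bg[{ch}] < 0")

    @property
    def coord(self) -> tuple[int, int, int]:
        return (self.block, self.row, self.col)

    @property
    def excluded(self) -> bool:
        return self.flag < 0


@dataclass
class ArrayScan:
    """All spots scanned on one array for one sample."""

    scan_id: str
    sample_id: str
    spots: list[SpotRecord]
    channels: tuple[int, ...] = (532,)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for s in self.spots:
            if s.coord in seen:
                raise ValidationError(f"scan {self.scan_id}: duplicate coordinate {s.coord}")
            seen.add(s.coord)

    def spot_map(self) -> dict[tuple[int, int, int], SpotRecord]:
        return {s.coord: s for s in self.spots}


@dataclass
class CohortManifest:
    """Cohort metadata table indexed by sample id.

    Clinical fields are optional and missing-capable (NaN).  The frame keeps
    the column order of :data:`MANIFEST_COLUMNS` plus any extra columns.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in manifest")
        bad_group = set(df["group"]) - GROUPS
        if bad_group:
            raise ValidationError(f"unknown group(s) {sorted(bad_group)}")
        bad_role = set(df["role"]) - ROLES
        if bad_role:
            raise ValidationError(f"unknown role(s) {sorted(bad_role)}")
        bad_status = set(df["acpa_status"]) - ACPA_STATUS
        if bad_status:
            raise ValidationError(f"unknown acpa_status value(s) {sorted(bad_status)}")
        if "disease_duration" in df:
            dur = pd.to_numeric(df["disease_duration"], errors="coerce")
            if (dur.dropna() < 0).any():
                raise ValidationError("disease_duration must be >= 0")
        if "anti_ccp" in df:
            titre = pd.to_numeric(df["anti_ccp"], errors="coerce")
            has = titre.notna()
            expected = np.where(titre[has] > ANTI_CCP_CUTOFF, "positive", "negative")
            actual = df.loc[has, "acpa_status"].to_numpy()
            if (expected != actual).any():
                i = np.nonzero(expected != actual)[0][0]
                sid = df.loc[has, "sample_id"].iloc[i]
                raise ValidationError(
                    f"sample {sid!r}: acpa_status inconsistent with anti_ccp titre "
                    f"(cutoff {ANTI_CCP_CUTOFF} U/mL)"
                )
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def row(self, sample_id: str) -> pd.Series:
        sel = self.frame[self.frame["sample_id"] == sample_id]
        if sel.empty:
            raise KeyError(sample_id)
        return sel.iloc[0]

    def ids_where(self, **conditions: object) -> list[str]:
        """Sample ids matching all equality conditions, in manifest order."""
        mask = pd.Series(True, index=self.frame.index)
        for col, val in conditions.items():
            mask &= self.frame[col] == val
        return list(self.frame.loc[mask, "sample_id"])

    @property
    def case_ids(self) -> list[str]:
        return self.ids_where(role="case")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_where(role="control")

    @property
    def hc_ids(self) -> list[str]:
        return self.ids_where(role="control", group="HC")


@dataclass
class IntensityMatrix:
    """Samples x probes aggregated intensities with per-probe QC annotations.

    ``net`` holds duplicate-averaged floored net signals (NaN marks a probe
    missing on that scan), ``rpd`` the duplicate relative percentage
    difference (%), ``snr`` the duplicate-averaged signal-to-noise ratio.
    """

    net: pd.DataFrame
    rpd: pd.DataFrame
    snr: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("rpd", "snr"):
            df = getattr(self, name)
            if not (df.index.equals(self.net.index) and df.columns.equals(self.net.columns)):
                raise ValidationError(f"{name} not aligned with net matrix")
        vals = self.net.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < NET_FLOOR:
            raise ValidationError(f"net intensities must be >= {NET_FLOOR}")
        rvals = self.rpd.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(rvals[~np.isnan(rvals)] < 0):
                raise ValidationError("rpd must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.net.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.net.columns)


# ---------------------------------------------------------------------------
# ATF-style header helpers
# ---------------------------------------------------------------------------


def _write_atf(path: Path, header: Mapping[str, str], columns: Sequence[str],
               rows: Iterable[Sequence[object]]) -> None:
    lines = ["ATF\t1.0", f"{len(header)}\t{len(columns)}"]
    lines += [f'"{k}={v}"' for k, v in header.items()]
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _read_atf(path: Path) -> tuple[dict[str, str], list[str], list[list[str]]]:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise FormatError(f"{path}: not an ATF-style file (missing 'ATF' signature)")
    try:
        n_header, _n_cols = (int(x) for x in lines[1].split("\t"))
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed ATF size line") from exc
    header: dict[str, str] = {}
    for raw in lines[2 : 2 + n_header]:
        item = raw.strip().strip('"')
        if "=" not in item:
            raise FormatError(f"{path}: malformed header record {raw!r}")
        k, v = item.split("=", 1)
        header[k] = v
    body = lines[2 + n_header :]
    if not body:
        raise FormatError(f"{path}: missing column header row")
    columns = body[0].split("\t")
    rows = [line.split("\t") for line in body[1:] if line.strip()]
    return header, columns, rows


def _fmt_num(v: float) -> str:
    """Render a real with Python's shortest round-tripping representation."""
    if isinstance(v, float) and v.is_integer():
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# layout I/O
# ---------------------------------------------------------------------------


def read_layout(path: str | Path) -> ArrayLayout:
    """Read a GAL-dialect layout file.

    The header must declare ``BlockCount``, ``BlockRows`` and ``BlockColumns``;
    the table must carry ``Block/Row/Column/ID/Name`` columns.  ``Accession``
    and ``Category`` columns are optional; without a Category column, control
    probes are recognised by their display name.
    """
    header, columns, rows = _read_atf(Path(path))
    for key in ("BlockCount", "BlockRows", "BlockColumns"):
        if key not in header:
            raise FormatError(f"{path}: layout header missing {key}")
    try:
        n_blocks = int(header["BlockCount"])
        block_rows = int(header["BlockRows"])
        block_cols = int(header["BlockColumns"])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer block geometry in header") from exc

    idx = {c: i for i, c in enumerate(columns)}
    for col in ("Block", "Row", "Column", "ID", "Name"):
        if col not in idx:
            raise FormatError(f"{path}: layout table missing column {col!r}")

    placements: dict[tuple[int, int, int], str] = {}
    probes: dict[str, ProbeAnnotation] = {}
    for row in rows:
        coord = (int(row[idx["Block"]]), int(row[idx["Row"]]), int(row[idx["Column"]]))
        probe_id = row[idx["ID"]]
        name = row[idx["Name"]]
        accession = row[idx["Accession"]] if "Accession" in idx else ""
        if "Category" in idx:
            category = row[idx["Category"]]
        else:
            category = _CONTROL_NAME_MAP.get(name.strip().lower(), "protein")
        if coord in placements:
            raise ValidationError(f"{path}: coordinate {coord} assigned twice")
        placements[coord] = probe_id
        ann = ProbeAnnotation(probe_id, name, accession, category)
        if probe_id in probes and probes[probe_id] != ann:
            raise ValidationError(f"{path}: probe {probe_id!r} annotated inconsistently")
        probes.setdefault(probe_id, ann)
    return ArrayLayout(n_blocks, block_rows, block_cols, placements, probes)


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    header = {
        "Type": "seroscreen ArrayLayout V1",
        "BlockCount": str(layout.n_blocks),
        "BlockRows": str(layout.block_rows),
        "BlockColumns": str(layout.block_cols),
    }
    columns = ["Block", "Row", "Column", "ID", "Name", "Accession", "Category"]
    rows = []
    for coord in sorted(layout.placements):
        pid = layout.placements[coord]
        ann = layout.probes[pid]
        rows.append([coord[0], coord[1], coord[2], pid, ann.display_name,
                     ann.accession, ann.category])
    _write_atf(Path(path), header, columns, rows)


# ---------------------------------------------------------------------------
# scan I/O
# ---------------------------------------------------------------------------

_SCAN_CHANNEL_COLS = {
    532: ("F532 Median", "B532 Median", "B532 SD"),
    635: ("F635 Median", "B635 Median", "B635 SD"),
}


def read_scan(path: str | Path, layout: ArrayLayout) -> ArrayScan:
    """Read a GPR-dialect scan file against a companion layout.

    Rows whose coordinates do not resolve to a layout placement are rejected.
    The 635-channel columns are optional.
    """
    header, columns, rows = _read_atf(Path(path))
    idx = {c: i for i, c in enumerate(columns)}
    mandatory = ["Block", "Row", "Column", "F532 Median", "B532 Median", "Flags"]
    for col in mandatory:
        if col not in idx:
            raise FormatError(f"{path}: scan table missing column {col!r}")
    channels = [532]
    if "F635 Median" in idx and "B635 Median" in idx:
        channels.append(635)

    spots: list[SpotRecord] = []
    for row in rows:
        coord = (int(row[idx["Block"]]), int(row[idx["Row"]]), int(row[idx["Column"]]))
        if coord not in layout.placements:
            raise ValidationError(f"{path}: coordinate {coord} not present in layout")
        fg: dict[int, float] = {}
        bg: dict[int, float] = {}
        bg_sd: dict[int, float] = {}
        for ch in channels:
            fcol, bcol, sdcol = _SCAN_CHANNEL_COLS[ch]
            fg[ch] = float(row[idx[fcol]])
            bg[ch] = float(row[idx[bcol]])
            if sdcol in idx and row[idx[sdcol]] != "":
                bg_sd[ch] = float(row[idx[sdcol]])
        spots.append(SpotRecord(*coord, fg=fg, bg=bg, bg_sd=bg_sd,
                                flag=int(row[idx["Flags"]])))
    return ArrayScan(
        scan_id=header.get("ScanID", Path(path).stem),
        sample_id=header.get("SampleID", Path(path).stem),
        spots=spots,
        channels=tuple(channels),
    )


def write_scan(scan: ArrayScan, layout: ArrayLayout, path: str | Path) -> None:
    header = {
        "Type": "seroscreen ScanResult V1",
        "ScanID": scan.scan_id,
        "SampleID": scan.sample_id,
    }
    columns = ["Block", "Row", "Column", "ID", "Name"]
    for ch in scan.channels:
        fcol, bcol, sdcol = _SCAN_CHANNEL_COLS[ch]
        columns += [fcol, bcol, sdcol]
    columns.append("Flags")
    rows = []
    for spot in scan.spots:
        pid = layout.placements.get(spot.coord, "")
        name = layout.probes[pid].display_name if pid else ""
        row: list[object] = [spot.block, spot.row, spot.col, pid, name]
        for ch in scan.channels:
            if ch not in spot.fg:
                raise MissingChannelError(
                    f"scan {scan.scan_id}: spot {spot.coord} lacks channel {ch}"
                )
            row += [
                _fmt_num(spot.fg[ch]),
                _fmt_num(spot.bg[ch]),
                _fmt_num(spot.bg_sd[ch]) if ch in spot.bg_sd else "",
            ]
        row.append(spot.flag)
        rows.append(row)
    _write_atf(Path(path), header, columns, rows)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> CohortManifest:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty manifest")
    columns = lines[0].split("\t")
    if "sample_id" not in columns:
        raise FormatError(f"{path}: manifest header missing 'sample_id'")
    records: list[list[object]] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise FormatError(f"{path}: row with {len(cells)} cells, expected {len(columns)}")
        rec: list[object] = []
        for col, cell in zip(columns, cells):
            if col in _MANIFEST_STR_COLUMNS:
                rec.append(cell)
            else:
                rec.append(float(cell) if cell != "" else math.nan)
        records.append(rec)
    frame = pd.DataFrame(records, columns=columns)
    return CohortManifest(frame)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = manifest.frame
    lines = ["\t".join(df.columns)]
    for _, row in df.iterrows():
        cells = []
        for col in df.columns:
            v = row[col]
            if col in _MANIFEST_STR_COLUMNS:
                cells.append(str(v))
            elif v is None or (isinstance(v, float) and math.isnan(v)):
                cells.append("")
            else:
                cells.append(_fmt_num(float(v)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# signal aggregation
# ---------------------------------------------------------------------------


def net_signal(spot: SpotRecord, channel: int = 532, floor: float = NET_FLOOR) -> float:
    """Background-subtracted signal ``max(fg - bg, floor)`` for one channel.

    The floor (default 1 fluorescence unit) keeps downstream log transforms
    defined when the local background exceeds the foreground.
    """
    if channel not in spot.fg or channel not in spot.bg:
        raise MissingChannelError(
            f"spot {spot.coord} has no channel {channel} (channels: {sorted(spot.fg)})"
        )
    return max(spot.fg[channel] - spot.bg[channel], floor)


def spot_snr(spot: SpotRecord, channel: int = 532) -> float:
    """Per-spot signal-to-noise ratio ``(fg - bg) / bg_sd`` (GenePix convention).

    Returns NaN when the background SD is absent or non-positive.
    """
    if channel not in spot.fg or channel not in spot.bg:
        raise MissingChannelError(f"spot {spot.coord} has no channel {channel}")
    sd = spot.bg_sd.get(channel)
    if sd is None or sd <= 0:
        return math.nan
    return (spot.fg[channel] - spot.bg[channel]) / sd


def aggregate_duplicates(
    scan: ArrayScan,
    layout: ArrayLayout,
    channel: int = 532,
    floor: float = NET_FLOOR,
    include_controls: bool = False,
) -> pd.DataFrame:
    """Collapse duplicate spots into one record per probe.

    For a probe with both duplicates present and unflagged:
    ``net`` is the mean of the two floored net signals, ``rpd`` the absolute
    difference over the pair mean x100, ``snr`` the mean per-spot SNR.  With a
    single usable spot, ``net``/``snr`` come from that spot and ``rpd`` is NaN
    (status ``single``); with none, all values are NaN (status ``missing``).
    The operation is symmetric in the duplicate pair.
    """
    spot_map = scan.spot_map()
    probe_ids = (
        list(layout.probes) if include_controls else layout.protein_probe_ids
    )
    records = []
    for pid in probe_ids:
        spots = [
            spot_map[c]
            for c in layout.positions(pid)
            if c in spot_map and not spot_map[c].excluded
        ]
        nets = [net_signal(s, channel, floor) for s in spots]
        snrs = [spot_snr(s, channel) for s in spots]
        if len(nets) >= 2:
            net = float(np.mean(nets))
            pair = nets[:2]
            rpd = abs(pair[0] - pair[1]) / ((pair[0] + pair[1]) / 2.0) * 100.0
            snr = float(np.mean(snrs)) if not any(math.isnan(x) for x in snrs) else math.nan
            status = "ok"
        elif len(nets) == 1:
            net, rpd, snr, status = nets[0], math.nan, snrs[0], "single"
        else:
            net, rpd, snr, status = math.nan, math.nan, math.nan, "missing"
        records.append((pid, net, rpd, snr, len(nets), status))
    return pd.DataFrame(
        records, columns=["probe_id", "net", "rpd", "snr", "n_spots", "status"]
    ).set_index("probe_id")


def build_matrix(
    scans: Sequence[ArrayScan],
    layout: ArrayLayout,
    manifest: CohortManifest,
    channel: int = 532,
    floor: float = NET_FLOOR,
) -> IntensityMatrix:
    """Aggregate a collection of scans into a samples x probes matrix.

    Rows are sorted by sample id so the result is invariant to input order;
    columns cover all protein-category probes in layout order.  Probes absent
    from a scan are recorded as NaN, never as zero.
    """
    sample_ids = [s.sample_id for s in scans]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(x for x in sample_ids if sample_ids.count(x) > 1)
        raise ValidationError(f"duplicate sample_id {dup!r} across scans")
    known = set(manifest.sample_ids)
    for sid in sample_ids:
        if sid not in known:
            raise ValidationError(f"scan sample_id {sid!r} not present in manifest")

    probe_ids = layout.protein_probe_ids
    order = sorted(range(len(scans)), key=lambda i: scans[i].sample_id)
    net_rows, rpd_rows, snr_rows = [], [], []
    for i in order:
        agg = aggregate_duplicates(scans[i], layout, channel, floor)
        agg = agg.reindex(probe_ids)
        net_rows.append(agg["net"].to_numpy())
        rpd_rows.append(agg["rpd"].to_numpy())
        snr_rows.append(agg["snr"].to_numpy())
    index = [scans[i].sample_id for i in order]
    return IntensityMatrix(
        net=pd.DataFrame(net_rows, index=index, columns=probe_ids),
        rpd=pd.DataFrame(rpd_rows, index=index, columns=probe_ids),
        snr=pd.DataFrame(snr_rows, index=index, columns=probe_ids),
    )
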