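"""Shared fixtures: tiny layouts, hand-built scans and a small cohort."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from seroscreen.array_io import (
    ArrayLayout,
    ArrayScan,
    CohortManifest,
    MANIFEST_COLUMNS,
    ProbeAnnotation,
    SpotRecord,
)
from seroscreen.simulate import SimulationConfig, build_layout, simulate_cohort


@pytest.fixture(scope="session")
def tiny_layout() -> ArrayLayout:
    """Three protein probes plus the six standard controls, all in duplicate."""
    return build_layout(3, block_rows=4, block_cols=4)


def make_scan(
    layout: ArrayLayout,
    fg_by_probe: dict[str, tuple[float, float]],
    sample_id: str = "S1",
    bg: float = 300.0,
    bg_sd: float = 100.0,
    flags: dict[tuple[int, int, int], int] | None = None,
) -> ArrayScan:
    """Build a scan giving each probe's duplicate spots explicit foregrounds.

    Probes absent from ``fg_by_probe`` get foreground equal to background.
    """
    flags = flags or {}
    spots = []
    for coord, pid in layout.placements.items():
        pair = fg_by_probe.get(pid)
        if pair is None:
            fg = bg
        else:
            first = layout.positions(pid)[0] == coord
            fg = pair[0] if first else pair[1]
        spots.append(
            SpotRecord(
                *coord,
                fg={532: float(fg)},
                bg={532: bg},
                bg_sd={532: bg_sd},
                flag=flags.get(coord, 0),
            )
        )
    return ArrayScan(scan_id=f"scan-{sample_id}", sample_id=sample_id, spots=spots)


def make_manifest(entries: list[tuple[str, str, str]]) -> CohortManifest:
    """Manifest from (sample_id, group, role) triples; clinical fields empty."""
    rows = []
    for sid, group, role in entries:
        row = {c: math.nan for c in MANIFEST_COLUMNS}
        row.update(sample_id=sid, group=group, role=role, acpa_status="unknown")
        rows.append(row)
    return CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


SMALL_CONFIG = dict(
    n_probes=40,
    n_informative=6,
    group_sizes={"RA": 30, "HC": 14, "AS": 4, "SLE": 4, "SS": 2, "OA": 2},
    n_acpa_negative=10,
    duration_scale_years=2.0,
    duration_missing_rate=0.0,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort with planted signal, shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, **SMALL_CONFIG)
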