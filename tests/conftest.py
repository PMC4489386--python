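"""Shared fixtures: small synthetic studies and hand-built geometries."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from bearlink.landcover import LandCoverMap
from bearlink.synthetic import SimConfig, SyntheticStudy, generate_study
from bearlink.telemetry import GpsFix

T0 = datetime(2012, 6, 1, 0, 0, tzinfo=timezone.utc)


def fix_at(hours: float, x: float, y: float, pdop: float = 2.0, animal="b1") -> GpsFix:
    return GpsFix(animal, T0 + timedelta(hours=hours), x, y, pdop)


@pytest.fixture(scope="session")
def small_study() -> SyntheticStudy:
    """A 7-bear, 20-day noise-free campaign shared across tests."""
    cfg = SimConfig(
        n_bears={"male": 2, "lone_female": 1, "female_cubs": 2, "female_yearlings": 2},
        n_days=20,
    )
    return generate_study(cfg, seed=3, noise_sd=0.0)


@pytest.fixture(scope="session")
def checkerboard_map() -> LandCoverMap:
    """8x8 checkerboard of 250-m Conifer/Swamp stands with one straight road."""
    stands, cats = [], []
    for i in range(8):
        for j in range(8):
            stands.append(box(j * 250, i * 250, (j + 1) * 250, (i + 1) * 250))
            cats.append("Conifer" if (i + j) % 2 == 0 else "Swamp")
    road = LineString([(0, 1000), (2000, 1000)])
    return LandCoverMap(
        stands=stands, categories=cats, linear={"secondary_road": [road]}
    )
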