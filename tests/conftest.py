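"""Shared fixtures: a reduced-scale synthetic section used across tests.

The test-scale spec keeps the full tissue architecture (nested zones, pole
clusters, five classes) but shrinks radii and cell areas so a section
renders in ~0.1 s at 416x416 px instead of minutes at full resolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from quanthisto import descriptors
from quanthisto.synthdata import SectionSpec, ZoneParams, generate_section

TEST_ZONES = {
    "xylem_vessel": ZoneParams(320, elongation=2.2, orientation="radial"),
    "xylem_fiber": ZoneParams(170, elongation=2.0, orientation="radial"),
    "cambium": ZoneParams(100, elongation=2.0, orientation="orthoradial"),
    "phloem": ZoneParams(340, elongation=1.8, orientation="orthoradial"),
    "bundle": ZoneParams(60, elongation=1.3, orientation="mixed"),
}


def make_test_spec(seed: int = 1, **overrides) -> SectionSpec:
    kwargs = dict(
        zone_radii={"xylem_outer": 60, "cambium_outer": 75, "phloem_outer": 140},
        pixel_size=0.7,
        cell_size_params=TEST_ZONES,
        pole_arc_spacing=70.0,
        pole_radius_um=10.0,
        pole_offset_um=8.0,
        wall_width=6,
        noise=6.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SectionSpec(**kwargs)


@pytest.fixture(scope="session")
def small_section():
    """(image, truth, masks) for the reduced-scale reference section."""
    return generate_section(make_test_spec(seed=1))


@pytest.fixture(scope="session")
def small_table(small_section) -> pd.DataFrame:
    """Ground-truth feature table of the reference section, with classes."""
    image, truth, _ = small_section
    table = descriptors.build_feature_table(truth.label_map, image.center)
    table["class"] = table["cell_id"].map(
        lambda i: truth.cell_classes[int(i)].value)
    return table


def labeled_table_for(seed: int) -> pd.DataFrame:
    """Feature table + ground-truth classes for an independent section."""
    image, truth, _ = generate_section(make_test_spec(seed=seed))
    table = descriptors.build_feature_table(truth.label_map, image.center)
    table["class"] = table["cell_id"].map(
        lambda i: truth.cell_classes[int(i)].value)
    return table.dropna(subset=["incline"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
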