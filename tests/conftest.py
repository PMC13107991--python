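"""Shared fixtures: synthetic panels processed once per session.

The panels are the study conditions for the end-to-end tests: a 30-image
default cohort with planted counts uniform in [5, 60], the same cohort
regenerated under a heavy illumination ramp, and a 20-image cohort of small
TUNEL+ cells (5-14 µm²) for the parameter-profile contrast.
"""

from __future__ import annotations

import numpy as np
import pytest

from tunelquant.classify import process_sample
from tunelquant.imaging import PipelineParams
from tunelquant.synthetic import SyntheticSpec, generate_panel

PANEL_SEED = 2026


@pytest.fixture(scope="session")
def primary_params() -> PipelineParams:
    return PipelineParams.from_profile("primary")

@pytest.fixture(scope="session")
def small_cell_params() -> PipelineParams:
    return PipelineParams.from_profile("small-cell")


def _process_panel(panel, params):
    return [(pair, truth, process_sample(pair, params)) for pair, truth in panel]


@pytest.fixture(scope="session")
def default_panel_processed(primary_params):
    """30 samples, default conditions, processed with the primary profile."""
    panel = generate_panel(30, (5, 60), seed=PANEL_SEED)
    return _process_panel(panel, primary_params)


@pytest.fixture(scope="session")
def heavy_illum_panel_processed(primary_params):
    """Same cohort design under an illumination ramp as strong as the signal."""
    spec = SyntheticSpec(illum_gradient=1.0)
    panel = generate_panel(30, (5, 60), seed=PANEL_SEED + 1, base_spec=spec)
    return _process_panel(panel, primary_params)


@pytest.fixture(scope="session")
def small_cell_panel(primary_params, small_cell_params):
    """20 samples with small TUNEL+ somata, processed under both profiles."""
    spec = SyntheticSpec(
        tunel_area_range_um2=(5.0, 14.0), debris_small_area_um2=(0.6, 2.0)
    )
    panel = generate_panel(20, (10, 30), seed=PANEL_SEED + 2, base_spec=spec)
    return {
        "panel": panel,
        "primary": _process_panel(panel, primary_params),
        "small-cell": _process_panel(panel, small_cell_params),
    }


@pytest.fixture(scope="session")
def single_sample():
    """One mid-density sample with ground truth, for unit-level checks."""
    from tunelquant.synthetic import generate_sample

    return generate_sample(SyntheticSpec(n_tunel_pos=15, seed=PANEL_SEED + 3))
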