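"""Shared fixtures: a small single-row plate and one session-scoped full screen.

The full default screen (96 wells, 151 frames at 4-min intervals, 1200x800 px)
is simulated once per session and its segmentation timed, so the end-to-end
tests share a single expensive dataset.
"""

from __future__ import annotations

import time

import pytest

from spherotox import plate_io, segmentation, synthetic
from spherotox.plate_io import Calibration, PlateLayout, WellSpec


@pytest.fixture()
def small_calib() -> Calibration:
    return Calibration(
        mm_per_px=0.05,
        grid_origin=(50.0, 50.0),
        grid_pitch=(100.0, 100.0),
        well_radius_px=45.0,
    )


@pytest.fixture()
def row_layout() -> PlateLayout:
    """A single-row, 8-well layout: 6 treatments, 1 vehicle, 1 empty."""
    wells = [
        WellSpec(f"A{i + 1}", 0, i, "drugX", 10.0 * (i + 1), "treatment", 1, "PBS")
        for i in range(6)
    ]
    wells.append(WellSpec("A7", 0, 6, None, 0.0, "vehicle", 1, "PBS"))
    wells.append(WellSpec("A8", 0, 7, None, 0.0, "empty", 1))
    return PlateLayout(wells=tuple(wells), n_rows=1, n_cols=8)


@pytest.fixture()
def row_render_cfg() -> synthetic.RenderConfig:
    return synthetic.RenderConfig(image_size=(100, 850), noise_sd=0.0, vignette_strength=0.0, seed=3)


@pytest.fixture(scope="session")
def screen_dataset(tmp_path_factory) -> dict:
    """The default 7-compound screen, simulated and segmented once per session."""
    out = tmp_path_factory.mktemp("screen")
    layout, models, calib, cfg = synthetic.default_screen(seed=7)
    t0 = time.perf_counter()
    truth = synthetic.generate_experiment(layout, models, calib, cfg, out)
    simulate_seconds = time.perf_counter() - t0
    frames = plate_io.load_manifest(out / "manifest.csv", out / "images")
    t0 = time.perf_counter()
    measurements = segmentation.measure_plate(frames, layout, calib)
    elapsed = time.perf_counter() - t0
    return {
        "dir": out,
        "layout": layout,
        "models": models,
        "calib": calib,
        "cfg": cfg,
        "truth": truth,
        "frames": frames,
        "measurements": measurements,
        "measure_seconds": elapsed,
        "simulate_seconds": simulate_seconds,
    }
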