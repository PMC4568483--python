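"""Synthetic plate time-lapse generator with analytic ground truth.

Emulates the spheroid-contraction assay as imaged from below a trans-illuminated
multiwell plate: one dark, near-circular spheroid per well on a bright
background, whose projected area shrinks over 10 h with dose-dependent
kinetics; frames every 4 min; n = 3 replicates per concentration; smooth
illumination vignetting and additive Gaussian noise.

The kinetic model is deliberately simple so the ground truth is analytic:

* per-well area follows a mono-exponential approach to an asymptote,
  ``A(t) = A_inf + (A0 - A_inf) * exp(-k(c) * t)``;
* the contraction rate constant responds to dose through a logistic in
  log10-concentration,
  ``k(c) = k_bot + (k_top - k_bot) / (1 + exp((log10 c - log_ic50) / slope_s))``,
  with ``k(0)`` defined as the zero-dose limit ``k_top``.

Real spheroids are rougher-edged, can disintegrate at high toxicant doses and
do not follow a single exponential; this generator makes no claim about those
regimes — it exists to give segmentation, kinetics and dose-response fitting a
known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import GenerationError, ValidationError
from .plate_io import (
    Calibration,
    ImageFrame,
    PlateLayout,
    WellSpec,
    write_calibration,
    write_image,
    write_layout,
    write_manifest,
)

#: Default acquisition schedule: one frame every 4 min for 10 h (151 frames).
def default_schedule() -> np.ndarray:
    return np.arange(0.0, 601.0, 4.0)


#: Default endpoint window (min) over which ground-truth rates are defined.
DEFAULT_WINDOW_MIN = 150.0


@dataclass(frozen=True)
class ContractionModel:
    """Dose-dependent contraction kinetics of one compound.

    Parameters
    ----------
    a0_mm2, a_inf_mm2
        Initial and asymptotic projected areas (mm^2), ``a_inf_mm2 < a0_mm2``.
    k_top, k_bot
        Contraction rate constants (1/min) at zero and at saturating dose.
    log_ic50
        log10 of the rate-constant transition midpoint (concentration in uM).
    slope_s
        Transition width in log10-concentration units.
    """

    a0_mm2: float
    a_inf_mm2: float
    k_top: float
    k_bot: float = 0.0
    log_ic50: float = 1.0
    slope_s: float = 0.3

    def __post_init__(self) -> None:
        if not self.a_inf_mm2 < self.a0_mm2:
            raise ValidationError("a_inf_mm2 must be < a0_mm2")
        if not (0 <= self.k_bot <= self.k_top):
            raise ValidationError("need 0 <= k_bot <= k_top")
        if not self.slope_s > 0:
            raise ValidationError("slope_s must be > 0")

    @property
    def is_flat(self) -> bool:
        """True when dose has no effect on the rate constant."""
        return self.k_bot == self.k_top

    def rate_constant(self, conc_um: float) -> float:
        """k(c), with k(0) defined as the zero-dose limit k_top."""
        if conc_um < 0:
            raise ValidationError("concentration must be >= 0")
        if conc_um == 0:
            return self.k_top
        x = np.log10(conc_um)
        return self.k_bot + (self.k_top - self.k_bot) * float(
            expit(-(x - self.log_ic50) / self.slope_s)
        )

    def area(self, times_min: np.ndarray, conc_um: float) -> np.ndarray:
        """Projected-area trajectory A(t) (mm^2) at one dose."""
        t = np.asarray(times_min, dtype=float)
        if np.any(t < 0):
            raise ValidationError("times must be non-negative")
        k = self.rate_constant(conc_um)
        return self.a_inf_mm2 + (self.a0_mm2 - self.a_inf_mm2) * np.exp(-k * t)

    # -- ground-truth endpoints -------------------------------------------

    def true_secant_rate(self, conc_um: float, window_min: float = DEFAULT_WINDOW_MIN) -> float:
        """(A(0) - A(window)) / window: positive contraction magnitude (mm^2/min)."""
        a = self.area(np.array([0.0, window_min]), conc_um)
        return float((a[0] - a[1]) / window_min)

    def true_ols_rate(
        self,
        times_min: np.ndarray,
        conc_um: float,
        window_min: float = DEFAULT_WINDOW_MIN,
    ) -> float:
        """Negated OLS slope of the noiseless trajectory over the window.

        This is the endpoint the analysis pipeline estimates; for a convex
        decreasing trajectory it differs slightly from the secant rate.
        """
        t = np.asarray(times_min, dtype=float)
        t = t[t <= window_min + 1e-9]
        a = self.area(t, conc_um)
        slope = np.polyfit(t, a, 1)[0]
        return float(-slope)

    def half_effect_conc(
        self,
        times_min: np.ndarray | None = None,
        window_min: float = DEFAULT_WINDOW_MIN,
    ) -> float:
        """Concentration (uM) at which the endpoint falls halfway between asymptotes.

        The endpoint (normalized OLS contraction rate over the window) is a
        saturating function of the rate constant, so its half-effect point is
        shifted from ``10**log_ic50``; this solves for the true midpoint of the
        dose-response curve the assay actually measures. NaN for flat models.
        """
        if self.is_flat:
            return float("nan")
        t = default_schedule() if times_min is None else np.asarray(times_min, float)
        t = t[t <= window_min + 1e-9]

        def endpoint(k: float) -> float:
            a = self.a_inf_mm2 + (self.a0_mm2 - self.a_inf_mm2) * np.exp(-k * t)
            return -np.polyfit(t, a, 1)[0]

        target = 0.5 * (endpoint(self.k_top) + endpoint(self.k_bot))
        k_half = brentq(
            lambda k: endpoint(k) - target, self.k_bot, self.k_top, xtol=1e-15
        )
        # invert the logistic dose->rate map at k_half
        u = (self.k_top - self.k_bot) / (k_half - self.k_bot) - 1.0
        x = self.log_ic50 + self.slope_s * np.log(u)
        return float(10.0**x)

    def with_half_effect(
        self,
        ic50_um: float,
        times_min: np.ndarray | None = None,
        window_min: float = DEFAULT_WINDOW_MIN,
    ) -> "ContractionModel":
        """Return a copy whose endpoint half-effect concentration equals ``ic50_um``.

        The half-effect log-concentration shifts one-for-one with ``log_ic50``,
        so a single offset computed at log_ic50 = 0 suffices.
        """
        ref = ContractionModel(
            self.a0_mm2, self.a_inf_mm2, self.k_top, self.k_bot, 0.0, self.slope_s
        )
        delta = np.log10(ref.half_effect_conc(times_min, window_min))
        return ContractionModel(
            self.a0_mm2,
            self.a_inf_mm2,
            self.k_top,
            self.k_bot,
            float(np.log10(ic50_um) - delta),
            self.slope_s,
        )


def area_trajectory(
    model: ContractionModel, conc_um: float, times_min: np.ndarray
) -> np.ndarray:
    """Functional alias for :meth:`ContractionModel.area`."""
    return model.area(times_min, conc_um)


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class RenderConfig:
    """Appearance of synthetic plate frames.

    Intensities are in [0, 1]; the spheroid must be darker than the background
    (trans-illumination of nanoparticle-laden cells). ``vignette_strength`` is
    the fractional fall-off of illumination at the image corners;
    ``noise_sd`` the additive Gaussian noise level; ``well_rim`` draws a darker
    annulus at each well's analysis radius.
    """

    image_size: tuple[int, int] = (800, 1200)
    background_level: float = 0.85
    spheroid_level: float = 0.25
    vignette_strength: float = 0.15
    noise_sd: float = 0.02
    well_rim: bool = False
    center_jitter: float = 0.05  # per-frame well-center jitter, fraction of pitch
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spheroid_level < self.background_level:
            raise ValidationError("spheroid_level must be < background_level")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.vignette_strength < 1):
            raise ValidationError("vignette_strength must be in [0, 1)")
        if not (0 <= self.center_jitter <= 0.05):
            raise ValidationError("center_jitter must be in [0, 0.05] of the pitch")


def default_calibration() -> Calibration:
    """Synthetic-plate calibration: 0.05 mm/px, 96 wells inside a 1200x800 frame."""
    return Calibration(
        mm_per_px=0.05,
        grid_origin=(70.0, 70.0),
        grid_pitch=(90.0, 95.0),
        well_radius_px=40.0,
    )


def _frame_rng(master_seed: int, frame_seed: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(master_seed, spawn_key=(frame_seed,)))
    )


def _vignette(shape: tuple[int, int], strength: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    cr, cc0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    d2 = (rr - cr) ** 2 + (cc - cc0) ** 2
    return 1.0 - strength * d2 / d2.max() if strength > 0 else np.ones(shape)


def render_frame(
    layout: PlateLayout,
    calib: Calibration,
    areas_mm2: Mapping[str, float],
    cfg: RenderConfig,
    frame_seed: int,
    time_min: float = 0.0,
    frame_id: int = 0,
) -> ImageFrame:
    """Render one plate frame: disks of the given areas at jittered well centers.

    The whole field is modulated by the radial illumination vignette and
    Gaussian noise is added last; output is deterministic given
    ``(cfg.seed, frame_seed)``.
    """
    rng = _frame_rng(cfg.seed, frame_seed)
    h, w = cfg.image_size
    img = np.full((h, w), cfg.background_level, dtype=np.float64)

    if cfg.well_rim:
        for well in layout.wells:
            cr, cc = calib.well_center(well.row, well.col)
            _draw_annulus(img, cr, cc, calib.well_radius_px, 1.5, cfg.background_level * 0.55)

    j = cfg.center_jitter
    for well in sorted(layout.wells, key=lambda w_: (w_.row, w_.col)):
        jr = rng.uniform(-j, j) * calib.grid_pitch[0]
        jc = rng.uniform(-j, j) * calib.grid_pitch[1]
        if well.role == "empty" or well.name not in areas_mm2:
            continue
        area = areas_mm2[well.name]
        r_px = np.sqrt(area / np.pi) / calib.mm_per_px
        if r_px > calib.well_radius_px:
            raise GenerationError(
                f"well {well.name}: spheroid radius {r_px:.1f} px exceeds the "
                f"well analysis radius {calib.well_radius_px} px"
            )
        cr, cc = calib.well_center(well.row, well.col)
        _draw_disk(img, cr + jr, cc + jc, r_px, cfg.spheroid_level)

    img *= _vignette((h, w), cfg.vignette_strength)
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return ImageFrame(pixels=img.astype(np.float32), time_min=time_min, frame_id=frame_id)


def _draw_disk(img: np.ndarray, cr: float, cc: float, r: float, level: float) -> None:
    """Fill pixels whose centers lie within radius r of (cr, cc)."""
    r0, r1 = max(0, int(np.floor(cr - r))), min(img.shape[0], int(np.ceil(cr + r)) + 1)
    c0, c1 = max(0, int(np.floor(cc - r))), min(img.shape[1], int(np.ceil(cc + r)) + 1)
    rr, cc_ = np.ogrid[r0:r1, c0:c1]
    mask = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r * r
    img[r0:r1, c0:c1][mask] = level


def _draw_annulus(
    img: np.ndarray, cr: float, cc: float, r: float, half_width: float, level: float
) -> None:
    lo, hi = r - half_width, r + half_width
    r0, r1 = max(0, int(np.floor(cr - hi))), min(img.shape[0], int(np.ceil(cr + hi)) + 1)
    c0, c1 = max(0, int(np.floor(cc - hi))), min(img.shape[1], int(np.ceil(cc + hi)) + 1)
    rr, cc_ = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
    mask = (d2 >= lo * lo) & (d2 <= hi * hi)
    img[r0:r1, c0:c1][mask] = level


def rasterized_disk_area(r: float) -> int:
    """Pixel count of a disk of radius r rasterized by the renderer's rule.

    Independent oracle for segmentation accuracy: counts integer lattice
    points within distance r of the origin.
    """
    n = int(np.ceil(r))
    rr, cc = np.mgrid[-n : n + 1, -n : n + 1]
    return int(np.count_nonzero(rr * rr + cc * cc <= r * r))


# ---------------------------------------------------------------------------
# experiment generation with ground truth


@dataclass
class GroundTruth:
    """Analytic truth tables for a generated experiment.

    ``areas``: (well, time_min, area_mm2) noiseless trajectories.
    ``wells``: per-well true secant / OLS contraction rates over the endpoint
    window and the vehicle-normalized OLS rate.
    ``compounds``: per-compound true endpoint half-effect IC50 (uM; NaN for
    dose-flat compounds) and the generating kinetic parameters.
    """

    areas: pd.DataFrame
    wells: pd.DataFrame
    compounds: pd.DataFrame
    window_min: float = DEFAULT_WINDOW_MIN

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        self.areas.to_csv(out / "ground_truth_areas.csv", index=False)
        self.wells.to_csv(out / "ground_truth_wells.csv", index=False)
        self.compounds.to_csv(out / "ground_truth_compounds.csv", index=False)


def _well_model(
    well: WellSpec,
    models: Mapping[str, ContractionModel],
    baseline: ContractionModel,
) -> tuple[ContractionModel, float] | None:
    """Model and concentration governing one well, or None for empty wells."""
    if well.role == "empty":
        return None
    if well.role == "vehicle":
        return baseline, 0.0
    if well.compound not in models:
        raise GenerationError(f"well {well.name}: no kinetic model for compound {well.compound!r}")
    return models[well.compound], well.concentration_um


def build_ground_truth(
    layout: PlateLayout,
    models: Mapping[str, ContractionModel],
    schedule: np.ndarray,
    window_min: float = DEFAULT_WINDOW_MIN,
    baseline: ContractionModel | None = None,
) -> GroundTruth:
    """Compute noiseless per-well trajectories and true endpoints for a layout."""
    if not layout.vehicle_wells():
        raise GenerationError("layout has no vehicle wells; normalization impossible")
    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 1 or len(schedule) == 0 or np.any(np.diff(schedule) <= 0):
        raise ValidationError("schedule must be a non-empty strictly increasing time list")
    if baseline is None:
        baseline = models[sorted(models)[0]]

    area_rows, well_rows = [], []
    for well in sorted(layout.wells, key=lambda w: (w.row, w.col)):
        mc = _well_model(well, models, baseline)
        if mc is None:
            continue
        model, conc = mc
        traj = model.area(schedule, conc)
        for t, a in zip(schedule, traj):
            area_rows.append({"well": well.name, "time_min": t, "area_mm2": a})
        well_rows.append(
            {
                "well": well.name,
                "compound": well.compound or "",
                "concentration_uM": conc,
                "role": well.role,
                "solvent": well.solvent or "",
                "true_secant_rate": model.true_secant_rate(conc, window_min),
                "true_ols_rate": model.true_ols_rate(schedule, conc, window_min),
            }
        )
    wells = pd.DataFrame(well_rows)

    # vehicle-normalized truth, per solvent group
    wells["true_normalized_rate"] = np.nan
    for solvent, grp in wells.groupby("solvent", sort=True):
        veh = grp[grp["role"] == "vehicle"]
        if veh.empty:  # treatments in a solvent group with no matching vehicle
            veh = wells[wells["role"] == "vehicle"]
        mean_veh = veh["true_ols_rate"].mean()
        wells.loc[grp.index, "true_normalized_rate"] = grp["true_ols_rate"] / mean_veh

    comp_rows = []
    for name in sorted(models):
        m = models[name]
        comp_rows.append(
            {
                "compound": name,
                "true_ic50_uM": m.half_effect_conc(schedule, window_min),
                "a0_mm2": m.a0_mm2,
                "a_inf_mm2": m.a_inf_mm2,
                "k_top": m.k_top,
                "k_bot": m.k_bot,
                "log_ic50": m.log_ic50,
                "slope_s": m.slope_s,
            }
        )
    return GroundTruth(
        areas=pd.DataFrame(area_rows),
        wells=wells,
        compounds=pd.DataFrame(comp_rows),
        window_min=window_min,
    )


def iter_frames(
    layout: PlateLayout,
    calib: Calibration,
    truth: GroundTruth,
    cfg: RenderConfig,
) -> Iterator[ImageFrame]:
    """Render the experiment's frames one at a time (memory-friendly)."""
    areas = truth.areas.pivot(index="time_min", columns="well", values="area_mm2")
    for fid, t in enumerate(areas.index):
        per_well = areas.loc[t].to_dict()
        yield render_frame(layout, calib, per_well, cfg, frame_seed=fid, time_min=float(t), frame_id=fid)


def generate_experiment(
    layout: PlateLayout,
    models: Mapping[str, ContractionModel],
    calib: Calibration,
    cfg: RenderConfig,
    out_dir: str | Path,
    schedule: np.ndarray | None = None,
    window_min: float = DEFAULT_WINDOW_MIN,
    baseline: ContractionModel | None = None,
) -> GroundTruth:
    """Write a complete synthetic experiment to ``out_dir``.

    Produces ``images/frame_NNNN.png``, ``manifest.csv``, ``layout.csv``,
    ``calibration.toml``, the three ground-truth CSVs and a
    ``run_metadata.json`` recording every generator parameter. All randomness
    derives from ``cfg.seed``. Returns the :class:`GroundTruth`.
    """
    if schedule is None:
        schedule = default_schedule()
    truth = build_ground_truth(layout, models, schedule, window_min, baseline)

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for frame in iter_frames(layout, calib, truth, cfg):
        fname = f"frame_{frame.frame_id:04d}.png"
        write_image(frame.pixels, img_dir / fname)
        entries.append((fname, frame.time_min))
    write_manifest(entries, out / "manifest.csv")
    write_layout(layout, out / "layout.csv")
    write_calibration(calib, out / "calibration.toml")
    truth.write(out)
    meta = {
        "seed": cfg.seed,
        "render": asdict(cfg),
        "calibration": asdict(calib),
        "window_min": window_min,
        "schedule_min": list(map(float, schedule)),
        "models": {k: asdict(v) for k, v in sorted(models.items())},
        "n_frames": len(entries),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return truth


# ---------------------------------------------------------------------------
# the default screen scenario


#: (compound, intended endpoint IC50 in uM, solvent, role); None IC50 = dose-flat.
DEFAULT_COMPOUNDS: tuple[tuple[str, float | None, str, str], ...] = (
    ("ATRA", 82.8, "DMSO", "treatment"),
    ("dexamethasone", 84.6, "DMSO", "treatment"),
    ("doxorubicin", 46.7, "PBS", "treatment"),
    ("5-fluorouracil", 253.0, "PBS", "treatment"),
    ("forskolin", 4.7, "PBS", "treatment"),
    ("SDS", 281.8, "PBS", "positive_control"),
    ("penicillin-G", None, "PBS", "negative_control"),
)

_NEGATIVE_CONTROL_MAX_UM = 5980.0  # penicillin-G top dose
_DILUTION = 6.0
_N_DOSES = 4
_N_REPS = 3
_TOP_DOSE_OVER_IC50 = 8.0


def default_models(
    a0_mm2: float = 1.8,
    a_inf_mm2: float = 0.72,
    k_top: float = 0.01,
    slope_s: float = 0.3,
    schedule: np.ndarray | None = None,
    window_min: float = DEFAULT_WINDOW_MIN,
) -> dict[str, ContractionModel]:
    """Kinetic models for the default seven-compound screen.

    Toxic compounds run from full-rate contraction (k_top) to none (k_bot = 0)
    with endpoint half-effect IC50s placed on the screen's concentration scale;
    the negative control is dose-flat (k_bot = k_top).
    """
    base = ContractionModel(a0_mm2, a_inf_mm2, k_top, 0.0, 0.0, slope_s)
    models = {}
    for name, ic50, _solvent, _role in DEFAULT_COMPOUNDS:
        if ic50 is None:
            models[name] = ContractionModel(a0_mm2, a_inf_mm2, k_top, k_top, 2.0, slope_s)
        else:
            models[name] = base.with_half_effect(ic50, schedule, window_min)
    return models


def default_doses(ic50_um: float | None) -> list[float]:
    """Four-point 1:6 serial dilution from ~8x the intended IC50 (descending)."""
    top = _NEGATIVE_CONTROL_MAX_UM if ic50_um is None else _TOP_DOSE_OVER_IC50 * ic50_um
    return [top / _DILUTION**i for i in range(_N_DOSES)]


def default_layout() -> PlateLayout:
    """The default 96-well screen.

    Rows A-G hold the seven compounds, each at four concentrations x three
    replicates across the row's twelve wells (highest dose in columns 1-3);
    row H holds six PBS and six DMSO vehicle wells.
    """
    wells: list[WellSpec] = []
    for row, (name, ic50, solvent, role) in enumerate(DEFAULT_COMPOUNDS):
        for d, conc in enumerate(default_doses(ic50)):
            for rep in range(_N_REPS):
                col = d * _N_REPS + rep
                wells.append(
                    WellSpec(
                        name=f"{chr(ord('A') + row)}{col + 1}",
                        row=row,
                        col=col,
                        compound=name,
                        concentration_um=conc,
                        role=role,
                        replicate=rep + 1,
                        solvent=solvent,
                    )
                )
    for col in range(12):
        solvent = "PBS" if col < 6 else "DMSO"
        wells.append(
            WellSpec(
                name=f"H{col + 1}",
                row=7,
                col=col,
                compound=None,
                concentration_um=0.0,
                role="vehicle",
                replicate=col % 6 + 1,
                solvent=solvent,
            )
        )
    return PlateLayout(wells=tuple(wells))


def default_screen(
    seed: int = 0, noise_sd: float = 0.02, vignette_strength: float = 0.15
) -> tuple[PlateLayout, dict[str, ContractionModel], Calibration, RenderConfig]:
    """Layout, models, calibration and render settings for the default screen."""
    layout = default_layout()
    models = default_models()
    calib = default_calibration()
    cfg = RenderConfig(noise_sd=noise_sd, vignette_strength=vignette_strength, seed=seed)
    return layout, models, calib, cfg
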