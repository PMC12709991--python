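"""Synthetic field trials, flight plans and contaminated multi-view measurements.

The generator emulates the structure of a drone-based canopy-temperature (CT)
campaign over a replicated variety trial:

* a row/column plot grid with genotype / treatment / replicate structure,
* plot-level true effects plus a separable AR(1)xAR(1) spatial field,
* a serpentine flight plan with a nadir, fixed-heading thermal camera,
* per-image per-plot measurements contaminated by a smooth within-flight
  temporal drift (thermal drift of the uncooled sensor), vignetting, a
  fractional-canopy-cover (FCC) viewing-angle effect, a sun-direction
  gradient and i.i.d. measurement noise.

Ground truth is retained so that every correction stage downstream can be
scored by parameter recovery.  All stochastic operations take an explicit
integer seed; a single seed fans out deterministically through
``numpy.random.SeedSequence(seed).spawn``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .viewgeom import LINEARIZED_COVARIATE_NAMES, RAW_COVARIATE_NAMES, SunPosition

logger = logging.getLogger(__name__)

__all__ = [
    "FieldLayout",
    "EffectConfig",
    "TrueEffects",
    "FlightPlan",
    "DriftModel",
    "GeometricEffectModel",
    "FanResponse",
    "make_field_layout",
    "simulate_true_surface",
    "plan_flight",
    "simulate_measurements",
    "simulate_fan_experiment",
    "MEASUREMENT_COLUMNS",
]

BORDER = "border"

#: Exact leading column order of the measurement table CSV.
MEASUREMENT_COLUMNS = (
    ("plot_id", "trigger_id", "time_s", "value_K")
    + RAW_COVARIATE_NAMES
    + LINEARIZED_COVARIATE_NAMES
)


# ---------------------------------------------------------------------------
# field layout
# ---------------------------------------------------------------------------

@dataclass
class FieldLayout:
    """Plot grid with design assignment and planar plot-centre coordinates.

    ``plots`` is a DataFrame with one row per plot: plot_id, row, col,
    genotype, treatment, replicate, x, y, is_border.  Rows run along the
    y (north) axis, columns along x (east); the sowing-row direction is a
    shared unit vector (default east, i.e. plots are long in x).
    """

    n_rows: int
    n_cols: int
    plots: pd.DataFrame
    plot_width: float = 1.5  # m, across sowing rows (row-to-row pitch)
    plot_length: float = 7.0  # m, along sowing rows (column pitch)
    row_direction: tuple = (1.0, 0.0)

    def __post_init__(self):
        if self.plots["plot_id"].duplicated().any():
            raise ValueError("plot_ids must be unique")
        rd = np.asarray(self.row_direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(rd)), 1.0, abs_tol=1e-9):
            raise ValueError("row_direction must have unit norm")

    @property
    def experiment_plots(self) -> pd.DataFrame:
        return self.plots[~self.plots["is_border"]]

    def bounding_box(self):
        """(xmin, ymin, xmax, ymax) of the union of plot rectangles."""
        half_l, half_w = self.plot_length / 2.0, self.plot_width / 2.0
        x, y = self.plots["x"].to_numpy(), self.plots["y"].to_numpy()
        return (x.min() - half_l, y.min() - half_w, x.max() + half_l, y.max() + half_w)


def make_field_layout(
    n_rows: int,
    n_cols: int,
    n_genotypes: int,
    n_treatments: int,
    n_reps: int,
    treatment_blocking: str = "nested",
    seed: int = 0,
    plot_width: float = 1.5,
    plot_length: float = 7.0,
) -> FieldLayout:
    """Randomized complete-block layout on an ``n_rows x n_cols`` grid.

    ``treatment_blocking``:

    * ``"nested"`` — genotype blocks randomly nested within treatment
      replicates (each replicate split into one block per treatment),
      mirroring a variety trial with crop-management treatments;
    * ``"side_by_side"`` — treatments occupy contiguous halves of the field
      with a randomized complete block of replicates inside each treatment,
      mirroring a fertilization trial.

    Surplus grid cells are labelled genotype ``"border"``.
    """
    needed = n_genotypes * n_treatments * n_reps
    n_plots = n_rows * n_cols
    if n_plots < needed:
        raise ValueError(
            f"grid of {n_plots} plots too small: design requires {needed} plots"
        )
    if treatment_blocking not in ("nested", "side_by_side"):
        raise ValueError(f"unknown treatment_blocking: {treatment_blocking!r}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genotypes = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    treatments = [f"T{k + 1}" for k in range(n_treatments)]

    # row-major grid cells; the first `needed` cells carry the experiment
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    assign = []  # (genotype, treatment, replicate)
    if treatment_blocking == "nested":
        for rep in range(1, n_reps + 1):
            treat_order = rng.permutation(treatments)
            for t in treat_order:
                for g in rng.permutation(genotypes):
                    assign.append((g, t, rep))
    else:  # side_by_side
        for t in treatments:
            for rep in range(1, n_reps + 1):
                for g in rng.permutation(genotypes):
                    assign.append((g, t, rep))

    records = []
    for idx, (r, c) in enumerate(cells):
        if idx < needed:
            g, t, rep = assign[idx]
            border = False
        else:
            g, t, rep, border = BORDER, BORDER, 0, True
        records.append(
            {
                "plot_id": f"P{r:03d}_{c:03d}",
                "row": r,
                "col": c,
                "genotype": g,
                "treatment": t,
                "replicate": rep,
                "x": c * plot_length,
                "y": r * plot_width,
                "is_border": border,
            }
        )
    plots = pd.DataFrame.from_records(records)
    return FieldLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        plots=plots,
        plot_width=plot_width,
        plot_length=plot_length,
    )


# ---------------------------------------------------------------------------
# true effects
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Standard deviations (K) of the generative effect families.

    Defaults follow field-realistic magnitudes: genotype differences of a few
    tenths of a kelvin against a ~1 K spatial field.  Explicit
    ``treatment_effects`` / ``genotype_effects`` override the random draw
    (handy for controlled recovery experiments).
    """

    sd_genotype: float = 0.3
    sd_treatment: float = 0.3
    sd_interaction: float = 0.0
    sd_replicate: float = 0.1
    sd_plot: float = 0.2
    sd_spatial: float = 1.0
    rho_row: float = 0.8
    rho_col: float = 0.8
    grand_mean: float = 298.0
    genotype_effects: dict | None = None
    treatment_effects: dict | None = None

    def validate(self):
        for name in ("sd_genotype", "sd_treatment", "sd_interaction",
                     "sd_replicate", "sd_plot", "sd_spatial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_row", "rho_col"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")


@dataclass
class TrueEffects:
    """Ground-truth effect decomposition of a simulated field."""

    grand_mean: float
    genotype: pd.Series  # indexed by genotype id
    treatment: pd.Series
    interaction: pd.Series  # MultiIndex (genotype, treatment)
    replicate: pd.Series
    plot: pd.Series  # indexed by plot_id
    spatial: pd.Series  # indexed by plot_id

    def plot_totals(self, layout: FieldLayout) -> pd.Series:
        """True static value per plot: grand mean + all plot-level effects."""
        p = layout.plots
        inter = self.interaction.reindex(
            pd.MultiIndex.from_arrays([p["genotype"], p["treatment"]])
        ).to_numpy()
        total = (
            self.grand_mean
            + self.genotype.reindex(p["genotype"]).to_numpy()
            + self.treatment.reindex(p["treatment"]).to_numpy()
            + np.nan_to_num(inter)
            + self.replicate.reindex(p["replicate"]).to_numpy()
            + self.plot.reindex(p["plot_id"]).to_numpy()
            + self.spatial.reindex(p["plot_id"]).to_numpy()
        )
        return pd.Series(total, index=p["plot_id"].to_numpy(), name="true_value")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (family, level, true_value) sidecar table."""
        rows = [("grand_mean", "", self.grand_mean)]
        for fam, s in (
            ("genotype", self.genotype),
            ("treatment", self.treatment),
            ("replicate", self.replicate),
            ("plot", self.plot),
            ("spatial", self.spatial),
        ):
            rows += [(fam, str(k), float(v)) for k, v in s.items()]
        rows += [
            ("interaction", f"{g}:{t}", float(v))
            for (g, t), v in self.interaction.items()
        ]
        return pd.DataFrame(rows, columns=["family", "level", "true_value"])


def _centered_normal(rng, levels, sd):
    x = rng.normal(0.0, sd, size=len(levels)) if sd > 0 else np.zeros(len(levels))
    if len(levels) > 1 and sd > 0:
        x = x - x.mean()
    return pd.Series(x, index=levels)


def simulate_true_surface(
    layout: FieldLayout, effect_config: EffectConfig | None = None, seed: int = 0
) -> TrueEffects:
    """Draw ground-truth effects for a layout.

    Effects are drawn i.i.d. normal per family then centred to sum to zero
    over their levels; the spatial field is drawn from the separable
    AR(1)xAR(1) covariance over the full plot grid (unit marginal variance
    times ``sd_spatial**2``).
    """
    cfg = effect_config or EffectConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed).spawn(6)
    p = layout.plots

    geno_levels = sorted(p["genotype"].unique())
    treat_levels = sorted(p["treatment"].unique())
    rep_levels = sorted(p["replicate"].unique())

    if cfg.genotype_effects is not None:
        geno = pd.Series(cfg.genotype_effects).reindex(geno_levels).fillna(0.0)
    else:
        geno = _centered_normal(np.random.default_rng(ss[0]), geno_levels, cfg.sd_genotype)
    if cfg.treatment_effects is not None:
        treat = pd.Series(cfg.treatment_effects).reindex(treat_levels).fillna(0.0)
    else:
        treat = _centered_normal(np.random.default_rng(ss[1]), treat_levels, cfg.sd_treatment)
    rep = _centered_normal(np.random.default_rng(ss[2]), rep_levels, cfg.sd_replicate)
    plot_eff = _centered_normal(np.random.default_rng(ss[3]), list(p["plot_id"]), cfg.sd_plot)

    # two-way interaction, double-centred so margins vanish
    inter_index = pd.MultiIndex.from_product([geno_levels, treat_levels])
    if cfg.sd_interaction > 0:
        m = np.random.default_rng(ss[4]).normal(
            0.0, cfg.sd_interaction, size=(len(geno_levels), len(treat_levels))
        )
        m = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()
        inter = pd.Series(m.ravel(), index=inter_index)
    else:
        inter = pd.Series(0.0, index=inter_index)

    # separable AR(1)xAR(1) field on the full grid
    if cfg.sd_spatial > 0:
        rng = np.random.default_rng(ss[5])
        lr = np.linalg.cholesky(_ar1_corr(layout.n_rows, cfg.rho_row))
        lc = np.linalg.cholesky(_ar1_corr(layout.n_cols, cfg.rho_col))
        z = rng.standard_normal((layout.n_rows, layout.n_cols))
        grid = cfg.sd_spatial * (lr @ z @ lc.T)
        spatial = pd.Series(
            grid[p["row"].to_numpy(), p["col"].to_numpy()], index=list(p["plot_id"])
        )
    else:
        spatial = pd.Series(0.0, index=list(p["plot_id"]))

    return TrueEffects(
        grand_mean=cfg.grand_mean,
        genotype=geno,
        treatment=treat,
        interaction=inter,
        replicate=rep,
        plot=plot_eff,
        spatial=spatial,
    )


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


# ---------------------------------------------------------------------------
# flight planning
# ---------------------------------------------------------------------------

@dataclass
class FlightPlan:
    """Serpentine nadir survey with a fixed camera heading.

    ``triggers`` has one row per image: trigger_id, time_s, x, y, z,
    along_track_direction (+1/-1).  The camera heading is constant (the image
    +y axis stays aligned with it regardless of flight direction).
    """

    triggers: pd.DataFrame
    flight_height: float
    fov_half_angles: tuple  # degrees (across = image x, along = image y)
    frame_interval: float
    camera_heading: float = 0.0

    def footprint_half_extent(self):
        """(hx, hy) metres: half-extent of the ground footprint."""
        hx = self.flight_height * math.tan(math.radians(self.fov_half_angles[0]))
        hy = self.flight_height * math.tan(math.radians(self.fov_half_angles[1]))
        return hx, hy

    @property
    def duration(self) -> float:
        return float(self.triggers["time_s"].iloc[-1])


def plan_flight(
    layout: FieldLayout,
    flight_height: float = 40.0,
    fov_half_angles: tuple = (22.5, 18.5),
    front_overlap: float = 0.8,
    side_overlap: float = 0.8,
    speed: float = 3.0,
    seed: int = 0,
    camera_heading: float = 0.0,
) -> FlightPlan:
    """Serpentine grid covering the layout bounding box plus one footprint.

    Flight lines run east--west (the field's long axis); line spacing and
    trigger spacing follow the standard photogrammetric overlap formulas from
    the footprint size.  The heading (and hence the image orientation) is
    fixed for the whole flight.
    """
    if not (0 <= front_overlap < 1 and 0 <= side_overlap < 1):
        raise ValueError("overlaps must be in [0, 1)")
    if flight_height <= 0:
        raise ValueError("flight height must be > 0")

    hx = flight_height * math.tan(math.radians(fov_half_angles[0]))
    hy = flight_height * math.tan(math.radians(fov_half_angles[1]))
    if 2 * hx < layout.plot_length or 2 * hy < layout.plot_width:
        logger.warning(
            "image footprint (%.1f x %.1f m) smaller than a plot; plots will "
            "never be fully visible", 2 * hx, 2 * hy,
        )
    dx = 2 * hx * (1 - front_overlap)  # trigger spacing along track
    dy = 2 * hy * (1 - side_overlap)  # flight-line spacing

    xmin, ymin, xmax, ymax = layout.bounding_box()
    xs_start, xs_stop = xmin - hx, xmax + hx
    ys = np.arange(ymin - hy, ymax + hy + 1e-9, dy)
    n_along = max(2, int(math.ceil((xs_stop - xs_start) / dx)) + 1)
    xs = np.linspace(xs_start, xs_stop, n_along)

    rows = []
    t = 0.0
    tid = 0
    for i, y in enumerate(ys):
        direction = 1 if i % 2 == 0 else -1
        line_xs = xs if direction == 1 else xs[::-1]
        for j, x in enumerate(line_xs):
            if j > 0:
                t += abs(line_xs[j] - line_xs[j - 1]) / speed
            rows.append((f"L{tid:05d}", t, x, y, flight_height, direction))
            tid += 1
        t += dy / speed  # turn to the next line
    triggers = pd.DataFrame(
        rows, columns=["trigger_id", "time_s", "x", "y", "z", "along_track_direction"]
    )
    return FlightPlan(
        triggers=triggers,
        flight_height=flight_height,
        fov_half_angles=fov_half_angles,
        frame_interval=dx / speed,
        camera_heading=camera_heading,
    )


# ---------------------------------------------------------------------------
# drift & geometric effect models
# ---------------------------------------------------------------------------

class DriftModel:
    """Smooth within-flight temporal drift of the apparent temperature.

    The basis is a sum of ``n_components`` random-phase sinusoids with
    periods >= duration / n_components, centred to zero time-mean over the
    flight and rescaled so max |drift| equals ``amplitude``.  Sign
    convention: sensor warming lowers the apparent temperature, so a positive
    drift value means a cooled (e.g. wind-exposed) sensor.
    """

    def __init__(self, amplitude: float, duration: float, seed: int = 0, n_components: int = 3):
        self.amplitude = float(amplitude)
        self.duration = float(duration)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
        kmax = n_components
        self.periods = duration / rng.uniform(0.5, kmax, size=n_components)
        self.phases = rng.uniform(0, 2 * math.pi, size=n_components)
        self.weights = rng.uniform(0.5, 1.0, size=n_components)
        grid = np.linspace(0.0, duration, 512)
        raw = self._raw(grid)
        self._offset = raw.mean()
        peak = np.max(np.abs(raw - self._offset))
        self._scale = 0.0 if (peak == 0 or amplitude == 0) else amplitude / peak

    def _raw(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for w, per, ph in zip(self.weights, self.periods, self.phases):
            out += w * np.sin(2 * math.pi * t / per + ph)
        return out

    def __call__(self, t):
        return (self._raw(t) - self._offset) * self._scale


@dataclass
class GeometricEffectModel:
    """Viewing-geometry contamination of per-image measurements.

    * ``vignetting_amplitude`` — K; radially symmetric offset over the image,
      zero at the image centre and ``-amplitude`` at unit (corner) radius:
      edges read cooler, as lens vignetting does.
    * ``fcc_effect`` — K per radian of |lateral row-direction viewing angle|;
      applied with a negative sign (oblique views across the rows see more
      canopy and less warm soil, hence cooler readings when soil is warmer).
    * ``sun_gradient`` — K per metre of longitudinal sun-direction distance.
    * ``noise_sd`` — K, i.i.d. Gaussian measurement noise.

    All magnitudes are configurable to exactly 0.
    """

    vignetting_amplitude: float = 0.0
    fcc_effect: float = 0.0
    sun_gradient: float = 0.0
    noise_sd: float = 0.0

    def vignetting(self, u, w):
        """Offset at normalized image coordinates u, w in [-1, 1]."""
        return -self.vignetting_amplitude * (np.asarray(u) ** 2 + np.asarray(w) ** 2) / 2.0

    def render_vignetting(self, shape=(512, 640)) -> np.ndarray:
        """Per-pixel K offsets on a raster (zero at the image centre)."""
        ny, nx = shape
        w, u = np.meshgrid(
            np.linspace(-1, 1, ny), np.linspace(-1, 1, nx), indexing="ij"
        )
        return self.vignetting(u, w)


# ---------------------------------------------------------------------------
# measurement simulation
# ---------------------------------------------------------------------------

def _geometry_columns(cam_xy, height, times, plot_xy, row_dir, sun, heading):
    """Vectorized raw + linearized covariates for matched camera/plot arrays."""
    off = cam_xy - plot_xy  # plot -> drone
    planar = np.hypot(off[:, 0], off[:, 1])
    total = np.hypot(planar, height)
    elev = np.degrees(np.arctan2(height, planar))

    def decomp(direction):
        lon = off @ direction
        lat = off @ np.array([direction[1], -direction[0]])
        return lon, lat

    row_lon, row_lat = decomp(row_dir)
    sun_dir = np.array(
        [math.sin(math.radians(sun.azimuth)), math.cos(math.radians(sun.azimuth))]
    )
    sun_lon, sun_lat = decomp(sun_dir)

    def ang(d):
        return np.degrees(np.arctan2(d, height))

    cols = {
        "drone_elevation_deg": elev,
        "dist_total_m": total,
        "rowdir_lat_dist_m": row_lat,
        "rowdir_lon_dist_m": row_lon,
        "rowdir_lat_angle_deg": ang(row_lat),
        "rowdir_lon_angle_deg": ang(row_lon),
        "sundir_lat_dist_m": sun_lat,
        "sundir_lon_dist_m": sun_lon,
        "sundir_lat_angle_deg": ang(sun_lat),
        "sundir_lon_angle_deg": ang(sun_lon),
    }
    elev_sin = np.sin(np.radians(elev))
    lin = {
        "Drone-Elevation-sin": elev_sin,
        "RowDir-lat-Dist": row_lat,
        "RowDir-lat-Dist-abs": np.abs(row_lat),
        "RowDir-lat-Angl-cos": np.cos(np.radians(cols["rowdir_lat_angle_deg"])),
        "RowDir-lat-Angl-abs": np.abs(cols["rowdir_lat_angle_deg"]),
        "RowDir-lon-Dist": row_lon,
        "RowDir-lon-Dist-abs": np.abs(row_lon),
        "RowDir-lon-Angl-cos": np.cos(np.radians(cols["rowdir_lon_angle_deg"])),
        "RowDir-lon-Angl-abs": np.abs(cols["rowdir_lon_angle_deg"]),
        "SunDir-lat-Dist": sun_lat,
        "SunDir-lat-Dist-abs": np.abs(sun_lat),
        "SunDir-lat-Angl-cos": np.cos(np.radians(cols["sundir_lat_angle_deg"])),
        "SunDir-lat-Angl-abs": np.abs(cols["sundir_lat_angle_deg"]),
        "SunDir-lon-Dist": sun_lon,
        "SunDir-lon-Dist-abs": np.abs(sun_lon),
        "SunDir-lon-Angl-cos": np.cos(np.radians(cols["sundir_lon_angle_deg"])),
        "SunDir-lon-Angl-abs": np.abs(cols["sundir_lon_angle_deg"]),
        "Interact.-SunDir-Drone": sun_lon * elev_sin,
        "Trigger-time": times,
        "Dist-tot": total,
    }
    cols.update(lin)

    # normalized image coordinates (camera heading fixed; +y image = heading)
    head = np.array(
        [math.sin(math.radians(heading)), math.cos(math.radians(heading))]
    )
    cam_to_plot = -off
    img_y_m = cam_to_plot @ head
    img_x_m = cam_to_plot @ np.array([head[1], -head[0]])
    return cols, img_x_m, img_y_m


def simulate_measurements(
    true_effects: TrueEffects,
    layout: FieldLayout,
    flight_plan: FlightPlan,
    sun: SunPosition | None = None,
    drift: DriftModel | None = None,
    geom: GeometricEffectModel | None = None,
    seed: int = 0,
    flight_id: str = "F1",
) -> pd.DataFrame:
    """Per-image per-plot CT measurements with all covariates attached.

    One record is produced for every (plot, trigger) pair where the plot
    rectangle lies fully inside the camera field of view.  The measured value
    is the plot's true static value plus drift, vignetting, the FCC
    viewing-angle effect, the sun-direction gradient and Gaussian noise.
    Plots never fully visible yield zero records and a logged warning.
    """
    sun = sun or SunPosition(azimuth=180.0, elevation=55.0)
    geom = geom or GeometricEffectModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC7]))

    hx, hy = flight_plan.footprint_half_extent()
    half_l, half_w = layout.plot_length / 2.0, layout.plot_width / 2.0
    plots = layout.plots
    plot_xy = plots[["x", "y"]].to_numpy()
    totals = true_effects.plot_totals(layout)
    height = flight_plan.flight_height
    row_dir = np.asarray(layout.row_direction, dtype=float)

    # heading-0 footprint is axis-aligned; general headings rotate the FOV box
    heading = flight_plan.camera_heading
    cos_h, sin_h = math.cos(math.radians(heading)), math.sin(math.radians(heading))

    trig = flight_plan.triggers
    rec_plot, rec_trig, rec_time = [], [], []
    cam_rows, plot_rows = [], []
    for _, tr in trig.iterrows():
        rel = plot_xy - np.array([tr["x"], tr["y"]])
        # plot corner extents in camera image axes (x right of heading, y along)
        rel_x = rel[:, 0] * cos_h - rel[:, 1] * sin_h
        rel_y = rel[:, 0] * sin_h + rel[:, 1] * cos_h
        ext_x = abs(half_l * cos_h) + abs(half_w * sin_h)
        ext_y = abs(half_l * sin_h) + abs(half_w * cos_h)
        inside = (np.abs(rel_x) + ext_x <= hx) & (np.abs(rel_y) + ext_y <= hy)
        idx = np.nonzero(inside)[0]
        if idx.size == 0:
            continue
        rec_plot.append(idx)
        rec_trig.append(np.full(idx.size, tr["trigger_id"], dtype=object))
        rec_time.append(np.full(idx.size, tr["time_s"]))
        cam_rows.append(np.repeat([[tr["x"], tr["y"]]], idx.size, axis=0))

    if not rec_plot:
        logger.warning("no plot was ever fully inside the field of view")
        return pd.DataFrame(columns=list(MEASUREMENT_COLUMNS) + ["flight_id", "image_x", "image_y"])

    plot_idx = np.concatenate(rec_plot)
    trig_ids = np.concatenate(rec_trig)
    times = np.concatenate(rec_time)
    cam_xy = np.concatenate(cam_rows)

    seen = np.zeros(len(plots), dtype=bool)
    seen[np.unique(plot_idx)] = True
    for pid in plots.loc[~seen, "plot_id"]:
        logger.warning("plot %s never fully visible in any image", pid)

    cols, img_x_m, img_y_m = _geometry_columns(
        cam_xy, height, times, plot_xy[plot_idx], row_dir, sun, heading
    )

    u = img_x_m / hx  # normalized image coordinates in [-1, 1]
    w = img_y_m / hy

    value = totals.to_numpy()[plot_idx].astype(float).copy()
    if drift is not None:
        value += drift(times)
    value += geom.vignetting(u, w)
    value += -geom.fcc_effect * np.abs(np.radians(cols["rowdir_lat_angle_deg"]))
    value += geom.sun_gradient * cols["sundir_lon_dist_m"]
    if geom.noise_sd > 0:
        value += rng.normal(0.0, geom.noise_sd, size=value.size)

    table = pd.DataFrame(
        {
            "plot_id": plots["plot_id"].to_numpy()[plot_idx],
            "trigger_id": trig_ids,
            "time_s": times,
            "value_K": value,
        }
    )
    for name in RAW_COVARIATE_NAMES:
        table[name] = cols[name]
    for name in LINEARIZED_COVARIATE_NAMES:
        table[name] = cols[name]
    table["flight_id"] = flight_id
    table["image_x"] = u
    table["image_y"] = w
    return table


# ---------------------------------------------------------------------------
# fan experiment
# ---------------------------------------------------------------------------

@dataclass
class FanResponse:
    """First-order sensor-response parameters of the fan-experiment emulator."""

    ambient: float = 22.0  # °C, room & initial sensor temperature
    target_temp: float = 22.0  # °C, PVC sheet true temperature
    tau_s: float = 90.0  # s, relaxation time constant of the sensor body
    lamp_heat: float = 10.0  # K, sensor setpoint offset while the lamp is on
    fan_cool: float = -6.0  # K, sensor setpoint offset while the fan is on
    gain: float = 2.0  # apparent-K per sensor-K (opposite sign)
    base_pixel_sd: float = 0.10  # K
    hot_object_sd: float = 1.50  # K while a hot object is inside the FOV
    dt: float = 1.0  # s, integration step
    duration: float | None = None  # s; default: last event + 5 tau
    noise_sd: float = 0.0


def simulate_fan_experiment(events, response_params: FanResponse | None = None, seed: int = 0):
    """Emulate the indoor sensor-drift experiment.

    ``events`` is a time-ordered sequence of ``(time_s, kind)`` for kinds
    ``fan_on / fan_off / lamp_on / lamp_off`` plus ``("hot_object", start,
    stop)`` entries.  The sensor temperature relaxes first-order toward an
    event-dependent setpoint; the apparent target temperature moves opposite
    to the sensor temperature (warming sensor -> lower reading); hot objects
    raise the pixel standard deviation only while inside the FOV.

    Returns a DataFrame: time_s, sensor_temp, apparent_target_temp, pixel_sd.
    """
    p = response_params or FanResponse()
    switches = []  # (t, kind)
    hot_windows = []
    for ev in events:
        if ev[0] == "hot_object":
            start, stop = float(ev[1]), float(ev[2])
            if stop < start:
                raise ValueError("hot_object stop before start")
            hot_windows.append((start, stop))
        else:
            t, kind = float(ev[0]), ev[1]
            if kind not in ("fan_on", "fan_off", "lamp_on", "lamp_off"):
                raise ValueError(f"unknown event kind: {kind!r}")
            switches.append((t, kind))
    if switches != sorted(switches, key=lambda e: e[0]):
        raise ValueError("events must be time-ordered")

    t_end = p.duration
    if t_end is None:
        last = max(
            [t for t, _ in switches] + [w[1] for w in hot_windows] + [0.0]
        )
        t_end = last + 5 * p.tau_s
    times = np.arange(0.0, t_end + p.dt / 2, p.dt)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA6]))
    fan = lamp = False
    sensor = p.ambient
    sw = list(switches)
    out = np.empty((times.size, 3))
    for i, t in enumerate(times):
        while sw and sw[0][0] <= t:
            _, kind = sw.pop(0)
            if kind == "fan_on":
                if fan:
                    logger.info("fan_on while fan already on; last event wins")
                fan = True
            elif kind == "fan_off":
                fan = False
            elif kind == "lamp_on":
                if lamp:
                    logger.info("lamp_on while lamp already on; last event wins")
                lamp = True
            else:
                lamp = False
        setpoint = p.ambient + (p.lamp_heat if lamp else 0.0) + (p.fan_cool if fan else 0.0)
        # exact first-order step keeps the trajectory strictly monotone
        sensor = setpoint + (sensor - setpoint) * math.exp(-p.dt / p.tau_s)
        apparent = p.target_temp - p.gain * (sensor - p.ambient)
        if p.noise_sd > 0:
            apparent += rng.normal(0.0, p.noise_sd)
        in_hot = any(a <= t <= b for a, b in hot_windows)
        sd = p.base_pixel_sd + (p.hot_object_sd if in_hot else 0.0)
        out[i] = (sensor, apparent, sd)

    return pd.DataFrame(
        {
            "time_s": times,
            "sensor_temp": out[:, 0],
            "apparent_target_temp": out[:, 1],
            "pixel_sd": out[:, 2],
        }
    )
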