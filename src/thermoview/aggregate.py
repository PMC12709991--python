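"""Pixel-to-plot aggregation, percentile selection and vignetting correction.

Each plot appears on many thermal frames; the pixels inside its (inward
buffered) region of interest are reduced to one value per image by a
percentile.  The percentile is chosen by maximising a repeatability curve:
low percentiles favour the (cooler) canopy when warm soil contaminates the
upper tail of the pixel distribution, high percentiles the reverse.

The vignetting correction is an ex-ante flat-field: frames of a uniform
target are averaged into a per-pixel offset image (zero mean) which is
subtracted from every frame before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import stage1

__all__ = [
    "PlotPixelSample",
    "PercentileCurve",
    "VignettingImage",
    "extract_percentile",
    "percentile_repeatability_curve",
    "choose_experiment_percentile",
    "build_vignetting_image",
    "apply_vignetting_correction",
    "plot_roi_polygon",
    "write_thermal_tiff",
    "read_thermal_tiff",
    "write_vignetting_tiff",
    "read_vignetting_tiff",
]


@dataclass
class PlotPixelSample:
    """Pixels of one plot on one image."""

    plot_id: str
    trigger_id: str
    pixel_values: np.ndarray  # temperatures, K or °C (units follow the frames)
    roi: Polygon | None = None

    def __post_init__(self):
        self.pixel_values = np.asarray(self.pixel_values, dtype=float).ravel()
        if self.pixel_values.size == 0:
            raise ValueError("pixel sample must contain at least one pixel")


@dataclass
class PercentileCurve:
    """Repeatability per candidate percentile and the chosen optimum."""

    percentiles: np.ndarray
    repeatability: np.ndarray
    chosen_percentile: int


@dataclass
class VignettingImage:
    """Per-pixel vignetting offsets (K), zero mean by construction."""

    offsets: np.ndarray

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        assert abs(self.offsets.mean()) < 1e-9


def plot_roi_polygon(layout, plot_id: str, buffer_m: float = 0.25) -> Polygon:
    """World-coordinate ROI of a plot: its rectangle buffered inward.

    The inward buffer (default 0.25 m) guards pixel extraction against
    georeferencing inaccuracy at the plot margins.
    """
    row = layout.plots.set_index("plot_id").loc[plot_id]
    half_l = layout.plot_length / 2.0 - buffer_m
    half_w = layout.plot_width / 2.0 - buffer_m
    if half_l <= 0 or half_w <= 0:
        raise ValueError("buffer larger than the plot")
    return box(row["x"] - half_l, row["y"] - half_w, row["x"] + half_l, row["y"] + half_w)


def extract_percentile(sample: PlotPixelSample, q: float) -> float:
    """Linear-interpolation percentile of a plot's pixel values."""
    if not 1 <= q <= 99:
        raise ValueError("percentile must be in [1, 99]")
    return float(np.percentile(sample.pixel_values, q, method="linear"))


def percentile_repeatability_curve(
    samples,
    layout,
    percentiles=None,
    n_rep: int | None = None,
) -> PercentileCurve:
    """Repeatability of plot values as a function of the aggregation percentile.

    For every candidate percentile q the per-image plot pixels are reduced to
    one value, averaged per plot over its images, and scored by the
    intraclass repeatability sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_rep)
    after replicate and row/column adjustment (via the stage-1 machinery in
    single-flight mode).  The chosen percentile is the argmax; ties resolve
    to the lower q.
    """
    if percentiles is None:
        percentiles = np.arange(1, 100)
    percentiles = np.asarray(sorted(percentiles), dtype=int)
    samples = list(samples)
    if not samples:
        raise ValueError("no pixel samples")

    meta = layout.plots.set_index("plot_id")
    counts = meta.loc[~meta["is_border"]].groupby("genotype").size()
    if counts.min() < 2:
        raise ValueError("repeatability undefined with a single replicate per genotype")

    reps = []
    for q in percentiles:
        per_image = pd.DataFrame(
            {
                "plot_id": [s.plot_id for s in samples],
                "value": [extract_percentile(s, q) for s in samples],
            }
        )
        plot_vals = per_image.groupby("plot_id")["value"].mean()
        reps.append(stage1.repeatability(plot_vals, layout, n_rep=n_rep))
    reps = np.asarray(reps)
    chosen = int(percentiles[int(np.argmax(reps))])  # argmax takes the first (lowest q) tie
    return PercentileCurve(percentiles=percentiles, repeatability=reps, chosen_percentile=chosen)


def choose_experiment_percentile(curves) -> int:
    """One percentile per experiment-year: majority vote over flight curves.

    Ties resolve to the lower percentile, matching the per-curve tie rule.
    """
    chosen = [c.chosen_percentile for c in curves]
    counts = pd.Series(chosen).value_counts()
    top = counts[counts == counts.max()].index
    return int(min(top))


def build_vignetting_image(flat_frames) -> VignettingImage:
    """Mean per-pixel offset of uniform-target frames, centred to zero mean."""
    frames = [np.asarray(f, dtype=float) for f in flat_frames]
    if not frames:
        raise ValueError("need at least one flat frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("flat frames must share one shape")
    mean = np.mean(frames, axis=0)
    return VignettingImage(offsets=mean - mean.mean())


def apply_vignetting_correction(frame: np.ndarray, correction: VignettingImage) -> np.ndarray:
    """Subtract the vignetting offsets from a frame, element-wise."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != correction.offsets.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match correction {correction.offsets.shape}"
        )
    return frame - correction.offsets


# ---------------------------------------------------------------------------
# TIFF I/O (thermal frames: single-band 16-bit, value = °C x 1000)
# ---------------------------------------------------------------------------

def write_thermal_tiff(path, temps_C: np.ndarray):
    import tifffile

    data = np.round(np.asarray(temps_C, dtype=float) * 1000.0).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_thermal_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(float) / 1000.0


def write_vignetting_tiff(path, image: VignettingImage):
    import tifffile

    tifffile.imwrite(path, image.offsets.astype(np.float32))


def read_vignetting_tiff(path) -> VignettingImage:
    import tifffile

    data = tifffile.imread(path).astype(float)
    return VignettingImage(offsets=data - data.mean())
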