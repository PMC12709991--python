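"""Vegetation indices, canopy cover, and CT--trait correlation analysis.

Canopy temperature (CT) is compared with plot-level reference traits (grain
yield, plant height, fractional canopy cover, multispectral vegetation
indices, ordinal ratings).  Because treatment effects can dominate and either
drive or mask genotypic correlations, both CT and reference traits are
carried through matched correction levels: uncorrected values are correlated
with uncorrected traits, spatially corrected with spatially corrected, and
treatment-deflated with treatment-deflated.  The pairing is enforced — a
mismatched request raises instead of silently computing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import stage1 as _stage1

logger = logging.getLogger(__name__)

__all__ = [
    "BandReflectances",
    "PixelClassCounts",
    "vegetation_indices",
    "fcc",
    "normalize_yield",
    "fit_reference_trait",
    "correlate",
    "rating_group_test",
    "LEVEL_PAIRING",
]

#: CT correction level -> required reference-trait correction level.
LEVEL_PAIRING = {
    "mean": "uncorrected",
    "t_c": "uncorrected",
    "ts_c": "ts_c",
    "t_defl": "t_defl",
}


@dataclass(frozen=True)
class BandReflectances:
    """Reflectance fractions of the bands used by the vegetation indices."""

    NIR842: float
    Red668: float
    Red650: float
    Blue444: float

    def __post_init__(self):
        for name in ("NIR842", "Red668", "Red650", "Blue444"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a reflectance fraction in [0, 1]")


@dataclass(frozen=True)
class PixelClassCounts:
    """Segmented pixel counts of a plot region."""

    green_plant: int
    senescent_plant: int
    background: int

    def __post_init__(self):
        if min(self.green_plant, self.senescent_plant, self.background) < 0:
            raise ValueError("pixel counts must be >= 0")


def vegetation_indices(bands: BandReflectances) -> dict:
    """DVI, EVI, NDVI and SAVI from band reflectances.

    DVI  = NIR842 - Red668
    EVI  = 2.5 (NIR842 - Red650) / (NIR842 + 6 Red650 - 7.5 Blue444 + 1)
    NDVI = (NIR842 - Red668) / (NIR842 + Red668)
    SAVI = 1.5 (NIR842 - Red650) / (NIR842 + Red650 + 0.5)

    A zero denominator yields NaN for that index (flagged, not a crash).
    """
    nir, r668, r650, blue = bands.NIR842, bands.Red668, bands.Red650, bands.Blue444
    out = {"DVI": nir - r668}

    def safe_div(num, den, name):
        if abs(den) < 1e-12:
            logger.warning("%s undefined: zero denominator", name)
            return float("nan")
        return num / den

    out["EVI"] = safe_div(2.5 * (nir - r650), nir + 6.0 * r650 - 7.5 * blue + 1.0, "EVI")
    out["NDVI"] = safe_div(nir - r668, nir + r668, "NDVI")
    out["SAVI"] = safe_div(1.5 * (nir - r650), nir + r650 + 0.5, "SAVI")
    return out


def fcc(counts: PixelClassCounts) -> float:
    """Fractional canopy cover: (green + senescent) / all pixels."""
    total = counts.green_plant + counts.senescent_plant + counts.background
    if total <= 0:
        raise ValueError("FCC undefined: no pixels")
    return (counts.green_plant + counts.senescent_plant) / total


def normalize_yield(fresh_weight, measured_moisture_pct):
    """Grain yield normalized to 15 % gravimetric water content.

    ``fresh_weight * (100 - moisture) / 85`` — dry matter rescaled to the
    15 %-moisture reporting convention.
    """
    m = np.asarray(measured_moisture_pct, dtype=float)
    if np.any((m < 0) | (m >= 100)):
        raise ValueError("moisture percentage out of range")
    out = np.asarray(fresh_weight, dtype=float) * (100.0 - m) / 85.0
    return float(out) if np.isscalar(fresh_weight) else out


def fit_reference_trait(trait_values: pd.Series, layout, config=None) -> pd.DataFrame:
    """Spatially correct a plot-level reference trait.

    The trait is fitted with the stage-1 decomposition without a temporal
    component (one synthetic trigger carries all plots), yielding trait
    analogues of the spatially corrected (``ts_c``) and treatment-deflated
    (``t_defl``) CT estimates.  Returns a DataFrame indexed by plot with
    columns ``uncorrected``, ``ts_c``, ``t_defl``.
    """
    trait_values = trait_values.dropna()
    meas = pd.DataFrame(
        {
            "plot_id": trait_values.index,
            "trigger_id": "ref",
            "time_s": 0.0,
            "value_K": trait_values.to_numpy(dtype=float),
        }
    )
    cfg = config or _stage1.Stage1Config(spline_knot_spacing=10)
    res = _stage1.CanopyTemperatureModel(meas, layout, cfg).fit()
    tsc = res.predict("ts_c").set_index("plot_id")["estimate_K"]
    tdefl = res.predict("t_defl").set_index("plot_id")["estimate_K"]
    meta = layout.plots.set_index("plot_id")
    exp_ids = tsc.index
    out = pd.DataFrame(
        {
            "uncorrected": trait_values.reindex(exp_ids),
            "ts_c": tsc,
            "t_defl": tdefl,
        }
    )
    out.index.name = "plot_id"
    return out


def correlate(
    ct_estimates: pd.DataFrame,
    trait_estimates: pd.DataFrame,
    level: str,
    trait: str = "trait",
    flight_id: str = "F1",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pearson correlation of CT with a reference trait at matched levels.

    ``ct_estimates`` is a plot-estimate table (plot_id, estimate_K, level) as
    produced by the stage-1 prediction chain; ``trait_estimates`` the output
    of :func:`fit_reference_trait`.  The correction levels must match:
    mean/t_c CT pairs with the uncorrected trait, ts_c with the spatially
    corrected trait, t_defl with the deflated trait.
    """
    if level not in LEVEL_PAIRING:
        raise ValueError(f"unknown CT level {level!r}")
    ct_level = ct_estimates["level"].unique()
    if len(ct_level) != 1 or ct_level[0] != level:
        raise ValueError(
            f"CT estimates are at level {list(ct_level)}, requested {level!r}"
        )
    trait_col = LEVEL_PAIRING[level]
    if trait_col not in trait_estimates.columns:
        raise ValueError(
            f"trait estimates lack the matched correction level {trait_col!r} "
            f"required for CT level {level!r}"
        )
    ct = ct_estimates.set_index("plot_id")["estimate_K"]
    tr = trait_estimates[trait_col]
    common = ct.index.intersection(tr.index)
    x, y = ct.reindex(common).to_numpy(), tr.reindex(common).to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need >= 3 matched plots")
    r, p = stats.pearsonr(x[ok], y[ok])
    return pd.DataFrame(
        [
            {
                "flight_id": flight_id,
                "trait": trait,
                "level": level,
                "r": float(r),
                "p": float(p),
                "n": n,
                "sig": bool(p <= alpha),
            }
        ]
    )


_SIG_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def rating_group_test(ct_values: pd.Series, ratings: pd.Series, min_group: int = 3) -> pd.DataFrame:
    """Pairwise rank-sum comparison of CT between ordinal rating groups.

    Groups with fewer than ``min_group`` plots are excluded (logged).
    Returns one row per group pair with the Mann-Whitney U statistic,
    two-sided p-value and a significance tier (ns / . / * / ** / ***).
    """
    df = pd.DataFrame({"ct": ct_values, "rating": ratings}).dropna()
    groups = {}
    for g, sub in df.groupby("rating"):
        if len(sub) < min_group:
            logger.warning("rating group %r has %d < %d members; excluded", g, len(sub), min_group)
            continue
        groups[g] = sub["ct"].to_numpy()
    keys = sorted(groups)
    if len(keys) < 2:
        raise ValueError("need >= 2 rating groups with enough members")
    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if np.array_equal(np.sort(groups[a]), np.sort(groups[b])):
                u, p = float("nan"), 1.0
            else:
                u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            tier = "ns"
            for thr, label in _SIG_TIERS:
                if p <= thr:
                    tier = label
                    break
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": len(groups[a]),
                    "n_b": len(groups[b]),
                    "U": float(u),
                    "p": float(p),
                    "sig": tier,
                }
            )
    return pd.DataFrame(rows)
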