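"""Area-based LiDAR predictors for plot-level biomass models.

Implements the standard area-based approach (ABA) plumbing: a digital
terrain model (DTM) rasterized from ground-classified returns, height
normalization of the point cloud against it, circular plot clipping, and
the plot-level height-distribution statistics used as model predictors:

* height percentiles of first-pulse and last-pulse returns,
* mean height of first-pulse returns above 5 m ("high-vegetation" mean),
* standard deviation of first-pulse return heights,
* the fraction of first-pulse (and last-pulse) returns below 1 m,
* canopy cover, the fraction of returns classified as vegetation.

Point clouds are plain :class:`pandas.DataFrame` objects with columns
``x, y, z, pulse, class`` where ``pulse`` is one of ``first``, ``last``
or ``single`` (a single-return pulse belongs to both the first- and
last-pulse pools) and ``class`` is ``ground``, ``vegetation`` or
``error``.  Error returns are excluded from every statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import binned_statistic_2d

from .errors import ConfigError, EmptyPlotError

KNOT_MS = 0.514444  # 1 knot in m/s

#: default percentile probabilities for the height-percentile features
DEFAULT_PERCENTILES: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)

POINT_COLUMNS = ("x", "y", "z", "pulse", "class")

_FIRST_POOL = ("first", "single")
_LAST_POOL = ("last", "single")


# ---------------------------------------------------------------------------
# survey geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanConfig:
    """Airborne survey parameters of a discrete-return scanner.

    Defaults reproduce a helicopter-borne Leica ALS50-II campaign flown
    at 2200 m above ground.
    """

    altitude_agl: float = 2200.0   # m above ground level
    speed_knots: float = 80.0      # ground speed
    pulse_rate: float = 52_900.0   # Hz
    scan_rate: float = 20.4        # scan lines per second
    half_angle_deg: float = 20.0   # scanning field-of-view half angle

    def __post_init__(self) -> None:
        for name in ("altitude_agl", "speed_knots", "pulse_rate", "scan_rate",
                     "half_angle_deg"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"ScanConfig.{name} must be positive")
        if self.half_angle_deg >= 90:
            raise ConfigError("scan half angle must be below 90 degrees")

    @property
    def speed_ms(self) -> float:
        return self.speed_knots * KNOT_MS


@dataclass(frozen=True)
class SurveyGeometry:
    """Derived scan geometry: swath width, pulse spacing and density."""

    swath_width: float          # m
    along_track_spacing: float  # m between successive scan lines
    pulse_density: float        # emitted pulses per m^2 at ground level

    def to_dict(self) -> dict:
        return {
            "swath_width_m": self.swath_width,
            "along_track_spacing_m": self.along_track_spacing,
            "pulse_density_per_m2": self.pulse_density,
        }


def survey_geometry(scan: ScanConfig) -> SurveyGeometry:
    """Compute swath width, along-track spacing and areal pulse density.

    swath = 2 * altitude * tan(half angle); along-track spacing is ground
    speed over scan rate; density is pulse rate over (speed * swath).
    """
    v = scan.speed_ms
    swath = 2.0 * scan.altitude_agl * math.tan(math.radians(scan.half_angle_deg))
    along = v / scan.scan_rate
    density = scan.pulse_rate / (v * swath)
    return SurveyGeometry(swath_width=swath, along_track_spacing=along,
                          pulse_density=density)


# ---------------------------------------------------------------------------
# DTM
# ---------------------------------------------------------------------------

@dataclass
class DTMGrid:
    """A regular bare-earth elevation raster.

    ``values[i, j]`` is the elevation of the cell whose center is at
    ``(origin_x + (j + 0.5) * cell_size, origin_y + (i + 0.5) * cell_size)``.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray  # shape (ny, nx)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigError("DTM cell size must be positive")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.values.shape
        return (self.origin_x, self.origin_y,
                self.origin_x + nx * self.cell_size,
                self.origin_y + ny * self.cell_size)

    def _interpolator(self) -> RegularGridInterpolator:
        ny, nx = self.values.shape
        ys = self.origin_y + (np.arange(ny) + 0.5) * self.cell_size
        xs = self.origin_x + (np.arange(nx) + 0.5) * self.cell_size
        return RegularGridInterpolator((ys, xs), self.values, method="linear",
                                       bounds_error=False, fill_value=None)

    def elevation(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear terrain elevation at arbitrary in-extent coordinates.

        Coordinates in the half-cell margin outside the outermost cell
        centers are clamped (constant extrapolation to the raster edge).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0, x1, y1 = self.extent
        outside = (x < x0) | (x > x1) | (y < y0) | (y > y1)
        if np.any(outside):
            idx = np.flatnonzero(outside)[:10]
            raise ConfigError(
                f"{int(outside.sum())} points fall outside the DTM extent "
                f"{self.extent}; first offending indices: {idx.tolist()}")
        ny, nx = self.values.shape
        half = 0.5 * self.cell_size
        xc = np.clip(x, x0 + half, x1 - half)
        yc = np.clip(y, y0 + half, y1 - half)
        interp = self._interpolator()
        return interp(np.column_stack([np.atleast_1d(yc), np.atleast_1d(xc)]))


def build_dtm(cloud: pd.DataFrame, cell_size: float = 1.0,
              bounds: tuple[float, float, float, float] | None = None) -> DTMGrid:
    """Rasterize ground-classified returns into a DTM.

    Each cell takes the mean elevation of the ground returns it contains;
    cells with no ground return are filled from their nearest populated
    neighbour (Euclidean distance transform).

    Parameters
    ----------
    cloud:
        Point table with at least ``x, y, z, class`` columns.
    cell_size:
        Raster resolution in meters (default 1 m).
    bounds:
        Optional ``(x0, y0, x1, y1)``; defaults to the ground-return bounding
        box.
    """
    if cell_size <= 0:
        raise ConfigError("cell_size must be positive")
    ground = cloud[cloud["class"] == "ground"]
    if len(ground) < 3:
        raise ConfigError("need at least 3 ground returns to build a DTM")
    x = ground["x"].to_numpy(float)
    y = ground["y"].to_numpy(float)
    z = ground["z"].to_numpy(float)
    if bounds is None:
        bounds = (x.min(), y.min(), x.max(), y.max())
    x0, y0, x1, y1 = bounds
    nx = max(1, int(math.ceil((x1 - x0) / cell_size)))
    ny = max(1, int(math.ceil((y1 - y0) / cell_size)))
    stat, _, _, _ = binned_statistic_2d(
        y, x, z, statistic="mean",
        bins=(ny, nx), range=[[y0, y0 + ny * cell_size], [x0, x0 + nx * cell_size]])
    missing = np.isnan(stat)
    if missing.all():
        raise ConfigError("no ground returns fall inside the requested bounds")
    if missing.any():
        # nearest-neighbour fill of empty cells
        _, (iy, ix) = ndimage.distance_transform_edt(missing, return_indices=True)
        stat = stat[iy, ix]
    return DTMGrid(origin_x=x0, origin_y=y0, cell_size=cell_size, values=stat)


def normalize_heights(cloud: pd.DataFrame, dtm: DTMGrid) -> pd.DataFrame:
    """Convert absolute elevations to heights above ground.

    Returns a copy of ``cloud`` whose ``z`` column holds
    ``z - dtm(x, y)`` (bilinear interpolation); all other columns,
    including the classification, are preserved.  Points outside the DTM
    extent raise :class:`ConfigError` listing the offenders.
    """
    out = cloud.copy()
    if len(out) == 0:
        return out
    ground_z = dtm.elevation(out["x"].to_numpy(float), out["y"].to_numpy(float))
    out["z"] = out["z"].to_numpy(float) - ground_z
    return out


# ---------------------------------------------------------------------------
# plot clipping and features
# ---------------------------------------------------------------------------

def clip_circle(cloud: pd.DataFrame, center: tuple[float, float],
                radius: float) -> pd.DataFrame:
    """Return the sub-cloud within horizontal distance ``radius`` of ``center``.

    The boundary is inclusive: a point at exactly ``radius`` is retained.
    """
    if radius < 0:
        raise ConfigError("radius must be non-negative")
    dx = cloud["x"].to_numpy(float) - center[0]
    dy = cloud["y"].to_numpy(float) - center[1]
    keep = dx * dx + dy * dy <= radius * radius
    return cloud.loc[keep]


def _pool(cloud: pd.DataFrame, kinds: tuple[str, ...]) -> np.ndarray:
    sel = cloud["pulse"].isin(kinds) & (cloud["class"] != "error")
    return cloud.loc[sel, "z"].to_numpy(float)


def canopy_cover(cloud: pd.DataFrame) -> float:
    """Fraction of non-error returns classified as vegetation."""
    ok = cloud[cloud["class"] != "error"]
    if len(ok) == 0:
        raise EmptyPlotError("cannot compute canopy cover of an empty plot")
    return float((ok["class"] == "vegetation").mean())


def extract_features(cloud: pd.DataFrame,
                     percentiles: Sequence[int] = DEFAULT_PERCENTILES,
                     high_threshold: float = 5.0,
                     low_threshold: float = 1.0) -> dict[str, float]:
    """Compute the plot-level predictor vector from a normalized sub-cloud.

    Heights must already be normalized to above-ground.  Percentiles are
    taken over all non-error returns of the pulse type (ground-height
    returns included; the below-1-m ratios carry the ground fraction).
    ``mean_high_first`` averages first-pulse heights strictly above 5 m and
    is 0 when no return clears the threshold.  Thresholds are strict on
    both sides (> 5 m, < 1 m).

    Raises :class:`EmptyPlotError` when either pulse pool is empty so that
    callers must flag the plot rather than receive silent zeros.
    """
    first = _pool(cloud, _FIRST_POOL)
    last = _pool(cloud, _LAST_POOL)
    if first.size == 0 or last.size == 0:
        raise EmptyPlotError("plot footprint has no usable returns")
    feats: dict[str, float] = {}
    fp = np.percentile(first, percentiles)
    lp = np.percentile(last, percentiles)
    for p, v in zip(percentiles, fp):
        feats[f"h{p:02d}_first"] = float(v)
    for p, v in zip(percentiles, lp):
        feats[f"h{p:02d}_last"] = float(v)
    high = first[first > high_threshold]
    feats["mean_high_first"] = float(high.mean()) if high.size else 0.0
    feats["std_first"] = float(first.std())
    feats["ratio_below1_first"] = float((first < low_threshold).mean())
    feats["ratio_below1_last"] = float((last < low_threshold).mean())
    feats["canopy_cover"] = canopy_cover(cloud)
    return feats


def feature_names(percentiles: Sequence[int] = DEFAULT_PERCENTILES) -> list[str]:
    """Stable column order of the predictor vector."""
    names = [f"h{p:02d}_first" for p in percentiles]
    names += [f"h{p:02d}_last" for p in percentiles]
    names += ["mean_high_first", "std_first",
              "ratio_below1_first", "ratio_below1_last", "canopy_cover"]
    return names


def plot_feature_table(cloud: pd.DataFrame, plots: pd.DataFrame,
                       percentiles: Sequence[int] = DEFAULT_PERCENTILES,
                       ) -> tuple[pd.DataFrame, list]:
    """Clip every plot footprint and extract its feature vector.

    ``plots`` needs ``plot_id, x, y, radius`` columns.  Returns the feature
    table (one row per plot with usable returns) and the list of plot ids
    that had to be skipped because their footprint was empty.
    """
    rows, skipped = [], []
    for rec in plots.itertuples(index=False):
        sub = clip_circle(cloud, (rec.x, rec.y), rec.radius)
        try:
            feats = extract_features(sub, percentiles=percentiles)
        except EmptyPlotError:
            skipped.append(rec.plot_id)
            continue
        feats["plot_id"] = rec.plot_id
        rows.append(feats)
    table = pd.DataFrame(rows)
    if len(table):
        table = table[["plot_id", *feature_names(percentiles)]]
    return table, skipped


# ---------------------------------------------------------------------------
# overlap removal
# ---------------------------------------------------------------------------

def decimate_overlap(cloud: pd.DataFrame, target_density: float,
                     cell_size: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Thin a point cloud to a uniform target density.

    Flight-line overlap leaves stripes of doubled density; area-based
    predictors assume uniform sampling noise, so each ``cell_size`` grid
    cell is randomly subsampled down to ``target_density * cell_size**2``
    points.  Cells already at or below the target are untouched.
    Deterministic given ``seed``.
    """
    if target_density <= 0:
        raise ConfigError("target_density must be positive")
    if len(cloud) == 0:
        return cloud.copy()
    rng = np.random.default_rng(seed)
    max_per_cell = max(1, int(math.floor(target_density * cell_size ** 2 + 1e-9)))
    ix = np.floor(cloud["x"].to_numpy(float) / cell_size).astype(np.int64)
    iy = np.floor(cloud["y"].to_numpy(float) / cell_size).astype(np.int64)
    key = ix * (iy.max() - iy.min() + 1 if len(iy) else 1) + (iy - (iy.min() if len(iy) else 0))
    order = np.argsort(key, kind="stable")
    keep = np.ones(len(cloud), dtype=bool)
    sorted_key = key[order]
    boundaries = np.flatnonzero(np.diff(sorted_key)) + 1
    groups = np.split(order, boundaries)
    for grp in groups:
        if grp.size > max_per_cell:
            drop = rng.choice(grp, size=grp.size - max_per_cell, replace=False)
            keep[drop] = False
    return cloud.loc[keep]
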