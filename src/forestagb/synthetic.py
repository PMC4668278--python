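"""Synthetic forest scenes, discrete-return point clouds and plot samples.

No public forest-inventory + LiDAR data set covers the study conditions
this package targets, so everything downstream is exercised on synthetic
data generated here.  Two levels of realism are provided:

* a **scene simulator**: Poisson-distributed trees with lognormal heights
  on a spatially correlated terrain, scanned by a gridded-pulse
  discrete-return model that emits classified first/last returns at the
  areal density implied by the survey geometry; and
* a fast **metric-table generator** that bypasses point clouds and draws
  (predictor vector, AGB) pairs directly from a latent-variable model
  calibrated to a :class:`~forestagb.presets.RegimePreset`.

Both are pure functions of ``(config, seed)``.

Plot sampling mirrors the two field designs compared by the validation
harness: simple random circular plots of 8.92 m radius (community crews)
and systematic clusters of eight 12.62 m plots on a 2 x 4 grid with
300 m spacing (professional crews).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.stats import norm

from .errors import ConfigError
from .features import DTMGrid, ScanConfig, survey_geometry, feature_names, \
    DEFAULT_PERCENTILES
from .presets import RegimePreset

COMMUNITY_RADIUS = 8.92      # m
PROFESSIONAL_RADIUS = 12.62  # m
CLUSTER_SPACING = 300.0      # m between plots, both directions
CLUSTER_SHAPE = (2, 4)       # columns (E-W) x rows (N-S)
AGB_TRUNCATION = 1500.0      # Mg/ha, upper truncation of clean presets


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic forest stand.

    Tree heights are lognormal (``height_mean_log``/``height_sd_log`` are
    the log-scale mean and SD in log-meters); DBH follows the power law
    ``dbh = a * height**b`` (cm from m); crown radius is a fixed fraction
    of height.  Terrain is a smooth Gaussian random field with the given
    relief SD and correlation length.
    """

    extent_x: float = 200.0           # m
    extent_y: float = 200.0           # m
    stem_density: float = 400.0       # trees per hectare
    height_mean_log: float = 2.55     # log m  (median height ~12.8 m)
    height_sd_log: float = 0.35
    dbh_a: float = 1.0                # dbh = a * h**b, cm
    dbh_b: float = 1.15
    crown_ratio: float = 0.18         # crown radius per unit height
    terrain_relief_sd: float = 5.0    # m
    terrain_correlation: float = 60.0  # m
    terrain_cell: float = 5.0         # m, terrain raster resolution

    def __post_init__(self) -> None:
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ConfigError("scene extents must be positive")
        if self.stem_density < 0:
            raise ConfigError("stem_density must be non-negative")
        if not 0 < self.crown_ratio <= 1:
            raise ConfigError("crown_ratio must be in (0, 1]")
        if self.terrain_relief_sd < 0:
            raise ConfigError("terrain_relief_sd must be non-negative")


@dataclass
class Scene:
    """A realized stand: tree table, terrain raster and extent."""

    trees: pd.DataFrame           # x, y, height, dbh, crown_radius
    terrain: DTMGrid
    extent: tuple[float, float]   # (extent_x, extent_y)


def _correlated_field(ny: int, nx: int, cell: float, correlation: float,
                      sd: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean Gaussian field with unit-free empirical SD ``sd``."""
    white = rng.standard_normal((ny, nx))
    sigma = max(correlation / cell, 1e-9)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    s = smooth.std()
    if s < 1e-12 or sd == 0:
        return np.zeros((ny, nx))
    return smooth * (sd / s)


def make_terrain(config: SceneConfig, seed: int) -> DTMGrid:
    cell = config.terrain_cell
    nx = max(2, int(math.ceil(config.extent_x / cell)))
    ny = max(2, int(math.ceil(config.extent_y / cell)))
    rng = np.random.default_rng(seed)
    values = 1000.0 + _correlated_field(ny, nx, cell, config.terrain_correlation,
                                        config.terrain_relief_sd, rng)
    return DTMGrid(origin_x=0.0, origin_y=0.0, cell_size=cell, values=values)


def make_scene(config: SceneConfig, seed: int) -> Scene:
    """Draw a stand: tree count ~ Poisson(density x area), uniform positions,
    lognormal heights, allometric DBH and crowns; deterministic per seed."""
    rng = np.random.default_rng(seed)
    area_ha = config.extent_x * config.extent_y / 10_000.0
    n = int(rng.poisson(config.stem_density * area_ha))
    height = rng.lognormal(config.height_mean_log, config.height_sd_log, size=n)
    trees = pd.DataFrame({
        "x": rng.uniform(0.0, config.extent_x, size=n),
        "y": rng.uniform(0.0, config.extent_y, size=n),
        "height": height,
        "dbh": config.dbh_a * height ** config.dbh_b,
        "crown_radius": config.crown_ratio * height,
    })
    terrain = make_terrain(config, seed=int(rng.integers(2 ** 31)))
    return Scene(trees=trees, terrain=terrain,
                 extent=(config.extent_x, config.extent_y))


# ---------------------------------------------------------------------------
# point-cloud simulation
# ---------------------------------------------------------------------------

def simulate_point_cloud(scene: Scene, scan: ScanConfig | None = None,
                         seed: int = 0, *,
                         canopy_noise_sd: float = 0.3,
                         ground_noise_sd: float = 0.05,
                         ground_penetration: float = 0.5,
                         error_rate: float = 0.002) -> pd.DataFrame:
    """Scan a scene with a gridded-pulse discrete-return model.

    Pulses are laid on a jittered grid whose along-track spacing is
    ground speed / scan rate and whose areal density matches the survey
    geometry (pulse rate / (speed x swath)).  A pulse over one or more
    crowns returns a first echo near the crown surface (vertical noise
    ``canopy_noise_sd``) and a last echo that reaches the ground with
    probability ``ground_penetration`` or stops inside the canopy
    otherwise.  Pulses over open ground produce a single return tagged
    ``pulse="single"`` (it belongs to both the first- and last-pulse
    pools).  A small fraction ``error_rate`` of spurious returns is added
    with class ``error``.  ``z`` is absolute elevation (terrain + object).
    """
    if scan is None:
        scan = ScanConfig()
    rng = np.random.default_rng(seed)
    geom = survey_geometry(scan)
    ex, ey = scene.extent
    ay = geom.along_track_spacing
    ax = 1.0 / (geom.pulse_density * ay)
    xs = np.arange(0.5 * ax, ex, ax)
    ys = np.arange(0.5 * ay, ey, ay)
    px, py = np.meshgrid(xs, ys)
    px = px.ravel() + rng.uniform(-0.5 * ax, 0.5 * ax, px.size)
    py = py.ravel() + rng.uniform(-0.5 * ay, 0.5 * ay, py.size)
    px = np.clip(px, 0.0, ex)
    py = np.clip(py, 0.0, ey)
    terrain_z = scene.terrain.elevation(px, py)

    trees = scene.trees
    crown_height = np.zeros(px.size)  # canopy surface height above ground
    if len(trees):
        max_crown = float(trees["crown_radius"].max())
        tree_xy = trees[["x", "y"]].to_numpy(float)
        tree_h = trees["height"].to_numpy(float)
        tree_cr = trees["crown_radius"].to_numpy(float)
        tree_tree = cKDTree(tree_xy)
        k = min(4, len(trees))
        dist, idx = tree_tree.query(np.column_stack([px, py]), k=k,
                                    distance_upper_bound=max_crown)
        dist = np.atleast_2d(dist.T).T if k == 1 else dist
        idx = np.atleast_2d(idx.T).T if k == 1 else idx
        for j in range(k):
            d = dist[:, j]
            i = idx[:, j]
            valid = np.isfinite(d) & (i < len(trees))
            if not valid.any():
                continue
            iv = i[valid]
            within = d[valid] <= tree_cr[iv]
            # paraboloid crown: height at center, half height at crown edge
            surf = tree_h[iv] * (1.0 - 0.5 * (d[valid] / np.maximum(tree_cr[iv], 1e-9)) ** 2)
            surf = np.where(within, surf, 0.0)
            sel = np.flatnonzero(valid)
            crown_height[sel] = np.maximum(crown_height[sel], surf)

    hit = crown_height > 0.0
    rows_x, rows_y, rows_z, rows_pulse, rows_class = [], [], [], [], []

    # open-ground pulses: one return, ground class
    gx, gy, gz = px[~hit], py[~hit], terrain_z[~hit]
    rows_x.append(gx)
    rows_y.append(gy)
    rows_z.append(gz + rng.normal(0.0, ground_noise_sd, gx.size))
    rows_pulse.append(np.full(gx.size, "single"))
    rows_class.append(np.full(gx.size, "ground"))

    # canopy pulses: first return at crown surface
    cx, cy = px[hit], py[hit]
    ct, ch = terrain_z[hit], crown_height[hit]
    rows_x.append(cx)
    rows_y.append(cy)
    rows_z.append(ct + ch + rng.normal(0.0, canopy_noise_sd, cx.size))
    rows_pulse.append(np.full(cx.size, "first"))
    rows_class.append(np.full(cx.size, "vegetation"))

    # ... and a last return: ground or mid-canopy
    to_ground = rng.random(cx.size) < ground_penetration
    last_h = np.where(to_ground,
                      rng.normal(0.0, ground_noise_sd, cx.size),
                      rng.uniform(0.3, np.maximum(ch, 0.31)))
    rows_x.append(cx)
    rows_y.append(cy)
    rows_z.append(ct + last_h)
    rows_pulse.append(np.full(cx.size, "last"))
    rows_class.append(np.where(to_ground, "ground", "vegetation"))

    # spurious returns
    n_err = int(rng.binomial(px.size, error_rate))
    if n_err:
        exr = rng.uniform(0.0, ex, n_err)
        eyr = rng.uniform(0.0, ey, n_err)
        ezr = scene.terrain.elevation(exr, eyr) + rng.uniform(-80.0, 300.0, n_err)
        rows_x.append(exr)
        rows_y.append(eyr)
        rows_z.append(ezr)
        rows_pulse.append(np.full(n_err, "single"))
        rows_class.append(np.full(n_err, "error"))

    return pd.DataFrame({
        "x": np.concatenate(rows_x),
        "y": np.concatenate(rows_y),
        "z": np.concatenate(rows_z),
        "pulse": np.concatenate(rows_pulse),
        "class": np.concatenate(rows_class),
    })


def inject_dtm_error(dtm: DTMGrid, error_sd: float, correlation_length: float,
                     seed: int = 0) -> DTMGrid:
    """Add spatially correlated elevation error to a terrain raster.

    Emulates the height-normalization error that steep terrain under dense
    canopy induces: the DTM drifts smoothly away from the true ground, so
    plot-level height features acquire a shared, spatially coherent bias.
    ``error_sd = 0`` returns the input unchanged; otherwise the injected
    field has empirical SD equal to ``error_sd``.  The unit error field
    depends only on ``(seed, correlation_length, grid shape)``, so scaling
    ``error_sd`` with everything else fixed scales the same field.
    """
    if error_sd < 0:
        raise ConfigError("error_sd must be non-negative")
    if error_sd == 0:
        return dtm
    rng = np.random.default_rng(seed)
    ny, nx = dtm.values.shape
    field = _correlated_field(ny, nx, dtm.cell_size, correlation_length,
                              error_sd, rng)
    return DTMGrid(origin_x=dtm.origin_x, origin_y=dtm.origin_y,
                   cell_size=dtm.cell_size, values=dtm.values + field)


# ---------------------------------------------------------------------------
# plot sampling designs
# ---------------------------------------------------------------------------

def sample_plots_community(extent: tuple[float, float], n: int, seed: int = 0,
                           radius: float = COMMUNITY_RADIUS) -> pd.DataFrame:
    """Simple random sample of fixed-radius circular plots.

    Centers are i.i.d. uniform over the extent eroded by one plot radius,
    so every footprint lies fully inside the scene.
    """
    ex, ey = extent
    if n < 0:
        raise ConfigError("n must be non-negative")
    if ex < 2 * radius or ey < 2 * radius:
        raise ConfigError("extent smaller than one plot diameter")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "plot_id": [f"C{i:04d}" for i in range(n)],
        "x": rng.uniform(radius, ex - radius, size=n),
        "y": rng.uniform(radius, ey - radius, size=n),
        "radius": radius,
        "team": "Comm",
    })


def sample_plots_professional(extent: tuple[float, float], n_clusters: int,
                              seed: int = 0,
                              radius: float = PROFESSIONAL_RADIUS,
                              spacing: float = CLUSTER_SPACING) -> pd.DataFrame:
    """Systematic clustered sample: 2 x 4 plots per cluster, 300 m apart.

    Each cluster has a random origin; its plots sit on two North-South
    columns of four, with ``spacing`` between plots in both directions.
    Plots whose footprint falls outside the scene are dropped, mirroring
    field campaigns where cluster plots land outside the area of interest.
    """
    ex, ey = extent
    ncol, nrow = CLUSTER_SHAPE
    foot_x = (ncol - 1) * spacing + 2 * radius
    foot_y = (nrow - 1) * spacing + 2 * radius
    if n_clusters < 0:
        raise ConfigError("n_clusters must be non-negative")
    if ex < foot_x or ey < foot_y:
        raise ConfigError(
            f"extent {extent} cannot accommodate the {foot_x:.0f} x "
            f"{foot_y:.0f} m cluster footprint")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        ox = rng.uniform(0.0, ex)
        oy = rng.uniform(0.0, ey)
        k = 0
        for i in range(ncol):
            for j in range(nrow):
                x = ox + i * spacing
                y = oy + j * spacing
                k += 1
                if radius <= x <= ex - radius and radius <= y <= ey - radius:
                    rows.append({"plot_id": f"P{c:03d}_{k}", "x": x, "y": y,
                                 "radius": radius, "team": "Prof",
                                 "cluster": c})
    return pd.DataFrame(rows, columns=["plot_id", "x", "y", "radius", "team",
                                       "cluster"])


# ---------------------------------------------------------------------------
# fast metric-table generator
# ---------------------------------------------------------------------------

def _truncated_latent_calibration(preset: RegimePreset,
                                  truncation: float = AGB_TRUNCATION) -> dict:
    """Solve the latent-lognormal parameters hitting a preset's targets.

    AGB is ``exp(mu + sigma * Z)`` with ``Z`` standard normal truncated
    above at ``z0 = (log(truncation) - mu) / sigma``; ``sigma`` comes from
    the target CV, and ``mu`` is solved so the truncated mean equals the
    target mean.  The example predictor is ``Z`` plus independent noise
    whose variance is solved in closed form (partial moments of the
    truncated normal) so the population predictor-AGB correlation equals
    ``target_r``.
    """
    sigma = math.sqrt(math.log(1.0 + preset.agb_cv ** 2))
    logk = math.log(truncation)

    def trunc_mean(mu: float) -> float:
        z0 = (logk - mu) / sigma
        return math.exp(mu + 0.5 * sigma ** 2) * norm.cdf(z0 - sigma) / norm.cdf(z0)

    mu_guess = math.log(preset.agb_mean) - 0.5 * sigma ** 2
    mu = brentq(lambda m: trunc_mean(m) - preset.agb_mean,
                mu_guess - 2.0, min(mu_guess + 2.0, logk - 1e-6))
    z0 = (logk - mu) / sigma
    phi0 = norm.cdf(z0)
    lam = norm.pdf(z0) / phi0
    ez = -lam
    varz = 1.0 - z0 * lam - lam ** 2
    ea = trunc_mean(mu)
    # E[Z exp(sigma Z) | Z <= z0] * exp(mu)
    eza = math.exp(mu + 0.5 * sigma ** 2) * (
        sigma * norm.cdf(z0 - sigma) - norm.pdf(z0 - sigma)) / phi0
    ea2 = math.exp(2 * mu + 2 * sigma ** 2) * norm.cdf(z0 - 2 * sigma) / phi0
    cov_za = eza - ez * ea
    var_a = ea2 - ea ** 2
    r0 = cov_za / math.sqrt(varz * var_a)
    if preset.target_r >= r0:
        raise ConfigError(
            f"target_r={preset.target_r} unreachable: the latent-lognormal "
            f"construction caps the predictor-AGB correlation at {r0:.3f} "
            f"for CV={preset.agb_cv}")
    noise_var = varz * (r0 ** 2 / preset.target_r ** 2 - 1.0)
    return {"mu": mu, "sigma": sigma, "z0": z0, "ez": ez, "varz": varz,
            "r0": r0, "noise_var": noise_var}


def _truncated_normal(rng: np.random.Generator, n: int, z0: float) -> np.ndarray:
    """Standard normal truncated above at z0, by redraw."""
    z = rng.standard_normal(n)
    bad = z > z0
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = z > z0
    return z


def make_metric_table(preset: RegimePreset, n: int, seed: int = 0, *,
                      contamination: float = 0.0,
                      percentiles=DEFAULT_PERCENTILES) -> pd.DataFrame:
    """Draw (predictor vector, AGB) plot records directly from a regime.

    A latent standardized predictor ``x`` carries all the information the
    LiDAR features hold about AGB: ``corr(x, AGB)`` equals the preset's
    ``target_r`` in population, and every feature column is a smooth
    function of ``x`` plus correlated noise, so a linear model on the
    feature set cannot beat the calibrated correlation.  The preset's
    ``predictor_shift`` is added to ``x`` before the features are built:
    the whole feature vector shifts coherently, emulating a
    design-dependent height-normalization offset the model cannot see.

    ``contamination`` optionally replaces that fraction of AGB values with
    implausible 1600-3600 Mg/ha outliers to exercise the outlier filter.

    Returns a DataFrame with ``plot_id``, ``agb`` and the standard feature
    columns; sample mean AGB and predictor-AGB correlation converge to the
    preset targets as ``n`` grows.
    """
    if n < 2:
        raise ConfigError("n must be at least 2")
    if not 0.0 <= contamination < 1.0:
        raise ConfigError("contamination must be in [0, 1)")
    cal = _truncated_latent_calibration(preset)
    rng = np.random.default_rng(seed)
    z = _truncated_normal(rng, n, cal["z0"])
    agb = np.exp(cal["mu"] + cal["sigma"] * z)
    eps = rng.normal(0.0, math.sqrt(cal["noise_var"]), size=n)
    x = (z - cal["ez"] + eps) / math.sqrt(cal["varz"] + cal["noise_var"])
    xs = x + preset.predictor_shift

    eta = rng.standard_normal(n)  # shared structural noise across features
    feats: dict[str, np.ndarray] = {}
    # canopy height scale driving the height features
    h_scale = 16.0 * np.exp(0.30 * (0.85 * xs + 0.53 * eta))
    q = np.linspace(0.15, 1.0, len(percentiles))
    gaps = np.diff(np.concatenate([[0.0], q]))
    inc_f = gaps[None, :] * np.exp(0.25 * rng.standard_normal((n, len(q))))
    inc_l = gaps[None, :] * np.exp(0.25 * rng.standard_normal((n, len(q))))
    cum_f = np.cumsum(inc_f, axis=1) * h_scale[:, None]
    cum_l = 0.6 * np.cumsum(inc_l, axis=1) * h_scale[:, None]
    for i, p in enumerate(percentiles):
        feats[f"h{p:02d}_first"] = cum_f[:, i]
        feats[f"h{p:02d}_last"] = cum_l[:, i]
    feats["mean_high_first"] = 12.0 + 4.0 * xs  # the designated example predictor
    feats["std_first"] = 0.22 * h_scale * np.exp(0.2 * rng.standard_normal(n))

    def _sigmoid(v):
        return 1.0 / (1.0 + np.exp(-v))

    drive = 0.8 * xs + 0.6 * eta
    feats["ratio_below1_first"] = _sigmoid(-1.2 - 0.9 * drive
                                           + 0.5 * rng.standard_normal(n))
    feats["ratio_below1_last"] = _sigmoid(-0.4 - 0.9 * drive
                                          + 0.5 * rng.standard_normal(n))
    feats["canopy_cover"] = _sigmoid(1.6 + 1.0 * (0.7 * xs + 0.7 * eta)
                                     + 0.4 * rng.standard_normal(n))

    if contamination > 0:
        n_bad = int(round(contamination * n))
        if n_bad:
            idx = rng.choice(n, size=n_bad, replace=False)
            agb[idx] = rng.uniform(1600.0, 3600.0, size=n_bad)

    table = pd.DataFrame({"plot_id": [f"{preset.name}_{i:05d}" for i in range(n)],
                          "agb": agb})
    for name in feature_names(percentiles):
        table[name] = feats[name]
    return table
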