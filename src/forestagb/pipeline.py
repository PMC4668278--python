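"""End-to-end scene pipeline: scenes -> point clouds -> plot features.

The metric-table generator (:func:`forestagb.synthetic.make_metric_table`)
is the fast path for model and harness experiments; this module runs the
full physical chain instead -- simulate a stand, scan it, build a DTM
from the ground returns, optionally perturb that DTM with spatially
correlated error, normalize heights and extract plot features -- so that
the degradation mechanism (terrain-model error eroding the predictor-AGB
correlation) can be demonstrated on the same machinery a real survey
would use.

Plots are generated as independent tiles (one stand per plot) rather
than one monolithic scene: plot footprints in either field design are
far apart relative to the terrain correlation length, so tile
independence loses nothing while keeping the simulation linear in the
number of plots.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import field as fieldmod
from .errors import EmptyPlotError
from .features import ScanConfig, build_dtm, clip_circle, extract_features, \
    normalize_heights, feature_names
from .synthetic import Scene, SceneConfig, inject_dtm_error, make_scene, \
    simulate_point_cloud

TILE_MARGIN = 7.0  # m of stand kept around the plot footprint


def simulate_plot_tile(scene_config: SceneConfig, radius: float, seed: int, *,
                       scan: ScanConfig | None = None,
                       dtm_error_sd: float = 0.0,
                       dtm_error_correlation: float = 30.0,
                       dtm_cell: float = 2.0,
                       allometry: tuple[float, float] = fieldmod.DEFAULT_ALLOMETRY,
                       ) -> dict[str, float]:
    """Simulate one plot: returns its feature dict plus the true AGB.

    The tile extent is the plot footprint plus a margin; true AGB comes
    from the allometric biomass of the trees rooted inside the footprint.
    ``dtm_error_sd`` perturbs the DTM used for normalization (the true
    terrain still generates the returns), reproducing the normalization
    error of difficult sites.
    """
    side = 2 * (radius + TILE_MARGIN)
    cfg = replace(scene_config, extent_x=side, extent_y=side)
    rng = np.random.SeedSequence(seed)
    s_scene, s_cloud, s_err = (int(c.generate_state(1)[0] % 2 ** 31)
                               for c in rng.spawn(3))
    scene = make_scene(cfg, s_scene)
    cloud = simulate_point_cloud(scene, scan, s_cloud)
    dtm = build_dtm(cloud, cell_size=dtm_cell, bounds=(0.0, 0.0, side, side))
    if dtm_error_sd > 0:
        dtm = inject_dtm_error(dtm, dtm_error_sd, dtm_error_correlation, s_err)
    normalized = normalize_heights(cloud, dtm)
    center = (side / 2.0, side / 2.0)
    sub = clip_circle(normalized, center, radius)
    feats = extract_features(sub)

    trees = scene.trees
    dx = trees["x"].to_numpy(float) - center[0]
    dy = trees["y"].to_numpy(float) - center[1]
    inside = trees.loc[dx * dx + dy * dy <= radius * radius]
    feats["agb"] = fieldmod.plot_agb(inside, radius, allometry)
    return feats


def scene_plot_dataset(n_plots: int, seed: int = 0, *,
                       scene_config: SceneConfig | None = None,
                       radius: float = 12.62,
                       scan: ScanConfig | None = None,
                       dtm_error_sd: float = 0.0,
                       dtm_error_correlation: float = 30.0) -> pd.DataFrame:
    """Simulate ``n_plots`` independent plot tiles into a feature table."""
    if scene_config is None:
        scene_config = SceneConfig()
    children = np.random.SeedSequence(seed).spawn(n_plots)
    rows = []
    for i, child in enumerate(children):
        tile_seed = int(child.generate_state(1)[0] % 2 ** 31)
        try:
            feats = simulate_plot_tile(scene_config, radius, tile_seed,
                                       scan=scan, dtm_error_sd=dtm_error_sd,
                                       dtm_error_correlation=dtm_error_correlation)
        except EmptyPlotError:
            continue
        feats["plot_id"] = f"S{i:05d}"
        rows.append(feats)
    table = pd.DataFrame(rows)
    return table[["plot_id", "agb", *feature_names()]]


def dtm_degradation_curve(error_sds, n_plots: int = 200, seed: int = 0, *,
                          scene_config: SceneConfig | None = None,
                          radius: float = 12.62,
                          predictor: str = "mean_high_first") -> pd.DataFrame:
    """Predictor-AGB correlation as a function of DTM error magnitude.

    Uses common random numbers: every error level re-normalizes the same
    simulated tiles against the same unit error field scaled to the
    requested SD, so the correlation decay is not confounded by
    between-level sampling noise.
    """
    if scene_config is None:
        scene_config = SceneConfig()
    children = np.random.SeedSequence(seed).spawn(n_plots)
    tiles = []
    for child in children:
        tile_seed = int(child.generate_state(1)[0] % 2 ** 31)
        tiles.append(tile_seed)
    rows = []
    for sd in error_sds:
        feats = []
        for i, tile_seed in enumerate(tiles):
            try:
                f = simulate_plot_tile(scene_config, radius, tile_seed,
                                       dtm_error_sd=float(sd))
            except EmptyPlotError:
                continue
            feats.append(f)
        df = pd.DataFrame(feats)
        r = float(np.corrcoef(df[predictor], df["agb"])[0, 1])
        rows.append({"dtm_error_sd": float(sd), "n_plots": len(df),
                     "correlation": r})
    return pd.DataFrame(rows)
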