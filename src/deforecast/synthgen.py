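"""Synthetic landscapes, censuses and deforestation histories.

Every downstream module is exercised on generated data with known
parameters: a spatially structured forest mask (thresholded smoothed
Gaussian noise, so fragmentation is tunable through the correlation
length), a Voronoi partition into administrative units, exponential
census trajectories with unit random effects, and land-cover series
whose clearing follows the same interval-corrected Bernoulli process
the models assume.  Truth records travel with each product so recovery
tests can compare posterior estimates against the generating values.

Default parameter values mirror the Madagascar study conditions:
30 m pixels, annual population growth 3.39%/yr, intensity coefficients
around beta0 = -5 (a ~1%/yr baseline clearing rate) with a positive
density effect beta1 = 0.02, and observation intervals of 4-6 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import landscape as ls
from .defor_model import DeforSampleSet, interval_prob
from .demography import CensusTable
from .geodata import Raster

__all__ = ["SynthConfig", "generate_landscape", "generate_census",
           "generate_history", "generate_defor_samples"]


@dataclass
class SynthConfig:
    """Generator settings; defaults give a desk-scale study landscape."""

    nrows: int = 200
    ncols: int = 200
    pixel_size: float = 30.0
    n_units: int = 50
    # demography truth
    rho: float = 0.0339           # annual growth rate, 1/yr
    alpha0: float = 10_000.0      # mean unit population at t=0 (1993)
    V: float = 10_000.0           # residual variance (counts^2)
    V_b: float = 1.0e6            # between-unit variance
    census_dates: tuple = (1993.0, 2006.0)
    # deforestation truth
    beta0: float = -5.0
    beta1: float = 0.02
    gamma: dict = field(default_factory=dict)  # location coefficients by name
    density_range: tuple = (0.0, 100.0)        # peop/km2 across units
    # landscape structure
    forest_frac_band: tuple = (0.4, 0.6)
    correlation_px: float = 6.0
    cloud_frac: float = 0.0
    piece_dates: dict = field(default_factory=lambda: {
        0: [2000.0, 2005.0, 2010.0],
        1: [2000.6, 2004.3, 2009.8],
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V <= 0 or self.V_b <= 0:
            raise ValueError("variances must be > 0")
        for j, dates in self.piece_dates.items():
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValueError(f"piece {j} dates must strictly increase")

    def template(self) -> Raster:
        return Raster(
            np.zeros((self.nrows, self.ncols)),
            transform=(0.0, self.nrows * self.pixel_size, self.pixel_size),
            semantics="class_code",
        )


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    field_ = gaussian_filter(rng.standard_normal(shape), sigma)
    return (field_ - field_.mean()) / max(field_.std(), 1e-12)


def generate_landscape(cfg: SynthConfig) -> dict:
    """Aligned covariate rasters plus the admin-unit partition.

    Returns a dict with ``forest`` (0/1), ``elevation_m``,
    ``dist_road_m``, ``dist_town_m``, ``protected``, ``unit_id`` rasters
    and a ``units`` table (unit_id, area_km2, density_peop_km2).  The
    forest fraction is drawn uniformly inside ``forest_frac_band`` and
    imposed exactly by quantile thresholding of the smoothed noise
    field, so fragmentation structure and cover are decoupled.
    """
    rng = np.random.default_rng(cfg.seed)
    tmpl = cfg.template()
    shape = (cfg.nrows, cfg.ncols)

    frac = rng.uniform(*cfg.forest_frac_band)
    noise = _smooth_field(rng, shape, cfg.correlation_px)
    forest = (noise > np.quantile(noise, 1.0 - frac)).astype(float)

    elev = 800.0 + 500.0 * _smooth_field(rng, shape, cfg.correlation_px * 2)
    elev -= elev.min()

    roads = np.zeros(shape)
    for _ in range(2):
        r0, r1 = rng.integers(0, cfg.nrows, 2)
        cols = np.arange(cfg.ncols)
        rows = np.clip(np.round(r0 + (r1 - r0) * cols / (cfg.ncols - 1)), 0,
                       cfg.nrows - 1).astype(int)
        roads[rows, cols] = 1.0
    towns = np.zeros(shape)
    t_idx = rng.choice(cfg.nrows * cfg.ncols, size=4, replace=False)
    towns.ravel()[t_idx] = 1.0

    protected = (_smooth_field(rng, shape, cfg.correlation_px * 2)
                 > 1.0).astype(float)

    # Voronoi partition into administrative units
    seeds_r = rng.uniform(0, cfg.nrows, cfg.n_units)
    seeds_c = rng.uniform(0, cfg.ncols, cfg.n_units)
    rr, cc = np.mgrid[0:cfg.nrows, 0:cfg.ncols]
    d2 = ((rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2)
    unit_id = d2.argmin(axis=2).astype(float) + 1.0

    px_km2 = (cfg.pixel_size / 1000.0) ** 2
    uids, counts = np.unique(unit_id, return_counts=True)
    units = pd.DataFrame({
        "unit_id": uids.astype(int),
        "area_km2": counts * px_km2,
        "density_peop_km2": rng.uniform(*cfg.density_range, size=len(uids)),
    })

    road_r = tmpl.like(roads, "class_code")
    town_r = tmpl.like(towns, "class_code")
    dens = np.zeros(shape)
    for _, row in units.iterrows():
        dens[unit_id == row["unit_id"]] = row["density_peop_km2"]
    return {
        "forest": tmpl.like(forest, "class_code"),
        "elevation_m": tmpl.like(elev, "distance_m"),
        "dist_road_m": ls.distance_to_target(road_r, 1),
        "dist_town_m": ls.distance_to_target(town_r, 1),
        "protected": tmpl.like(protected, "class_code"),
        "unit_id": tmpl.like(unit_id, "unit_id"),
        "density_peop_km2": tmpl.like(dens, "density_peop_km2"),
        "units": units,
    }


def generate_census(cfg: SynthConfig) -> tuple[CensusTable, dict]:
    """Census counts from the exponential growth model, with truth.

    P_k(t) = (alpha0 + b_k) exp(rho t) + Normal(0, V) at each date in
    ``census_dates``; b_k ~ Normal(0, V_b).  Counts are floored at 0.
    """
    if len(cfg.census_dates) < 2:
        raise ValueError("need >= 2 census dates")
    rng = np.random.default_rng(cfg.seed + 1)
    b = rng.normal(0.0, np.sqrt(cfg.V_b), cfg.n_units)
    areas = rng.uniform(10.0, 50.0, cfg.n_units)
    rows = []
    for k in range(cfg.n_units):
        for date in cfg.census_dates:
            t = date - 1993.0
            mean = (cfg.alpha0 + b[k]) * np.exp(cfg.rho * t)
            pop = max(mean + rng.normal(0.0, np.sqrt(cfg.V)), 0.0)
            rows.append({
                "unit_id": k + 1, "level": "firaisana", "parent_id": None,
                "date": date, "population": pop, "area_km2": areas[k],
            })
    truth = {"rho": cfg.rho, "alpha0": cfg.alpha0, "V": cfg.V,
             "V_b": cfg.V_b, "b": b.tolist()}
    return CensusTable(pd.DataFrame(rows)), truth


def generate_history(land: dict, cfg: SynthConfig) -> tuple[ls.LandCoverMap, dict]:
    """Three-date land-cover series under the true clearing process.

    Between consecutive observation ranks, each forest pixel clears
    with probability 1 - (1 - theta_i)^{Y_i}: theta_i is the annual
    rate expit(beta0 + beta1 D_i) modulated multiplicatively by the
    normalized location weight expit(x_i' gamma) (uniform when gamma is
    empty), and Y_i comes from the pixel's mosaic-piece dates.  With an
    empty gamma this is exactly the intensity model's data-generating
    process.  Optional cloud patches overwrite a configured fraction of
    pixels at the middle observation.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    tmpl = cfg.template()
    shape = (cfg.nrows, cfg.ncols)

    # vertical mosaic slabs, one per piece
    piece = np.zeros(shape)
    pieces = sorted(cfg.piece_dates)
    bounds = np.linspace(0, cfg.ncols, len(pieces) + 1).astype(int)
    for j, (lo, hi) in zip(pieces, zip(bounds[:-1], bounds[1:])):
        piece[:, lo:hi] = j
    piece_r = tmpl.like(piece, "class_code")

    dens = land["density_peop_km2"].values
    theta = expit(cfg.beta0 + cfg.beta1 * dens)

    forest = land["forest"].values == 1
    codes = [np.where(forest, ls.LC_FOREST, ls.LC_NONFOREST).astype(float)]
    realized = []
    state = forest.copy()
    for i0 in (0, 1):
        Y = np.zeros(shape)
        for j, dates in cfg.piece_dates.items():
            Y[piece == j] = dates[i0 + 1] - dates[i0]
        p = interval_prob(theta, Y)
        if cfg.gamma:
            stack = _history_stack(tmpl, land, state)
            w = _location_weight(stack, cfg.gamma)
            w = w / w[state].mean()
            p = np.clip(p * w, 0.0, 0.999999)
        clear = state & (rng.random(shape) < p)
        state = state & ~clear
        realized.append(int(clear.sum()))
        codes.append(np.where(state, ls.LC_FOREST,
                              ls.LC_NONFOREST).astype(float))

    if cfg.cloud_frac > 0:
        n_cloud = int(cfg.cloud_frac * cfg.nrows * cfg.ncols)
        idx = rng.choice(cfg.nrows * cfg.ncols, size=n_cloud, replace=False)
        codes[1].ravel()[idx] = ls.LC_CLOUD

    lcmap = ls.LandCoverMap(
        codes=[tmpl.like(c, "landcover") for c in codes],
        piece_id=piece_r,
        piece_dates=cfg.piece_dates,
    )
    truth = {"beta0": cfg.beta0, "beta1": cfg.beta1, "gamma": dict(cfg.gamma),
             "cleared_per_period": realized,
             "initial_forest_px": int(forest.sum())}
    return lcmap, truth


def _history_stack(tmpl: Raster, land: dict, state: np.ndarray) -> ls.CovariateStack:
    fmask = tmpl.like(state.astype(float), "class_code")
    cleared = tmpl.like(
        ((land["forest"].values == 1) & ~state).astype(float), "class_code"
    )
    from .forecast import distance_to_edge  # local: avoids module cycle
    rasters = {k: v for k, v in land.items()
               if k not in ("units", "forest", "unit_id")}
    rasters["dist_fedge_m"] = distance_to_edge(fmask)
    rasters["dist_dpatch_m"] = ls.distance_to_target(cleared, 1)
    rasters["frag_class"] = ls.fragmentation_classify(fmask)
    return ls.CovariateStack(rasters)


def _location_weight(stack: ls.CovariateStack, gamma: dict) -> np.ndarray:
    eta = np.zeros(stack.template.shape)
    for name, coef in gamma.items():
        if name == "intercept":
            eta += coef
        else:
            vals = stack[name].values
            eta += coef * np.where(stack[name].mask(), vals, 0.0)
    return expit(eta)


def generate_defor_samples(
    n: int,
    beta0: float,
    beta1: float,
    density_range: tuple = (0.0, 100.0),
    y_range: tuple = (4.0, 6.0),
    seed: int = 0,
) -> DeforSampleSet:
    """Tabular samples straight from the intensity model.

    D ~ Uniform(density_range), Y ~ Uniform(y_range),
    z ~ Bernoulli(1 - (1 - expit(beta0 + beta1 D))^Y).  The direct
    route for parameter-recovery experiments at a chosen n.
    """
    rng = np.random.default_rng(seed)
    D = rng.uniform(*density_range, size=n)
    Y = rng.uniform(*y_range, size=n)
    theta = expit(beta0 + beta1 * D)
    z = (rng.random(n) < interval_prob(theta, Y)).astype(int)
    df = pd.DataFrame({
        "pixel_id": np.arange(n), "z": z, "Y": Y, "density": D,
    })
    return DeforSampleSet(df, ["density"])
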