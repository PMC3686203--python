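"""Annual-step deforestation simulator.

Each simulated year couples two fitted sub-models:

* intensity — project unit populations forward at the demographic
  growth rate, spread them to a density map, average density over the
  still-forested project-site pixels, and convert it to the annual
  clearing rate theta0 = expit(beta0 + beta1 * D);
* location — recompute the dynamic landscape covariates (distance to
  forest edge, fragmentation class, distance to cleared patches) from
  the current forest state, evaluate the transition potential
  delta = expit(x' gamma) per forest pixel, and clear the n1 pixels
  with the highest delta, where n1 = floor(theta0 * F + carry) with the
  fractional remainder carried to the next year.

Everything else (elevation, roads, towns, protection) stays frozen.
Cleared pixels never revert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import landscape as ls
from .defor_model import LogisticFit
from .demography import density_raster, project_population
from .geodata import Raster, require_aligned

__all__ = [
    "ForecastResult",
    "intensity_step",
    "allocation_count",
    "location_probabilities",
    "simulate",
]


def _coefs(fit) -> np.ndarray:
    """Posterior-mean coefficients from a fit, or a plain vector."""
    if isinstance(fit, LogisticFit):
        return fit.posterior_mean()
    if isinstance(fit, tuple) and len(fit) == 2 and isinstance(fit[0], list):
        return np.asarray(fit[1], dtype=float)
    return np.asarray(fit, dtype=float)


def _names(fit, stack: ls.CovariateStack | None = None) -> list[str]:
    """Coefficient names for a fit: explicit for a LogisticFit or a
    (names, coefs) pair; otherwise intercept + stack order."""
    if isinstance(fit, LogisticFit):
        return fit.names
    if isinstance(fit, tuple) and len(fit) == 2 and isinstance(fit[0], list):
        return list(fit[0])
    if stack is None:
        raise ValueError("plain coefficient vectors need a covariate stack")
    names = ["intercept"] + list(stack.rasters)
    if len(names) != _coefs(fit).size:
        raise ValueError(
            "coefficient count does not match the stack; pass (names, coefs)"
        )
    return names


def intensity_step(intensity_fit, mean_density: float) -> float:
    """Annual clearing rate at the current mean population density.

    theta0 = expit(beta0 + beta1 * D) using posterior-mean
    coefficients (or any explicit (beta0, beta1) pair).
    """
    beta = _coefs(intensity_fit)
    if beta.size != 2:
        raise ValueError("intensity model must have exactly (beta0, beta1)")
    return float(expit(beta[0] + beta[1] * mean_density))


def allocation_count(
    theta0: float, forest_pixels: int, carry: float = 0.0
) -> tuple[int, float]:
    """Whole pixels to clear this year, carrying the fractional rest.

    raw = theta0 * F + carry; n1 = floor(raw); the remainder is
    returned for next year so that sub-pixel quantities are not lost to
    rounding.  n1 is capped at the available forest (with a warning).
    """
    if not 0.0 <= theta0 < 1.0:
        raise ValueError("theta0 must lie in [0, 1)")
    raw = theta0 * forest_pixels + carry
    n1 = int(np.floor(raw))
    new_carry = raw - n1
    if n1 > forest_pixels:
        warnings.warn("allocation exceeds remaining forest; capped", stacklevel=2)
        n1, new_carry = forest_pixels, 0.0
    return n1, new_carry


def _stack_design(
    stack: ls.CovariateStack, names: list[str], flat_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix rows for the given flat pixel indices.

    Returns (X, valid): rows of X follow the fit's coefficient order
    (intercept first, ``frag:<label>`` indicators read from the
    ``frag_class`` raster); ``valid`` flags pixels with no nodata
    covariate underneath.
    """
    frag_lookup = {f"frag:{lab}": code for code, lab in ls.FRAG_LABELS.items()}
    X = np.empty((flat_idx.size, len(names)))
    valid = np.ones(flat_idx.size, dtype=bool)
    for col, name in enumerate(names):
        if name == "intercept":
            X[:, col] = 1.0
            continue
        if name in frag_lookup:
            rast = stack["frag_class"]
            vals = rast.values.ravel()[flat_idx]
            X[:, col] = (vals == frag_lookup[name]).astype(float)
        else:
            rast = stack[name]
            X[:, col] = rast.values.ravel()[flat_idx]
        valid &= rast.mask().ravel()[flat_idx]
    return X, valid


def location_probabilities(
    location_fit, stack: ls.CovariateStack, forest_mask: Raster
) -> Raster:
    """Transition potential delta = expit(x' gamma) per forest pixel.

    Forest pixels with a nodata covariate are excluded (left nodata)
    and counted in a warning; non-forest pixels are nodata.
    """
    require_aligned(stack.template, forest_mask)
    gamma = _coefs(location_fit)
    names = _names(location_fit, stack)
    idx = np.flatnonzero(forest_mask.values == 1)
    X, valid = _stack_design(stack, names, idx)
    out = np.full(forest_mask.shape, forest_mask.nodata, dtype=float)
    if (~valid).any():
        warnings.warn(
            f"{int((~valid).sum())} forest pixels excluded (nodata covariates)",
            stacklevel=2,
        )
    out.ravel()[idx[valid]] = expit(X[valid] @ gamma)
    return forest_mask.like(out, "probability")


@dataclass
class ForecastResult:
    """Per-year series and the final year-of-deforestation map."""

    table: pd.DataFrame  # year, mean_density, theta0, n1, forest_px
    defor_year: Raster
    stopped_early: bool = False
    meta: dict = field(default_factory=dict)


def simulate(
    forest: Raster,
    deforested: Raster,
    project_mask: Raster,
    unit_raster: Raster,
    populations_ref: dict,
    areas_km2: dict,
    intensity_fit,
    location_fit,
    rho: float,
    s0: int,
    horizon: int,
    seed: int = 0,
    static_stack: ls.CovariateStack | None = None,
    frag_window: int = 7,
    use_carry: bool = True,
) -> ForecastResult:
    """Simulate annual deforestation from ``s0`` (exclusive) to ``horizon``.

    ``forest``/``deforested`` are 0/1 state rasters at ``s0``;
    ``populations_ref`` holds unit populations at ``s0`` (projected
    forward each year at rate ``rho``); ``project_mask`` restricts
    clearing to the project site while dynamic covariates see the whole
    landscape.  Ties in the transition potential are broken uniformly
    at random with ``seed``, which makes runs bit-reproducible.
    """
    require_aligned(forest, deforested, project_mask, unit_raster)
    if static_stack is not None:
        require_aligned(forest, static_stack.template)
    if horizon < s0:
        raise ValueError("horizon must be >= s0")
    rng = np.random.default_rng(seed)

    forest_now = (forest.values == 1).copy()
    cleared = (deforested.values == 1).copy()
    site = project_mask.values == 1
    defor_year = np.full(forest.shape, forest.nodata, dtype=float)

    carry = 0.0
    rows = []
    stopped = False
    for year in range(s0 + 1, horizon + 1):
        site_forest = forest_now & site
        F = int(site_forest.sum())
        if F == 0:
            stopped = True
            warnings.warn(f"forest exhausted before {year}", stacklevel=2)
            break
        pops = {
            u: project_population(P, s0, rho, year)
            for u, P in populations_ref.items()
        }
        dens = density_raster(pops, areas_km2, unit_raster)
        dvals = dens.values[site_forest & dens.mask()]
        mean_density = float(dvals.mean()) if dvals.size else 0.0
        theta0 = intensity_step(intensity_fit, mean_density)
        n1, carry = allocation_count(theta0, F, carry if use_carry else 0.0)

        # refresh the dynamic covariates the location model uses
        fmask = forest.like(forest_now.astype(float), "class_code")
        try:
            needed = set(_names(location_fit))
        except ValueError:  # bare vector: names resolve only via the stack
            needed = {"dist_fedge_m", "dist_dpatch_m", "frag:all"}
        dynamic: dict[str, Raster] = {}
        if "dist_fedge_m" in needed:
            dynamic["dist_fedge_m"] = distance_to_edge(fmask)
        if "dist_dpatch_m" in needed:
            dynamic["dist_dpatch_m"] = ls.distance_to_target(
                forest.like(cleared.astype(float), "class_code"), 1
            )
        if any(n.startswith("frag:") for n in needed):
            dynamic["frag_class"] = ls.fragmentation_classify(fmask, frag_window)
        rasters = dict(static_stack.rasters) if static_stack else {}
        rasters.update(dynamic)
        rasters.setdefault("density_peop_km2", dens)
        stack = ls.CovariateStack(rasters, years={k: year for k in dynamic})

        delta = location_probabilities(location_fit, stack, fmask)
        cand = np.flatnonzero(site_forest & delta.mask())
        dvalues = delta.values.ravel()[cand]
        take = min(n1, cand.size)
        # descending delta, random tie-break
        order = np.lexsort((rng.random(cand.size), -dvalues))
        hit = cand[order[:take]]
        forest_now.ravel()[hit] = False
        cleared.ravel()[hit] = True
        defor_year.ravel()[hit] = year
        rows.append({
            "year": year, "mean_density": mean_density, "theta0": theta0,
            "n1": take, "forest_px": F - take,
        })

    return ForecastResult(
        table=pd.DataFrame(rows),
        defor_year=forest.like(defor_year, "year"),
        stopped_early=stopped,
        meta={"s0": s0, "horizon": horizon, "seed": seed,
              "frag_window": frag_window, "use_carry": use_carry},
    )


def distance_to_edge(forest_mask: Raster) -> Raster:
    """Distance from each forest pixel to the nearest non-forest pixel.

    Non-forest pixels get nodata: the covariate is only defined inside
    the forest.
    """
    nonforest = forest_mask.like(
        (forest_mask.values != 1).astype(float), "class_code"
    )
    dist = ls.distance_to_target(nonforest, 1)
    vals = dist.values.copy()
    vals[forest_mask.values != 1] = forest_mask.nodata
    return forest_mask.like(vals, "distance_m")
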