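"""Spatial covariates and pixel sampling for the deforestation models.

Covers the landscape drivers of where clearing happens: Euclidean
distances (to forest edge, to previously cleared patches, to roads and
towns), the Riitters moving-window forest-fragmentation classes, and
land-policy / density pass-throughs.  Also draws the forest-pixel
samples — with per-pixel observation intervals taken from the satellite
mosaic-piece dates — that feed the intensity and location models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .defor_model import DeforSampleSet
from .geodata import Raster, require_aligned

__all__ = [
    "LC_FOREST", "LC_NONFOREST", "LC_WETLAND", "LC_CLOUD", "LC_SHADE",
    "FRAG_PATCH", "FRAG_TRANSITIONAL", "FRAG_PERFORATED", "FRAG_EDGE",
    "FRAG_INTERIOR", "FRAG_LABELS",
    "LandCoverMap", "CovariateStack",
    "distance_to_target", "fragmentation_classify",
    "sample_pixels", "build_design",
]

# land-cover codes: forest, nonforest (crops/rock/savanna), wetland,
# cloud, shade
LC_FOREST, LC_NONFOREST, LC_WETLAND, LC_CLOUD, LC_SHADE = 1, 2, 3, 4, 5
_UNOBSERVABLE = (LC_CLOUD, LC_SHADE)

# Riitters fragmentation classes for forest pixels
FRAG_PATCH, FRAG_TRANSITIONAL, FRAG_PERFORATED, FRAG_EDGE, FRAG_INTERIOR = (
    1, 2, 3, 4, 5,
)
FRAG_LABELS = {
    FRAG_PATCH: "patch",
    FRAG_TRANSITIONAL: "transitional",
    FRAG_PERFORATED: "perforated",
    FRAG_EDGE: "edge",
    FRAG_INTERIOR: "interior",
}


@dataclass
class LandCoverMap:
    """Land-cover observations plus the mosaic-piece date bookkeeping.

    ``codes[i]`` is the land-cover raster at observation rank i.
    ``piece_id`` assigns each pixel to the mosaic piece (satellite
    scene) it came from, and ``piece_dates[j][i]`` is the decimal-year
    acquisition date of piece j at rank i — the source of the per-pixel
    observation intervals Y.
    """

    codes: list[Raster]
    piece_id: Raster
    piece_dates: dict[int, list[float]]

    def __post_init__(self) -> None:
        require_aligned(*self.codes, self.piece_id)
        for j, dates in self.piece_dates.items():
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValueError(f"piece {j}: dates must strictly increase")
        for r in self.codes:
            valid = r.values[r.mask()]
            bad = ~np.isin(valid, (LC_FOREST, LC_NONFOREST, LC_WETLAND,
                                   LC_CLOUD, LC_SHADE))
            if bad.any():
                raise ValueError("land-cover codes outside the five classes")

    def interval_years(self, i0: int, i1: int) -> np.ndarray:
        """Per-pixel decimal-year interval between ranks i0 and i1."""
        out = np.empty(self.piece_id.shape)
        pid = self.piece_id.values
        for j, dates in self.piece_dates.items():
            out[pid == j] = dates[i1] - dates[i0]
        return out


@dataclass
class CovariateStack:
    """Named, grid-aligned covariate rasters.

    Dynamic members (fragmentation, distance to forest edge, distance
    to cleared patches) carry the year they describe in ``years``;
    static members (elevation, roads, towns, protection, density) do
    not change during a simulation.
    """

    rasters: dict[str, Raster]
    years: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        require_aligned(*self.rasters.values())

    def __getitem__(self, name: str) -> Raster:
        return self.rasters[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rasters

    @property
    def template(self) -> Raster:
        return next(iter(self.rasters.values()))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def distance_to_target(source: Raster, target_codes) -> Raster:
    """Center-to-center Euclidean distance (m) to the nearest target pixel.

    Target pixels get 0.  Uses the exact Euclidean distance transform,
    scaled by the pixel size.  With no target pixel at all the result
    is all-nodata (with a warning) — there is nothing to measure to.
    """
    is_target = np.isin(source.values, np.atleast_1d(target_codes))
    if not is_target.any():
        warnings.warn("no target pixels; returning all-nodata distances",
                      stacklevel=2)
        vals = np.full(source.shape, source.nodata)
        return source.like(vals, "distance_m")
    dist = distance_transform_edt(~is_target, sampling=source.pixel_size)
    return source.like(dist.astype(float), "distance_m")


# ---------------------------------------------------------------------------
# Riitters fragmentation
# ---------------------------------------------------------------------------

def _window_sum(arr: np.ndarray, up: int, down: int, left: int, right: int) -> np.ndarray:
    """Sum of ``arr`` over clamped windows [r-up, r+down] x [c-left, c+right]."""
    nr, nc = arr.shape
    cs = np.zeros((nr + 1, nc + 1))
    cs[1:, 1:] = arr.cumsum(0).cumsum(1)
    r = np.arange(nr)[:, None]
    c = np.arange(nc)[None, :]
    r0 = np.clip(r - up, 0, nr)
    r1 = np.clip(r + down + 1, 0, nr)
    c0 = np.clip(c - left, 0, nc)
    c1 = np.clip(c + right + 1, 0, nc)
    return cs[r1, c1] - cs[r0, c1] - cs[r1, c0] + cs[r0, c0]


def fragmentation_classify(forest_mask: Raster, window: int = 7) -> Raster:
    """Riitters Pf/Pff moving-window fragmentation classes.

    For each forest pixel, Pf is the forest proportion within the
    ``window`` x ``window`` neighborhood (cropped at borders) and Pff
    the proportion of forest-forest pairs among cardinal-adjacent pixel
    pairs (within the window) having at least one forest member.

    Classes: interior Pf = 1; patch Pf < 0.4; transitional
    0.4 <= Pf < 0.6; perforated Pf >= 0.6 and Pf > Pff; edge otherwise.
    Non-forest pixels are nodata.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    nr, nc = forest_mask.shape
    if window > nr or window > nc:
        raise ValueError("window larger than the raster")
    f = (forest_mask.values == 1).astype(float)
    h = window // 2

    n_cells = _window_sum(np.ones_like(f), h, h, h, h)
    n_forest = _window_sum(f, h, h, h, h)
    pf = n_forest / n_cells

    # horizontal pairs: pair (r, c)-(r, c+1) lives at pair-grid [r, c];
    # it lies in the window centered at (R, C) iff c in [C-h, C+h-1]
    ff_h = f[:, :-1] * f[:, 1:]
    any_h = np.maximum(f[:, :-1], f[:, 1:])
    ff_v = f[:-1, :] * f[1:, :]
    any_v = np.maximum(f[:-1, :], f[1:, :])

    def pair_sum_h(pairs):
        full = np.zeros((nr, nc))
        full[:, : nc - 1] = pairs
        return _window_sum(full, h, h, h, h - 1)

    def pair_sum_v(pairs):
        full = np.zeros((nr, nc))
        full[: nr - 1, :] = pairs
        return _window_sum(full, h, h - 1, h, h)

    ff = pair_sum_h(ff_h) + pair_sum_v(ff_v)
    anyf = pair_sum_h(any_h) + pair_sum_v(any_v)
    with np.errstate(invalid="ignore", divide="ignore"):
        pff = np.where(anyf > 0, ff / anyf, 0.0)

    cls = np.full((nr, nc), forest_mask.nodata, dtype=float)
    forest = f == 1
    cls[forest & (pf >= 1.0)] = FRAG_INTERIOR
    cls[forest & (pf < 0.4)] = FRAG_PATCH
    cls[forest & (pf >= 0.4) & (pf < 0.6)] = FRAG_TRANSITIONAL
    hi = forest & (pf >= 0.6) & (pf < 1.0)
    cls[hi & (pf > pff)] = FRAG_PERFORATED
    cls[hi & (pf <= pff)] = FRAG_EDGE
    return forest_mask.like(cls, "class_code")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_pixels(
    lcmap: LandCoverMap,
    Q0: int,
    Q1: int,
    seed: int = 0,
) -> DeforSampleSet:
    """Draw forest pixels observed over the two change periods.

    Q0 pixels forested at rank 0 (outcome judged at rank 1) and Q1
    pixels forested at rank 1 (outcome at rank 2) are sampled uniformly
    without replacement, excluding pixels under cloud or shade at
    either endpoint.  Each sample carries z (1 if nonforest at the
    later rank), its interval Y from the mosaic-piece dates, and the
    period index (location covariates only make sense for period 1,
    where prior clearing is observable).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for period, (i0, i1, q) in enumerate(((0, 1, Q0), (1, 2, Q1))):
        c0 = lcmap.codes[i0].values
        c1 = lcmap.codes[i1].values
        eligible = (
            (c0 == LC_FOREST)
            & ~np.isin(c0, _UNOBSERVABLE)
            & ~np.isin(c1, _UNOBSERVABLE)
            & lcmap.codes[i0].mask()
            & lcmap.codes[i1].mask()
        )
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            raise ValueError(f"no eligible forest pixels at rank {i0}")
        if q > idx.size:
            warnings.warn(
                f"requested {q} samples but only {idx.size} eligible; using all",
                stacklevel=2,
            )
            chosen = idx
        else:
            chosen = rng.choice(idx, size=q, replace=False)
        Y = lcmap.interval_years(i0, i1).ravel()[chosen]
        z = (c1.ravel()[chosen] != LC_FOREST).astype(int)
        frames.append(pd.DataFrame({
            "pixel_id": chosen, "z": z, "Y": Y, "period": period,
        }))
    return DeforSampleSet(pd.concat(frames, ignore_index=True))


def build_design(
    stack: CovariateStack,
    samples: DeforSampleSet,
    covariates: list[str] | None = None,
    frag_reference: int = FRAG_PATCH,
) -> DeforSampleSet:
    """Attach covariate values to sampled pixels.

    Rows align one-to-one with the samples; the fragmentation class
    expands to treatment-coded indicators (``frag_reference`` is the
    omitted level) and the intercept is implicit in the downstream
    design matrix.  Samples falling on nodata covariates are dropped
    with a reported count; an all-constant covariate triggers a
    rank-deficiency warning before fitting ever sees it.
    """
    if covariates is None:
        covariates = [n for n in stack.rasters]
    nr, nc = stack.template.shape
    pid = samples.df["pixel_id"].to_numpy()
    if pid.max() >= nr * nc:
        raise ValueError("sample pixels fall outside the stack extent")

    df = samples.df.reset_index(drop=True).copy()
    cov_names: list[str] = []
    valid = np.ones(len(df), dtype=bool)
    for name in covariates:
        rast = stack[name]
        vals = rast.values.ravel()[pid].astype(float)
        ok = rast.mask().ravel()[pid]
        valid &= ok
        if name == "frag_class":
            for code, label in FRAG_LABELS.items():
                if code == frag_reference:
                    continue
                col = f"frag:{label}"
                df[col] = (vals == code).astype(float)
                cov_names.append(col)
        else:
            df[name] = vals
            cov_names.append(name)
    n_drop = int((~valid).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} samples on nodata covariates",
                      stacklevel=2)
        df = df[valid].reset_index(drop=True)
    for col in cov_names:
        if df[col].nunique() <= 1:
            warnings.warn(
                f"covariate {col!r} is constant: design will be rank deficient",
                stacklevel=2,
            )
    return DeforSampleSet(df, cov_names)
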