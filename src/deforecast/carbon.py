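"""Aboveground-carbon maps and CO2 emissions from simulated clearing.

Aboveground carbon density (ACD, Mg C/ha) maps carry cloud/shadow gaps
over forest; these are filled with the mean ACD of the valid forest in
the same project site, then the map is smoothed with a 3x3 moving
average to suppress salt-and-pepper noise.  Overlaying the
year-of-deforestation map on the prepared ACD map converts each
cleared pixel's carbon stock to CO2 at the molecular-to-atomic mass
ratio 44/12.  Only aboveground biomass is accounted: no belowground
biomass, no soil carbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import Raster, require_aligned

__all__ = ["AcdMap", "CO2_PER_C", "prepare_acd", "emissions"]

#: Mg CO2 released per Mg of carbon (molecular mass 44 over atomic 12)
CO2_PER_C = 44.0 / 12.0


@dataclass
class AcdMap:
    """Aboveground carbon density raster with its reference year."""

    raster: Raster
    reference_year: float

    def __post_init__(self) -> None:
        if self.raster.semantics != "acd_Mg_ha":
            raise ValueError("ACD raster must carry acd_Mg_ha semantics")
        valid = self.raster.values[self.raster.mask()]
        if (valid < 0).any():
            raise ValueError("ACD values must be >= 0 or nodata")


def prepare_acd(acd: AcdMap, forest_mask: Raster, project_sites: Raster) -> AcdMap:
    """Gap-fill forest ACD per project site, then smooth 3x3.

    Step 1: forest pixels with nodata ACD take the mean valid-forest
    ACD of their project site (``project_sites`` is a unit_id raster;
    a site with no valid ACD pixel is an error).  Step 2: 3x3 moving
    average, windows cropped at borders and nodata cells.
    """
    require_aligned(acd.raster, forest_mask, project_sites)
    vals = acd.raster.values.astype(float).copy()
    valid = acd.raster.mask()
    forest = forest_mask.values == 1

    for sid in np.unique(project_sites.values[project_sites.mask()]):
        in_site = project_sites.values == sid
        ref = vals[in_site & forest & valid]
        gaps = in_site & forest & ~valid
        if gaps.any():
            if ref.size == 0:
                raise ValueError(f"project site {sid} has no valid forest ACD")
            vals[gaps] = ref.mean()
            valid |= gaps

    smoothed = _masked_boxcar3(vals, valid)
    out = np.where(valid, smoothed, acd.raster.nodata)
    return AcdMap(acd.raster.like(out, "acd_Mg_ha"), acd.reference_year)


def _masked_boxcar3(vals: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """3x3 mean over valid cells only (cropped at borders/nodata)."""
    num = np.zeros_like(vals, dtype=float)
    den = np.zeros_like(vals, dtype=float)
    v = np.where(valid, vals, 0.0)
    m = valid.astype(float)
    nr, nc = vals.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rs = slice(max(dr, 0), nr + min(dr, 0))
            rd = slice(max(-dr, 0), nr + min(-dr, 0))
            cs = slice(max(dc, 0), nc + min(dc, 0))
            cd = slice(max(-dc, 0), nc + min(-dc, 0))
            num[rd, cd] += v[rs, cs]
            den[rd, cd] += m[rs, cs]
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, 0.0)


def emissions(
    defor_year: Raster, acd: AcdMap, pixel_area_ha: float | None = None
) -> pd.DataFrame:
    """Annual and cumulative CO2 emissions from cleared pixels.

    For each simulated year: area cleared (ha) and CO2 released
    (Mg CO2 = sum of ACD * pixel area * 44/12 over the pixels cleared
    that year).  A cleared pixel without ACD after preparation is a
    contract violation and raises.
    """
    require_aligned(defor_year, acd.raster)
    if pixel_area_ha is None:
        pixel_area_ha = defor_year.pixel_area_ha
    if pixel_area_ha <= 0:
        raise ValueError("pixel_area_ha must be > 0")
    cleared = defor_year.mask()
    if (cleared & ~acd.raster.mask()).any():
        raise ValueError("cleared pixel with nodata ACD: run prepare_acd first")
    years = np.unique(defor_year.values[cleared]).astype(int)
    rows = []
    for year in years:
        sel = cleared & (defor_year.values == year)
        carbon = float(acd.raster.values[sel].sum()) * pixel_area_ha
        rows.append({
            "year": int(year),
            "ha_deforested": float(sel.sum()) * pixel_area_ha,
            "MgCO2": carbon * CO2_PER_C,
        })
    out = pd.DataFrame(rows, columns=["year", "ha_deforested", "MgCO2"])
    out["cumulative_MgCO2"] = out["MgCO2"].cumsum()
    return out
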