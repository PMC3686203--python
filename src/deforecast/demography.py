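"""Hierarchical exponential population-growth model and projections.

Census counts P_k(t) for administrative unit k follow

    P_k(t) = (alpha0 + b_k) exp(rho t) + eps,
    eps ~ Normal(0, V),   b_k ~ Normal(0, V_b),

with t in decimal years measured from the 1993 census (t = 0).  rho is
the annual growth rate shared across units; b_k absorbs between-unit
differences in 1993 size so that repeated counts of the same unit are
not treated as independent.  Priors are noninformative conjugates:
Normal(0, 1e6) on alpha0 and rho, Inverse-Gamma(0.001, 0.001) on V and
V_b.  Given rho, the model is linear in (alpha0, b_k), so everything
except rho is Gibbs-sampled; rho takes an adaptive random-walk
Metropolis step.

Fitted growth feeds the forecast: unit populations are projected as
P(t) = P_ref exp(rho (t - t_ref)) and spread uniformly within each
unit to make pixel-level density maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geodata import Raster
from .mcmc import McmcConfig, ScaleAdapter

__all__ = [
    "CensusTable",
    "DemographicFit",
    "T0_YEAR",
    "fit_demographic_model",
    "project_population",
    "density_raster",
]

#: calendar year at which the model clock starts (t = 0)
T0_YEAR = 1993.0

_IG_SHAPE = 0.001  # Inverse-Gamma prior shape/rate on V and V_b
_IG_RATE = 0.001
_PRIOR_VAR = 1.0e6  # Normal prior variance on alpha0 and rho


@dataclass
class CensusTable:
    """Repeated population counts per administrative unit.

    Columns: ``unit_id``, ``level``, ``parent_id`` (optional), ``date``
    (calendar year, decimal), ``population``, ``area_km2``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"unit_id", "date", "population", "area_km2"}
        missing = req - set(self.df.columns)
        if missing:
            raise ValueError(f"census table missing columns {sorted(missing)}")
        if (self.df["population"] < 0).any():
            raise ValueError("populations must be >= 0")
        if not np.isfinite(self.df["date"]).all():
            raise ValueError("census dates must be finite")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CensusTable":
        return cls(pd.read_csv(path))

    def model_frame(self) -> pd.DataFrame:
        """Observations keyed to firaisana-level units on the model clock.

        1993-era firaisana records attach directly; later fokontany
        counts are aggregated up to their parent firaisana (summing
        populations per firaisana and date), so both censuses inform a
        single per-firaisana trajectory.
        """
        df = self.df.copy()
        if "level" not in df.columns:
            df["level"] = "firaisana"
        top = df[df["level"] == "firaisana"][["unit_id", "date", "population"]]
        sub = df[df["level"] == "fokontany"]
        if len(sub):
            if sub["parent_id"].isna().any():
                raise ValueError("fokontany records need parent_id for aggregation")
            agg = (
                sub.groupby(["parent_id", "date"], as_index=False)["population"]
                .sum()
                .rename(columns={"parent_id": "unit_id"})
            )
            top = pd.concat([top, agg], ignore_index=True)
        top["t"] = top["date"] - T0_YEAR
        return top


@dataclass
class DemographicFit:
    """Posterior draws for (alpha0, rho, V, V_b, b_k)."""

    alpha0: np.ndarray
    rho: np.ndarray
    V: np.ndarray
    V_b: np.ndarray
    b: np.ndarray  # (n_draws, n_units)
    unit_ids: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.V <= 0) or (self.b.shape[1] and np.any(self.V_b <= 0)):
            raise ValueError("retained variance draws must be positive")

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, draws in (("alpha0", self.alpha0), ("rho", self.rho),
                            ("V", self.V), ("V_b", self.V_b)):
            if draws.size:
                rows[name] = {
                    "mean": draws.mean(),
                    "q2.5": np.quantile(draws, 0.025),
                    "q97.5": np.quantile(draws, 0.975),
                }
        return pd.DataFrame(rows).T

    @property
    def rho_mean(self) -> float:
        return float(self.rho.mean())


def fit_demographic_model(
    census: CensusTable,
    mcmc: McmcConfig | None = None,
    random_effects: bool = True,
) -> DemographicFit:
    """Gibbs-within-Metropolis sampler for the growth model.

    Requires observations at >= 2 distinct dates (rho is otherwise
    unidentifiable) and, when ``random_effects`` is on, >= 2 units.
    Reports posterior draws plus the rho-step acceptance rate.
    """
    mcmc = mcmc or McmcConfig()
    frame = census.model_frame()
    if frame["t"].nunique() < 2:
        raise ValueError("need censuses at >= 2 distinct dates to identify rho")
    units = sorted(frame["unit_id"].unique())
    k_index = {u: i for i, u in enumerate(units)}
    K = len(units)
    if random_effects and K < 2:
        raise ValueError("random effects need >= 2 units; pass random_effects=False")

    t = frame["t"].to_numpy(dtype=float)
    P = frame["population"].to_numpy(dtype=float)
    kk = frame["unit_id"].map(k_index).to_numpy()
    n = len(P)

    rng = mcmc.rng()
    # moment-based starting values: pooled log-ratio growth, then the
    # implied 1993 intercept and residual variance.  Starting inside
    # the posterior's high-density region matters here: with few
    # observations the (rho, V) geometry is a funnel that a cold-start
    # random walk explores poorly.
    rho = _log_ratio_growth(frame)
    m0 = np.exp(np.clip(rho * t, -700.0, 700.0))
    alpha0 = float((P / m0).mean())
    b = np.zeros(K)
    resid0 = P - alpha0 * m0
    V = max(float(resid0 @ resid0) / max(n - 1, 1), 1e-8 * max(alpha0**2, 1.0))
    V_b = max(V, 1.0)

    adapter = ScaleAdapter(1, initial=0.01)
    n_total = mcmc.n_burn + mcmc.n_iter
    keep = mcmc.n_retained
    out = {
        "alpha0": np.empty(keep), "rho": np.empty(keep),
        "V": np.empty(keep), "V_b": np.empty(keep),
        "b": np.empty((keep, K)),
    }
    kept = 0
    rho_accepts = 0

    def sse(rho_val, alpha0_val, b_vec):
        m = np.exp(np.clip(rho_val * t, -700.0, 700.0))
        r = P - (alpha0_val + b_vec[kk]) * m
        return float(r @ r)

    for it in range(n_total):
        m = np.exp(rho * t)
        # alpha0 | rest  (Normal conjugate)
        resid = P - b[kk] * m
        prec = (m @ m) / V + 1.0 / _PRIOR_VAR
        mean = (m @ resid) / V / prec
        alpha0 = mean + math.sqrt(1.0 / prec) * rng.standard_normal()
        # b_k | rest
        if random_effects:
            resid = P - alpha0 * m
            for k in range(K):
                sel = kk == k
                mk = m[sel]
                prec_k = (mk @ mk) / V + 1.0 / V_b
                mean_k = (mk @ resid[sel]) / V / prec_k
                b[k] = mean_k + math.sqrt(1.0 / prec_k) * rng.standard_normal()
        # V | rest
        ss = sse(rho, alpha0, b)
        V = 1.0 / rng.gamma(_IG_SHAPE + n / 2.0, 1.0 / (_IG_RATE + ss / 2.0))
        # V_b | rest
        if random_effects:
            V_b = 1.0 / rng.gamma(
                _IG_SHAPE + K / 2.0, 1.0 / (_IG_RATE + (b @ b) / 2.0)
            )
        # rho | rest  (random-walk Metropolis)
        rho_new = rho + adapter.scales[0] * rng.standard_normal()
        ll_diff = -(sse(rho_new, alpha0, b) - ss) / (2.0 * V)
        ll_diff += (rho**2 - rho_new**2) / (2.0 * _PRIOR_VAR)
        accept = math.log(rng.random()) < ll_diff
        if accept:
            rho = rho_new
            if it >= mcmc.n_burn:
                rho_accepts += 1
        if it < mcmc.n_burn:
            adapter.record(0, accept)
        elif (it - mcmc.n_burn) % mcmc.thin == mcmc.thin - 1:
            out["alpha0"][kept] = alpha0
            out["rho"][kept] = rho
            out["V"][kept] = V
            out["V_b"][kept] = V_b
            out["b"][kept] = b
            kept += 1

    return DemographicFit(
        alpha0=out["alpha0"][:kept],
        rho=out["rho"][:kept],
        V=out["V"][:kept],
        V_b=out["V_b"][:kept],
        b=out["b"][:kept],
        unit_ids=units,
        meta={
            "n_burn": mcmc.n_burn, "n_iter": mcmc.n_iter,
            "thin": mcmc.thin, "seed": mcmc.seed,
            "rho_acceptance": rho_accepts / mcmc.n_iter,
            "random_effects": random_effects,
        },
    )


def _log_ratio_growth(frame: pd.DataFrame) -> float:
    """Median per-unit log-ratio growth rate; 0 where unavailable."""
    rates = []
    for _, grp in frame.groupby("unit_id"):
        grp = grp.sort_values("t")
        p0, p1 = grp["population"].iloc[0], grp["population"].iloc[-1]
        dt = grp["t"].iloc[-1] - grp["t"].iloc[0]
        if p0 > 0 and p1 > 0 and dt > 0:
            rates.append(math.log(p1 / p0) / dt)
    return float(np.median(rates)) if rates else 0.0


def project_population(P_ref: float, t_ref: float, rho: float, t: float) -> float:
    """P_ref * exp(rho (t - t_ref)); t before t_ref back-projects."""
    if P_ref < 0:
        raise ValueError("reference population must be >= 0")
    return P_ref * math.exp(rho * (t - t_ref))


def density_raster(
    populations: dict,
    areas_km2: dict,
    unit_raster: Raster,
) -> Raster:
    """Spread unit populations uniformly to pixels (peop/km2).

    Every pixel of a unit takes the unit's density P/area; pixels
    outside all units stay nodata.  Units that appear in the raster
    must come with a population and a positive area.
    """
    vals = np.full(unit_raster.shape, unit_raster.nodata, dtype=float)
    present = np.unique(unit_raster.values[unit_raster.mask()])
    for uid in present:
        key = uid if uid in populations else int(uid)
        if key not in populations or key not in areas_km2:
            raise ValueError(f"unit {uid} has pixels but no population/area")
        if areas_km2[key] <= 0:
            raise ValueError(f"unit {uid} has zero area")
        vals[unit_raster.values == uid] = populations[key] / areas_km2[key]
    return unit_raster.like(vals, "density_peop_km2")
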