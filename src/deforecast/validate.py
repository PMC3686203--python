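"""Map-validation indices and the repeated 70/30 cross-validation harness.

Predictions of a rare binary event (a pixel clears or not) are scored
with the standard land-change indices computed from the confusion
table: overall accuracy, figure of merit, sensitivity, specificity,
the true skill statistic and Cohen's kappa.  Because the annual
clearing rate is ~1%, overall accuracy alone is uninformative (the
"predict nothing" model scores ~99%); the figure of merit
h/(h+m+fa) is the discriminating index for allocation skill.

Continuous transition potentials are binarized the way the simulator
allocates clearing: the expected number of cleared test pixels is
computed from the intensity model (through each row's observation
interval) and that many highest-potential rows are marked as predicted
cleared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .defor_model import (
    DeforSampleSet,
    fit_interval_logistic,
    interval_prob,
)
from .mcmc import McmcConfig

__all__ = ["ConfusionTable", "indices", "cross_validate"]


@dataclass
class ConfusionTable:
    """2x2 counts: observed vs predicted deforestation."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms,
               self.correct_rejections) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return (self.hits + self.misses + self.false_alarms
                + self.correct_rejections)

    @classmethod
    def from_arrays(cls, obs, pred) -> "ConfusionTable":
        obs = np.asarray(obs, dtype=bool)
        pred = np.asarray(pred, dtype=bool)
        return cls(
            hits=int((obs & pred).sum()),
            misses=int((obs & ~pred).sum()),
            false_alarms=int((~obs & pred).sum()),
            correct_rejections=int((~obs & ~pred).sum()),
        )


def indices(t: ConfusionTable) -> dict[str, float]:
    """The six performance indices; undefined ratios come back as NaN.

    OA = (h+cr)/N; FOM = h/(h+m+fa); Sen = h/(h+m); Spe = cr/(cr+fa);
    TSS = Sen + Spe - 1; kappa = (OA - Pe)/(1 - Pe) with Pe the
    marginal chance-agreement expectation.
    """
    h, m, fa, cr = (t.hits, t.misses, t.false_alarms, t.correct_rejections)
    N = t.total
    if N == 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    oa = (h + cr) / N
    sen = ratio(h, h + m)
    spe = ratio(cr, cr + fa)
    p_obs1 = (h + m) / N
    p_pred1 = (h + fa) / N
    pe = p_obs1 * p_pred1 + (1 - p_obs1) * (1 - p_pred1)
    return {
        "OA": oa,
        "FOM": ratio(h, h + m + fa),
        "Sen": sen,
        "Spe": spe,
        "TSS": sen + spe - 1,
        "K": ratio(oa - pe, 1 - pe),
    }


def cross_validate(
    data: DeforSampleSet,
    q0_data: DeforSampleSet,
    intensity_covariates: list[str],
    repeats: int = 10,
    split: float = 0.7,
    seed: int = 0,
    mcmc: McmcConfig | None = None,
    max_redraws: int = 20,
) -> pd.DataFrame:
    """Repeated 70/30 cross-validation of the coupled model.

    Per repeat: split the later-period samples (``data``, which carry
    the location covariates); refit the intensity model on the training
    split pooled with the earlier-period ``q0_data`` (density covariate
    only) and the location model on the training split; on the test
    split, sum interval-corrected intensity predictions to an expected
    cleared count, mark that many highest-potential rows as predicted
    cleared, and score the confusion table.  A split whose test part
    holds a single class is redrawn (and logged).

    Returns mean and sd per index over the repeats, scaled x100 for
    percentage-style reporting.
    """
    mcmc = mcmc or McmcConfig()
    rng = np.random.default_rng(seed)
    n = len(data)
    n_train = int(round(split * n))
    per_repeat = []
    for rep in range(repeats):
        for attempt in range(max_redraws):
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            test_z = data.df["z"].to_numpy()[test_idx]
            if 0 < test_z.sum() < len(test_z):
                break
            warnings.warn(f"repeat {rep}: single-class test split, redrawn",
                          stacklevel=2)
        else:
            raise RuntimeError("could not draw a two-class test split")

        train = DeforSampleSet(
            data.df.iloc[train_idx].reset_index(drop=True), data.covariates
        )
        test = DeforSampleSet(
            data.df.iloc[test_idx].reset_index(drop=True), data.covariates
        )
        # intensity: training rows + the earlier-period pool, density only
        cols = ["pixel_id", "z", "Y"] + intensity_covariates
        pooled = pd.concat(
            [train.df[cols], q0_data.df[cols]], ignore_index=True
        )
        rep_mcmc = McmcConfig(mcmc.n_burn, mcmc.n_iter, mcmc.thin,
                              seed=mcmc.seed + rep)
        ifit = fit_interval_logistic(
            DeforSampleSet(pooled, intensity_covariates), rep_mcmc
        )
        lfit = fit_interval_logistic(train, rep_mcmc)

        # expected cleared count on the test split via each row's Y
        Xi = np.column_stack(
            [np.ones(len(test))]
            + [test.df[c].to_numpy(dtype=float) for c in intensity_covariates]
        )
        theta = expit(Xi @ ifit.posterior_mean())
        n_test = int(round(interval_prob(theta, test.df["Y"].to_numpy()).sum()))
        delta = expit(test.design() @ lfit.posterior_mean())
        order = np.lexsort((rng.random(len(test)), -delta))
        pred = np.zeros(len(test), dtype=bool)
        pred[order[:n_test]] = True
        per_repeat.append(indices(ConfusionTable.from_arrays(test_z == 1, pred)))

    tab = pd.DataFrame(per_repeat)
    return pd.DataFrame({
        "mean": tab.mean() * 100.0,
        "sd": tab.std(ddof=1) * 100.0,
        "repeats": repeats,
    })
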