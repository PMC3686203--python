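"""Shared MCMC configuration and adaptive random-walk helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["McmcConfig", "ScaleAdapter"]


@dataclass
class McmcConfig:
    """Chain length and reproducibility settings.

    ``n_burn`` adaptive burn-in iterations are discarded, then
    ``n_iter`` iterations are run keeping every ``thin``-th draw.
    """

    n_burn: int = 5000
    n_iter: int = 5000
    thin: int = 5
    seed: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_iter // self.thin

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class ScaleAdapter:
    """Tunes per-component random-walk proposal scales during burn-in.

    Every ``batch`` proposals per component, the scale is multiplied or
    divided by ``exp(step)`` to steer the empirical acceptance rate into
    the 20-50% band (target 0.3) that keeps a Gaussian random walk
    efficient.
    """

    def __init__(self, n_components: int, initial: float = 0.1,
                 batch: int = 50, target: float = 0.3, step: float = 0.25):
        self.scales = np.full(n_components, initial, dtype=float)
        self.accepted = np.zeros(n_components)
        self.proposed = np.zeros(n_components)
        self.batch = batch
        self.target = target
        self.step = step

    def record(self, j: int, accepted: bool) -> None:
        self.proposed[j] += 1
        if accepted:
            self.accepted[j] += 1
        if self.proposed[j] >= self.batch:
            rate = self.accepted[j] / self.proposed[j]
            if rate < 0.2:
                self.scales[j] /= np.exp(self.step)
            elif rate > 0.5:
                self.scales[j] *= np.exp(self.step)
            else:
                # nudge toward the 0.3 sweet spot
                self.scales[j] *= np.exp(self.step * (rate - self.target))
            self.accepted[j] = 0.0
            self.proposed[j] = 0.0

    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.proposed > 0,
                            self.accepted / np.maximum(self.proposed, 1), np.nan)
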