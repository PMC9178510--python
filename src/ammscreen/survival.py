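"""Baseline time-to-onset law for the simulator and the scan likelihood.

Onset ages are modeled as Weibull with proportional hazards: a genotype with
hazard ratio ``c`` has survival S(t)^c where S is the baseline survival. The
law is parameterized by two screen-level quantities a mouse facility actually
observes — cumulative incidence by the monitoring horizon, and the median
onset age among affected animals — rather than by raw shape/scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import HORIZON_WEEKS

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class WeibullOnset:
    """Weibull onset law: S(t) = exp(-(t/scale)^shape)."""

    shape: float
    scale: float
    horizon: float = HORIZON_WEEKS

    @classmethod
    def from_screen_design(
        cls,
        incidence: float,
        median_onset: float,
        horizon: float = HORIZON_WEEKS,
    ) -> "WeibullOnset":
        """Solve shape/scale from cumulative incidence at ``horizon`` and the
        median onset among affected mice (the age by which half the eventual
        cases have occurred): F(median_onset) = incidence / 2.
        """
        if not 0 < incidence < 1:
            raise ValueError("incidence must be in (0, 1)")
        if not 0 < median_onset < horizon:
            raise ValueError("median_onset must be in (0, horizon)")
        h_full = -math.log1p(-incidence)        # cumulative hazard at horizon
        h_half = -math.log1p(-incidence / 2.0)  # cumulative hazard at median
        shape = math.log(h_full / h_half) / math.log(horizon / median_onset)
        scale = horizon / h_full ** (1.0 / shape)
        return cls(shape=shape, scale=scale, horizon=horizon)

    def cumulative_hazard(self, t: float, hazard_ratio: float = 1.0) -> float:
        return hazard_ratio * (t / self.scale) ** self.shape

    def survival(self, t: float, hazard_ratio: float = 1.0) -> float:
        return math.exp(-self.cumulative_hazard(t, hazard_ratio))

    def cdf(self, t: float, hazard_ratio: float = 1.0) -> float:
        return -math.expm1(-self.cumulative_hazard(t, hazard_ratio))

    def median(self, hazard_ratio: float = 1.0) -> float:
        """Median of the (uncensored) onset law under a hazard ratio; inf
        when the hazard ratio is zero."""
        if hazard_ratio <= 0:
            return math.inf
        return self.scale * (_LN2 / hazard_ratio) ** (1.0 / self.shape)

    def sample(
        self, rng: np.random.Generator, hazard_ratio: np.ndarray | float, size: int | None = None
    ) -> np.ndarray:
        """Draw latent (continuous) onset times via inverse transform."""
        hr = np.asarray(hazard_ratio, dtype=float)
        if size is None:
            size = hr.shape if hr.shape else 1
        e = rng.exponential(size=size)
        with np.errstate(divide="ignore"):
            t = self.scale * np.where(hr > 0, e / np.maximum(hr, 1e-300), np.inf) ** (
                1.0 / self.shape
            )
        return t
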