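"""Noisy observation of the true response at placed locations.

Observations follow a proportional (heteroscedastic) Gaussian error model:
at a location with true response ``f(x)`` each of the ``r`` replicates is

    y = f(x) + eps,   eps ~ Normal(0, sigma),
    sigma = max(noise_level * |f(x)|, sd_floor).

``noise_level`` is a fraction of the absolute true response (0.2 and 1.0
are the two study levels; 0.2 is close to noise levels reported for real
ecological measurements, 1.0 is an extreme high-noise scenario).  The
``sd_floor`` keeps a small nonzero scatter where ``f(x)`` crosses zero so
such points do not act as artificial noise-free anchors; by default it is
``noise_level * 0.01 * range(f)``.  Draws are never truncated — responses
are in arbitrary units and may go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .designs import PlacementResult
from .shapes import ResponseShape

__all__ = ["NoiseModel", "SampleSet", "make_noise_model", "draw_samples"]

#: default sd floor as a fraction of the dense-grid response range,
#: additionally scaled by the noise level
DEFAULT_SD_FLOOR_FRACTION = 0.01


@dataclass(frozen=True)
class NoiseModel:
    """Proportional Gaussian noise: ``sigma = max(noise_level*|f|, sd_floor)``."""

    noise_level: float
    sd_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.sd_floor < 0:
            raise ValueError("sd_floor must be >= 0")


def make_noise_model(
    shape: ResponseShape,
    noise_level: float,
    sd_floor_fraction: float = DEFAULT_SD_FLOOR_FRACTION,
) -> NoiseModel:
    """Noise model with the default response-range-scaled sd floor."""
    return NoiseModel(
        noise_level=noise_level,
        sd_floor=noise_level * sd_floor_fraction * shape.f_range,
    )


@dataclass
class SampleSet:
    """Drawn observations for one simulation run.

    ``x`` repeats each of the ``L`` distinct locations ``r`` times;
    ``y`` holds the corresponding noisy responses.  ``meta`` carries the
    scenario bookkeeping (shape, strategy, procedure, noise, seed, ...).
    """

    x: np.ndarray
    y: np.ndarray
    meta: Dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.x.size

    def distinct_locations(self) -> np.ndarray:
        return np.unique(self.x)


def draw_samples(
    shape: ResponseShape,
    placement: PlacementResult,
    n_replicates: int,
    noise: NoiseModel,
    rng: Optional[np.random.Generator] = None,
    meta: Optional[Dict] = None,
) -> SampleSet:
    """Replicate each placed location ``n_replicates`` times with noise.

    Draws are independent across locations and replicates and fully
    determined by ``rng``.  With ``noise_level == 0`` (and the default
    floor, which then also vanishes) the observations equal ``f(x)``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    x_loc = placement.locations
    f_loc = np.asarray(shape.evaluate(x_loc), dtype=float)
    sigma_loc = np.maximum(noise.noise_level * np.abs(f_loc), noise.sd_floor)

    x = np.repeat(x_loc, n_replicates)
    mu = np.repeat(f_loc, n_replicates)
    if noise.noise_level == 0 and noise.sd_floor == 0:
        y = mu.copy()
    else:
        if rng is None:
            raise ValueError("a seeded rng is required when noise is nonzero")
        y = mu + rng.standard_normal(x.size) * np.repeat(sigma_loc, n_replicates)

    m = dict(meta or {})
    m.setdefault("shape_id", shape.shape_id)
    m.setdefault("strategy_id", placement.strategy_id)
    m.setdefault("extremes_included", placement.extremes_included)
    m.setdefault("n_replicates", int(n_replicates))
    m.setdefault("noise_level", float(noise.noise_level))
    return SampleSet(x=x, y=y, meta=m)
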