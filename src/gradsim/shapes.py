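"""True response shapes along an environmental gradient.

A gradient study samples a response variable (biomass, photosynthetic
activity, species richness, ...) at chosen positions along a continuous
environmental driver (temperature, soil moisture, pH, ...).  The simulator
works with a registry of deterministic "true" response curves ``y = f(x)``
covering the shapes most commonly reported in ecology: linear, centred hump,
skewed hump, saturating, exponential and logistic.  Variables are in
arbitrary units on a strictly positive domain (default ``[1, 100]``), each
curve scaled so the response spans roughly ``[0, 100]``.

Every shape carries its analytic first derivative: preferential sampling
strategies use ``|f'|`` to locate regions of steep change, and the
"extremeness" criticality uses the cached dense-grid minimum and maximum of
``f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np

__all__ = [
    "DEFAULT_GRID_SIZE",
    "SHAPE_IDS",
    "GradientDomain",
    "ResponseShape",
    "default_registry",
    "make_shape",
]

#: Size of the dense grid used for cached curve statistics, criticality
#: weights and the evaluation grid.
DEFAULT_GRID_SIZE = 1000

SHAPE_IDS = (
    "linear",
    "hump",
    "skewed_hump",
    "saturating",
    "exponential",
    "logistic",
)


@dataclass(frozen=True)
class GradientDomain:
    """Closed interval of the environmental driver, in arbitrary units.

    ``x_min`` must be strictly positive so that log-spaced placement is
    defined everywhere on the domain.
    """

    x_min: float = 1.0
    x_max: float = 100.0

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"x_min must be < x_max, got [{self.x_min}, {self.x_max}]")
        if self.x_min <= 0:
            raise ValueError("x_min must be > 0 so log-spaced placement is defined")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.x_max - self.x_min)

    def grid(self, size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
        """Equidistant grid spanning the domain, endpoints included."""
        return np.linspace(self.x_min, self.x_max, size)

    def contains(self, x: np.ndarray) -> np.ndarray:
        # tiny tolerance absorbs floating-point endpoints from linspace/geomspace
        tol = 1e-9 * (self.x_max - self.x_min)
        return (x >= self.x_min - tol) & (x <= self.x_max + tol)


class ResponseShape:
    """A deterministic true response curve with analytic derivative.

    Parameters
    ----------
    shape_id : str
        Registry identifier.
    fn, derivative : callable
        Vectorized ``f(x)`` and ``f'(x)``.
    domain : GradientDomain
        Driver interval on which the shape is defined.
    grid_size : int
        Dense-grid size used to cache curve statistics (min, max, range).
    """

    def __init__(
        self,
        shape_id: str,
        fn: Callable[[np.ndarray], np.ndarray],
        derivative: Callable[[np.ndarray], np.ndarray],
        domain: Optional[GradientDomain] = None,
        grid_size: int = DEFAULT_GRID_SIZE,
    ) -> None:
        self.shape_id = str(shape_id)
        self.domain = domain if domain is not None else GradientDomain()
        self._fn = fn
        self._deriv = derivative
        self._x_dense = self.domain.grid(grid_size)
        f = np.asarray(fn(self._x_dense), dtype=float)
        if f.shape != self._x_dense.shape or not np.all(np.isfinite(f)):
            raise ValueError(f"shape {shape_id!r} is not finite/single-valued on its domain")
        self._f_dense = f
        self.f_min = float(f.min())
        self.f_max = float(f.max())
        self.f_range = self.f_max - self.f_min
        self._nominal_order: Optional[int] = None  # filled lazily by fitpredict

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, x: np.ndarray) -> None:
        if not np.all(self.domain.contains(x)):
            bad = np.asarray(x)[~self.domain.contains(np.asarray(x))]
            raise ValueError(
                f"x outside domain [{self.domain.x_min}, {self.domain.x_max}] "
                f"for shape {self.shape_id!r}: {bad[:5]!r}"
            )

    def evaluate(self, x):
        """Noiseless true response ``f(x)``; scalar in, scalar out."""
        xa = np.asarray(x, dtype=float)
        self._check_domain(xa)
        out = np.asarray(self._fn(xa), dtype=float)
        return float(out) if np.isscalar(x) or xa.ndim == 0 else out

    __call__ = evaluate

    def derivative(self, x):
        """Analytic slope ``f'(x)``; scalar in, scalar out."""
        xa = np.asarray(x, dtype=float)
        self._check_domain(xa)
        out = np.asarray(self._deriv(xa), dtype=float)
        return float(out) if np.isscalar(x) or xa.ndim == 0 else out

    def dense_values(self, size: int = DEFAULT_GRID_SIZE):
        """Cached ``(x, f(x))`` on the equidistant dense grid."""
        if size == self._x_dense.size:
            return self._x_dense, self._f_dense
        x = self.domain.grid(size)
        return x, np.asarray(self._fn(x), dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ResponseShape({self.shape_id!r}, domain=[{self.domain.x_min}, "
            f"{self.domain.x_max}], range=[{self.f_min:.3g}, {self.f_max:.3g}])"
        )


def make_shape(
    shape_id: str,
    fn: Callable,
    derivative: Callable,
    domain: Optional[GradientDomain] = None,
) -> ResponseShape:
    """Register-ready shape from a ``(callable, derivative, domain)`` triple."""
    return ResponseShape(shape_id, fn, derivative, domain=domain)


# -- default registry -------------------------------------------------------
#
# Constants below put every curve on [1, 100] with responses spanning
# ≈[0, 100] arbitrary units.  The hump is an exact centred quadratic; the
# skewed hump a Ricker curve peaking at x = 20; the exponential is
# normalized to run from 0 to 100 over the domain; the logistic has its
# inflection at the domain midpoint.


def _linear(domain: GradientDomain) -> ResponseShape:
    return ResponseShape("linear", lambda x: x + 0.0, lambda x: np.ones_like(np.asarray(x, float)), domain)


def _hump(domain: GradientDomain) -> ResponseShape:
    m, h = domain.midpoint, domain.half_width
    a = 100.0 / h**2
    return ResponseShape(
        "hump",
        lambda x: 100.0 - a * (x - m) ** 2,
        lambda x: -2.0 * a * (x - m),
        domain,
    )


def _skewed_hump(domain: GradientDomain, peak_x: float = 20.0) -> ResponseShape:
    # Ricker curve scaled to a maximum of 100 at x = peak_x
    t = peak_x
    return ResponseShape(
        "skewed_hump",
        lambda x: 100.0 * (x / t) * np.exp(1.0 - x / t),
        lambda x: (100.0 / t) * np.exp(1.0 - x / t) * (1.0 - x / t),
        domain,
    )


def _saturating(domain: GradientDomain) -> ResponseShape:
    c = 100.0 / math.log(domain.x_max)
    return ResponseShape(
        "saturating",
        lambda x: c * np.log(x),
        lambda x: c / x,
        domain,
    )


def _exponential(domain: GradientDomain, k: float = 0.05) -> ResponseShape:
    e0, e1 = math.exp(k * domain.x_min), math.exp(k * domain.x_max)
    s = 100.0 / (e1 - e0)
    return ResponseShape(
        "exponential",
        lambda x: s * (np.exp(k * x) - e0),
        lambda x: s * k * np.exp(k * x),
        domain,
    )


def _logistic(domain: GradientDomain, rate: float = 0.15) -> ResponseShape:
    x0 = domain.midpoint

    def f(x):
        return 100.0 / (1.0 + np.exp(-rate * (np.asarray(x, float) - x0)))

    def fprime(x):
        y = f(x)
        return rate * y * (1.0 - y / 100.0)

    return ResponseShape("logistic", f, fprime, domain)


def default_registry(domain: Optional[GradientDomain] = None) -> Dict[str, ResponseShape]:
    """The six default response shapes, addressable by string id."""
    d = domain if domain is not None else GradientDomain()
    return {
        "linear": _linear(d),
        "hump": _hump(d),
        "skewed_hump": _skewed_hump(d),
        "saturating": _saturating(d),
        "exponential": _exponential(d),
        "logistic": _logistic(d),
    }
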