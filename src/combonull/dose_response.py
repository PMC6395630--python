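"""Hill dose-effect curves: evaluation, inversion, sensitivity, fitting.

The four-parameter Hill curve

    f(a) = e_min + (e_max - e_min) / (1 + (ec50 / a)**n)

is the standard monotone model for monotherapy dose-effect data.  ``e_min``
is the untreated baseline, ``e_max`` the asymptotic saturation level, ``ec50``
the dose producing the half-maximal effect and ``n`` the Hill coefficient
(cooperativity).  Curves here are strictly increasing; decreasing readouts
(e.g. viability) should be pre-transformed with :func:`to_increasing`.

The *effect-sensitivity curve* s(x) = f'(f^{-1}(x)) re-expresses the slope of
the dose-effect curve as a function of the effect level.  It is the
right-hand side of the autonomous ODE dx/da = s(x) that the dose-effect curve
solves, and the quantity the Hand null model averages across drugs.  For a
Hill curve it has the closed form

    s(x) = n / (ec50 * (e_max - e_min))
           * (x - e_min)**(1 - 1/n) * (e_max - x)**(1 + 1/n).

Outside [e_min, e_max] the sensitivity is zero by convention (the
zero-extension used for partial agents), which keeps Hand-model integrands
total functions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

from .errors import DoseDomainError, EffectOutOfRangeError

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

__all__ = [
    "HillCurve",
    "ZeroEffectCurve",
    "potency_ratio",
    "to_increasing",
    "fit_hill",
    "select_monotherapy_model",
]


@dataclass(frozen=True)
class HillCurve:
    """Strictly increasing four-parameter Hill dose-effect curve.

    Parameters
    ----------
    e_min : float
        Baseline effect (untreated condition).
    e_max : float
        Asymptotic maximal effect; must exceed ``e_min``.  Never attained at
        finite dose.
    ec50 : float
        Dose at the half-maximal effect, > 0 (concentration units).
    n : float
        Hill coefficient, > 0 (dimensionless).
    """

    e_min: float
    e_max: float
    ec50: float
    n: float

    def __post_init__(self):
        for name in ("e_min", "e_max", "ec50", "n"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not self.e_max > self.e_min:
            raise ValueError(
                f"e_max must exceed e_min (got e_min={self.e_min}, e_max={self.e_max})"
            )
        if not self.ec50 > 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if not self.n > 0:
            raise ValueError(f"Hill coefficient must be positive, got {self.n}")

    # -- evaluation ---------------------------------------------------------

    def _f(self, a: float) -> float:
        """Scalar fast path; assumes a >= 0 already checked."""
        if a == 0.0:
            return self.e_min
        if math.isinf(a):
            return self.e_max
        return self.e_min + (self.e_max - self.e_min) / (1.0 + (self.ec50 / a) ** self.n)

    def __call__(self, a):
        """Effect at dose ``a`` (scalar or array).  a = 0 returns ``e_min``
        by the limit convention."""
        if isinstance(a, (float, int)):
            if not a >= 0:
                raise DoseDomainError(f"dose must be non-negative, got {a}")
            return self._f(float(a))
        a = np.asarray(a, dtype=float)
        if np.any(a < 0) or np.any(np.isnan(a)):
            raise DoseDomainError("doses must be non-negative and finite")
        with np.errstate(divide="ignore", over="ignore"):
            out = self.e_min + (self.e_max - self.e_min) / (1.0 + (self.ec50 / a) ** self.n)
        return np.where(a == 0, self.e_min, np.where(np.isinf(a), self.e_max, out))

    # -- inversion ----------------------------------------------------------

    def _finv(self, x: float) -> float:
        """Scalar inverse without range checks (caller guarantees interior x)."""
        return self.ec50 * ((x - self.e_min) / (self.e_max - x)) ** (1.0 / self.n)

    def _finv0(self, x: float) -> float:
        """Inverse capped at the baseline: x <= e_min maps to dose 0.

        Internal helper for iterated constructions that start at the
        baseline effect, where the strict inverse is undefined.
        """
        if x <= self.e_min:
            return 0.0
        return self._finv(x)

    def inverse(self, x):
        """Dose producing effect ``x``; defined for e_min < x < e_max.

        Raises
        ------
        EffectOutOfRangeError
            With ``boundary="below_min"`` or ``"above_max"``; the latter is
            the partial-agent saturation case.
        """
        if isinstance(x, (float, int)):
            self._check_effect_interior(float(x))
            return self._finv(float(x))
        x = np.asarray(x, dtype=float)
        if np.any(x <= self.e_min):
            raise EffectOutOfRangeError(
                f"effect {x.min()} at or below baseline e_min={self.e_min}",
                boundary="below_min",
            )
        if np.any(x >= self.e_max):
            raise EffectOutOfRangeError(
                f"effect {x.max()} at or above saturation e_max={self.e_max}",
                boundary="above_max",
            )
        return self.ec50 * ((x - self.e_min) / (self.e_max - x)) ** (1.0 / self.n)

    def _check_effect_interior(self, x: float) -> None:
        if not x > self.e_min:
            raise EffectOutOfRangeError(
                f"effect {x} at or below baseline e_min={self.e_min}",
                boundary="below_min",
            )
        if not x < self.e_max:
            raise EffectOutOfRangeError(
                f"effect {x} at or above saturation e_max={self.e_max}",
                boundary="above_max",
            )

    # -- sensitivity --------------------------------------------------------

    def sensitivity(self, x):
        """Effect-sensitivity s(x) = f'(f^{-1}(x)), zero-extended outside
        [e_min, e_max].

        At ``x = e_min`` the value is 0 for n > 1, finite for n = 1 and
        +inf for n < 1 (the curve starts with infinite slope); at
        ``x = e_max`` it is 0.  Never raises: total by convention so that
        Hand-model integrands are total functions.
        """
        scalar = isinstance(x, (float, int))
        x = np.asarray(x, dtype=float)
        c = self.n / (self.ec50 * (self.e_max - self.e_min))
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            u = x - self.e_min
            v = self.e_max - x
            val = c * u ** (1.0 - 1.0 / self.n) * v ** (1.0 + 1.0 / self.n)
        inside = (x >= self.e_min) & (x <= self.e_max)
        out = np.where(inside, val, 0.0)
        # 0**0 == 1 in numpy, so the n == 1 baseline limit is already right;
        # n < 1 gives +inf at e_min, which is the correct one-sided limit.
        if scalar:
            return float(out)
        return out

    # -- transforms ---------------------------------------------------------

    def normalised(self, top: float | None = None) -> "HillCurve":
        """Affinely rescale the effect axis so e_min -> 0 and ``top`` -> 1.

        ``top`` defaults to this curve's own ``e_max``.  Offered as optional
        preprocessing (Bliss requires the larger maximal effect of a pair to
        be 1); never applied implicitly.
        """
        if top is None:
            top = self.e_max
        scale = top - self.e_min
        if scale <= 0:
            raise ValueError("normalisation scale must be positive")
        return replace(
            self,
            e_min=0.0,
            e_max=(self.e_max - self.e_min) / scale,
        )


@dataclass(frozen=True)
class ZeroEffectCurve:
    """Flat dose-effect curve: a drug with no dose response.

    Competitor of the Hill model in BIC-based monotherapy model selection.
    Has no inverse.
    """

    e_min: float

    def __call__(self, a):
        if isinstance(a, (float, int)):
            if not a >= 0:
                raise DoseDomainError(f"dose must be non-negative, got {a}")
            return self.e_min
        a = np.asarray(a, dtype=float)
        if np.any(a < 0):
            raise DoseDomainError("doses must be non-negative")
        return np.full_like(a, self.e_min, dtype=float)

    def inverse(self, x):
        raise EffectOutOfRangeError(
            "a zero-effect curve has no inverse", boundary="above_max"
        )


def potency_ratio(curve_a: HillCurve, curve_b: HillCurve, x) -> float:
    """Potency ratio alpha(x) = f_A^{-1}(x) / f_B^{-1}(x).

    How much more dose of A than of B is needed for the same effect ``x``;
    geometrically the (negative) slope of the Loewe isobole at level ``x``.
    Constant in ``x`` exactly when the curves share e_max and n (parallel
    curves on a log-dose axis).

    ``x`` must lie strictly between the shared baseline and
    min(e_max_a, e_max_b).
    """
    return curve_a.inverse(x) / curve_b.inverse(x)


def to_increasing(effects, top: float = 1.0):
    """Map a decreasing readout (e.g. viability) onto the increasing
    convention used throughout: effect -> top - effect."""
    return top - np.asarray(effects, dtype=float)


# -- fitting (thin wrappers over the sklearn-style estimators) --------------


def fit_hill(
    table: "pd.DataFrame",
    n_starts: int = 10,
    random_state: int | None = 0,
    max_nfev: int | None = None,
):
    """Least-squares Hill fit to a monotherapy table.

    ``table`` needs columns ``dose`` and ``effect`` (a ``replicate`` column
    is allowed and ignored by the fit).  Requires at least four distinct
    doses.  Returns a fitted :class:`combonull.estimators.HillCurveRegressor`
    whose ``curve_``, ``rss_`` and ``log_likelihood_`` attributes hold the
    estimate and diagnostics.  Deterministic for a fixed ``random_state``.
    """
    from .estimators import HillCurveRegressor

    est = HillCurveRegressor(
        n_starts=n_starts, random_state=random_state, max_nfev=max_nfev
    )
    return est.fit(np.asarray(table["dose"], float), np.asarray(table["effect"], float))


@dataclass
class ModelSelection:
    """Outcome of Hill vs zero-effect monotherapy model selection."""

    winner: str  # "hill" | "zero_effect"
    bic_hill: float
    bic_zero: float
    hill_fit: object
    zero_fit: object


def select_monotherapy_model(
    table: "pd.DataFrame",
    n_starts: int = 10,
    random_state: int | None = 0,
) -> ModelSelection:
    """Choose between a Hill and a zero-effect monotherapy model by BIC.

    BIC = k ln m - 2 ln L with m the number of records and k counting the
    mean parameters plus one noise variance for either model (k = 5 for
    Hill, k = 2 for zero-effect).  Lower BIC wins; ties break toward the
    zero-effect model (parsimony).
    """
    from .estimators import HillCurveRegressor, ZeroEffectRegressor

    dose = np.asarray(table["dose"], float)
    eff = np.asarray(table["effect"], float)
    hill = HillCurveRegressor(n_starts=n_starts, random_state=random_state).fit(dose, eff)
    zero = ZeroEffectRegressor().fit(dose, eff)
    m = len(eff)
    bic_hill = 5 * math.log(m) - 2.0 * hill.log_likelihood_
    bic_zero = 2 * math.log(m) - 2.0 * zero.log_likelihood_
    winner = "hill" if bic_hill < bic_zero else "zero_effect"
    return ModelSelection(winner, bic_hill, bic_zero, hill, zero)
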