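"""Numerical core of the Hand null model.

The Hand model constructs the dose-effect curve of the fixed-ratio mixture
C_lambda (one unit = lam units of A plus (1-lam) units of B) from the ODE

    f_AB'(f_AB^{-1}(x)) = lam * s_A(x) + (1 - lam) * s_B(x),   f_AB(e_min) = 0,

i.e. at every effect level both agents contribute linearly to the
instantaneous gain in effect, with weights given by the mixture ratio.
Because the right-hand side vanishes at the baseline whenever both Hill
coefficients exceed one (the initial condition is an equilibrium of the
forward ODE), the robust primary route is the equivalent integral
representation of the inverse combined curve

    f_AB^{-1}(x) = Integral_{e_min}^{x} dy / (lam*s_A(y) + (1-lam)*s_B(y)),

whose integrand has integrable power-law singularities at the baseline and
at the attainable supremum.  This module evaluates that integral on
geometric (factor-of-two) node ladders clustered toward both endpoints, one
Gauss-Legendre panel per ladder segment, with the remaining endpoint slivers
integrated by a local power-law fit.  The combined curve itself is recovered
by monotone (Brent) inversion within the bracketing table segment.

Partial agents: if one curve saturates at a lower level, its sensitivity is
zero above that level, so beyond the mixture dose c*(lam) at which the lower
saturation is reached the combined curve is driven by the full agent alone
and has the closed form

    f_AB(c* + t) = f_full(f_full^{-1}(e_max_partial) + w_full * t),  t > 0,

with w_full the mixture weight of the full agent.  The curve (a*, b*) =
(lam*c*, (1-lam)*c*) is the *limit isobole* at the partial agent's maximal
effect.

Everything here is written against a minimal curve protocol (``e_min``,
``e_max``, call, ``inverse``, ``sensitivity``) rather than Hill curves
specifically; :class:`CombinedCurve` itself satisfies the protocol, so
mixtures of mixtures (the associativity property) can be built directly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .errors import DoseDomainError, EffectOutOfRangeError, QuadratureError

__all__ = [
    "HandSettings",
    "CombinedCurve",
    "combined_curve",
    "combined_sensitivity",
    "hand_inverse",
    "hand_combined_curve",
    "c_star",
    "limit_isobole",
    "PartialAgentGeometry",
    "tallarida_iterated",
]

_GL16_T, _GL16_W = leggauss(16)


@dataclass(frozen=True)
class HandSettings:
    """Numerical knobs for the Hand engine.

    k_ladder
        Depth of the geometric node ladders: the endpoint slivers handled by
        the local power-law fit have width ~ (range) * 2**-(k_ladder + 1).
        Deep by default because near the baseline the integrand is a
        *mixture* of power laws (one per curve) whose composition keeps
        drifting as the effect approaches the baseline, so the single-law
        sliver extrapolation is only asymptotically exact; driving the
        sliver far down makes its absolute contribution (and hence the
        extrapolation error) negligible.  Ladder nodes that are not
        representable above the baseline (non-zero e_min at extreme depth)
        are dropped automatically.
    k_top_init
        Initial ladder depth toward the (asymptotic) supremum for equal-
        maximal-effect pairs; extended on demand for very large doses.
    emax_equal_rtol
        Relative tolerance deciding whether the two maximal effects count as
        equal (activates / deactivates the partial-agent code path).
    xtol_rel
        Brent tolerance for effect-level inversion, relative to the effect
        range.
    """

    k_ladder: int = 110
    k_top_init: int = 16
    emax_equal_rtol: float = 1e-9
    xtol_rel: float = 1e-13


DEFAULT_SETTINGS = HandSettings()


def combined_sensitivity(pair, lam: float, x):
    """Mixture effect-sensitivity s_AB(x) = lam*s_A(x) + (1-lam)*s_B(x).

    Each curve's own zero-extension applies above its saturation level, so
    for a partial agent A this reduces to (1-lam)*s_B(x) on
    [e_max_A, e_max_B).  Total (never raises) for x >= e_min.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"mixture ratio must lie in [0, 1], got {lam}")
    if lam == 0.0:
        return pair.curve_b.sensitivity(x)
    if lam == 1.0:
        return pair.curve_a.sensitivity(x)
    return lam * pair.curve_a.sensitivity(x) + (1.0 - lam) * pair.curve_b.sensitivity(x)


class CombinedCurve:
    """Dose-effect curve of the fixed-ratio mixture C_lambda under the Hand
    model; the vertical ray-cut of the Hand effect surface.

    Satisfies the same curve protocol as :class:`~combonull.dose_response.
    HillCurve` (``e_min``, ``e_max``, call, ``inverse``, ``sensitivity``), so
    combined curves can themselves be members of a pair — which is how the
    associative property is exercised numerically.

    ``e_max`` is the attainable supremum of the mixture: the saturation
    level of whichever contributing agent reaches higher (for interior
    ``lam``), approached asymptotically, never attained.
    """

    def __init__(self, pair, lam: float, settings: HandSettings = DEFAULT_SETTINGS):
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"mixture ratio must lie in [0, 1], got {lam}")
        self.pair = pair
        self.lam = float(lam)
        self.settings = settings
        self._delegate = None
        if lam == 1.0:
            self._delegate = pair.curve_a
            return
        if lam == 0.0:
            self._delegate = pair.curve_b
            return

        ca, cb = pair.curve_a, pair.curve_b
        self._lo = ca.e_min
        ea, eb = ca.e_max, cb.e_max
        self._sup = max(ea, eb)
        brk = min(ea, eb)
        rng = self._sup - self._lo
        self._partial = (self._sup - brk) > settings.emax_equal_rtol * rng
        if self._partial:
            if ea < eb:
                self._full, self._w_full = cb, 1.0 - lam
            else:
                self._full, self._w_full = ca, lam
            self._brk = brk
            top = brk
        else:
            self._brk = None
            top = self._sup
        self._top = top
        self._build_table(top)

    # -- table construction -------------------------------------------------

    def _phi(self, y):
        """Integrand 1 / s_AB(y) of the inverse combined curve."""
        s = self.lam * self.pair.curve_a.sensitivity(y) + (1.0 - self.lam) * self.pair.curve_b.sensitivity(y)
        with np.errstate(divide="ignore"):
            return np.where(s > 0, 1.0 / s, np.inf)

    def _panel(self, x0, x1):
        """Gauss-Legendre panel integral of phi over [x0, x1] (vectorised
        over segment arrays)."""
        x0 = np.atleast_1d(np.asarray(x0, float))
        x1 = np.atleast_1d(np.asarray(x1, float))
        mid = 0.5 * (x0 + x1)
        half = 0.5 * (x1 - x0)
        pts = mid[:, None] + half[:, None] * _GL16_T[None, :]
        vals = self._phi(pts.ravel()).reshape(pts.shape)
        return (vals * _GL16_W[None, :]).sum(axis=1) * half

    def _build_table(self, top: float):
        lo = self._lo
        rng = top - lo
        k = self.settings.k_ladder
        # geometric ladder toward the baseline: lo + (rng/2)*2^-j, j = k..0;
        # drop depths that are no longer representable above lo
        bottom = lo + (rng / 2.0) * 2.0 ** (-np.arange(k, -1, -1, dtype=float))
        bottom = np.unique(bottom[bottom > lo])
        if self._partial:
            # mirrored ladder toward the (regular) breakpoint
            topside = top - (rng / 2.0) * 2.0 ** (-np.arange(1, k + 1, dtype=float))
            topside = np.unique(topside[(topside > bottom[-1]) & (topside < top)])
            nodes = np.concatenate([bottom, topside])
        else:
            # open ladder toward the asymptotic supremum, extended on demand
            j = np.arange(2, self.settings.k_top_init + 1, dtype=float)
            topside = top - rng * 2.0 ** (-j)
            nodes = np.concatenate([bottom, topside])
            self._k_top = self.settings.k_top_init

        # baseline sliver: phi ~ C*u^gamma, integrable (gamma > -1)
        u0 = float(bottom[0] - lo)
        phi1 = float(self._phi(np.array([lo + u0]))[0])
        phi2 = float(self._phi(np.array([lo + 2.0 * u0]))[0])
        self._gam_b, tail_b = _power_tail(phi1, phi2, u0)
        self._u0 = u0
        self._tail_b = tail_b

        seg = self._panel(nodes[:-1], nodes[1:])
        cum = np.empty(nodes.size)
        cum[0] = tail_b
        np.cumsum(seg, out=cum[1:])
        cum[1:] += tail_b

        if self._partial:
            # breakpoint sliver (regular endpoint, gamma ~ 0)
            v0 = float(top - nodes[-1])
            psi1 = float(self._phi(np.array([top - v0]))[0])
            psi2 = float(self._phi(np.array([top - 2.0 * v0]))[0])
            self._gam_t, tail_t = _power_tail(psi1, psi2, v0)
            self._v0 = v0
            self._tail_t = tail_t
            nodes = np.append(nodes, top)
            cum = np.append(cum, cum[-1] + tail_t)
            self._cstar = float(cum[-1])
        self._x = nodes
        self._I = cum
        if not np.all(np.isfinite(cum)):
            raise QuadratureError(
                f"combined-curve quadrature produced non-finite doses (lam={self.lam})"
            )

    def _extend_top(self) -> bool:
        """Append one more ladder node toward the supremum (equal-e_max
        pairs only).  Returns False once float resolution is exhausted."""
        rng = self._sup - self._lo
        self._k_top += 1
        x_new = self._sup - rng * 2.0 ** (-self._k_top)
        if not x_new > self._x[-1]:
            return False
        seg = float(self._panel(self._x[-1], x_new)[0])
        self._x = np.append(self._x, x_new)
        self._I = np.append(self._I, self._I[-1] + seg)
        return True

    # -- protocol -----------------------------------------------------------

    @property
    def e_min(self) -> float:
        if self._delegate is not None:
            return self._delegate.e_min
        return self._lo

    @property
    def e_max(self) -> float:
        if self._delegate is not None:
            return self._delegate.e_max
        return self._sup

    @property
    def c_star(self) -> float:
        """Mixture dose at which the partial agent's maximal effect is
        attained (finite only for full/partial pairs at interior lam)."""
        if self._delegate is not None or not self._partial:
            raise ValueError(
                "c_star is defined only for full/partial pairs at interior mixture ratios"
            )
        return self._cstar

    def sensitivity(self, x):
        if self._delegate is not None:
            return self._delegate.sensitivity(x)
        return combined_sensitivity(self.pair, self.lam, x)

    def inverse(self, x: float) -> float:
        """Mixture dose at which effect ``x`` is reached,
        f_AB^{-1}(x) (the tabulated inverse integral)."""
        if self._delegate is not None:
            if x == self._delegate.e_min:
                return 0.0
            return self._delegate.inverse(x)
        x = float(x)
        if x == self._lo:
            return 0.0
        if not x > self._lo:
            raise EffectOutOfRangeError(
                f"effect {x} below baseline {self._lo}", boundary="below_min"
            )
        if not x < self._sup:
            raise EffectOutOfRangeError(
                f"effect {x} at or above attainable supremum {self._sup}",
                boundary="above_max",
            )
        if self._partial and x >= self._brk:
            if x == self._brk:
                return self._cstar
            # closed-form tail driven by the full agent alone
            return self._cstar + (
                self._full.inverse(x) - self._full.inverse(self._brk)
            ) / self._w_full
        if x <= self._x[0]:
            u = x - self._lo
            return self._tail_b * (u / self._u0) ** (self._gam_b + 1.0)
        if self._partial and x > self._top - self._v0:
            v = self._top - x
            return self._cstar - self._tail_t * (v / self._v0) ** (self._gam_t + 1.0)
        while x > self._x[-1]:
            if not self._extend_top():
                return float(self._I[-1])
        k = int(np.searchsorted(self._x, x))
        if self._x[k] == x:
            return float(self._I[k])
        return float(self._I[k - 1] + self._panel(self._x[k - 1], x)[0])

    def __call__(self, c):
        """Effect of mixture dose ``c``: f_AB(c), by monotone inversion of
        the tabulated inverse."""
        if isinstance(c, (list, tuple, np.ndarray)):
            return np.array([self(float(ci)) for ci in np.asarray(c, float).ravel()])
        c = float(c)
        if not c >= 0:
            raise DoseDomainError(f"dose must be non-negative, got {c}")
        if self._delegate is not None:
            return self._delegate(c)
        if c == 0.0:
            return self._lo
        if math.isinf(c):
            return self._sup
        if self._partial and c >= self._cstar:
            return self._full(
                self._full.inverse(self._brk) + self._w_full * (c - self._cstar)
            )
        if c <= self._I[0]:
            if self._tail_b <= 0.0:
                return self._lo
            u = self._u0 * (c / self._tail_b) ** (1.0 / (self._gam_b + 1.0))
            return self._lo + u
        if self._partial and c > self._cstar - self._tail_t:
            v = self._v0 * ((self._cstar - c) / self._tail_t) ** (1.0 / (self._gam_t + 1.0))
            return self._top - v
        while c > self._I[-1]:
            if not self._extend_top():
                return float(self._x[-1])
        k = int(np.searchsorted(self._I, c))
        if self._I[k] == c:
            return float(self._x[k])
        x0, x1 = self._x[k - 1], self._x[k]
        resid = c - self._I[k - 1]

        def g(x):
            return float(self._panel(x0, x)[0]) - resid

        xtol = max(self.settings.xtol_rel * (self._sup - self._lo), 5e-16)
        return float(brentq(g, x0, x1, xtol=xtol, rtol=8.9e-16))


def _power_tail(f1: float, f2: float, u0: float) -> tuple[float, float]:
    """Fit phi ~ C*u^gamma from values at u0 and 2*u0 and return
    (gamma, integral over [0, u0])."""
    if not (math.isfinite(f1) and math.isfinite(f2)) or f1 <= 0.0 or f2 <= 0.0:
        return 0.0, 0.0
    gam = math.log2(f2 / f1)
    gam = max(gam, -0.99)  # integrability guard; true exponents are > -1
    return gam, f1 * u0 / (gam + 1.0)


@lru_cache(maxsize=4096)
def _combined_cached(pair, lam: float, settings: HandSettings) -> CombinedCurve:
    return CombinedCurve(pair, lam, settings)


def combined_curve(pair, lam: float, settings: HandSettings = DEFAULT_SETTINGS) -> CombinedCurve:
    """Memoised :class:`CombinedCurve` factory (falls back to a fresh build
    for unhashable pairs, e.g. pairs of combined curves)."""
    try:
        return _combined_cached(pair, float(lam), settings)
    except TypeError:
        return CombinedCurve(pair, lam, settings)


def hand_inverse(pair, lam: float, x: float, settings: HandSettings = DEFAULT_SETTINGS) -> float:
    """Dose of the mixture C_lambda at which the Hand combined curve reaches
    effect ``x``; collapses to the single-curve inverse at lam in {0, 1}."""
    return combined_curve(pair, lam, settings).inverse(x)


def hand_combined_curve(pair, lam: float, c: float, settings: HandSettings = DEFAULT_SETTINGS) -> float:
    """Effect of dose ``c`` of the mixture C_lambda under the Hand model."""
    return combined_curve(pair, lam, settings)(c)


def c_star(pair, lam: float, settings: HandSettings = DEFAULT_SETTINGS) -> float:
    """Mixture dose at which the partial agent's maximal effect is attained.

    Defined for pairs whose maximal effects genuinely differ.  When the
    mixture is the pure partial agent (lam = 1 with A partial, or lam = 0
    with B partial) the level is only reached asymptotically and ``inf`` is
    returned.
    """
    partial = pair.partial_agent
    if partial is None:
        raise ValueError("c_star requires a full/partial pair (differing maximal effects)")
    if (partial == "a" and lam == 1.0) or (partial == "b" and lam == 0.0):
        return math.inf
    brk = min(pair.curve_a.e_max, pair.curve_b.e_max)
    if lam == 0.0 or lam == 1.0:  # pure full agent
        full = pair.curve_b if lam == 0.0 else pair.curve_a
        return full.inverse(brk)
    return combined_curve(pair, lam, settings).c_star


@dataclass(frozen=True)
class PartialAgentGeometry:
    """Limit isobole of the Hand model at the partial agent's maximal effect.

    Parametrised by the mixture ratio: (a*, b*) = (lam*c*, (1-lam)*c*).
    With A partial, b* is continuous, strictly decreasing in lam, and tends
    to 0 as lam -> 1 — in contrast with the Loewe model, whose limit isobole
    at the same level is the horizontal line b = f_B^{-1}(e_max_A).
    """

    lam: np.ndarray
    c_star: np.ndarray
    a_star: np.ndarray
    b_star: np.ndarray


def limit_isobole(pair, lam_grid=None, settings: HandSettings = DEFAULT_SETTINGS) -> PartialAgentGeometry:
    """Compute the Hand limit-isobole polyline over a grid of mixture ratios.

    Requires a full/partial pair.  At the pure-partial endpoint c* is
    infinite but the partial agent's own axis contribution of the *other*
    drug is 0 (the limit), which is what is reported there.
    """
    if pair.partial_agent is None:
        raise ValueError("limit_isobole requires a full/partial pair")
    if lam_grid is None:
        lam_grid = np.linspace(0.0, 1.0, 41)
    lam_grid = np.asarray(lam_grid, dtype=float)
    cs = np.array([c_star(pair, float(l), settings) for l in lam_grid])
    with np.errstate(invalid="ignore"):
        a = lam_grid * cs
        b = (1.0 - lam_grid) * cs
    # resolve inf * 0 at the pure-partial endpoint by its limit
    if pair.partial_agent == "a":
        b[lam_grid == 1.0] = 0.0
    else:
        a[lam_grid == 0.0] = 0.0
    return PartialAgentGeometry(lam=lam_grid, c_star=cs, a_star=a, b_star=b)


def tallarida_iterated(pair, a: float, b: float, N: int, order: str = "a_first") -> float:
    """Finite-N alternating dose-equivalence scheme linking Tallarida to Hand.

    Both doses are split into N equal pieces da = a/N and db = b/N which are
    applied alternately: each piece elevates the current effect level along
    its own curve from the equivalent dose,

        x <- f_A(da + f_A^{-1}(x)),   then   x <- f_B(db + f_B^{-1}(x)), ...

    N = 1 with ``order="a_first"`` reproduces the directional Tallarida
    model E_{T,A->B} exactly; as N grows the scheme converges (at rate
    ~ 1/N, independent of the order) to the Hand model, whose ODE is the
    first-order Taylor limit of one alternation cycle.

    When a curve is already saturated at the current level the step is taken
    with zero gain (the capping convention mirroring the Hand model's
    zero-extension of the sensitivity), so the scheme is total.
    """
    if N < 1 or int(N) != N:
        raise ValueError(f"N must be a positive integer, got {N}")
    if not (a >= 0 and b >= 0):
        raise DoseDomainError("doses must be non-negative")
    if order not in ("a_first", "b_first"):
        raise ValueError(f"order must be 'a_first' or 'b_first', got {order!r}")
    ca, cb = pair.curve_a, pair.curve_b
    steps = [(ca, a / N), (cb, b / N)]
    if order == "b_first":
        steps.reverse()
    (c1, d1), (c2, d2) = steps
    e1, e2 = c1.e_max, c2.e_max
    x = ca.e_min
    for _ in range(int(N)):
        if d1 > 0.0 and x < e1:
            x = c1._f(d1 + c1._finv0(x))
        if d2 > 0.0 and x < e2:
            x = c2._f(d2 + c2._finv0(x))
    return x
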