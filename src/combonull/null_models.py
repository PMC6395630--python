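"""Reference-effect surfaces E(a, b) for the five combination null models.

A *null model* predicts the effect of a dose pair (a, b) under the
assumption of zero interaction, given only the monotherapy dose-effect
curves f_A and f_B; measured effects above / below the reference are scored
synergistic / antagonistic.  Implemented here:

loewe
    Straight isoboles: E is the unique effect level x solving
    a/f_A^{-1}(x) + b/f_B^{-1}(x) = 1.  Undefined for levels at or above
    min(e_max_a, e_max_b) — a full/partial pair leaves the strip
    b >= f_B^{-1}(e_max_A) unassigned.
loewe_hsa
    Loewe where defined, extended by HSA beyond its domain; continuous
    across the horizontal limit isobole.
tallarida_ab / tallarida_ba
    Sequential dose equivalence, E = f_B(b + f_B^{-1}(f_A(a))) and the
    role-swapped counterpart.  Direction-dependent (not commutative); the
    two directions bracket a range.
tallarida_lb / tallarida_ub
    Pointwise min / max of the two directions.
hand
    Instantaneous dose equivalence: the combined curve solves an ODE in
    which both agents contribute linearly to the gain in effect (numerics
    in :mod:`combonull.hand_engine`).  Commutative, associative, satisfies
    the sham principle, defined for full and partial agents.
bliss
    Probabilistic independence E = f_A + f_B - f_A*f_B on effects
    normalised so the larger maximal effect is 1.
hsa
    Highest single agent, E = max(f_A, f_B).

Systematic orderings (wherever both sides are defined):
HSA <= Loewe <= Hand, HSA <= Bliss, TallaridaLB <= TallaridaUB.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .dose_response import HillCurve
from .errors import (
    DoseDomainError,
    EquivalentDoseUndefinedError,
    LoeweUndefinedError,
    UnnormalisedEffectError,
)
from .hand_engine import DEFAULT_SETTINGS, HandSettings, combined_curve

__all__ = [
    "MODEL_NAMES",
    "CurvePair",
    "NullModelSurface",
    "loewe_effect",
    "loewe_hsa_effect",
    "tallarida_effect",
    "TallaridaEnvelope",
    "tallarida_envelope",
    "bliss_effect",
    "hsa_effect",
    "hand_effect",
    "evaluate_surface",
    "RayCurve",
]

MODEL_NAMES = (
    "loewe",
    "loewe_hsa",
    "tallarida_ab",
    "tallarida_ba",
    "tallarida_lb",
    "tallarida_ub",
    "hand",
    "bliss",
    "hsa",
)

_EMAX_EQUAL_RTOL = 1e-9


@dataclass(frozen=True)
class CurvePair:
    """Two monotherapy dose-effect curves sharing a common baseline.

    The shared baseline reflects that e_min describes the untreated
    condition, which is the same regardless of which drug is (not) given.
    The curve with the lower maximal effect, if the maxima genuinely differ,
    is the *partial agent*.
    """

    curve_a: HillCurve
    curve_b: HillCurve

    def __post_init__(self):
        ea, eb = self.curve_a.e_min, self.curve_b.e_min
        if not math.isclose(ea, eb, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"curves must share the baseline effect (got {ea} and {eb})"
            )

    @property
    def e_min(self) -> float:
        return self.curve_a.e_min

    @property
    def e_max_top(self) -> float:
        """The larger of the two maximal effects (full agent's saturation)."""
        return max(self.curve_a.e_max, self.curve_b.e_max)

    @property
    def e_max_low(self) -> float:
        return min(self.curve_a.e_max, self.curve_b.e_max)

    @property
    def partial_agent(self) -> str | None:
        """``"a"`` / ``"b"`` for the curve saturating strictly lower, or
        None when the maximal effects agree within relative 1e-9."""
        span = self.e_max_top - self.e_min
        if abs(self.curve_a.e_max - self.curve_b.e_max) <= _EMAX_EQUAL_RTOL * span:
            return None
        return "a" if self.curve_a.e_max < self.curve_b.e_max else "b"

    @property
    def is_normalised(self) -> bool:
        """True when e_min = 0 and the larger e_max = 1 (Bliss convention)."""
        return abs(self.e_min) <= 1e-9 and abs(self.e_max_top - 1.0) <= 1e-9

    def swapped(self) -> "CurvePair":
        return CurvePair(self.curve_b, self.curve_a)

    def normalised(self) -> "CurvePair":
        """Affine effect rescaling: e_min -> 0, larger e_max -> 1."""
        top = self.e_max_top
        return CurvePair(
            self.curve_a.normalised(top=top), self.curve_b.normalised(top=top)
        )


def _check_doses(a: float, b: float) -> None:
    if not (a >= 0 and b >= 0) or math.isinf(a) or math.isinf(b):
        raise DoseDomainError(f"doses must be finite and non-negative, got ({a}, {b})")


def loewe_effect(pair: CurvePair, a: float, b: float) -> float:
    """Loewe reference effect: the unique level x with
    a/f_A^{-1}(x) + b/f_B^{-1}(x) = 1.

    The left-hand side is strictly decreasing in x, so a bracketed Brent
    search on (e_min, min(e_max_a, e_max_b)) finds the root.  Raises
    :class:`LoeweUndefinedError` (carrying the limiting level) when no level
    below the smaller maximal effect satisfies the equation — the
    partial-agent strip beyond the horizontal limit isobole.
    """
    _check_doses(a, b)
    ca, cb = pair.curve_a, pair.curve_b
    if a == 0.0 and b == 0.0:
        return pair.e_min
    if b == 0.0:
        return ca._f(a) if isinstance(ca, HillCurve) else ca(a)
    if a == 0.0:
        return cb._f(b) if isinstance(cb, HillCurve) else cb(b)
    x_max = pair.e_max_low
    rng = x_max - pair.e_min
    eps = 1e-12 * rng

    def g(x: float) -> float:
        return a / ca.inverse(x) + b / cb.inverse(x) - 1.0

    # exact definedness: the limit of the Loewe sum as x -> min(e_max).
    # A curve attaining x_max only asymptotically contributes 0 there; a
    # curve whose maximum lies strictly above contributes its finite term.
    span = pair.e_max_top - pair.e_min
    limit_sum = 0.0
    for curve, dose in ((ca, a), (cb, b)):
        if curve.e_max - x_max > _EMAX_EQUAL_RTOL * span:
            limit_sum += dose / curve.inverse(x_max)
    if limit_sum >= 1.0:
        raise LoeweUndefinedError(
            "Loewe model undefined: no effect level below "
            f"min(e_max) = {x_max} solves the additivity equation at "
            f"(a, b) = ({a}, {b})",
            limit_level=x_max,
        )
    lo = pair.e_min + eps
    hi = x_max - eps
    if g(lo) <= 0.0:
        # both doses below resolution: effect indistinguishable from baseline
        return lo
    if g(hi) > 0.0:
        # defined, but the root sits within eps of the limiting level
        return hi
    return float(brentq(g, lo, hi, xtol=1e-10 * rng, rtol=8.9e-16))


def hsa_effect(pair: CurvePair, a: float, b: float) -> float:
    """Highest-single-agent reference: max(f_A(a), f_B(b))."""
    _check_doses(a, b)
    return max(pair.curve_a(a), pair.curve_b(b))


def loewe_hsa_effect(pair: CurvePair, a: float, b: float) -> float:
    """Loewe where defined, HSA beyond its domain.

    For a partial agent A the extension takes over exactly on
    b >= f_B^{-1}(e_max_A), where HSA equals f_B(b); the combined surface is
    continuous across the horizontal limit isobole.
    """
    try:
        return loewe_effect(pair, a, b)
    except LoeweUndefinedError:
        return hsa_effect(pair, a, b)


def tallarida_effect(pair: CurvePair, a: float, b: float, direction: str = "a_to_b") -> float:
    """Directional Tallarida reference.

    ``a_to_b``: dose a is converted into its B-equivalent f_B^{-1}(f_A(a))
    and applied on top of b through f_B, E = f_B(b + f_B^{-1}(f_A(a))).
    ``b_to_a`` swaps the roles.  Raises
    :class:`EquivalentDoseUndefinedError` when the target curve saturates
    below the source effect (only possible when the source is the full
    agent).
    """
    _check_doses(a, b)
    if direction == "a_to_b":
        src, src_dose, tgt, tgt_dose, tgt_name = pair.curve_a, a, pair.curve_b, b, "b"
    elif direction == "b_to_a":
        src, src_dose, tgt, tgt_dose, tgt_name = pair.curve_b, b, pair.curve_a, a, "a"
    else:
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    x_equiv = src._f(src_dose) if isinstance(src, HillCurve) else src(src_dose)
    if x_equiv >= tgt.e_max:
        raise EquivalentDoseUndefinedError(
            f"curve_{tgt_name} saturates at {tgt.e_max} below the source effect "
            f"{x_equiv}; no equivalent dose exists",
            saturating=tgt_name,
        )
    if x_equiv <= tgt.e_min:
        d0 = 0.0
    else:
        d0 = tgt.inverse(x_equiv)
    total = tgt_dose + d0
    return tgt._f(total) if isinstance(tgt, HillCurve) else tgt(total)


class TallaridaEnvelope(NamedTuple):
    lb: float
    ub: float
    directions_defined: tuple[str, ...]


def tallarida_envelope(pair: CurvePair, a: float, b: float) -> TallaridaEnvelope:
    """Lower/upper Tallarida bounds, min and max of the two directions.

    If only one direction is evaluable (full/partial pairs at high doses of
    the full agent) that value serves as both bounds, flagged through
    ``directions_defined``.
    """
    values: dict[str, float] = {}
    errors = []
    for direction in ("a_to_b", "b_to_a"):
        try:
            values[direction] = tallarida_effect(pair, a, b, direction)
        except EquivalentDoseUndefinedError as err:
            errors.append(err)
    if not values:
        raise EquivalentDoseUndefinedError(
            "both Tallarida directions are undefined at "
            f"(a, b) = ({a}, {b})",
            saturating="a",
        ) from (errors[0] if errors else None)
    vals = list(values.values())
    return TallaridaEnvelope(min(vals), max(vals), tuple(values))


def bliss_effect(
    pair: CurvePair, a: float, b: float, normalisation: str = "strict"
) -> float:
    """Bliss independence reference E = f_A + f_B - f_A * f_B.

    Valid only on the normalised effect scale (e_min = 0, larger e_max = 1).
    ``normalisation="strict"`` (default) raises on an unnormalised pair;
    ``"auto"`` rescales internally and maps the result back to the original
    scale.
    """
    _check_doses(a, b)
    if pair.is_normalised:
        fa, fb = pair.curve_a(a), pair.curve_b(b)
        return fa + fb - fa * fb
    if normalisation != "auto":
        raise UnnormalisedEffectError(
            "Bliss requires e_min = 0 and the larger e_max = 1 "
            f"(got e_min={pair.e_min}, top e_max={pair.e_max_top}); "
            "pass normalisation='auto' or normalise the pair explicitly"
        )
    scale = pair.e_max_top - pair.e_min
    pa = (pair.curve_a(a) - pair.e_min) / scale
    pb = (pair.curve_b(b) - pair.e_min) / scale
    return pair.e_min + scale * (pa + pb - pa * pb)


def hand_effect(
    pair: CurvePair, a: float, b: float, settings: HandSettings = DEFAULT_SETTINGS
) -> float:
    """Hand reference effect E_H(a, b) = f_AB,lam(a + b) with
    lam = a / (a + b); (0, 0) maps to the baseline directly."""
    _check_doses(a, b)
    if a == 0.0 and b == 0.0:
        return pair.e_min
    lam = a / (a + b)
    return combined_curve(pair, lam, settings)(a + b)


_MODEL_FUNCS = {
    "loewe": loewe_effect,
    "loewe_hsa": loewe_hsa_effect,
    "hsa": hsa_effect,
    "hand": hand_effect,
}


@dataclass(frozen=True)
class NullModelSurface:
    """An evaluatable reference surface for one named model and curve pair.

    ``effect`` raises structured errors inside undefined regions;
    ``effect_status`` converts them into (nan, status) codes — the gaps are
    scientific content, never silent NaNs.

    Options
    -------
    loewe_extension
        If True, the ``loewe`` surface falls back to HSA where Loewe is
        undefined (reported with status ``"extended_hsa"``).
    bliss_normalisation
        ``"strict"`` or ``"auto"`` (see :func:`bliss_effect`).
    """

    model: str
    pair: CurvePair
    loewe_extension: bool = False
    bliss_normalisation: str = "strict"
    settings: HandSettings = field(default=DEFAULT_SETTINGS)

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {MODEL_NAMES}"
            )

    @property
    def e_min(self) -> float:
        return self.pair.e_min

    def effect(self, a: float, b: float) -> float:
        m = self.model
        if m == "loewe" and self.loewe_extension:
            return loewe_hsa_effect(self.pair, a, b)
        if m in _MODEL_FUNCS:
            if m == "hand":
                return hand_effect(self.pair, a, b, self.settings)
            return _MODEL_FUNCS[m](self.pair, a, b)
        if m == "bliss":
            return bliss_effect(self.pair, a, b, self.bliss_normalisation)
        if m == "tallarida_ab":
            return tallarida_effect(self.pair, a, b, "a_to_b")
        if m == "tallarida_ba":
            return tallarida_effect(self.pair, a, b, "b_to_a")
        env = tallarida_envelope(self.pair, a, b)
        return env.lb if m == "tallarida_lb" else env.ub

    def effect_status(self, a: float, b: float) -> tuple[float, str]:
        """Reference effect with a per-point status code instead of raising.

        Statuses: ``"ok"``, ``"extended_hsa"`` (Loewe gap filled by HSA),
        ``"one_direction"`` (Tallarida envelope collapsed onto the single
        defined direction), ``"undefined_loewe"``, ``"undefined_tallarida"``.
        """
        m = self.model
        try:
            if m == "loewe" and self.loewe_extension:
                try:
                    return loewe_effect(self.pair, a, b), "ok"
                except LoeweUndefinedError:
                    return hsa_effect(self.pair, a, b), "extended_hsa"
            if m in ("tallarida_lb", "tallarida_ub"):
                env = tallarida_envelope(self.pair, a, b)
                val = env.lb if m == "tallarida_lb" else env.ub
                status = "ok" if len(env.directions_defined) == 2 else "one_direction"
                return val, status
            return self.effect(a, b), "ok"
        except LoeweUndefinedError:
            return math.nan, "undefined_loewe"
        except EquivalentDoseUndefinedError:
            return math.nan, "undefined_tallarida"

    def evaluate(self, grid_a, grid_b) -> tuple[np.ndarray, np.ndarray]:
        return evaluate_surface(self, grid_a, grid_b)

    def ray_inverse(self, lam: float, x: float) -> float | None:
        """Dose c with E(lam*c, (1-lam)*c) = x, when available in closed or
        tabulated form (Hand: the combined-curve inverse).  None means the
        caller should fall back to a generic root search."""
        if self.model == "hand":
            return combined_curve(self.pair, lam, self.settings).inverse(x)
        return None


def evaluate_surface(surface: NullModelSurface, grid_a, grid_b) -> tuple[np.ndarray, np.ndarray]:
    """Reference-effect matrix over a dose grid, with per-cell status codes.

    ``grid_a`` indexes rows, ``grid_b`` columns; both must be ascending and
    non-negative.  Cells where the model is undefined hold NaN and a reason
    code; a leading zero dose row/column reproduces the monotherapy curves
    exactly.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    for g, name in ((grid_a, "grid_a"), (grid_b, "grid_b")):
        if np.any(g < 0):
            raise DoseDomainError(f"{name} contains negative doses")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly ascending")
    values = np.empty((grid_a.size, grid_b.size))
    status = np.empty((grid_a.size, grid_b.size), dtype=object)
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            values[i, j], status[i, j] = surface.effect_status(float(a), float(b))
    return values, status


class RayCurve:
    """Dose-effect curve of a surface along the fixed-ratio ray
    gamma(c) = (lam*c, (1-lam)*c) — a vertical ray-cut through any surface.

    Satisfies the curve protocol far enough (e_min, e_max, call, inverse) to
    serve as a monotherapy in a derived pair, which is how associativity of
    a null model is exercised: ray-cuts become the new coordinate axes.  The
    inverse is a bracketed root search (the surface is increasing along
    rays).  ``e_max`` must be supplied when the surface cannot report an
    attainable supremum itself.
    """

    def __init__(self, surface, lam: float, e_max: float):
        self.surface = surface
        self.lam = float(lam)
        self.e_min = surface.e_min
        self.e_max = float(e_max)

    def __call__(self, c):
        if isinstance(c, (list, tuple, np.ndarray)):
            return np.array([self(float(ci)) for ci in np.asarray(c, float).ravel()])
        c = float(c)
        if c == 0.0:
            return self.e_min
        return self.surface.effect(self.lam * c, (1.0 - self.lam) * c)

    def inverse(self, x: float) -> float:
        if x == self.e_min:
            return 0.0
        if not self.e_min < x < self.e_max:
            raise ValueError(f"effect {x} outside ({self.e_min}, {self.e_max})")
        c_hi = 1.0
        for _ in range(200):
            if self(c_hi) >= x:
                break
            c_hi *= 2.0
        else:
            raise ValueError(f"effect {x} not reached along the ray")
        return float(brentq(lambda c: self(c) - x, 0.0, c_hi, xtol=1e-14, rtol=8.9e-16))
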