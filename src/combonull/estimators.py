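"""scikit-learn-style estimators.

The fit/predict-shaped parts of the toolkit live here:

* :class:`HillCurveRegressor` — four-parameter Hill fit of a monotherapy
  titration (dose -> effect), multi-start least squares.
* :class:`ZeroEffectRegressor` — flat competitor model for BIC selection.
* :class:`NullModelReference` — fits the two monotherapy curves from the
  axis rows of a combination experiment and predicts the reference effect of
  a chosen null model for arbitrary dose pairs.
* :class:`SynergyClassifier` — same fit, but predicts a per-point verdict
  (synergistic / antagonistic / additive / undefined) for rows carrying a
  measured effect.

All follow the sklearn conventions (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``fit`` returns ``self``) and compose
with sklearn model-selection utilities.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

from .dose_response import HillCurve, ZeroEffectCurve
from .errors import UnderdeterminedFitError
from .null_models import CurvePair, NullModelSurface

__all__ = [
    "HillCurveRegressor",
    "ZeroEffectRegressor",
    "NullModelReference",
    "SynergyClassifier",
]


def _gaussian_loglik(rss: float, m: int) -> float:
    """Profile log-likelihood at the MLE noise variance sigma^2 = rss/m."""
    sigma2 = max(rss / m, 1e-300)
    return -0.5 * m * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _as_dose_vector(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError(f"expected a single dose column, got shape {X.shape}")
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError(f"expected a 1d or (n, 1) dose array, got shape {X.shape}")
    if not np.all(np.isfinite(X)) or np.any(X < 0):
        raise ValueError("doses must be finite and non-negative")
    return X


class HillCurveRegressor(RegressorMixin, BaseEstimator):
    """Least-squares Hill curve fit under Gaussian noise.

    EC50 and the Hill coefficient are fitted on the log scale (positivity),
    with ``n_starts`` Latin-hypercube multi-starts to cope with the
    multi-modal Hill objective; the best residual sum of squares wins.
    Deterministic for a fixed ``random_state``.

    Attributes (after fit)
    ----------------------
    curve_ : HillCurve
    e_min_, e_max_, ec50_, n_ : float
    rss_ : float                  residual sum of squares
    sigma_ : float                MLE noise sd
    log_likelihood_ : float       Gaussian profile log-likelihood
    converged_ : bool             best start reported optimizer success
    """

    def __init__(
        self,
        n_starts: int = 10,
        random_state: int | None = 0,
        max_nfev: int | None = None,
    ):
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_nfev = max_nfev

    def fit(self, X, y):
        dose = _as_dose_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != dose.shape:
            raise ValueError("dose and effect arrays must align")
        if not np.all(np.isfinite(y)):
            raise ValueError("effects must be finite")
        n_distinct = np.unique(dose).size
        if n_distinct < 4:
            raise UnderdeterminedFitError(
                f"Hill fit needs >= 4 distinct doses, got {n_distinct}"
            )
        self.n_features_in_ = 1

        span = float(y.max() - y.min())
        pos = dose[dose > 0]
        lo_d, hi_d = float(pos.min()), float(pos.max())

        def unpack(theta):
            e_min = theta[0]
            e_max = e_min + math.exp(theta[1])
            return e_min, e_max, math.exp(theta[2]), math.exp(theta[3])

        def resid(theta):
            e_min, e_max, ec50, n = unpack(theta)
            with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
                pred = e_min + (e_max - e_min) / (1.0 + (ec50 / np.maximum(dose, 1e-300)) ** n)
            pred = np.where(dose == 0, e_min, pred)
            return pred - y

        span_f = max(span, 1e-3)
        lower = np.array(
            [y.min() - 0.5 * span_f, math.log(0.25 * span_f), math.log(0.5 * lo_d), math.log(0.3)]
        )
        upper = np.array(
            [y.min() + 0.25 * span_f, math.log(2.5 * span_f), math.log(2.0 * hi_d), math.log(6.0)]
        )
        sampler = qmc.LatinHypercube(d=4, seed=self.random_state)
        starts = lower + sampler.random(self.n_starts) * (upper - lower)

        best = None
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=self.max_nfev)
            except Exception:  # numerical blow-up of a bad start
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all Hill fit starts failed")
        e_min, e_max, ec50, n = unpack(best.x)
        self.curve_ = HillCurve(e_min, e_max, ec50, n)
        self.e_min_, self.e_max_, self.ec50_, self.n_ = e_min, e_max, ec50, n
        r = resid(best.x)
        self.rss_ = float(r @ r)
        m = dose.size
        self.n_obs_ = m
        self.sigma_ = math.sqrt(max(self.rss_ / m, 0.0))
        self.log_likelihood_ = _gaussian_loglik(self.rss_, m)
        self.converged_ = bool(best.status > 0)
        return self

    def predict(self, X):
        dose = _as_dose_vector(X)
        return np.asarray(self.curve_(dose))


class ZeroEffectRegressor(RegressorMixin, BaseEstimator):
    """Flat (dose-independent) effect model; BIC competitor of the Hill fit."""

    def fit(self, X, y):
        dose = _as_dose_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != dose.shape:
            raise ValueError("dose and effect arrays must align")
        self.n_features_in_ = 1
        self.level_ = float(y.mean())
        self.curve_ = ZeroEffectCurve(self.level_)
        r = y - self.level_
        self.rss_ = float(r @ r)
        m = y.size
        self.n_obs_ = m
        self.sigma_ = math.sqrt(self.rss_ / m)
        self.log_likelihood_ = _gaussian_loglik(self.rss_, m)
        return self

    def predict(self, X):
        dose = _as_dose_vector(X)
        return np.full(dose.shape, self.level_)


def _fit_pair_from_axes(X, y, n_starts, random_state):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"expected dose pairs of shape (n, 2), got {X.shape}")
    on_a = X[:, 1] == 0
    on_b = X[:, 0] == 0
    fits = []
    for mask, col in ((on_a, 0), (on_b, 1)):
        reg = HillCurveRegressor(n_starts=n_starts, random_state=random_state)
        reg.fit(X[mask, col], y[mask])
        fits.append(reg)
    fit_a, fit_b = fits
    # impose the shared-baseline assumption: both curves describe the same
    # untreated condition, so the two independent e_min estimates are pooled
    # (record-weighted average) before the pair is assembled
    wa, wb = fit_a.n_obs_, fit_b.n_obs_
    e_min = (wa * fit_a.e_min_ + wb * fit_b.e_min_) / (wa + wb)
    curve_a = HillCurve(e_min, max(fit_a.e_max_, e_min + 1e-9), fit_a.ec50_, fit_a.n_)
    curve_b = HillCurve(e_min, max(fit_b.e_max_, e_min + 1e-9), fit_b.ec50_, fit_b.n_)
    return CurvePair(curve_a, curve_b), fit_a, fit_b


class NullModelReference(RegressorMixin, BaseEstimator):
    """Null-model reference predictor fitted from monotherapy axis data.

    ``fit(X, y)`` takes dose pairs X of shape (n, 2); rows with dose_b = 0
    form drug A's titration and rows with dose_a = 0 drug B's (the (0, 0)
    row contributes to both).  ``predict`` returns the chosen model's
    reference effect per dose pair, NaN where the model is undefined (or
    the HSA-extended value for the Loewe model when ``loewe_extension``).
    """

    def __init__(
        self,
        model: str = "hand",
        n_starts: int = 10,
        random_state: int | None = 0,
        loewe_extension: bool = False,
        bliss_normalisation: str = "strict",
    ):
        self.model = model
        self.n_starts = n_starts
        self.random_state = random_state
        self.loewe_extension = loewe_extension
        self.bliss_normalisation = bliss_normalisation

    def fit(self, X, y):
        pair, fit_a, fit_b = _fit_pair_from_axes(X, y, self.n_starts, self.random_state)
        self.pair_ = pair
        self.fit_a_, self.fit_b_ = fit_a, fit_b
        self.surface_ = NullModelSurface(
            self.model,
            pair,
            loewe_extension=self.loewe_extension,
            bliss_normalisation=self.bliss_normalisation,
        )
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for i, (a, b) in enumerate(X):
            out[i], _ = self.surface_.effect_status(float(a), float(b))
        return out


class SynergyClassifier(BaseEstimator):
    """Per-point synergy verdicts against one null model.

    Rows are (dose_a, dose_b, measured_effect).  ``fit`` learns the two
    monotherapy Hill curves from the axis rows (where one dose is zero);
    ``predict`` labels every row synergistic / antagonistic / additive by
    comparing the measured effect against the reference within an additive
    band of half-width ``delta`` (undefined where the reference is).
    """

    def __init__(
        self,
        model: str = "hand",
        delta: float = 0.01,
        n_starts: int = 10,
        random_state: int | None = 0,
        loewe_extension: bool = False,
        bliss_normalisation: str = "strict",
    ):
        self.model = model
        self.delta = delta
        self.n_starts = n_starts
        self.random_state = random_state
        self.loewe_extension = loewe_extension
        self.bliss_normalisation = bliss_normalisation

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                f"expected rows (dose_a, dose_b, effect), got shape {X.shape}"
            )
        pair, fit_a, fit_b = _fit_pair_from_axes(
            X[:, :2], X[:, 2], self.n_starts, self.random_state
        )
        self.pair_ = pair
        self.fit_a_, self.fit_b_ = fit_a, fit_b
        self.surface_ = NullModelSurface(
            self.model,
            pair,
            loewe_extension=self.loewe_extension,
            bliss_normalisation=self.bliss_normalisation,
        )
        self.classes_ = np.array(
            ["additive", "antagonistic", "synergistic", "undefined"]
        )
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        labels = []
        for a, b, measured in X:
            ref, status = self.surface_.effect_status(float(a), float(b))
            if status.startswith("undefined") or math.isnan(measured):
                labels.append("undefined")
            elif measured > ref + self.delta:
                labels.append("synergistic")
            elif measured < ref - self.delta:
                labels.append("antagonistic")
            else:
                labels.append("additive")
        return np.asarray(labels)
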