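"""Isoboles, convexity diagnostics, synergy classification and cross-model
comparison.

An isobole is the level set of a reference surface at a fixed effect, the
horizontal cut of the effect surface projected into the (dose A, dose B)
plane.  It separates the plane into synergy (below) and antagonism (above).
Loewe isoboles are straight by construction; Hand isoboles are convex,
which is why the Hand reference bounds the Loewe reference from above.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr

from .errors import EffectOutOfRangeError, IsoboleError
from .null_models import NullModelSurface

__all__ = [
    "Isobole",
    "compute_isobole",
    "ConvexityReport",
    "convexity_diagnostic",
    "classify",
    "SynergyCall",
    "ModelComparison",
    "compare_models",
    "plot_isobologram",
]

VERDICTS = ("synergistic", "antagonistic", "additive", "undefined")


@dataclass(frozen=True)
class Isobole:
    """Polyline level set of a surface at effect ``level``.

    Vertices are parametrised by the ray angle lam = a/(a+b), ordered from
    the pure-A axis (lam = 1) to the pure-B axis (lam = 0), so the
    a-coordinates decrease while the b-coordinates increase along the
    polyline.  Rays on which the level is unreachable (or the model
    undefined) carry NaN vertices and ``status == "truncated"``.
    """

    model: str
    level: float
    lam: np.ndarray
    a: np.ndarray
    b: np.ndarray
    valid: np.ndarray
    status: str  # "closed" | "truncated"


def compute_isobole(surface: NullModelSurface, x: float, resolution: int = 50) -> Isobole:
    """Trace the isobole of ``surface`` at effect level ``x``.

    For each of ``resolution`` ray angles lam the dose c solving
    E(lam*c, (1-lam)*c) = x is found — directly from the combined-curve
    inverse where the surface provides it (Hand), otherwise by a bracketed
    root search in c (every surface here is increasing along rays).
    """
    e_min = surface.e_min
    if not x > e_min:
        raise IsoboleError(f"level {x} not above the baseline {e_min}")
    lams = np.linspace(1.0, 0.0, resolution)
    a = np.full(resolution, np.nan)
    b = np.full(resolution, np.nan)
    valid = np.zeros(resolution, dtype=bool)
    for i, lam in enumerate(lams):
        c = _ray_solve(surface, float(lam), x)
        if c is not None:
            a[i], b[i] = lam * c, (1.0 - lam) * c
            valid[i] = True
    if not valid.any():
        raise IsoboleError(
            f"effect level {x} unattainable on every ray for model {surface.model}"
        )
    status = "closed" if valid.all() else "truncated"
    return Isobole(surface.model, x, lams, a, b, valid, status)


def _ray_solve(surface: NullModelSurface, lam: float, x: float) -> float | None:
    try:
        c = surface.ray_inverse(lam, x)
    except EffectOutOfRangeError:
        return None
    if c is not None:
        return c

    def f(c: float) -> float:
        val, status = surface.effect_status(lam * c, (1.0 - lam) * c)
        if not status.startswith("undefined"):
            return val
        # inside an undefined strip the defined part of the surface has
        # already saturated above any traceable level: treat as +inf
        return math.inf

    if f(0.0) >= x:
        return None
    c_hi = 1.0
    for _ in range(200):
        if f(c_hi) >= x:
            break
        c_hi *= 2.0
    else:
        return None
    return float(brentq(lambda c: f(c) - x, 0.0, c_hi, xtol=1e-13, rtol=8.9e-16))


@dataclass(frozen=True)
class ConvexityReport:
    """Discrete convexity diagnostic of an isobole, b as a function of a.

    ``min_second_difference`` is the smallest increment between successive
    chord slopes (non-negative for a convex polyline); the verdict compares
    it against ``-tol * scale`` with ``scale`` the larger of 1 and the
    slope magnitude, so straight isoboles pass at float noise.  Truncated
    isoboles are analysed piecewise over contiguous valid runs.
    """

    min_second_difference: float
    convex: bool
    n_vertices: int
    scale: float


def convexity_diagnostic(isobole: Isobole, tol: float = 1e-7) -> ConvexityReport:
    runs = _valid_runs(isobole.valid)
    min_d2 = math.inf
    scale = 1.0
    n_used = 0
    for run in runs:
        a = isobole.a[run]
        b = isobole.b[run]
        if a.size < 3:
            continue
        order = np.argsort(a)
        a, b = a[order], b[order]
        da = np.diff(a)
        keep = da > 0
        slopes = np.diff(b)[keep] / da[keep]
        if slopes.size < 2:
            continue
        d2 = np.diff(slopes)
        min_d2 = min(min_d2, float(d2.min()))
        scale = max(scale, float(np.abs(slopes).max()))
        n_used += a.size
    if n_used < 3:
        raise IsoboleError("convexity diagnostic needs at least 3 usable vertices")
    return ConvexityReport(
        min_second_difference=min_d2,
        convex=min_d2 >= -tol * scale,
        n_vertices=n_used,
        scale=scale,
    )


def _valid_runs(valid: np.ndarray) -> list[np.ndarray]:
    runs = []
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    start = 0
    for stop in list(breaks) + [idx.size - 1]:
        runs.append(idx[start : stop + 1])
        start = stop + 1
    return runs


@dataclass(frozen=True)
class SynergyCall:
    """Verdict for one dose pair under one null model."""

    dose_a: float
    dose_b: float
    measured: float
    model: str
    reference: float
    status: str
    verdict: str
    delta: float


def classify(
    checkerboard: pd.DataFrame,
    surfaces: list[NullModelSurface],
    delta: float = 0.01,
) -> pd.DataFrame:
    """Classify measured dose pairs against each reference surface.

    ``checkerboard`` needs columns ``dose_a``, ``dose_b``, ``effect``;
    replicates (a ``replicate`` column) are averaged per dose pair first.
    A point is synergistic when measured > reference + delta, antagonistic
    when measured < reference - delta, additive within the band, and
    undefined when the reference itself is (never dropped silently).
    ``delta = 0`` reproduces the strict synergistic/antagonistic dichotomy.

    Because the references are systematically ordered
    (HSA <= Loewe <= Hand, TallaridaLB <= TallaridaUB), verdicts are
    ordered too: a point antagonistic against a lower reference cannot be
    synergistic against a higher one.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    agg = (
        checkerboard.groupby(["dose_a", "dose_b"], as_index=False)["effect"].mean()
    )
    rows = []
    for _, rec in agg.iterrows():
        a, b, measured = float(rec.dose_a), float(rec.dose_b), float(rec.effect)
        for surface in surfaces:
            ref, status = surface.effect_status(a, b)
            if status.startswith("undefined") or math.isnan(measured):
                verdict = "undefined"
            elif measured > ref + delta:
                verdict = "synergistic"
            elif measured < ref - delta:
                verdict = "antagonistic"
            else:
                verdict = "additive"
            rows.append(
                SynergyCall(a, b, measured, surface.model, ref, status, verdict, delta)
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ModelComparison:
    """Cross-model comparison of reference effects on a shared grid.

    ``table`` is the long per-cell record; ``differences`` summarises the
    signed pairwise gaps reference(x) - reference(y) over cells where both
    are defined; ``spearman`` holds the rank-correlation matrix.
    """

    table: pd.DataFrame
    differences: pd.DataFrame
    spearman: pd.DataFrame
    n_undefined: pd.Series


def compare_models(
    surfaces: list[NullModelSurface], grid_a, grid_b
) -> ModelComparison:
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    recs = []
    for surface in surfaces:
        values, status = surface.evaluate(grid_a, grid_b)
        for i, a in enumerate(grid_a):
            for j, b in enumerate(grid_b):
                recs.append(
                    (a, b, surface.model, values[i, j], status[i, j])
                )
    table = pd.DataFrame(
        recs, columns=["dose_a", "dose_b", "model", "reference", "status"]
    )
    wide = table.pivot_table(
        index=["dose_a", "dose_b"], columns="model", values="reference"
    )
    models = [s.model for s in surfaces]
    wide = wide[models]
    diff_rows = []
    corr = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
    for mi in models:
        for mj in models:
            if mi == mj:
                continue
            both = wide[[mi, mj]].dropna()
            d = both[mi] - both[mj]
            if len(both) >= 2:
                rho = spearmanr(both[mi], both[mj]).statistic
            else:
                rho = math.nan
            corr.loc[mi, mj] = rho
            diff_rows.append(
                {
                    "model_x": mi,
                    "model_y": mj,
                    "n": len(both),
                    "mean": d.mean(),
                    "q05": d.quantile(0.05) if len(d) else math.nan,
                    "q50": d.quantile(0.50) if len(d) else math.nan,
                    "q95": d.quantile(0.95) if len(d) else math.nan,
                    "frac_positive": (d > 0).mean() if len(d) else math.nan,
                }
            )
    differences = pd.DataFrame(diff_rows)
    n_undefined = table[table.status.str.startswith("undefined")].groupby("model").size()
    n_undefined = n_undefined.reindex(models, fill_value=0)
    return ModelComparison(table, differences, corr, n_undefined)


def plot_isobologram(surfaces, level: float, resolution: int = 60, ax=None):
    """Overlay the isoboles of several surfaces at one effect level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for surface in surfaces:
        iso = compute_isobole(surface, level, resolution)
        ax.plot(iso.a[iso.valid], iso.b[iso.valid], label=surface.model)
    ax.set_xlabel("dose A")
    ax.set_ylabel("dose B")
    ax.set_title(f"isoboles at effect {level:g}")
    ax.legend(fontsize=8)
    return ax
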