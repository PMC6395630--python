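"""Synthetic monotherapy and checkerboard screens with known ground truth.

The generator emulates the measurement design of large oncology combination
screens: per-drug monotherapy titrations plus a 4-by-4 factorial dose grid
("checkerboard") per combination, with additive Gaussian readout noise.
The combination effects are drawn around the reference surface of a chosen
ground-truth null model, optionally perturbed by a multiplicative (or
additive) interaction factor, so that every downstream module — fitting,
reference evaluation, classification — can be tested closed-loop against a
known truth without external data.

Defaults (chosen once as a realistic desk-scale regime): 4 log-spaced
checkerboard doses per drug anchored at the EC50 (EC50 * 2^{-2..1}), 7-dose
monotherapy titrations (EC50 * 2^{-3..3}), 3 replicates, noise sd 0.02 on
the normalised effect scale, interaction factor kappa = 1 (no interaction).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import HillCurve
from .null_models import CurvePair, NullModelSurface

__all__ = [
    "ScreenSpec",
    "CheckerboardResult",
    "default_monotherapy_doses",
    "default_checkerboard_doses",
    "generate_monotherapy",
    "generate_checkerboard",
]


def default_monotherapy_doses(curve: HillCurve, n: int = 7) -> np.ndarray:
    """Log-spaced titration anchored at the EC50: ec50 * 2^{-3..3}."""
    return curve.ec50 * 2.0 ** np.linspace(-3, 3, n)


def default_checkerboard_doses(curve: HillCurve) -> np.ndarray:
    """Four log-spaced combination doses, ec50 * {1/4, 1/2, 1, 2}."""
    return curve.ec50 * 2.0 ** np.arange(-2, 2, dtype=float)


@dataclass
class ScreenSpec:
    """Recipe for one synthetic two-drug screen.

    kappa multiplies the reference effect (measured about the baseline) and
    the result is clipped to the attainable range, so kappa > 1 builds in
    synergy and kappa < 1 antagonism relative to ``true_model``;
    ``interaction="additive"`` instead adds ``kappa`` as an offset.  The
    seed fixes the full output bitwise.
    """

    pair: CurvePair
    true_model: str = "hand"
    doses_a: np.ndarray | None = None
    doses_b: np.ndarray | None = None
    mono_doses_a: np.ndarray | None = None
    mono_doses_b: np.ndarray | None = None
    kappa: float = 1.0
    interaction: str = "multiplicative"  # or "additive"
    noise_sd: float = 0.02
    replicates: int = 3
    seed: int | None = 0
    loewe_extension: bool = False
    extra_surface_kwargs: dict = field(default_factory=dict)


@dataclass
class CheckerboardResult:
    checkerboard: pd.DataFrame
    monotherapy_a: pd.DataFrame
    monotherapy_b: pd.DataFrame
    truth: dict


def generate_monotherapy(
    curve: HillCurve,
    doses=None,
    replicates: int = 3,
    noise_sd: float = 0.02,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    drug: str = "A",
) -> pd.DataFrame:
    """Monotherapy table: effect = f(dose) + N(0, sd), long format with
    columns drug, dose, effect, replicate.  Reproducible under ``seed``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    if doses is None:
        doses = default_monotherapy_doses(curve)
    doses = np.asarray(doses, dtype=float)
    dose_col = np.tile(doses, replicates)
    rep_col = np.repeat(np.arange(replicates), doses.size)
    clean = curve(dose_col)
    effect = clean + rng.normal(0.0, noise_sd, size=dose_col.size)
    return pd.DataFrame(
        {"drug": drug, "dose": dose_col, "effect": effect, "replicate": rep_col}
    )


def generate_checkerboard(spec: ScreenSpec) -> CheckerboardResult:
    """Checkerboard + monotherapy tables drawn around a ground-truth model.

    measured = clip(interaction(reference), attainable range) + noise.
    Cells where the true model is undefined (Loewe without extension) are
    emitted with NaN effect and a reason status — flagged, not fabricated.
    """
    pair = spec.pair
    rng = np.random.default_rng(spec.seed)
    surface = NullModelSurface(
        spec.true_model,
        pair,
        loewe_extension=spec.loewe_extension,
        **spec.extra_surface_kwargs,
    )
    da = (
        np.asarray(spec.doses_a, float)
        if spec.doses_a is not None
        else default_checkerboard_doses(pair.curve_a)
    )
    db = (
        np.asarray(spec.doses_b, float)
        if spec.doses_b is not None
        else default_checkerboard_doses(pair.curve_b)
    )
    e_min, e_top = pair.e_min, pair.e_max_top
    rows = []
    for a in da:
        for b in db:
            ref, status = surface.effect_status(float(a), float(b))
            if status.startswith("undefined"):
                for r in range(spec.replicates):
                    rows.append(("A", "B", a, b, np.nan, r, status))
                continue
            if spec.interaction == "multiplicative":
                mean = e_min + spec.kappa * (ref - e_min)
            elif spec.interaction == "additive":
                mean = ref + spec.kappa
            else:
                raise ValueError(f"unknown interaction mode {spec.interaction!r}")
            mean = float(np.clip(mean, e_min, e_top))
            for r in range(spec.replicates):
                eff = mean + rng.normal(0.0, spec.noise_sd)
                rows.append(("A", "B", a, b, eff, r, status))
    checkerboard = pd.DataFrame(
        rows,
        columns=["drug_a", "drug_b", "dose_a", "dose_b", "effect", "replicate", "status"],
    )
    mono_a = generate_monotherapy(
        pair.curve_a, spec.mono_doses_a, spec.replicates, spec.noise_sd, rng=rng, drug="A"
    )
    mono_b = generate_monotherapy(
        pair.curve_b, spec.mono_doses_b, spec.replicates, spec.noise_sd, rng=rng, drug="B"
    )
    truth = {
        "true_model": spec.true_model,
        "kappa": spec.kappa,
        "interaction": spec.interaction,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "curve_a": vars_of(pair.curve_a),
        "curve_b": vars_of(pair.curve_b),
    }
    return CheckerboardResult(checkerboard, mono_a, mono_b, truth)


def vars_of(curve: HillCurve) -> dict:
    return {"e_min": curve.e_min, "e_max": curve.e_max, "ec50": curve.ec50, "n": curve.n}
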