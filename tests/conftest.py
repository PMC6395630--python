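"""Shared fixtures and random-instance generators.

Random Hill pairs are drawn on the normalised effect scale (baseline 0,
larger maximal effect 1) with EC50 log-uniform in [0.3, 3] and Hill
coefficients in [0.5, 4] — the regime typical of cell-viability screens.
"""
from __future__ import annotations

import numpy as np
import pytest

from combonull import CurvePair, HillCurve


def random_curve(rng: np.random.Generator, e_max: float = 1.0) -> HillCurve:
    return HillCurve(
        0.0,
        e_max,
        float(np.exp(rng.uniform(np.log(0.3), np.log(3.0)))),
        float(rng.uniform(0.5, 4.0)),
    )


def random_pair(
    rng: np.random.Generator, partial_fraction: float = 0.3
) -> CurvePair:
    """Normalised pair; with probability ``partial_fraction`` drug A is a
    partial agent saturating in [0.5, 0.95]."""
    e_max_a = 1.0
    if rng.random() < partial_fraction:
        e_max_a = float(rng.uniform(0.5, 0.95))
    return CurvePair(random_curve(rng, e_max_a), random_curve(rng, 1.0))


def random_constant_potency_pair(rng: np.random.Generator) -> tuple[CurvePair, float]:
    """Pair with constant potency ratio alpha = ec50_a / ec50_b (shared
    e_max and n: parallel curves on the log-dose axis)."""
    n = float(rng.uniform(0.6, 3.5))
    ka = float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
    kb = float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
    return CurvePair(HillCurve(0, 1, ka, n), HillCurve(0, 1, kb, n)), ka / kb


def random_doses(rng: np.random.Generator, k: int = 8, lo=0.05, hi=5.0) -> np.ndarray:
    return np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), k)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def simple_pair() -> CurvePair:
    return CurvePair(HillCurve(0, 1, 1.0, 1.5), HillCurve(0, 1, 2.0, 2.5))


@pytest.fixture
def partial_pair() -> CurvePair:
    """A partial (saturates at 0.8), B full."""
    return CurvePair(HillCurve(0, 0.8, 1.0, 2.0), HillCurve(0, 1.0, 1.0, 2.0))
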