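"""Isobole extraction, convexity diagnostics, synergy calls and the
cross-model comparison summaries."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from combonull import (
    CurvePair,
    HillCurve,
    NullModelSurface,
    classify,
    compare_models,
    compute_isobole,
    convexity_diagnostic,
    limit_isobole,
)
from combonull.errors import IsoboleError

from conftest import random_pair


class _SyntheticSurface:
    """Hand-crafted monotone surface for negative controls: effect =
    g(norm(a, b)) with circular level sets (concave b(a) isoboles)."""

    model = "synthetic_circular"
    e_min = 0.0

    def effect(self, a, b):
        r = math.hypot(a, b)
        return r / (1.0 + r)

    def effect_status(self, a, b):
        return self.effect(a, b), "ok"

    def ray_inverse(self, lam, x):
        return None


class TestComputeIsobole:
    def test_loewe_isobole_is_straight(self, simple_pair):
        iso = compute_isobole(NullModelSurface("loewe", simple_pair), 0.5, 40)
        resid = (
            iso.a[iso.valid] / simple_pair.curve_a.inverse(0.5)
            + iso.b[iso.valid] / simple_pair.curve_b.inverse(0.5)
            - 1.0
        )
        assert np.abs(resid).max() < 1e-8
        assert iso.status == "closed"

    def test_vertex_ordering(self, simple_pair):
        iso = compute_isobole(NullModelSurface("hand", simple_pair), 0.4, 30)
        assert np.all(np.diff(iso.a[iso.valid]) < 0)
        assert np.all(np.diff(iso.b[iso.valid]) > 0)

    def test_sham_pair_unit_slope_line(self):
        c = HillCurve(0, 1, 1.3, 1.7)
        pair = CurvePair(c, c)
        for model in ("loewe", "hand"):
            iso = compute_isobole(NullModelSurface(model, pair), 0.5, 25)
            np.testing.assert_allclose(
                iso.a[iso.valid] + iso.b[iso.valid], c.inverse(0.5), atol=1e-7
            )

    def test_vertices_reproduce_level(self, rng):
        pair = random_pair(rng, partial_fraction=0.0)
        for model in ("hand", "bliss", "tallarida_ub"):
            surface = NullModelSurface(model, pair)
            iso = compute_isobole(surface, 0.55, 15)
            for i in np.flatnonzero(iso.valid):
                assert surface.effect(float(iso.a[i]), float(iso.b[i])) == pytest.approx(
                    0.55, abs=1e-7
                )

    def test_hand_limit_isobole_consistency(self, partial_pair):
        """The Hand isobole at the partial agent's maximum equals the
        limit-isobole parametrisation, and both match an independent
        quadrature of c*(lam)."""
        surface = NullModelSurface("hand", partial_pair)
        iso = compute_isobole(surface, 0.8, 21)
        geo = limit_isobole(partial_pair, iso.lam[iso.valid])
        np.testing.assert_allclose(iso.a[iso.valid], geo.a_star, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(iso.b[iso.valid], geo.b_star, rtol=1e-5, atol=1e-8)
        for lam in (0.25, 0.6):
            want, _ = quad(
                lambda y: 1.0
                / (
                    lam * partial_pair.curve_a.sensitivity(float(y))
                    + (1 - lam) * partial_pair.curve_b.sensitivity(float(y))
                ),
                0.0,
                0.8,
                limit=400,
            )
            i = np.argmin(np.abs(iso.lam - lam))
            assert iso.a[i] + iso.b[i] == pytest.approx(want, rel=1e-6)

    def test_truncation_reported(self, partial_pair):
        # level above the partial agent's maximum: the pure-A ray cannot reach it
        iso = compute_isobole(NullModelSurface("hand", partial_pair), 0.9, 21)
        assert iso.status == "truncated"
        assert not iso.valid[0]  # lam = 1 ray
        assert iso.valid[-1]  # pure full agent reaches it

    def test_unattainable_level(self, simple_pair):
        with pytest.raises(IsoboleError):
            compute_isobole(NullModelSurface("hand", simple_pair), 0.0, 10)


class TestConvexity:
    def test_straight_isobole_is_convex(self, simple_pair):
        iso = compute_isobole(NullModelSurface("loewe", simple_pair), 0.5, 30)
        rep = convexity_diagnostic(iso)
        assert rep.convex

    def test_hand_isobole_convex(self, rng):
        for _ in range(5):
            pair = random_pair(rng, partial_fraction=0.0)
            iso = compute_isobole(NullModelSurface("hand", pair), 0.6, 50)
            rep = convexity_diagnostic(iso)
            assert rep.convex, rep

    def test_concave_negative_control(self):
        iso = compute_isobole(_SyntheticSurface(), 0.5, 30)
        rep = convexity_diagnostic(iso)
        assert not rep.convex
        assert rep.min_second_difference < -1e-3


class TestClassify:
    def _board(self, points):
        return pd.DataFrame(points, columns=["dose_a", "dose_b", "effect"])

    def test_exact_reference_is_additive(self, simple_pair):
        surfaces = [NullModelSurface(m, simple_pair) for m in ("loewe", "hand", "hsa")]
        rows = []
        for a, b in [(0.4, 0.9), (1.2, 0.3)]:
            rows.append((a, b, surfaces[0].effect(a, b)))
        calls = classify(self._board(rows), [surfaces[0]], delta=0.01)
        assert (calls.verdict == "additive").all()

    def test_split_verdict_across_models(self):
        """A measured effect lying between two references is synergistic
        against the lower and antagonistic against the higher (strict
        dichotomy, delta = 0)."""
        pair = CurvePair(HillCurve(0, 1, 1, 1), HillCurve(0, 1, 1, 2))
        surfaces = [
            NullModelSurface(m, pair)
            for m in ("hsa", "tallarida_lb", "loewe", "hand", "tallarida_ub")
        ]
        measured = 0.7  # refs at (1,1): 0.5, 2/3, 0.724, 0.754, 0.8
        calls = classify(self._board([(1.0, 1.0, measured)]), surfaces, delta=0.0)
        v = calls.set_index("model").verdict
        assert v["hsa"] == v["tallarida_lb"] == "synergistic"
        assert v["loewe"] == v["hand"] == v["tallarida_ub"] == "antagonistic"

    def test_verdict_ordering_consistency(self, rng):
        """With delta = 0 a point synergistic against model M cannot be
        antagonistic against any model with a lower reference."""
        pair = random_pair(rng, partial_fraction=0.0)
        surfaces = [
            NullModelSurface(m, pair) for m in ("hsa", "loewe", "hand", "bliss")
        ]
        board = self._board([(0.8, 0.8, 0.6), (1.5, 0.2, 0.3)])
        calls = classify(board, surfaces, delta=0.0)
        for (_, _), grp in calls.groupby(["dose_a", "dose_b"]):
            grp = grp.sort_values("reference")
            verdicts = list(grp.verdict)
            # once antagonistic (reference above measured), never synergistic later
            seen_antagonistic = False
            for v in verdicts:
                if v == "antagonistic":
                    seen_antagonistic = True
                assert not (seen_antagonistic and v == "synergistic")

    def test_undefined_reference_is_reported(self, partial_pair):
        b_far = 2 * partial_pair.curve_b.inverse(0.8)
        calls = classify(
            self._board([(1.0, b_far, 0.9)]),
            [NullModelSurface("loewe", partial_pair)],
            delta=0.01,
        )
        assert list(calls.verdict) == ["undefined"]

    def test_replicates_averaged(self, simple_pair):
        surface = NullModelSurface("hsa", simple_pair)
        ref = surface.effect(1.0, 1.0)
        board = pd.DataFrame(
            {
                "dose_a": [1.0, 1.0],
                "dose_b": [1.0, 1.0],
                "effect": [ref + 0.5, ref - 0.5],
                "replicate": [0, 1],
            }
        )
        calls = classify(board, [surface], delta=0.01)
        assert len(calls) == 1 and calls.verdict.iloc[0] == "additive"

    def test_negative_band_rejected(self, simple_pair):
        with pytest.raises(ValueError):
            classify(self._board([(1, 1, 0.5)]), [NullModelSurface("hsa", simple_pair)], delta=-1)


class TestCompareModels:
    def test_sham_columns_identical(self):
        c = HillCurve(0, 1, 1.0, 1.6)
        pair = CurvePair(c, c)
        surfaces = [
            NullModelSurface(m, pair) for m in ("loewe", "hand", "tallarida_ab")
        ]
        comp = compare_models(surfaces, [0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        wide = comp.table.pivot_table(
            index=["dose_a", "dose_b"], columns="model", values="reference"
        )
        np.testing.assert_allclose(wide["hand"], wide["loewe"], atol=1e-7)
        np.testing.assert_allclose(wide["tallarida_ab"], wide["loewe"], atol=1e-7)

    def test_systematic_sign_pattern(self, rng):
        """Hand - Loewe, Loewe - HSA, Bliss - HSA, T_UB - T_LB all
        non-negative wherever both references are defined."""
        pair = random_pair(rng, partial_fraction=0.0)
        models = ["hsa", "loewe", "hand", "bliss", "tallarida_lb", "tallarida_ub"]
        surfaces = [NullModelSurface(m, pair) for m in models]
        grid = np.array([0.0, 0.2, 0.6, 1.5, 3.0])
        comp = compare_models(surfaces, grid, grid)
        d = comp.differences.set_index(["model_x", "model_y"])
        for pair_key in [
            ("hand", "loewe"),
            ("loewe", "hsa"),
            ("bliss", "hsa"),
            ("tallarida_ub", "tallarida_lb"),
        ]:
            row = d.loc[pair_key]
            assert row["q05"] >= -1e-9, pair_key

    def test_screen_level_tendencies(self, rng):
        """On a synthetic screen the references are highly rank-correlated;
        TallaridaLB tends to bound the dose-effect based models from below,
        and Hand sits closer to TallaridaUB than to HSA."""
        models = ["hsa", "loewe", "hand", "tallarida_lb", "tallarida_ub"]
        frames = []
        for _ in range(12):
            pair = random_pair(rng, partial_fraction=0.0)
            grid = np.exp(np.linspace(np.log(0.1), np.log(3.0), 4))
            comp = compare_models(
                [NullModelSurface(m, pair) for m in models], grid, grid
            )
            frames.append(
                comp.table.pivot_table(
                    index=["dose_a", "dose_b"], columns="model", values="reference"
                ).reset_index(drop=True)
            )
        wide = pd.concat(frames, ignore_index=True).dropna()
        corr = wide.corr(method="spearman")
        assert corr.loc["hand", "loewe"] > 0.9
        assert corr.loc["hand", "tallarida_ub"] > 0.9
        assert ((wide["tallarida_lb"] <= wide["loewe"] + 1e-9).mean()) > 0.8
        assert ((wide["tallarida_lb"] <= wide["hand"] + 1e-9).mean()) > 0.8
        assert (wide["hand"] - wide["tallarida_ub"]).abs().median() < (
            wide["hand"] - wide["hsa"]
        ).abs().median()

    def test_undefined_cells_counted_not_dropped_silently(self, partial_pair):
        b_lim = partial_pair.curve_b.inverse(0.8)
        grid_b = np.array([0.0, 0.5 * b_lim, 2 * b_lim, 3 * b_lim])
        comp = compare_models(
            [NullModelSurface("loewe", partial_pair), NullModelSurface("hand", partial_pair)],
            np.array([0.0, 1.0]),
            grid_b,
        )
        # axis points stay defined (monotherapy); interior strip cells do not
        assert comp.n_undefined["loewe"] == 2
        assert comp.n_undefined["hand"] == 0
        assert np.allclose(np.diag(comp.spearman.values), 1.0)
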