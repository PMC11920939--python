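"""Two-species equilibria, classification, isoclines and vector fields."""

import numpy as np
import pytest
from scipy.optimize import root

from glvsim import (ScenarioConfig, CommunityModel, TwoSpeciesModel,
                    enumerate_equilibria, interior_equilibrium,
                    isocline_polylines, simulate, vector_field_grid)


@pytest.fixture()
def strong_mutualism():
    # saddle interior point: a12 * a21 = 4 > 1 = a11 * a22
    return TwoSpeciesModel(r1=-1.0, r2=-1.0, a11=-1.0, a12=2.0,
                           a21=2.0, a22=-1.0)


@pytest.fixture()
def bounded_mutualism():
    return TwoSpeciesModel(r1=-1.0, r2=-1.0, a11=-1.0, a12=2.0,
                           a21=2.0, a22=-1.0, Nmax=10.0)


class TestInteriorEquilibrium:
    def test_decoupled_logistics(self):
        model = TwoSpeciesModel(r1=1.0, r2=1.0, a11=-1.0, a12=0.0,
                                a21=0.0, a22=-1.0)
        point = interior_equilibrium(model)
        assert point.coordinates == pytest.approx((1.0, 1.0))
        assert point.kind == "interior"
        assert point.stability == "stable"

    def test_strong_mutualism_saddle(self, strong_mutualism):
        point = interior_equilibrium(strong_mutualism)
        assert point.coordinates == pytest.approx((1.0, 1.0))
        assert point.stability == "saddle"
        eig = sorted(np.real(point.eigenvalues))
        assert eig == pytest.approx([-3.0, 1.0])

    def test_parallel_isoclines_give_none(self):
        model = TwoSpeciesModel(r1=1.0, r2=1.0, a11=-1.0, a12=0.5,
                                a21=-2.0, a22=-1.0)
        # A singular: second row = -2 * first row
        assert interior_equilibrium(model) is None

    def test_classification_matches_simulated_fates(self):
        # brute-force oracle: integrate many perturbed starts of random
        # mutualistic pairs; a saddle verdict must coincide with trajectories
        # leaving the equilibrium, a stable verdict with trajectories staying
        rng = np.random.default_rng(8)
        cfg = ScenarioConfig(S=2, t_max=200.0)
        for _ in range(6):
            a12, a21 = rng.uniform(0.2, 2.0, size=2)
            model = TwoSpeciesModel(r1=0.0, r2=0.0, a11=-1.0, a12=a12,
                                    a21=a21, a22=-1.0)
            # choose r so that (1, 1) is the interior equilibrium
            A = model.A
            Nstar = np.ones(2)
            community = CommunityModel.from_equilibrium(A, Nstar)
            model = TwoSpeciesModel(r1=community.r[0], r2=community.r[1],
                                    a11=-1.0, a12=a12, a21=a21, a22=-1.0)
            point = interior_equilibrium(model)
            assert point.coordinates == pytest.approx((1.0, 1.0))
            stayed = 0
            for _ in range(20):
                N0 = np.abs(Nstar + rng.normal(0, 0.02, 2))
                out = simulate(community, N0, cfg)
                stayed += (out.stop_reason == "converged"
                           and np.abs(out.N_final - Nstar).max() < 0.2)
            if point.stability == "stable":
                assert stayed == 20
            else:
                assert stayed < 20


class TestEnumerateEquilibria:
    def test_origin_always_present_and_stable_for_fig1_setup(self,
                                                             strong_mutualism):
        points = enumerate_equilibria(strong_mutualism)
        origin = next(p for p in points if p.kind == "trivial")
        assert origin.coordinates == (0.0, 0.0)
        assert origin.stability == "stable"  # r1, r2 < 0

    def test_double_ceiling_point_is_stable(self, bounded_mutualism):
        points = enumerate_equilibria(bounded_mutualism)
        ceiling = next(p for p in points
                       if p.coordinates == (10.0, 10.0))
        assert ceiling.kind == "ceiling"
        assert ceiling.stability == "stable"

    def test_residuals_vanish(self, bounded_mutualism):
        for p in enumerate_equilibria(bounded_mutualism):
            res = np.abs(bounded_mutualism.rhs(np.array(p.coordinates))).max()
            assert res <= 1e-10

    def test_matches_multistart_root_scan(self, bounded_mutualism):
        # independent oracle: Newton solves seeded on a coarse grid
        model = bounded_mutualism
        found = []
        for x0 in np.linspace(0.0, 10.0, 21):
            for y0 in np.linspace(0.0, 10.0, 21):
                sol = root(lambda v: model.rhs(v), np.array([x0, y0]),
                           tol=1e-12)
                if not sol.success:
                    continue
                v = sol.x
                if np.any(v < -1e-9) or np.any(v > 10.0 + 1e-9):
                    continue
                v = np.clip(v, 0.0, 10.0)
                if np.abs(model.rhs(v)).max() > 1e-9:
                    continue
                if not any(np.allclose(v, w, atol=1e-6) for w in found):
                    found.append(v)
        enumerated = [np.array(p.coordinates)
                      for p in enumerate_equilibria(model)]
        assert len(found) == len(enumerated)
        for v in found:
            assert any(np.allclose(v, w, atol=1e-6) for w in enumerated)

    def test_bounded_perturbed_saddle_reaches_origin_or_ceiling(
            self, bounded_mutualism):
        # every perturbation of the unstable interior point must end at the
        # origin or at the double-ceiling point: no third attractor
        A = bounded_mutualism.A
        Nstar = np.ones(2)
        community = CommunityModel.from_equilibrium(A, Nstar, bounded=True,
                                                    Nmax=10.0)
        cfg = ScenarioConfig(S=2, bounded=True, Nmax=10.0,
                             blow_up_threshold=9.0, t_max=2000.0)
        rng = np.random.default_rng(17)
        fates = set()
        for _ in range(200):
            N0 = np.abs(Nstar + rng.normal(0, 0.02, 2))
            out = simulate(community, N0, cfg)
            assert out.stop_reason == "converged"
            if np.abs(out.N_final).max() < 1e-3:
                fates.add("origin")
            elif np.abs(out.N_final - 10.0).max() < 1e-2:
                fates.add("ceiling")
            else:
                raise AssertionError(f"unexpected attractor {out.N_final}")
        assert fates == {"origin", "ceiling"}


class TestVectorFieldAndIsoclines:
    def test_zero_vector_at_equilibrium(self, strong_mutualism):
        grid = vector_field_grid(strong_mutualism, (0.0, 2.0), (0.0, 2.0),
                                 resolution=3)
        at_eq = grid[(grid.N1 == 1.0) & (grid.N2 == 1.0)]
        assert len(at_eq) == 1
        assert at_eq.dN1_dt.iloc[0] == 0.0
        assert at_eq.dN2_dt.iloc[0] == 0.0

    def test_grid_shape_and_order(self, strong_mutualism):
        grid = vector_field_grid(strong_mutualism, (0.0, 1.0), (0.0, 1.0),
                                 resolution=4)
        assert len(grid) == 16
        # lexicographic ordering
        assert (grid.sort_values(["N1", "N2"]).reset_index(drop=True)
                .equals(grid))

    def test_ceiling_rows_have_zero_velocity(self, bounded_mutualism):
        grid = vector_field_grid(bounded_mutualism, (0.0, 10.0), (0.0, 10.0),
                                 resolution=5)
        assert (grid[grid.N1 == 10.0].dN1_dt == 0.0).all()
        assert (grid[grid.N2 == 10.0].dN2_dt == 0.0).all()

    def test_bounded_and_unbounded_fields_agree_in_sign(self, strong_mutualism,
                                                        bounded_mutualism):
        raw = vector_field_grid(strong_mutualism, (0.1, 9.0), (0.1, 9.0),
                                resolution=6)
        capped = vector_field_grid(bounded_mutualism, (0.1, 9.0), (0.1, 9.0),
                                   resolution=6)
        np.testing.assert_array_equal(np.sign(raw.dN1_dt), np.sign(capped.dN1_dt))
        np.testing.assert_array_equal(np.sign(raw.dN2_dt), np.sign(capped.dN2_dt))

    def test_isoclines_pass_through_interior_equilibrium(self, strong_mutualism):
        table = isocline_polylines(strong_mutualism, (0.0, 2.0), (0.0, 2.0),
                                   n_points=201)
        s1 = table[table.isocline == "species1"]
        # N1 = 1 lies on the species-1 isocline at N2 = 1
        row = s1.iloc[(s1.N1 - 1.0).abs().argmin()]
        assert row.N2 == pytest.approx(1.0, abs=1e-9)


def test_self_limitation_required():
    with pytest.raises(ValueError):
        TwoSpeciesModel(r1=1.0, r2=1.0, a11=0.5, a12=0.0, a21=0.0, a22=-1.0)
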