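"""2D channel tier: permeability law, flow solver, transport, patch BC."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from thrombosim.channel import (ChannelGeometry, ChannelModel, FlowParams,
                                PermeabilityParams, SingularResistance,
                                inlet_pressure, permeability_resistance,
                                platelet_mobility, run_scenario)
from thrombosim.parameters import load_parameters


class TestPermeability:
    def test_no_fibrin_no_drag(self):
        assert permeability_resistance(0.0, 0.0) == 0.0

    def test_hand_evaluated_reference_point(self):
        """Davies law at full normalization (Fp~ = 0.7), no platelets:
        (16/alpha^2) * 0.7^1.5 * (1 + 56*0.7^3) with alpha = 6e-4 mm."""
        expected = 16.0 / 6e-4**2 * 0.7**1.5 * (1 + 56 * 0.7**3)
        assert permeability_resistance(7000.0, 0.0) == pytest.approx(expected)
        assert expected == pytest.approx(5.26e8, rel=1e-3)

    def test_drag_diverges_towards_packing_limit(self):
        vals = [permeability_resistance(100.0, pc)
                for pc in (0.0, 200.0, 350.0, 399.0)]
        assert all(np.diff(vals) > 0)
        with pytest.raises(SingularResistance):
            permeability_resistance(100.0, 400.0)

    def test_normalization_caps_at_seven_tenths(self):
        assert permeability_resistance(7000.0, 0.0) == \
            permeability_resistance(70000.0, 0.0)


class TestInletPressure:
    def test_zero_and_linearity(self):
        geom, flow = ChannelGeometry(), FlowParams()
        assert inlet_pressure(0.0, geom, flow) == 0.0
        assert inlet_pressure(80.0, geom, flow) == \
            pytest.approx(2 * inlet_pressure(40.0, geom, flow))


@pytest.fixture(scope="module")
def clot_free():
    geom = ChannelGeometry(L=2.0, patch_start=0.6, h=0.04)
    model = ChannelModel(geom, gamma=40.0, phif0=0.0)
    return geom, model


class TestFlowSolver:
    def test_converges_to_poiseuille_parabola(self, clot_free):
        geom, model = clot_free
        yc = (np.arange(geom.ny) + 0.5) * geom.h
        exact = model.p_in / (2 * model.flow_params.mu * geom.L) * yc * (geom.H - yc)
        mid = model.flow.u[geom.nx // 2]
        assert np.max(np.abs(mid - exact)) / exact.max() < 0.01

    def test_wall_shear_matches_configured_gamma(self, clot_free):
        geom, model = clot_free
        shear = model.flow.wall_shear_bottom(geom.h)
        assert abs(np.median(shear) - 40.0) / 40.0 < 0.02

    def test_discrete_incompressibility(self, clot_free):
        geom, model = clot_free
        umax = np.abs(model.flow.u).max()
        assert np.abs(model.flow.divergence(geom.h)).max() < 1e-8 * umax / geom.h

    def test_inflow_outflow_balance(self, clot_free):
        geom, model = clot_free
        qin = model.flow.u[0].sum() * geom.h
        qout = model.flow.u[-1].sum() * geom.h
        assert abs(qin - qout) / abs(qout) < 1e-6

    def test_uniform_extreme_resistance_stalls_flow(self, clot_free):
        geom, model = clot_free
        R = np.full((geom.nx, geom.ny), 1e12)
        stalled = model._solver.solve(R, model.p_in)
        assert np.abs(stalled.u).max() < 1e-9 * np.abs(model.flow.u).max()


def _closed_box_model(**overrides) -> ChannelModel:
    """No flow, no kinetics, patch off: pure transport in a sealed box."""
    geom = ChannelGeometry(L=1.0, patch_start=0.4, h=0.05)
    zeroed = {k: 0.0 for k in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8",
                               "k9", "k10", "k11", "k12", "k13", "phic0")}
    zeroed.update(overrides)
    ps = load_parameters("table2").with_overrides(**zeroed)
    return ChannelModel(geom, ps, gamma=0.0, alpha1=0.0)


class TestTransport:
    def test_closed_box_conserves_every_species(self):
        model = _closed_box_model()
        rng = np.random.default_rng(3)
        for name in model.fields:
            if name != "Fp":
                model.fields[name] = rng.uniform(1.0, 5.0,
                                                 model.fields[name].shape)
        model.phif = rng.uniform(10.0, 50.0, model.phif.shape)
        model.phic = rng.uniform(1.0, 5.0, model.phic.shape)
        # inlet Dirichlet species: uniform at their inlet value -> no flux
        for name, val in model.inlet_values.items():
            if name in ("P", "A", "Fg"):
                model.fields[name][:] = val
        model.phif[:] = model.phif0
        before = {n: model.fields[n].sum() for n in model.fields}
        before["platelets"] = (model.phif + model.phic).sum()
        for _ in range(200):
            model.step(0.01)
        for n in model.fields:
            after = model.fields[n].sum()
            assert after == pytest.approx(before[n], rel=1e-8, abs=1e-12)
        assert (model.phif + model.phic).sum() == \
            pytest.approx(before["platelets"], rel=1e-8)

    def test_uniform_fields_follow_pure_reaction_odes(self):
        """Stagnant, spatially uniform plasma must reproduce an independent
        ODE integration of the full volume kinetics."""
        geom = ChannelGeometry(L=1.0, patch_start=0.4, h=0.05)
        ps = load_parameters("table2").with_overrides(phic0=0.0)
        model = ChannelModel(geom, ps, gamma=0.0, alpha1=0.0, phif0=300.0)
        k = model.k
        T0 = 0.5  # below the ignition knee: smooth kinetics over the window
        model.fields["T"][:] = T0
        model.fields["Ba"][:] = 2.0
        model.phic[:] = 1.0

        def rhs(t, s):
            P, T, Ba, A, Fg, F, Fp, pf, pc = s
            act = (k["k1"] * pc + k["k2"] * Ba + k["k3"] * T
                   + k["k4"] * T**2 + k["k5"] * T**3)
            bprod = (k["k7"] * pc + k["k8"] * T) * (k["B0"] - Ba)
            fib = k["k10"] * T * Fg / (k["K10"] + Fg)
            pact = (k["k12"] * T + k["k13"] * pc) * pf
            return [-act * P, act * P - k["k6"] * A * T,
                    bprod - k["k9"] * A * Ba,
                    -k["k6"] * A * T - k["k9"] * A * Ba,
                    -fib, fib - k["k11"] * F, k["k11"] * F, -pact, pact]

        t_end = 5.0
        y0 = [k["P0"], T0, 2.0, k["A0"], k["Fg0"], 0.0, 0.0, 300.0, 1.0]
        sol = solve_ivp(rhs, (0, t_end), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        n = int(round(t_end / 0.002))
        for _ in range(n):
            model.step(0.002)
        got = [model.fields[x][3, 3] for x in
               ("P", "T", "Ba", "A", "Fg", "F", "Fp")]
        got += [model.phif[3, 3], model.phic[3, 3]]
        ref = sol.y[:, -1]
        assert np.allclose(got, ref, rtol=5e-3, atol=1e-5)

    def test_mobility_vanishes_at_packing_limit(self):
        assert platelet_mobility(400.0, 400.0) == 0.0
        assert platelet_mobility(500.0, 400.0) == 0.0
        assert 0.0 < platelet_mobility(200.0, 400.0) < 1.0


class TestPatchBoundary:
    def test_saturated_patch_has_zero_flux(self):
        model = _closed_box_model()
        model.fields["Ba"][:] = model.k["B0"]
        before = model.fields["Ba"].copy()
        model._apply_patch_bc(0.1)
        assert np.array_equal(model.fields["Ba"], before)

    def test_patch_off_matches_no_patch_run(self):
        a = _closed_box_model()
        b = _closed_box_model()
        for m in (a, b):
            m.surface = type(m.surface)(alpha1=0.0, beta1=m.surface.beta1)
        for _ in range(50):
            a.step(0.01)
            b.step(0.01)
        assert np.array_equal(a.fields["Ba"], b.fields["Ba"])

    def test_linear_robin_profile_matches_closed_form(self):
        """With beta1 = 0 the patch BC is linear.  Against an imposed linear
        sink lam*Ba the steady profile is C*cosh(kappa(H - y)) with
        kappa = sqrt(lam/D); C follows from the Robin balance at the wall,
        with the surface amplitude chosen comparable to D*kappa so the
        profile is genuinely Robin-limited rather than pinned at B0."""
        D = 5e-5
        kappa = 5.0           # 1/mm
        lam = kappa**2 * D    # 1/s
        a1 = 5e-4             # flux amplitude ~ D*kappa
        # patch spans every bottom-wall cell: the profile is then purely 1D
        geom = ChannelGeometry(L=0.24, H=1.0, patch_start=1e-3,
                               patch_width=0.239, h=0.02)
        zeroed = {k: 0.0 for k in ("k1", "k2", "k3", "k4", "k5", "k6", "k7",
                                   "k8", "k9", "k10", "k11", "k12", "k13",
                                   "phic0")}
        ps = load_parameters("table2").with_overrides(**zeroed)
        model = ChannelModel(geom, ps, gamma=0.0, phif0=0.0, alpha1=a1)
        model.surface = type(model.surface)(alpha1=a1, beta1=0.0)
        dt = 0.5
        for _ in range(8000):  # ~7 relaxation times of the slowest mode
            model.step(dt)  # includes the patch BC
            model.fields["Ba"] /= (1.0 + dt * lam)
        yc = (np.arange(geom.ny) + 0.5) * geom.h
        # the discrete flux senses Ba half a cell above the wall:
        # D*kappa*sinh(kappa H) * C = a1 * (B0 - C*cosh(kappa(H - h/2)))
        C = a1 * model.k["B0"] / (
            D * kappa * np.sinh(kappa * geom.H)
            + a1 * np.cosh(kappa * (geom.H - 0.5 * geom.h)))
        exact = C * np.cosh(kappa * (geom.H - yc))
        mid = model.fields["Ba"][geom.nx // 2]
        assert np.max(np.abs(mid - exact)) / exact.max() < 0.02


class TestScenario:
    def test_no_trigger_means_no_initiation(self):
        geom = ChannelGeometry(L=2.0, patch_start=0.6, h=0.04)
        ps = load_parameters("table2").with_overrides(phic0=0.0)
        res = run_scenario(geom, ps, gamma=40.0, phif0=0.0, alpha1=0.0,
                           t_end=20.0)
        assert res.initiation_time is None and not res.occluded
        q = res.timeline["flowrate_mm2_s"]
        assert np.allclose(q, q.iloc[0], rtol=1e-9)

    def test_fibrin_polymer_is_monotone_and_platelets_capped(self):
        geom = ChannelGeometry(L=2.0, patch_start=0.6, h=0.04)
        model = ChannelModel(geom, gamma=25.0, phif0=300.0)
        prev = model.fields["Fp"].copy()
        for _ in range(400):
            model.step(model.stable_dt())
            fp = model.fields["Fp"]
            assert np.all(fp >= prev - 1e-12)
            prev = fp.copy()
        assert np.all(model.phif + model.phic
                      <= model.perm.phi_max * (1 + 1e-9))
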