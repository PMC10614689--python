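from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fuspet.data_model import PlasmaParams, TissueParams
from fuspet.plasma import plasma_auc, plasma_concentration
from fuspet.synthetic import default_schedule
from fuspet.tissue import (
    analytic_m1tcm,
    analytic_tissue_curve,
    frame_averaged_total,
    influx_rate,
    simulate_m1tcm,
    simulate_m2tcm,
)


class TestInfluxRate:
    def test_window_rate_then_resealed_rate(self):
        p = TissueParams(K_FUS=0.163, t_FUS=0.2, K1=0.030, k2=0.3, vB=0.05)
        assert influx_rate(0.0, p) == 0.163
        assert influx_rate(0.2, p) == 0.163  # boundary belongs to the window
        assert influx_rate(0.21, p) == 0.030

    def test_equal_rates_recover_classic_model(self):
        p = TissueParams(K_FUS=0.05, t_FUS=0.2, K1=0.05, k2=0.3, vB=0.05)
        t = np.linspace(0, 1, 11)
        np.testing.assert_array_equal(influx_rate(t, p), np.full(11, 0.05))

    def test_sham_has_no_window(self):
        p = TissueParams(K_FUS=0.163, t_FUS=0.2, K1=0.030, k2=0.3, vB=0.05)
        assert influx_rate(0.0, p, window=False) == 0.030


class TestNumericVsAnalytic:
    def test_one_tissue_solution_matches_convolution_oracle(self, c4_plasma, week_grid):
        tissue = TissueParams(K_FUS=0.167, t_FUS=0.165, K1=0.030, k2=0.300, vB=0.064)
        grid = np.unique(np.append(week_grid, tissue.t_FUS))
        sim = simulate_m1tcm(c4_plasma, 70.0, tissue, grid)
        oracle = analytic_m1tcm(c4_plasma, 70.0, tissue, grid)
        assert np.max(np.abs(sim.c_free - oracle)) / np.max(oracle) < 1e-6

    def test_two_tissue_solution_matches_eigen_oracle(self, mut_plasma, week_grid):
        tissue = TissueParams(K_FUS=0.188, t_FUS=0.161, K1=0.051, k2=0.491, vB=0.063, k3=0.077, k4=0.015)
        grid = np.unique(np.append(week_grid, tissue.t_FUS))
        sim = simulate_m2tcm(mut_plasma, 70.0, tissue, grid)
        cf, cs = analytic_tissue_curve(mut_plasma, 70.0, tissue, grid)
        assert np.max(np.abs(sim.c_free - cf)) / np.max(cf) < 1e-6
        assert np.max(np.abs(sim.c_spec - cs)) / np.max(cs) < 1e-6

    def test_degenerate_efflux_equal_to_hybrid_rate(self, c4_plasma):
        """k2 colliding with a plasma hybrid rate exercises the limiting
        t*exp(-k2 t) convolution form."""
        alpha, _ = c4_plasma.hybrid_rates
        tissue = TissueParams(K_FUS=0.1, t_FUS=0.15, K1=0.05, k2=alpha, vB=0.05)
        grid = np.unique(np.concatenate([np.linspace(0, 24, 2000), [0.15]]))
        sim = simulate_m1tcm(c4_plasma, 70.0, tissue, grid)
        oracle = analytic_m1tcm(c4_plasma, 70.0, tissue, grid)
        assert np.max(np.abs(sim.c_free - oracle)) / np.max(oracle) < 1e-5


class TestModelStructure:
    def test_no_entry_means_pure_vascular_signal(self, c4_plasma):
        tissue = TissueParams(K_FUS=0.0, t_FUS=0.15, K1=0.0, k2=0.3, vB=0.06)
        grid = np.linspace(0, 24, 200)
        sim = simulate_m1tcm(c4_plasma, 70.0, tissue, grid)
        assert np.all(sim.c_free == 0)
        blood = 0.55 * plasma_concentration(c4_plasma, 70.0, grid)
        np.testing.assert_allclose(sim.c_total, 0.06 * blood, rtol=1e-10)

    def test_total_is_component_identity(self, mut_plasma, all_tissue_sets):
        tissue = all_tissue_sets[("C4FcMUT", "pet_ce")]
        grid = np.unique(np.concatenate([np.linspace(0, 48, 500), [tissue.t_FUS]]))
        sim = simulate_m2tcm(mut_plasma, 70.0, tissue, grid)
        np.testing.assert_allclose(
            sim.c_total, (1 - tissue.vB) * (sim.c_free + sim.c_spec) + sim.c_vasc, rtol=1e-12
        )

    def test_mass_balance_without_efflux(self, c4_plasma):
        """With k2 = k4 = 0 and a constant entry rate, the total tissue
        amount equals k_in * integral of plasma (quadrature oracle)."""
        K = 0.1
        tissue = TissueParams(K_FUS=K, t_FUS=0.15, K1=K, k2=0.0, vB=0.0, k3=0.05, k4=0.0)
        grid = np.unique(np.concatenate([np.linspace(0, 48, 2000), [0.15]]))
        sim = simulate_m2tcm(c4_plasma, 70.0, tissue, grid)
        expected = K * plasma_auc(c4_plasma, 70.0, 0.0, 48.0)
        total = sim.c_free[-1] + sim.c_spec[-1]
        assert total == pytest.approx(expected, rel=1e-6)

    def test_irreversible_binding_accumulates_monotonically(self, c4_plasma):
        """k4 = 0 makes the specifically bound pool non-decreasing."""
        tissue = TissueParams(K_FUS=0.155, t_FUS=0.15, K1=0.069, k2=0.742, vB=0.058, k3=0.017, k4=0.0)
        grid = np.unique(np.concatenate([np.linspace(0, 168, 2000), [0.15]]))
        sim = simulate_m2tcm(c4_plasma, 70.0, tissue, grid)
        assert np.all(np.diff(sim.c_spec) >= -1e-10)

    def test_invariant_to_window_length_when_rates_equal(self, c4_plasma):
        grid = np.unique(np.concatenate([np.linspace(0, 24, 500), [0.1, 0.4]]))
        base = dict(K_FUS=0.08, K1=0.08, k2=0.4, vB=0.05)
        sim_a = simulate_m1tcm(c4_plasma, 70.0, TissueParams(t_FUS=0.1, **base), grid)
        sim_b = simulate_m1tcm(c4_plasma, 70.0, TissueParams(t_FUS=0.4, **base), grid)
        np.testing.assert_allclose(sim_a.c_free, sim_b.c_free, atol=1e-9)

    def test_grid_refinement_around_window_edge_stable(self, c4_plasma):
        tissue = TissueParams(K_FUS=0.167, t_FUS=0.165, K1=0.030, k2=0.300, vB=0.064)
        coarse = np.unique(np.concatenate([np.linspace(0, 168, 200), [0.165]]))
        fine = np.unique(np.concatenate([np.linspace(0, 168, 200), np.linspace(0.1, 0.25, 500), [0.165]]))
        a = simulate_m1tcm(c4_plasma, 70.0, tissue, coarse).c_free[-1]
        b = simulate_m1tcm(c4_plasma, 70.0, tissue, fine).c_free[-1]
        assert abs(a - b) / a < 1e-8

    def test_one_tissue_rejects_binding_rates(self, c4_plasma):
        tissue = TissueParams(K_FUS=0.1, t_FUS=0.1, K1=0.05, k2=0.3, vB=0.05, k3=0.1)
        with pytest.raises(ValueError):
            simulate_m1tcm(c4_plasma, 70.0, tissue, np.linspace(0, 1, 10))


class TestMonotonicity:
    @pytest.mark.parametrize(
        "param,direction",
        [("K_FUS", +1), ("K1", +1), ("k3", +1), ("k2", -1)],
    )
    def test_signal_auc_monotone_in_rates(self, mut_plasma, all_tissue_sets, param, direction):
        """Exposure must increase with the entry/binding rates and decrease
        with efflux, checked by finite differences around cohort means."""
        base = all_tissue_sets[("C4FcMUT", "t1w_mri_ce")]
        t = np.unique(np.concatenate([np.linspace(0, 168, 2000), [base.t_FUS]]))

        def signal_auc(tp):
            cf, cs = analytic_tissue_curve(mut_plasma, 70.0, tp, t)
            return np.trapezoid(cf + cs, t)

        lo = signal_auc(replace(base, **{param: getattr(base, param) * 0.9}))
        hi = signal_auc(replace(base, **{param: getattr(base, param) * 1.1}))
        assert direction * (hi - lo) > 0

    @settings(max_examples=25, deadline=None)
    @given(
        kfus=st.floats(0.0, 1.0),
        tfus=st.floats(0.0, 0.5),
        k1=st.floats(0.0, 0.5),
        k2=st.floats(0.0, 2.0),
        k3=st.floats(0.0, 1.0),
        k4=st.floats(0.0, 0.5),
    )
    def test_components_never_negative(self, c4_plasma, kfus, tfus, k1, k2, k3, k4):
        tissue = TissueParams(K_FUS=kfus, t_FUS=tfus, K1=k1, k2=k2, vB=0.05, k3=k3, k4=k4)
        t = np.unique(np.concatenate([np.linspace(0, 168, 300), [tfus]]))
        cf, cs = analytic_tissue_curve(c4_plasma, 70.0, tissue, t)
        assert np.all(cf >= -1e-9)
        assert np.all(cs >= -1e-9)


class TestFrameAveraging:
    def test_matches_adaptive_quadrature_per_frame(self, c4_plasma):
        """Frame-averaged prediction equals brute-force quadrature of the
        model over each frame, including the frame containing t_FUS."""
        tissue = TissueParams(K_FUS=0.167, t_FUS=0.165, K1=0.030, k2=0.300, vB=0.064)
        sched = default_schedule()
        pred = frame_averaged_total(c4_plasma, 100.0, tissue, sched)

        def total(tt):
            cf, cs = analytic_tissue_curve(c4_plasma, 100.0, tissue, np.array([tt]))
            cp = plasma_concentration(c4_plasma, 100.0, tt)
            return float((1 - tissue.vB) * (cf[0] + cs[0]) + tissue.vB * 0.55 * cp)

        for i in np.r_[0:12, 24:29]:  # early frames (incl. the t_FUS one) + statics
            a, b = sched.start[i], sched.end[i]
            brute, _ = quad(total, a, b, points=[tissue.t_FUS] if a < tissue.t_FUS < b else None, limit=200)
            assert pred[i] == pytest.approx(brute / (b - a), rel=1e-7)

    def test_midtime_close_to_frame_average_when_slowly_varying(self, c4_plasma):
        tissue = TissueParams(K_FUS=0.167, t_FUS=0.165, K1=0.030, k2=0.300, vB=0.064)
        sched = default_schedule()
        pred = frame_averaged_total(c4_plasma, 100.0, tissue, sched)
        cf, cs = analytic_tissue_curve(c4_plasma, 100.0, tissue, sched.mid)
        cp = plasma_concentration(c4_plasma, 100.0, sched.mid)
        mid = (1 - tissue.vB) * (cf + cs) + tissue.vB * 0.55 * cp
        late = slice(24, 29)  # 20-min statics, slowly varying curve
        assert np.max(np.abs(pred[late] - mid[late]) / mid[late]) < 0.005
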