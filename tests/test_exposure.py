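from dataclasses import replace

import numpy as np
import pytest

from fuspet.data_model import TimeActivityCurve, TissueParams
from fuspet.exposure import (
    auc,
    default_dense_grid,
    dose_normalized_simulation,
    specific_dominance_time,
    tissue_to_plasma_ratio,
)
from fuspet.plasma import plasma_auc, plasma_concentration
from fuspet.synthetic import default_schedule
from fuspet.tissue import analytic_tissue_curve, simulate_m1tcm


class TestAuc:
    def test_constant_curve(self):
        t = np.linspace(0, 168, 500)
        assert auc(t, np.ones_like(t), 0, 168) == pytest.approx(168.0)

    def test_trapezoid_matches_biexponential_closed_form(self, c4_plasma):
        t = default_dense_grid(168.0)
        cp = plasma_concentration(c4_plasma, 70.0, t)
        closed = plasma_auc(c4_plasma, 70.0, 0.0, 168.0)
        assert auc(t, cp, 0, 168) == pytest.approx(closed, rel=1e-3)

    def test_coarse_grid_warns(self):
        t = np.linspace(0, 168, 50)
        with pytest.warns(UserWarning):
            auc(t, np.ones_like(t), 0, 168)

    def test_invalid_interval_rejected(self):
        t = np.linspace(0, 168, 200)
        with pytest.raises(ValueError):
            auc(t, np.ones_like(t), 100, 10)


class TestDoseNormalizedSimulation:
    def test_linearity_in_dose(self, c4_plasma, all_tissue_sets):
        tissue = all_tissue_sets[("C4", "pet_ce")]
        s70 = dose_normalized_simulation(c4_plasma, tissue, dose=70.0)
        s140 = dose_normalized_simulation(c4_plasma, tissue, dose=140.0)
        np.testing.assert_allclose(2 * s70.signal(), s140.signal(), rtol=1e-6, atol=1e-8)

    def test_no_binding_equals_one_tissue_solution(self, c4_plasma, all_tissue_sets):
        tissue = replace(all_tissue_sets[("C4", "pet_ce")], k3=0.0, k4=0.0)
        sim2 = dose_normalized_simulation(c4_plasma, tissue, dose=70.0)
        sim1 = simulate_m1tcm(c4_plasma, 70.0, tissue, sim2.time)
        assert np.all(sim2.c_spec == 0)
        np.testing.assert_allclose(sim2.signal(), sim1.c_free, atol=1e-10)

    def test_grid_refinement_changes_auc_below_point_one_percent(self, c4_plasma, all_tissue_sets):
        tissue = all_tissue_sets[("C4", "pet_ce")]
        sim = dose_normalized_simulation(c4_plasma, tissue)
        a_coarse = auc(sim.time, sim.signal(), 0, 168)
        fine = np.unique(np.concatenate([sim.time, np.linspace(0, 168, 40001)]))
        sim_f = dose_normalized_simulation(c4_plasma, tissue, grid=fine)
        a_fine = auc(sim_f.time, sim_f.signal(), 0, 168)
        assert abs(a_coarse - a_fine) / a_fine < 1e-3


class TestDominanceTime:
    def test_never_crossed_without_binding(self, c4_plasma, all_tissue_sets):
        tissue = replace(all_tissue_sets[("C4", "pet_ce")], k3=0.0, k4=0.0)
        sim = dose_normalized_simulation(c4_plasma, tissue)
        assert specific_dominance_time(sim) == np.inf

    def test_finite_crossing_with_irreversible_binding(self, c4_plasma):
        tissue = TissueParams(K_FUS=0.15, t_FUS=0.15, K1=0.05, k2=0.0, vB=0.05, k3=0.1, k4=0.0)
        sim = dose_normalized_simulation(c4_plasma, tissue)
        assert np.isfinite(specific_dominance_time(sim))

    def test_dominance_time_decreases_with_binding_rate(self, mut_plasma, all_tissue_sets):
        base = all_tissue_sets[("C4FcMUT", "pet_ce")]
        times = []
        for k3 in (0.05, 0.1, 0.2):
            sim = dose_normalized_simulation(mut_plasma, replace(base, k3=k3))
            times.append(specific_dominance_time(sim))
        assert times[0] > times[1] > times[2]


class TestTissueToPlasmaRatio:
    def test_tissue_equal_to_plasma_gives_unity(self, c4_plasma):
        sched = default_schedule()
        cp = plasma_concentration(c4_plasma, 100.0, sched.mid)
        tac = TimeActivityCurve("r", sched, cp)
        np.testing.assert_allclose(tissue_to_plasma_ratio(tac, c4_plasma), 1.0, rtol=1e-12)

    def test_zero_tissue_gives_zero(self, c4_plasma):
        sched = default_schedule()
        tac = TimeActivityCurve("r", sched, np.zeros(len(sched)))
        np.testing.assert_array_equal(tissue_to_plasma_ratio(tac, c4_plasma), 0.0)

    def test_vanishing_plasma_masked_not_divided(self, mut_plasma):
        sched = default_schedule()
        tac = TimeActivityCurve("r", sched, np.ones(len(sched)))
        ratio = tissue_to_plasma_ratio(tac, mut_plasma, floor=1e3)  # absurd floor forces masking
        assert np.all(np.isnan(ratio))

    def test_tumor_ratio_exceeds_contralateral_from_five_hours(self, mut_plasma, all_tissue_sets):
        """Specific binding retains antibody in the tumour while the healthy
        hemisphere washes out with plasma."""
        sched = default_schedule()
        ratios = {}
        for region in ("t1w_mri_ce", "contralateral"):
            tp = all_tissue_sets[("C4FcMUT", region)]
            cf, cs = analytic_tissue_curve(mut_plasma, 100.0, tp, sched.mid)
            cp = plasma_concentration(mut_plasma, 100.0, sched.mid)
            tac = TimeActivityCurve(region, sched, (1 - tp.vB) * (cf + cs) + tp.vB * 0.55 * cp)
            ratios[region] = tissue_to_plasma_ratio(tac, mut_plasma)
        late = sched.mid >= 5.0
        assert np.all(ratios["t1w_mri_ce"][late] > ratios["contralateral"][late])
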