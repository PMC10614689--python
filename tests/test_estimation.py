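import numpy as np
import pandas as pd
import pytest

from fuspet.data_model import TimeActivityCurve
from fuspet.estimation import (
    compare_models,
    fit_tissue,
    group_compare,
    plasma_param_ttest,
    summarize_cohort,
)
from fuspet.fitting import FitResult, aic_least_squares
from fuspet.synthetic import CohortSpec, default_schedule, generate_subject

REGION_MODEL = {"contralateral": "m1tcm", "t1w_mri_ce": "m2tcm", "pet_ce": "m2tcm"}


def _noise_free_subject(fmt, region):
    spec = CohortSpec.from_reference(
        fmt, regions=(region,), n_subjects=1, noise_scale=0.0, seed=0, zero_variation=True
    )
    return generate_subject(spec, 0)


class TestNoiseFreeSelfConsistency:
    @pytest.mark.parametrize(
        "fmt,region",
        [("C4", "contralateral"), ("C4", "pet_ce"), ("C4FcMUT", "t1w_mri_ce")],
    )
    def test_fit_recovers_generating_parameters(self, fmt, region, all_tissue_sets):
        """Fitting the model to its own noise-free output returns the
        generating cohort-mean parameters to optimizer tolerance."""
        subject = _noise_free_subject(fmt, region)
        truth = all_tissue_sets[(fmt, region)]
        fit = fit_tissue(
            subject.region_tacs[region],
            subject.true_params["plasma"],
            model=REGION_MODEL[region],
            n_starts=4,
            seed=0,
        )
        assert fit.converged
        for name, est in fit.estimates.items():
            tv = getattr(truth, name)
            if tv > 0:
                assert est == pytest.approx(tv, rel=0.01), name
            else:
                assert est == pytest.approx(0.0, abs=1e-3), name

    def test_all_zero_tac_drives_entry_to_zero(self, c4_plasma):
        sched = default_schedule()
        tac = TimeActivityCurve("contralateral", sched, np.zeros(len(sched)))
        fit = fit_tissue(tac, c4_plasma, model="m1tcm", n_starts=4, seed=0)
        assert fit.estimates["K_FUS"] == pytest.approx(0.0, abs=1e-6)
        assert fit.estimates["K1"] == pytest.approx(0.0, abs=1e-6)
        assert any("lower_bound" in f for f in fit.flags)


def _mock_fit(model, n_params, wssr, n=29, estimates=None):
    est = estimates or {f"p{i}": 1.0 for i in range(n_params)}
    return FitResult(
        model=model,
        estimates=est,
        standard_errors={k: 0.1 for k in est},
        aic=aic_least_squares(n, wssr, n_params),
        residuals=np.zeros(n),
        weighted_ssr=wssr,
        converged=True,
        n_starts_used=1,
        n_obs=n,
    )


class TestModelComparison:
    def test_equal_fit_quality_prefers_fewer_parameters(self):
        """Identical SSR: the 2-parameter penalty decides (delta AIC = 4)."""
        f1 = _mock_fit("m1tcm", 5, 1.0)
        f2 = _mock_fit("m2tcm", 7, 1.0)
        sel = compare_models(f1, f2)
        assert sel.selected == "m1tcm"
        assert sel.delta_aic == pytest.approx(4.0)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            compare_models(_mock_fit("m1tcm", 5, 1.0, n=29), _mock_fit("m2tcm", 7, 1.0, n=24))

    def test_substantially_better_fit_wins_despite_penalty(self):
        f1 = _mock_fit("m1tcm", 5, 2.0)
        f2 = _mock_fit("m2tcm", 7, 1.0)
        assert compare_models(f1, f2).selected == "m2tcm"


class TestCohortSummary:
    def test_identical_fits_have_zero_sd(self):
        fits = {("C4", "contralateral"): [
            _mock_fit("m1tcm", 2, 1.0, estimates={"k2": 0.3}) for _ in range(3)
        ]}
        out = summarize_cohort(fits)
        assert out.loc[out.parameter == "k2", "sd"].item() == 0.0

    def test_mean_and_sd_arithmetic(self):
        fits = {("C4", "contralateral"): [
            _mock_fit("m1tcm", 1, 1.0, estimates={"k2": 0.2}),
            _mock_fit("m1tcm", 1, 1.0, estimates={"k2": 0.4}),
        ]}
        out = summarize_cohort(fits)
        row = out[out.parameter == "k2"].iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sd"] == pytest.approx(0.1414, abs=1e-3)
        assert row["n"] == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort({("C4", "contralateral"): []})


class TestGroupCompare:
    def test_bonferroni_single_comparison_is_raw_p(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "value": np.r_[rng.normal(0.3, 0.1, 6), rng.normal(0.02, 0.01, 8)],
                "format": ["C4"] * 6 + ["C4FcMUT"] * 8,
                "region": "contralateral",
            }
        )
        out = group_compare(df)
        pair = out["pairwise"].iloc[0]
        assert pair["p_adjusted"] == pytest.approx(pair["p_raw"])

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(2)
        rows = []
        for region in ("contralateral", "t1w_mri_ce", "pet_ce"):
            for fmt in ("C4", "C4FcMUT"):
                for v in rng.normal(0.5, 0.2, 5):
                    rows.append({"value": abs(v), "format": fmt, "region": region})
        out = group_compare(pd.DataFrame(rows))
        assert (out["pairwise"]["p_adjusted"] <= 1.0).all()

    def test_zero_variance_group_flagged(self):
        df = pd.DataFrame(
            {
                "value": [0.3, 0.3, 0.1, 0.2],
                "format": ["C4", "C4", "C4FcMUT", "C4FcMUT"],
                "region": "contralateral",
            }
        )
        out = group_compare(df)
        assert any("zero_within_group_variance" in f for f in out["flags"])

    def test_type_one_error_rate_near_nominal(self):
        """Two groups from the same distribution: ~5% rejections at alpha 5%."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            _, p = plasma_param_ttest(rng.normal(0, 1, 8), rng.normal(0, 1, 8))
            rejections += p < 0.05
        assert 0.03 < rejections / n_rep < 0.075
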