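"""Population fitting, empirical-Bayes estimates and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from vancopta.datasets import StudyDesign, generate_study
from vancopta.estimation import (
    SaemEstimator,
    bootstrap_ci,
    fit_population,
    gof_metrics,
    individual_map,
)
from vancopta.pk import PopulationParameters


@pytest.fixture(scope="module")
def dataset_30():
    return generate_study(StudyDesign(n_subjects=30), rng_seed=77)


@pytest.fixture(scope="module")
def fast_fit(dataset_30):
    est = SaemEstimator(n_burn=400, n_smooth=200, random_state=3)
    return est.fit(dataset_30)


class TestGofMetrics:
    def test_perfect_predictions(self):
        m = gof_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["mae"] == 0.0 and m["mape"] == 0.0 and m["rmse"] == 0.0

    def test_hand_computed_values(self):
        m = gof_metrics([10.0, 20.0], [11.0, 18.0])
        assert m["mae"] == pytest.approx(1.5)
        assert m["mape"] == pytest.approx(10.0)
        assert m["rmse"] == pytest.approx(np.sqrt(2.5))

    def test_zero_observations_excluded_from_mape(self):
        m = gof_metrics([0.0, 10.0], [1.0, 11.0])
        assert m["n_excluded_mape"] == 1
        assert m["mape"] == pytest.approx(10.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            gof_metrics([1.0], [1.0, 2.0])


class TestIndividualMap:
    def test_tight_prior_pins_eta_to_zero(self):
        data = generate_study(StudyDesign(n_subjects=1), rng_seed=5)
        pop = PopulationParameters(omega_cl=1e-4, omega_q=1e-4, omega_v1=1e-4, rho_v1_cl=0.0)
        eta, conc, _ = individual_map(pop, data)
        assert np.max(np.abs(eta)) < 1e-3
        assert len(conc) == 7

    def test_rich_data_recovers_individual_clearance(self):
        """A subject with dense sampling and tiny residual noise has an
        essentially identified CL: the MAP estimate lands within 2%."""
        pop = PopulationParameters(b=1e-3)
        design = StudyDesign(
            n_subjects=1,
            sampling_times_after_dose=tuple(np.round(np.linspace(0.5, 11.5, 50), 3)),
        )
        from vancopta.datasets import truth_bundle

        data, _, eta = truth_bundle(rng_seed=123, design=design, pop=pop)
        eta_hat, _, _ = individual_map(pop, data)
        cl_true = pop.theta0_cl * (data["EGFR"].iloc[0] / 144.0) ** pop.theta1_cl * np.exp(
            eta["ETA_CL"].iloc[0]
        )
        cl_hat = pop.theta0_cl * (data["EGFR"].iloc[0] / 144.0) ** pop.theta1_cl * np.exp(eta_hat[0])
        assert cl_hat == pytest.approx(cl_true, rel=0.02)


class TestPopulationFit:
    def test_recovers_clearance_scale(self, fast_fit):
        """A 30-subject study-design dataset generated at the reference
        parameters returns clearance and volume estimates on the right
        scale (single replicate, generous tolerance)."""
        p = fast_fit.params_
        assert p["theta0_cl"] == pytest.approx(5.2, rel=0.30)
        assert p["v1"] == pytest.approx(21.22, rel=0.45)
        assert 0.005 < p["b"] < 0.06
        assert 0.05 < p["omega_cl"] < 0.5

    def test_trace_and_result_structure(self, fast_fit):
        res = fast_fit.result_
        assert res.converged
        assert res.n_subjects == 30
        assert np.isfinite(res.objective)
        assert res.bic > res.objective
        assert set(res.trace["phase"]) == {"burn", "smooth"}
        assert len(res.eta) == 30

    def test_two_compartment_preferred_on_two_compartment_data(self, dataset_30):
        """Model selection sanity: BIC favours the true two-compartment
        structure over a one-compartment fit of the same data."""
        fit2 = fit_population(dataset_30, rng_seed=1, n_burn=300, n_smooth=150)
        fit1 = fit_population(
            dataset_30, rng_seed=1, n_compartments=1, n_burn=300, n_smooth=150
        )
        assert fit2.bic < fit1.bic

    def test_blq_records_dropped_and_counted(self, dataset_30):
        data = dataset_30.copy()
        obs_idx = data.index[data["EVID"] == 0][:2]
        data.loc[obs_idx, "DV"] = 1.0  # below the 3 mg/L quantification limit
        est = SaemEstimator(n_burn=40, n_smooth=20, compute_objective=False, random_state=0)
        est.fit(data)
        expected = int((data.loc[data["EVID"] == 0, "DV"] < 3.0).sum())
        assert expected >= 2
        assert est.result_.n_blq_dropped == expected

    def test_requires_two_subjects(self):
        data = generate_study(StudyDesign(n_subjects=1), rng_seed=0)
        with pytest.raises(ValueError):
            SaemEstimator().fit(data)

    def test_sklearn_param_interface(self):
        est = SaemEstimator(n_burn=10)
        assert est.get_params()["n_burn"] == 10
        est.set_params(n_burn=20)
        assert est.n_burn == 20


class TestBootstrap:
    def test_identical_subjects_give_zero_width_ci(self):
        """Resampling a dataset whose subjects are all identical produces
        identical refits, hence degenerate intervals."""
        one = generate_study(StudyDesign(n_subjects=1), rng_seed=9)
        parts = []
        for sid in range(1, 5):
            sub = one.copy()
            sub["ID"] = sid
            parts.append(sub)
        data = pd.concat(parts, ignore_index=True)
        out = bootstrap_ci(
            data,
            n_boot=50,
            rng_seed=0,
            n_burn=60,
            n_smooth=30,
            compute_objective=False,
        )
        width = out["table"]["ci_hi"] - out["table"]["ci_lo"]
        assert float(width.abs().max()) == 0.0
        assert out["n_fits"] == 1  # every resample hit the content cache

    def test_ci_covers_truth_on_small_study(self):
        """Percentile bootstrap interval for theta0 contains the generating
        value on a small synthetic study."""
        data = generate_study(StudyDesign(n_subjects=12), rng_seed=41)
        out = bootstrap_ci(
            data,
            n_boot=50,
            rng_seed=2,
            n_burn=150,
            n_smooth=80,
            mh_steps=4,
            compute_objective=False,
        )
        row = out["table"].loc["theta0_cl"]
        assert row["ci_lo"] <= 5.2 <= row["ci_hi"]
        assert out["n_failed"] == 0
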