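"""Fitting: objective contract, parameter paths, identifiability guard,
parameter recovery against the generating values."""

import numpy as np
import pytest

from pbpkddi import DoseEvent, StudyProtocol
from pbpkddi.drugs import carbamazepine_epoxide_model, carbamazepine_model
from pbpkddi.engine.system import SolverConfig
from pbpkddi.errors import ConfigurationError, ValidationError
from pbpkddi.fitting import (
    FitDataset,
    FitSpec,
    FreeParameter,
    fit_parameters,
    get_parameter,
    objective,
    residuals,
    set_parameter,
)
from pbpkddi.synthetic import NoiseModel, generate_observed_dataset

CBZ = "carbamazepine"
CBZE = "carbamazepine-10,11-epoxide"

FIT_SOLVER = SolverConfig(rtol=1e-6, atol=1e-9)


def _models():
    return {CBZ: carbamazepine_model(), CBZE: carbamazepine_epoxide_model()}


def _single_dose_protocol():
    return StudyProtocol(
        events=[DoseEvent(CBZ, 400.0, 0.0, "solution")],
        sampling_times_h=[1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0],
        analytes=[(CBZ, "plasma"), (CBZE, "plasma")],
    )


@pytest.fixture(scope="module")
def noise_free_dataset():
    study = generate_observed_dataset(
        _single_dose_protocol(),
        _models(),
        NoiseModel(sigma_log10=0.0, seed=1),
        solver=FIT_SOLVER,
    )
    return FitDataset(protocol=study.protocol, observed=study.observed)


class TestParameterPaths:
    def test_get_and_set(self):
        drugs = _models()
        path = f"{CBZ}/process/CYP3A4->{CBZE}/k_cat"
        assert get_parameter(drugs, path) == 0.75
        set_parameter(drugs, path, 1.5)
        assert get_parameter(drugs, path) == 1.5

    def test_interaction_path(self):
        drugs = _models()
        assert get_parameter(drugs, f"{CBZ}/interaction/CYP3A4/E_max") == 6.0

    def test_scalar_and_alias_paths(self):
        drugs = _models()
        assert get_parameter(drugs, f"{CBZ}/lipophilicity") == 2.0
        assert get_parameter(drugs, f"{CBZ}/cl_hep") == 0.02
        assert get_parameter(drugs, f"{CBZE}/gfr_fraction") == 0.21

    def test_unresolvable_path(self):
        with pytest.raises(ConfigurationError):
            get_parameter(_models(), f"{CBZ}/process/CYP1A2/k_cat")


class TestObjective:
    def test_zero_at_truth(self, noise_free_dataset):
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.07, 7.5)
            ],
            datasets=[noise_free_dataset],
            drugs=_models(),
            solver=FIT_SOLVER,
        )
        assert objective([0.75], spec) == pytest.approx(0.0, abs=1e-10)

    def test_tenfold_scaled_observations_shift_loss_by_n(self, noise_free_dataset):
        # oracle: each log10 residual becomes exactly -1
        scaled = noise_free_dataset.observed.copy()
        scaled["value"] = scaled["value"] * 10.0
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.07, 7.5)
            ],
            datasets=[FitDataset(noise_free_dataset.protocol, scaled)],
            drugs=_models(),
            solver=FIT_SOLVER,
        )
        n = len(scaled)
        assert objective([0.75], spec) == pytest.approx(n, rel=1e-6)

    def test_dataset_order_invariance(self, noise_free_dataset):
        half = len(noise_free_dataset.observed) // 2
        d1 = FitDataset(
            noise_free_dataset.protocol, noise_free_dataset.observed.iloc[:half]
        )
        d2 = FitDataset(
            noise_free_dataset.protocol, noise_free_dataset.observed.iloc[half:]
        )
        params = [
            FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.07, 7.5)
        ]
        s12 = FitSpec(params, [d1, d2], _models(), solver=FIT_SOLVER)
        s21 = FitSpec(params, [d2, d1], _models(), solver=FIT_SOLVER)
        assert objective([1.1], s12) == pytest.approx(objective([1.1], s21))

    def test_empty_dataset_is_an_error(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            FitDataset(
                _single_dose_protocol(),
                pd.DataFrame(columns=["analyte", "matrix", "time_h", "value"]),
            )


class TestIdentifiabilityGuard:
    def test_joint_emax_ec50_fit_is_refused(self, noise_free_dataset):
        with pytest.raises(ValidationError, match="identifiable"):
            FitSpec(
                parameters=[
                    FreeParameter(f"{CBZ}/interaction/CYP3A4/E_max", 0.1, 30.0),
                    FreeParameter(f"{CBZ}/interaction/CYP3A4/EC_50", 1.0, 100.0),
                ],
                datasets=[noise_free_dataset],
                drugs=_models(),
            )

    def test_override_flag(self, noise_free_dataset):
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/interaction/CYP3A4/E_max", 0.1, 30.0),
                FreeParameter(f"{CBZ}/interaction/CYP3A4/EC_50", 1.0, 100.0),
            ],
            datasets=[noise_free_dataset],
            drugs=_models(),
            allow_joint_induction_fit=True,
        )
        assert len(spec.parameters) == 2


class TestRecovery:
    def test_kcat_recovered_from_noise_free_profiles(self, noise_free_dataset):
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.075, 7.5)
            ],
            datasets=[noise_free_dataset],
            drugs=_models(),
            n_starts=2,
            seed=7,
            solver=FIT_SOLVER,
        )
        result = fit_parameters(spec)
        estimate = result.estimates[f"{CBZ}/process/CYP3A4->{CBZE}/k_cat"]
        assert estimate == pytest.approx(0.75, rel=0.01)

    def test_gfr_fraction_recovered_with_noise_and_replicates(self):
        # 15% lognormal residual noise (sigma_log10 ~ 0.065), 3 replicates
        protocol = StudyProtocol(
            events=[DoseEvent(CBZ, 400.0, 0.0, "solution")],
            sampling_times_h=[2.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0],
            analytes=[(CBZ, "urine_fe"), (CBZ, "plasma")],
        )
        datasets = []
        for seed in (11, 12, 13):
            study = generate_observed_dataset(
                protocol,
                _models(),
                NoiseModel(sigma_log10=np.log10(1.15), seed=seed),
                solver=FIT_SOLVER,
            )
            datasets.append(FitDataset(study.protocol, study.observed))
        spec = FitSpec(
            parameters=[FreeParameter(f"{CBZ}/gfr_fraction", 0.003, 0.3)],
            datasets=datasets,
            drugs=_models(),
            n_starts=2,
            seed=5,
            solver=FIT_SOLVER,
        )
        result = fit_parameters(spec)
        assert result.estimates[f"{CBZ}/gfr_fraction"] == pytest.approx(
            0.03, rel=0.25
        )

    def test_start_at_truth_converges_immediately(self, noise_free_dataset):
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.075, 7.5)
            ],
            datasets=[noise_free_dataset],
            drugs=_models(),
            n_starts=1,
            seed=3,
            solver=FIT_SOLVER,
        )
        result = fit_parameters(spec, x0=[0.75])
        assert result.objective == pytest.approx(0.0, abs=1e-8)
        assert result.starts[0]["converged"]

    def test_best_objective_bounds_all_starts(self, noise_free_dataset):
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.075, 7.5)
            ],
            datasets=[noise_free_dataset],
            drugs=_models(),
            n_starts=2,
            seed=7,
            solver=FIT_SOLVER,
        )
        result = fit_parameters(spec)
        finals = [s["objective"] for s in result.starts if s["converged"]]
        assert result.objective <= min(finals) + 1e-12


class TestResidualVector:
    def test_monotone_refinement_property(self, noise_free_dataset):
        # the refined objective never exceeds the start's objective
        spec = FitSpec(
            parameters=[
                FreeParameter(f"{CBZ}/process/CYP3A4->{CBZE}/k_cat", 0.075, 7.5)
            ],
            datasets=[noise_free_dataset],
            drugs=_models(),
            n_starts=2,
            seed=21,
            solver=FIT_SOLVER,
        )
        result = fit_parameters(spec)
        for start in result.starts:
            if start["converged"]:
                start_obj = float(np.sum(residuals(start["x0"], spec) ** 2))
                assert start["objective"] <= start_obj + 1e-9
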