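import numpy as np
import pytest

from pbpkddi import DDIProtocol, DoseEvent, StudyProtocol, simulate_ddi, simulate_study
from pbpkddi.drugs import carbamazepine_model, get_drug
from pbpkddi.errors import AssemblyError, ValidationError
from pbpkddi.trials import (
    auc_last,
    cmax,
    ddi_auc_ratio,
    ddi_cmax_ratio,
    fraction_excreted_urine,
    saliva_profile,
)

CBZ = "carbamazepine"
CBZE = "carbamazepine-10,11-epoxide"


class TestNCA:
    def test_auc_constant_segment(self):
        assert auc_last([0.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_auc_triangle(self):
        assert auc_last([0.0, 1.0, 2.0], [0.0, 2.0, 0.0]) == pytest.approx(2.0)

    def test_auc_linearity(self):
        t = [0.0, 1.0, 2.5, 4.0]
        c = [0.0, 3.0, 2.0, 0.5]
        assert auc_last(t, [5 * x for x in c]) == pytest.approx(5 * auc_last(t, c))

    def test_auc_needs_two_samples(self):
        with pytest.raises(ValidationError):
            auc_last([0.0], [1.0])

    def test_cmax(self):
        assert cmax([1.0, 3.0, 2.0]) == 3.0
        assert cmax([7.0, 7.0]) == 7.0
        assert cmax([2 * x for x in (1.0, 3.0, 2.0)]) == 6.0
        with pytest.raises(ValidationError):
            cmax([])

    def test_ratios(self):
        assert ddi_auc_ratio(4.0, 4.0) == 1.0
        assert ddi_auc_ratio(2.0, 4.0) == 0.5
        assert ddi_auc_ratio(3.0 * 7, 5.0 * 7) == pytest.approx(
            ddi_auc_ratio(3.0, 5.0)
        )
        assert ddi_cmax_ratio(2.0, 4.0) == 0.5
        with pytest.raises(ValidationError):
            ddi_auc_ratio(1.0, 0.0)


class TestSaliva:
    def test_one_to_four_ratio_with_packaged_fu(self):
        plasma = np.array([0.0, 4.0, 8.0, 2.0])
        saliva = saliva_profile(plasma, 0.25)
        assert np.allclose(saliva, plasma / 4.0)

    def test_identity_at_fu_one(self):
        plasma = np.array([1.0, 2.0])
        assert np.allclose(saliva_profile(plasma, 1.0), plasma)

    def test_zero_plasma(self):
        assert np.all(saliva_profile(np.zeros(3), 0.25) == 0.0)


class TestProtocolValidation:
    def test_requires_analyte(self):
        with pytest.raises(ValidationError):
            StudyProtocol(events=[], sampling_times_h=[1.0], analytes=[])

    def test_unknown_matrix(self):
        with pytest.raises(ValidationError):
            StudyProtocol(
                events=[],
                sampling_times_h=[1.0],
                analytes=[(CBZ, "hair")],
            )

    def test_unsorted_sampling(self):
        with pytest.raises(ValidationError):
            StudyProtocol(
                events=[],
                sampling_times_h=[2.0, 1.0],
                analytes=[(CBZ, "plasma")],
            )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            DoseEvent(CBZ, -1.0, 0.0)


class TestSimulateStudy:
    def test_zero_dose_gives_zero_profiles(self, coarse_cfg):
        protocol = StudyProtocol(
            events=[DoseEvent(CBZ, 0.0, 0.0, "solution")],
            sampling_times_h=[1.0, 4.0, 8.0],
            analytes=[(CBZ, "plasma"), (CBZE, "plasma")],
        )
        result = simulate_study(protocol, config=coarse_cfg)
        assert np.all(result.observable(CBZ) == 0.0)
        assert np.all(result.observable(CBZE) == 0.0)

    def test_metabolite_peaks_after_parent(self, single_dose_result):
        t = single_dose_result.time_h
        t_parent = t[np.argmax(single_dose_result.observable(CBZ))]
        t_metab = t[np.argmax(single_dose_result.observable(CBZE))]
        assert t_metab > t_parent

    def test_saliva_observable_is_quarter_of_plasma(self, single_dose_result):
        plasma = single_dose_result.observable(CBZ, "plasma")
        saliva = single_dose_result.observable(CBZ, "saliva")
        assert np.allclose(saliva, plasma * 0.25)

    def test_urine_fraction_nondecreasing_and_below_one(self, single_dose_result):
        fe = fraction_excreted_urine(single_dose_result, CBZ)
        assert np.all(np.diff(fe) >= -1e-12)
        assert fe[-1] <= 1.0
        assert fe[-1] > 0.0

    def test_concentrations_nonnegative(self, single_dose_result):
        for series in single_dose_result.series.values():
            assert np.all(series >= 0.0)

    def test_to_frame_schema(self, single_dose_result):
        frame = single_dose_result.to_frame()
        assert list(frame.columns) == [
            "time_h",
            "analyte",
            "matrix",
            "concentration_umol_per_L",
            "concentration_mg_per_L",
        ]
        plasma = frame[(frame.analyte == CBZ) & (frame.matrix == "plasma")]
        ratio = (
            plasma.concentration_mg_per_L / plasma.concentration_umol_per_L
        ).dropna()
        assert np.allclose(ratio, 236.27 / 1000.0)

    def test_liver_cyp3a4_above_baseline_after_14_days_tid(self, tid14):
        # autoinduction under 400 mg three-times-daily
        system, grid, traj = tid14
        offset = system.pool_offset()
        for k, pool in enumerate(system.pools):
            if pool.enzyme == "CYP3A4" and pool.organ == 3:
                assert traj[-1, offset + k] > traj[0, offset + k]


class TestSimulateDDI:
    def test_zero_mg_perpetrator_equals_alone_arm(self, coarse_cfg):
        victim = StudyProtocol(
            events=[DoseEvent(CBZ, 400.0, 0.0, "solution")],
            sampling_times_h=np.linspace(1.0, 48.0, 20).tolist(),
            analytes=[(CBZ, "plasma")],
        )
        ddi = DDIProtocol(
            victim=victim,
            perpetrator_events=[DoseEvent("erythromycin", 0.0, 0.0)],
        )
        alone, together = simulate_ddi(ddi, config=coarse_cfg)
        assert np.allclose(
            alone.observable(CBZ), together.observable(CBZ), rtol=1e-6
        )

    def test_mbi_perpetrator_raises_victim_auc(self, coarse_cfg):
        victim = StudyProtocol(
            events=[DoseEvent(CBZ, 400.0, 48.0, "solution")],
            sampling_times_h=np.linspace(1.0, 48.0, 20).tolist(),
            analytes=[(CBZ, "plasma")],
        )
        perp = [DoseEvent("erythromycin", 500.0, float(8 * i)) for i in range(12)]
        alone, together = simulate_ddi(
            DDIProtocol(victim=victim, perpetrator_events=perp), config=coarse_cfg
        )
        r = ddi_auc_ratio(
            auc_last(together.time_h, together.observable(CBZ)),
            auc_last(alone.time_h, alone.observable(CBZ)),
        )
        assert r > 1.0

    def test_inducer_perpetrator_lowers_victim_auc(self, coarse_cfg):
        victim = StudyProtocol(
            events=[DoseEvent("alprazolam", 1.0, 7 * 24.0)],
            sampling_times_h=np.linspace(1.0, 48.0, 20).tolist(),
            analytes=[("alprazolam", "plasma")],
        )
        perp = [
            DoseEvent(CBZ, 400.0, float(12 * i), "solution") for i in range(14)
        ]
        alone, together = simulate_ddi(
            DDIProtocol(victim=victim, perpetrator_events=perp), config=coarse_cfg
        )
        r = ddi_auc_ratio(
            auc_last(together.time_h, together.observable("alprazolam")),
            auc_last(alone.time_h, alone.observable("alprazolam")),
        )
        assert r < 1.0

    def test_require_interaction_distinguishes_null_perpetrator(self, coarse_cfg):
        cbz = carbamazepine_model()
        cbz.interactions = []
        victim = StudyProtocol(
            events=[DoseEvent("alprazolam", 1.0, 0.0)],
            sampling_times_h=[1.0, 2.0],
            analytes=[("alprazolam", "plasma")],
        )
        ddi = DDIProtocol(
            victim=victim, perpetrator_events=[DoseEvent(CBZ, 400.0, 0.0)]
        )
        models = {CBZ: cbz, "alprazolam": get_drug("alprazolam"),
                  CBZE: get_drug(CBZE)}
        with pytest.raises(AssemblyError, match="null perpetrator"):
            simulate_ddi(ddi, models, require_interaction=True)
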