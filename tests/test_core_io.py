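import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clamptrace import (
    ClampProtocol,
    GIRProfile,
    Group,
    SampleSeries,
    Subject,
    UnitContext,
    compute_bsa,
)
from clamptrace.core import GLUCOSE_MW, GLYCEROL_MW, SAMPLING_SCHEDULE
from clamptrace.io import (
    LoadError,
    read_protocol,
    read_series,
    read_subject_table,
    write_protocol,
    write_series,
    write_subject_table,
)


class TestBSA:
    @pytest.mark.parametrize(
        "height,weight,expected",
        [(160, 90, 2.0), (180, 80, 2.0), (175.6, 90.9, math.sqrt(175.6 * 90.9 / 3600))],
    )
    def test_mosteller_values(self, height, weight, expected):
        assert compute_bsa(height, weight) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("height,weight", [(0, 80), (170, 0), (-160, 90)])
    def test_nonpositive_inputs_rejected(self, height, weight):
        with pytest.raises(ValueError):
            compute_bsa(height, weight)

    @given(
        height=st.floats(120, 220),
        weight=st.floats(35, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_closed_form_agreement(self, height, weight):
        assert compute_bsa(height, weight) == pytest.approx(
            math.sqrt(height * weight / 3600.0), abs=1e-12
        )


class TestUnits:
    def test_glucose_mass_to_mole(self):
        assert UnitContext.mg_glucose_to_umol(1.0) == pytest.approx(1000 / 180.16, rel=1e-12)
        assert UnitContext.mg_glucose_to_umol(1.0) == pytest.approx(5.5506, abs=1e-4)

    def test_glycerol_mass_to_mole(self):
        assert UnitContext.mg_glycerol_to_umol(1.0) == pytest.approx(1000 / 92.09, rel=1e-12)

    @given(x=st.floats(1e-6, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_mass_mole_round_trip_identity(self, x):
        for mw in (GLUCOSE_MW, GLYCEROL_MW):
            assert UnitContext.umol_to_mg(UnitContext.mg_to_umol(x, mw), mw) == pytest.approx(
                x, rel=1e-12
            )

    def test_distribution_volume(self):
        assert UnitContext(80.0, 0.22).v_ml_per_kg == pytest.approx(220.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            UnitContext(0.0)
        with pytest.raises(ValueError):
            UnitContext(80.0, v_frac=1.5)


class TestProtocol:
    def test_default_constants_field_by_field(self):
        p = ClampProtocol()
        assert p.glucose_tracer_prime_mg_kg == 2.0
        assert p.glucose_tracer_rate_mg_kg_min == 0.02
        assert p.glycerol_tracer_prime_mg_kg == 0.12
        assert p.glycerol_tracer_rate_mg_kg_min == 0.0067
        assert p.insulin_rate_low_mU_m2_min == 10.0
        assert p.insulin_rate_high_mU_m2_min == 40.0
        assert p.infusate_enrichment_low_mg_g == 8.0
        assert p.infusate_enrichment_high_mg_g == 10.0
        assert p.v_frac == 0.22
        assert p.glycaemic_target_mmol_l == 5.0
        assert p.basal_window == (-30.0, 0.0)
        assert p.low_window == (90.0, 120.0)
        assert p.high_window == (210.0, 240.0)

    def test_packaged_defaults_match_dataclass(self):
        assert read_protocol() == ClampProtocol()

    def test_window_outside_stage_rejected(self):
        with pytest.raises(ValueError):
            ClampProtocol(low_window=(110.0, 150.0))

    def test_v_frac_bounds(self):
        with pytest.raises(ValueError):
            ClampProtocol(v_frac=0.0)

    def test_infusate_enrichment_by_stage(self):
        p = ClampProtocol()
        assert p.infusate_enrichment_at(-10) == 0.0
        assert p.infusate_enrichment_at(60) == 8.0
        assert p.infusate_enrichment_at(200) == 10.0


class TestSubject:
    def test_bsa_derived(self):
        s = Subject("a", Group.WEM, weight_kg=80.0, height_cm=180.0)
        assert s.bsa_m2 == pytest.approx(2.0)

    def test_missing_covariates_are_none(self):
        s = Subject("a", Group.BAM, 80.0, 180.0)
        assert s.vat_kg is None and s.muscle_kg is None

    def test_invalid_anthropometry(self):
        with pytest.raises(ValueError):
            Subject("a", Group.BAM, -1.0, 180.0)


class TestGIRProfile:
    def test_step_lookup_and_zero_before_start(self):
        g = GIRProfile([0.0, 5.0, 10.0], [1.0, 2.0, 4.0])
        assert g.rate_at(-3.0) == 0.0
        assert g.rate_at(0.0) == 1.0
        assert g.rate_at(7.5) == 2.0
        assert g.rate_at(100.0) == 4.0

    def test_window_mean_integrates_steps_exactly(self):
        g = GIRProfile([0.0, 10.0], [2.0, 6.0])
        # [0,20]: 10 min at 2 + 10 min at 6
        assert g.window_mean(0.0, 20.0) == pytest.approx(4.0)
        assert g.window_mean(5.0, 15.0) == pytest.approx(4.0)

    def test_monotone_times_required(self):
        with pytest.raises(ValueError):
            GIRProfile([0.0, 0.0], [1.0, 2.0])


def _demo_series() -> SampleSeries:
    t = np.array(SAMPLING_SCHEDULE)
    rng = np.random.default_rng(5)
    gly_ttr = np.where(t <= 120, 0.045 + 0.0001 * t.clip(0), np.nan)
    gly_ttr[np.argmin(np.abs(t - 230.0))] = np.nan
    return SampleSeries(
        t_min=t,
        glucose_mmol_l=5.0 + 0.05 * rng.standard_normal(t.size),
        insulin_pmol_l=np.full(t.size, 60.0),
        nefa_mmol_l=np.full(t.size, 0.5),
        glucose_ttr=np.full(t.size, 0.0123),
        glycerol_umol_l=np.where(t <= 120, 65.0, np.nan),
        glycerol_ttr=gly_ttr,
        gir=GIRProfile([0.0, 5.0, 120.0], [0.0, 1.5, 4.0]),
    )


class TestSeriesIO:
    def test_round_trip_lossless(self, tmp_path):
        s = _demo_series()
        f = tmp_path / "s.csv"
        write_series(s, f)
        s2 = read_series(f)
        np.testing.assert_array_equal(s.t_min, s2.t_min[np.isin(s2.t_min, s.t_min)])
        for name in ("glucose_mmol_l", "insulin_pmol_l", "nefa_mmol_l",
                     "glucose_ttr", "glycerol_umol_l", "glycerol_ttr"):
            a = getattr(s, name)
            b = getattr(s2, name)[np.isin(s2.t_min, s.t_min)]
            np.testing.assert_array_equal(a, b)  # bit-identical incl. NaN pattern
        np.testing.assert_array_equal(s.gir.times, s2.gir.times)
        np.testing.assert_array_equal(s.gir.rates, s2.gir.rates)

    def test_round_trip_bytes_stable(self, tmp_path):
        s = _demo_series()
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_series(s, f1)
        write_series(read_series(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_missing_sample_loads_without_error(self, tmp_path):
        s = _demo_series()  # glycerol TTR missing at 230 min by construction
        f = tmp_path / "s.csv"
        write_series(s, f)
        s2 = read_series(f)
        t, _ = s2.channel("glycerol_ttr")
        assert 230.0 not in t

    def test_duplicate_time_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("t_min,glucose_mmol_l\n0,5.0\n0,5.1\n")
        with pytest.raises(LoadError, match="duplicate"):
            read_series(f)

    def test_negative_concentration_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("t_min,glucose_mmol_l\n0,5.0\n10,-1.0\n")
        with pytest.raises(LoadError, match="negative"):
            read_series(f)

    def test_unknown_column_rejected(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("t_min,lactate\n0,5.0\n")
        with pytest.raises(LoadError, match="unknown"):
            read_series(f)


class TestSubjectTableIO:
    def test_round_trip_with_missing_covariates(self, tmp_path):
        subs = [
            Subject("BAM001", Group.BAM, 90.9, 175.6, vat_kg=3.7, sat_kg=None, muscle_kg=20.7),
            Subject("WEM001", Group.WEM, 94.2, 176.8),
        ]
        f = tmp_path / "subjects.csv"
        write_subject_table(subs, f)
        back = read_subject_table(f)
        assert back == subs

    def test_protocol_yaml_round_trip(self, tmp_path):
        p = ClampProtocol(v_frac=0.19)
        f = tmp_path / "proto.yaml"
        write_protocol(p, f)
        assert read_protocol(f) == p
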