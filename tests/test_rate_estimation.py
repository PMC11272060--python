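"""Rate reconstruction from streams, gas traces and the kLa balance."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import denitflux as dn
from denitflux.rate_estimation import (
    AIR_O2_FRACTION,
    ConfigError,
    DataError,
    GasTrace,
    Rate,
    ReactorConfig,
    StreamSpec,
    biomass_production_rate,
    dissolved_rates_from_table,
    gas_accumulation_rate,
    n2_rate_by_difference,
    o2_consumption_rate,
    overall_dissolved_rate,
    overall_from_aerobic_o2,
)
from denitflux.phase_resolution import PhaseSchedule


def make_trace(n=60, y_n2o=0.0, y_o2=0.2095, do=0.8, y_n2o_in=0.0):
    ones = np.ones(n)
    return GasTrace(
        time_min=np.arange(float(n)),
        y_o2=y_o2 * ones,
        y_n2o=y_n2o * ones,
        y_co2=4e-4 * ones,
        do_frac=do * ones,
        y_o2_in=0.2095 * ones,
        y_n2o_in=y_n2o_in * ones,
        y_co2_in=4e-4 * ones,
    )


class TestOverallDissolvedRate:
    def test_pass_through_is_zero(self):
        feed = StreamSpec(0.5, {"no3": [10.0, 10.0]})
        out = StreamSpec(0.5, {"no3": [10.0, 10.0]})
        assert overall_dissolved_rate(feed, out, "no3").value == pytest.approx(0.0)

    def test_no3_uptake_matches_flux_difference(self):
        # feed flux 0.93 N-mmol/h, effluent flux 0.123 N-mmol/h
        f = 0.75 / 48.0
        feed = StreamSpec(f, {"no3": [0.93 / f]})
        out = StreamSpec(f, {"no3": [0.123 / f]})
        r = overall_dissolved_rate(feed, out, "no3")
        assert r.value == pytest.approx(-0.807, abs=1e-9)
        assert r.phase_scope == "overall"

    def test_fully_consumed_vfa(self):
        f = 0.75 / 48.0
        feed = StreamSpec(f, {"acetate": [2.69 / f]})
        out = StreamSpec(f, {"acetate": [0.0]})
        assert overall_dissolved_rate(feed, out, "acetate").value == pytest.approx(-2.69)

    def test_replicate_spread_propagates(self):
        feed = StreamSpec(1.0, {"x": [10.0]})
        out = StreamSpec(1.0, {"x": [5.0, 6.0, 4.0]})
        r = overall_dissolved_rate(feed, out, "x")
        assert r.sd == pytest.approx(np.std([5, 6, 4], ddof=1))

    def test_missing_compound_raises(self):
        with pytest.raises(DataError):
            overall_dissolved_rate(
                StreamSpec(1.0, {"a": [1]}), StreamSpec(1.0, {"b": [1]}), "a"
            )

    def test_negative_flow_rejected(self):
        with pytest.raises(ConfigError):
            StreamSpec(-1.0, {"a": [1]})


class TestGasAccumulationRate:
    def test_zero_difference(self):
        cfg = ReactorConfig()
        tr = make_trace(y_n2o=0.0)
        assert gas_accumulation_rate(tr, None, "n2o", cfg).value == pytest.approx(0.0)

    def test_hand_calculation_n2o(self):
        # y_N2O = 1e-4, F = 24 L/h, P = 1 atm, T = 293.15 K -> 0.1995 N-mmol/h
        cfg = ReactorConfig(gas_flow=24.0, pressure=1.0, temperature=293.15)
        tr = make_trace(y_n2o=1.0e-4)
        r = gas_accumulation_rate(tr, None, "n2o", cfg)
        assert r.value == pytest.approx(2 * 1.0e-4 * 24.0 / (0.08206 * 293.15) * 1e3, rel=1e-9)
        assert r.value == pytest.approx(0.1995, abs=5e-4)

    def test_constant_window_equals_point_value(self):
        cfg = ReactorConfig()
        tr = make_trace(y_n2o=2e-5)
        full = gas_accumulation_rate(tr, None, "n2o", cfg).value
        narrow = gas_accumulation_rate(tr, (10.0, 11.0), "n2o", cfg).value
        assert full == pytest.approx(narrow)

    def test_empty_window_raises(self):
        with pytest.raises(DataError):
            gas_accumulation_rate(make_trace(), (1000.0, 1001.0), "co2", ReactorConfig())

    def test_unknown_gas_rejected(self):
        with pytest.raises(DataError):
            gas_accumulation_rate(make_trace(), None, "ch4", ReactorConfig())

    @settings(max_examples=30, deadline=None)
    @given(y=st.floats(0, 1e-3), scale=st.floats(0.1, 4.0))
    def test_linear_in_fraction_difference_and_gas_flow(self, y, scale):
        cfg = ReactorConfig()
        cfg2 = ReactorConfig(gas_flow=cfg.gas_flow * scale)
        base = gas_accumulation_rate(make_trace(y_n2o=y), None, "n2o", cfg).value
        assert gas_accumulation_rate(make_trace(y_n2o=2 * y if 2 * y <= 1 else y), None, "n2o", cfg).value == pytest.approx(
            (2 if 2 * y <= 1 else 1) * base, abs=1e-12
        )
        assert gas_accumulation_rate(make_trace(y_n2o=y), None, "n2o", cfg2).value == pytest.approx(
            scale * base, rel=1e-9, abs=1e-12
        )


class TestO2ConsumptionRate:
    def test_zero_driving_force_at_saturation(self):
        cfg = ReactorConfig()
        tr = make_trace(do=1.0, y_o2=AIR_O2_FRACTION)
        assert o2_consumption_rate(tr, None, cfg).value == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_example(self):
        # kLa 50/h, sat 0.284 mmol/L, DO = 0.826 of sat, V = 0.75 L -> -1.85 mmol/h
        cfg = ReactorConfig(kla=50.0, henry_o2=0.284e-3 / AIR_O2_FRACTION, volume=0.75)
        tr = make_trace(do=0.826, y_o2=AIR_O2_FRACTION)
        r = o2_consumption_rate(tr, None, cfg)
        assert r.value == pytest.approx(-50 * 0.284 * (1 - 0.826) * 0.75, rel=1e-3)
        assert r.value == pytest.approx(-1.85, abs=0.01)
        assert r.phase_scope == "aerobic"

    def test_halving_driving_force_halves_rate(self):
        cfg = ReactorConfig()
        r1 = o2_consumption_rate(make_trace(do=0.8), None, cfg).value
        r2 = o2_consumption_rate(make_trace(do=0.9), None, cfg).value
        assert r2 == pytest.approx(0.5 * r1, rel=1e-9)

    def test_unset_kla_raises(self):
        cfg = ReactorConfig()
        cfg.kla = None
        with pytest.raises(ConfigError):
            o2_consumption_rate(make_trace(), None, cfg)


class TestDerivedRates:
    def test_biomass_from_nh4(self, registry):
        r = biomass_production_rate(Rate("nh4", -0.2368), registry)
        assert r.value == pytest.approx(1.184)
        assert r.compound == "biomass"

    def test_biomass_zero_and_scaling(self, registry):
        assert biomass_production_rate(Rate("nh4", 0.0), registry).value == 0.0
        reg = dn.default_registry()
        reg.biomass_nc_ratio = 0.1
        assert biomass_production_rate(Rate("nh4", -1.0), reg).value == pytest.approx(10.0)

    def test_positive_nh4_warns(self, registry):
        with pytest.warns(UserWarning):
            biomass_production_rate(Rate("nh4", 0.5), registry)

    @pytest.mark.parametrize(
        "no3,n2o,expected",
        [(-0.807, 0.0565, 0.7505), (-1.0, 1.0, 0.0), (0.0, 0.0, 0.0)],
    )
    def test_n2_by_difference(self, no3, n2o, expected):
        r = n2_rate_by_difference(Rate("no3", no3), Rate("n2o", n2o))
        assert r.value == pytest.approx(expected)

    def test_n2_difference_conserves_nitrogen(self):
        no3, n2o, no2 = Rate("no3", -0.9), Rate("n2o", 0.05), Rate("no2", 0.02)
        n2 = n2_rate_by_difference(no3, n2o, no2)
        assert -no3.value == pytest.approx(n2o.value + n2.value + no2.value)

    def test_n2_mixed_scope_rejected(self):
        with pytest.raises(ValueError):
            n2_rate_by_difference(
                Rate("no3", -1, phase_scope="aerobic"), Rate("n2o", 0.1)
            )

    @pytest.mark.parametrize(
        "aer,oxic_h,expected",
        [(-1.170, 16.0, -0.780), (-1.170, 24.0, -1.170), (-1.170, 0.0, 0.0)],
    )
    def test_overall_from_aerobic_o2(self, aer, oxic_h, expected):
        sched = PhaseSchedule(1, 24.0, 0.0, net_oxic_h=oxic_h)
        r = overall_from_aerobic_o2(Rate("o2", aer, phase_scope="aerobic"), sched)
        assert r.value == pytest.approx(expected)
        assert r.phase_scope == "overall"

    def test_overall_from_aerobic_requires_aerobic_scope(self):
        with pytest.raises(ValueError):
            overall_from_aerobic_o2(Rate("o2", -1.0), PhaseSchedule(4, 4, 2))


class TestSampleTable:
    def test_empty_table_raises(self):
        with pytest.raises(DataError):
            dissolved_rates_from_table(
                pd.DataFrame(columns=["time_h", "phase_label", "compound", "replicate", "conc_mM"]),
                {},
                ReactorConfig(),
            )

    def test_missing_columns_raise(self):
        with pytest.raises(DataError):
            dissolved_rates_from_table(pd.DataFrame({"compound": ["a"]}), {}, ReactorConfig())

    def test_uniform_concentration_gives_flux_difference(self):
        cfg = ReactorConfig()
        rows = [
            {"time_h": 0, "phase_label": lab, "compound": "no3", "replicate": r, "conc_mM": 4.0}
            for lab in ("start_oxic", "end_oxic", "end_anoxic")
            for r in (1, 2)
        ]
        rates = dissolved_rates_from_table(
            pd.DataFrame(rows), {"no3": 10.0}, cfg, PhaseSchedule(4, 4, 2)
        )
        assert rates["no3"].value == pytest.approx(cfg.flow * (4.0 - 10.0))


class TestGasTraceValidation:
    def test_rejects_non_uniform_sampling(self):
        with pytest.raises(DataError):
            GasTrace(
                time_min=np.array([0.0, 2.0, 3.0]),
                y_o2=np.zeros(3), y_n2o=np.zeros(3), y_co2=np.zeros(3),
                do_frac=np.zeros(3),
            )

    def test_rejects_fraction_outside_unit_interval(self):
        with pytest.raises(DataError):
            GasTrace(
                time_min=np.arange(3.0),
                y_o2=np.array([0.1, 1.5, 0.1]), y_n2o=np.zeros(3), y_co2=np.zeros(3),
                do_frac=np.zeros(3),
            )

    def test_frame_round_trip(self):
        tr = make_trace(n=10, y_n2o=1e-5)
        back = GasTrace.from_frame(tr.to_frame())
        np.testing.assert_allclose(back.y_n2o, tr.y_n2o)
        np.testing.assert_allclose(back.do_frac, tr.do_frac)


def test_hrt_srt_mismatch_warns():
    with pytest.warns(UserWarning):
        ReactorConfig(hrt=48.0, srt=72.0)
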