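"""Cycle mass-balance apportionment, NTR and performance metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitropath.apportionment import (
    BatchProfile,
    CycleEndpoints,
    StoichParams,
    apportion_phase1,
    apportion_phase2,
    delta_nitrate_ammonium_ratio,
    mix_feed,
    nitrate_to_nitrite_transformation,
    nitrogen_removal_efficiency,
    pathway_contributions,
    phase_summary,
)

conc = st.floats(min_value=0.0, max_value=40.0, allow_nan=False)


def endpoints(nh4_i, no2_i, no3_i, nh4_f, no2_f, no3_f):
    return CycleEndpoints(nh4_i, no2_i, no3_i, nh4_f, no2_f, no3_f)


class TestStoichParams:
    def test_paper_defaults(self):
        p = StoichParams()
        assert p.r_tn_per_nh4 == 2.04
        assert p.r_no3_per_tn == pytest.approx(0.26 / 2.04)

    def test_closed_mode_recomputes_from_reaction_vector(self):
        p = StoichParams.closed()
        assert p.r_tn_per_nh4 == pytest.approx(1 + 1.32 - 0.26)
        assert p.r_no3_per_tn == pytest.approx(0.26 / 2.06)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            StoichParams(r_tn_per_nh4=0.9)


class TestMixFeed:
    def test_half_exchange_from_empty_residual(self):
        out = mix_feed({"nh4": 0.0}, {"nh4": 14.3}, 0.5)
        assert out["nh4"] == pytest.approx(7.15)

    def test_full_exchange_returns_influent(self):
        out = mix_feed({"nh4": 3.0, "no2": 1.0}, {"nh4": 12.5, "no2": 12.3}, 1.0)
        assert out == pytest.approx({"nh4": 12.5, "no2": 12.3})

    def test_equal_records_are_fixed_point(self):
        rec = {"nh4": 5.0, "no2": 6.0}
        for ratio in (0.1, 0.5, 0.9):
            assert mix_feed(rec, rec, ratio) == pytest.approx(rec)

    def test_mismatched_analytes_rejected(self):
        with pytest.raises(ValueError, match="analyte"):
            mix_feed({"nh4": 1.0}, {"no2": 1.0}, 0.5)

    def test_ratio_bounds(self):
        with pytest.raises(ValueError):
            mix_feed({"nh4": 0.0}, {"nh4": 1.0}, 0.0)


class TestPhase1:
    def test_hand_worked_example(self):
        app = apportion_phase1(endpoints(14, 14, 1, 2, 2, 9))
        assert app.delta_n == pytest.approx(16.0)
        assert app.tn_anammox == pytest.approx(16.0)
        assert app.nh4_aob == pytest.approx(12 - 16 / 2.04, abs=1e-9)
        assert app.no3_nob == pytest.approx(8 - 16 * 0.26 / 2.04, abs=1e-9)
        assert app.warnings == ()

    def test_no_change_gives_zero_components(self):
        app = apportion_phase1(endpoints(5, 5, 1, 5, 5, 1))
        assert app.delta_n == 0
        assert app.tn_anammox == 0
        assert app.nh4_aob == 0
        assert app.no3_nob == 0

    def test_pure_anammox_exposes_constant_mismatch(self):
        """Endpoints from exact 1.32/0.26 stoichiometry: the conventional
        2.04 constant leaves a small negative AOB residue; the closed
        constant (2.06) zeroes it."""
        ep = endpoints(10, 13.2, 0, 0, 0, 2.6)
        app = apportion_phase1(ep)
        assert app.nh4_aob == pytest.approx(10 - 20.6 / 2.04, abs=1e-9)
        assert app.nh4_aob < 0
        assert any("nh4_aob" in w for w in app.warnings)
        closed = apportion_phase1(ep, StoichParams.closed())
        assert closed.nh4_aob == pytest.approx(0.0, abs=1e-9)
        assert closed.no3_nob == pytest.approx(0.0, abs=1e-9)

    def test_clamp_mode_zeroes_but_still_warns(self):
        app = apportion_phase1(endpoints(10, 13.2, 0, 0, 0, 2.6), clamp=True)
        assert app.nh4_aob == 0.0
        assert app.warnings


class TestPhase2:
    def test_hand_worked_example(self):
        app = apportion_phase2(endpoints(10, 10, 2, 0, 0, 1))
        assert app.tn_anammox == pytest.approx(20.4)
        assert app.no3_denitratation == pytest.approx(2 + 2.6 - 1, abs=1e-9)
        assert app.delta_n == pytest.approx(21.0)
        assert app.tn_denitritation == pytest.approx(0.6, abs=1e-9)

    def test_no_change_gives_zero_components(self):
        app = apportion_phase2(endpoints(4, 4, 1, 4, 4, 1))
        assert app.tn_anammox == 0
        assert app.no3_denitratation == 0
        assert app.tn_denitritation == 0

    def test_nitrate_production_violates_assumption(self):
        app = apportion_phase2(endpoints(10, 0, 0, 0, 0, 5))
        assert app.no3_denitratation == pytest.approx(0 + 2.6 - 5, abs=1e-9)
        assert any("no3_denitratation" in w for w in app.warnings)

    @given(conc, conc, conc, conc, conc, conc)
    @settings(max_examples=500, deadline=None)
    def test_identity_holds_by_construction(self, a, b, c, d, e, f):
        """Denitritation is defined as ΔN minus the anammox share, so the
        three-way identity holds at machine level for any endpoints."""
        app = apportion_phase2(endpoints(a, b, c, d, e, f))
        assert app.tn_denitritation == app.delta_n - app.tn_anammox
        assert app.tn_anammox + app.tn_denitritation == pytest.approx(
            app.delta_n, abs=1e-12
        )

    @given(*(conc,) * 9)
    @settings(max_examples=100, deadline=None)
    def test_interval_additivity(self, a, b, c, d, e, f, g, h, i):
        """Apportioning a cycle equals summing its sub-interval
        apportionments: the balance equations are linear in the deltas."""
        whole = apportion_phase2(endpoints(a, b, c, g, h, i))
        first = apportion_phase2(endpoints(a, b, c, d, e, f))
        second = apportion_phase2(endpoints(d, e, f, g, h, i))
        for attr in ("delta_n", "tn_anammox", "no3_denitratation", "tn_denitritation"):
            assert getattr(first, attr) + getattr(second, attr) == pytest.approx(
                getattr(whole, attr), abs=1e-9
            )


class TestContributions:
    def test_phase2_shares(self):
        app = apportion_phase2(endpoints(10, 10, 2, 0, 0, 1))
        shares = pathway_contributions(app)
        assert shares["anammox"] == pytest.approx(20.4 / 21 * 100, abs=0.05)
        assert shares["denitritation"] == pytest.approx(100 - 20.4 / 21 * 100, abs=0.05)

    def test_pure_anammox_is_all_anammox(self):
        app = apportion_phase2(endpoints(10, 13.2, 0, 0, 0, 2.6), StoichParams.closed())
        shares = pathway_contributions(app)
        assert shares["anammox"] == pytest.approx(100.0, abs=1e-6)

    def test_phase1_nitrate_production_shares(self):
        app = apportion_phase1(endpoints(14, 14, 1, 2, 2, 9))
        shares = pathway_contributions(app)
        anammox_no3 = 16 * 0.26 / 2.04
        expected_nob = (8 - anammox_no3) / 8 * 100
        assert shares["nob_nitrate"] == pytest.approx(expected_nob, abs=1e-6)

    def test_no_removal_rejected(self):
        app = apportion_phase2(endpoints(5, 5, 1, 5, 5, 1))
        with pytest.raises(ValueError):
            pathway_contributions(app)


class TestDeltaRatio:
    def test_pure_anammox_theoretical_value(self):
        assert delta_nitrate_ammonium_ratio(
            endpoints(10, 13.2, 0, 0, 0, 2.6)
        ) == pytest.approx(0.26)

    def test_flat_nitrate_gives_zero(self):
        assert delta_nitrate_ammonium_ratio(endpoints(10, 5, 3, 4, 5, 3)) == 0.0

    def test_direct_arithmetic(self):
        assert delta_nitrate_ammonium_ratio(
            endpoints(14, 0, 1, 2, 0, 9)
        ) == pytest.approx(8 / 12)

    def test_no_ammonium_removal_rejected(self):
        with pytest.raises(ValueError):
            delta_nitrate_ammonium_ratio(endpoints(5, 5, 1, 5, 4, 2))


def make_profile(time, nh4, no2, no3):
    return BatchProfile(np.asarray(time), np.asarray(nh4), np.asarray(no2), np.asarray(no3))


class TestNTR:
    def test_endpoint_half_conversion(self):
        p = make_profile([0, 60], [0, 0], [0, 5], [15, 5])
        res = nitrate_to_nitrite_transformation(p)
        assert res.maximum == pytest.approx(50.0)

    def test_no_accumulation_gives_zero(self):
        p = make_profile([0, 30, 60], [0, 0, 0], [0, 0, 0], [15, 10, 5])
        assert nitrate_to_nitrite_transformation(p).maximum == pytest.approx(0.0)

    def test_maximum_at_transient_peak(self):
        """Complete denitrification returns nitrite to zero; the maximum
        must capture the mid-trace peak, not the endpoint."""
        p = make_profile([0, 60, 120], [0, 0, 0], [0, 6, 0], [15, 7, 1])
        res = nitrate_to_nitrite_transformation(p)
        assert res.maximum == pytest.approx(6 / 8 * 100)
        assert res.series[-1] == pytest.approx(0.0)

    def test_scale_invariance(self):
        p1 = make_profile([0, 60], [0, 0], [0, 5], [15, 5])
        p2 = make_profile([0, 60], [0, 0], [0, 15], [45, 15])
        r1 = nitrate_to_nitrite_transformation(p1)
        r2 = nitrate_to_nitrite_transformation(p2)
        assert r1.maximum == pytest.approx(r2.maximum)

    def test_undefined_when_nitrate_never_reduced(self):
        p = make_profile([0, 60], [0, 0], [0, 1], [15.0, 14.95])
        res = nitrate_to_nitrite_transformation(p)
        assert not res.defined
        assert np.isnan(res.maximum)

    def test_zero_initial_nitrate_rejected(self):
        p = make_profile([0, 60], [0, 0], [0, 1], [0, 0])
        with pytest.raises(ValueError):
            nitrate_to_nitrite_transformation(p)

    def test_profile_time_must_increase(self):
        with pytest.raises(ValueError):
            make_profile([0, 0], [0, 0], [0, 0], [15, 5])


class TestRemovalEfficiency:
    @pytest.mark.parametrize(
        "influent,effluent,expected",
        [(20.0, 20.0, 0.0), (20.0, 0.0, 100.0), (26.8, 3.4, (1 - 3.4 / 26.8) * 100)],
    )
    def test_values(self, influent, effluent, expected):
        assert nitrogen_removal_efficiency(influent, effluent) == pytest.approx(expected)

    def test_nonpositive_influent_rejected(self):
        with pytest.raises(ValueError):
            nitrogen_removal_efficiency(0.0, 1.0)


class TestPhaseSummary:
    def test_constant_series_has_zero_sd(self):
        df = pd.DataFrame({"phase": ["a"] * 4, "nh4": [7.0] * 4})
        out = phase_summary(df)
        assert out.loc["a", "nh4_std"] == pytest.approx(0.0)

    def test_two_point_hand_arithmetic(self):
        df = pd.DataFrame({"phase": ["a", "a"], "x": [10.0, 14.0]})
        out = phase_summary(df)
        assert out.loc["a", "x_mean"] == pytest.approx(12.0)
        assert out.loc["a", "x_std"] == pytest.approx(2.828, abs=1e-3)

    def test_single_record_phase_rejected(self):
        df = pd.DataFrame({"phase": ["a", "b", "b"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="a"):
            phase_summary(df)

    def test_recovers_influent_spec_means(self):
        """Sampling-theory check: campaign means land within 2 sd/sqrt(n)
        of the generating influent distribution."""
        from scipy.stats import truncnorm

        from nitropath.simulator import PHASE1_INFLUENT, sample_influent

        rng = np.random.default_rng(7)
        n = 400
        rows = [dict(phase="phase1", **sample_influent(PHASE1_INFLUENT, rng)) for _ in range(n)]
        out = phase_summary(pd.DataFrame(rows))
        for analyte in ("nh4", "no2", "no3"):
            mu = PHASE1_INFLUENT.mean[analyte]
            sd = PHASE1_INFLUENT.sd[analyte]
            # exact mean of the zero-truncated generating distribution
            expected = truncnorm.mean((0 - mu) / sd, np.inf, loc=mu, scale=sd)
            assert abs(out.loc["phase1", f"{analyte}_mean"] - expected) < 2 * sd / np.sqrt(n)
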