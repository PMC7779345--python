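"""Direct/indirect decomposition identities and the DABBLE statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dabble import (
    AxisMismatchError,
    CurveProcessingError,
    DecompositionConfig,
    LQParameters,
    UndefinedStatisticError,
    ValidationError,
    dabble,
    dabble_let_profile,
    df_indirect,
    evaluate_sf,
    make_curve,
    sf_direct,
    sf_indirect,
)

LN10 = math.log(10.0)

params_st = st.tuples(st.floats(0.01, 5.0), st.floats(0.0, 1.0)).map(
    lambda ab: LQParameters(ab[0], ab[1], "radicals")
)


def rad_params(alpha, beta):
    return LQParameters(alpha, beta, "radicals")


class TestComponentFractions:
    def test_zero_exposure(self):
        p = rad_params(LN10, 0.0)
        assert df_indirect(p, 0.0, 0.76) == 0.0
        assert sf_indirect(p, 0.0, 0.76) == 1.0
        assert sf_direct(p, 0.0, 0.76) == 1.0

    def test_degenerate_k(self):
        p = rad_params(LN10, 0.0)
        assert df_indirect(p, 3.0, 0.0) == 0.0        # no indirect action
        assert sf_direct(p, 3.0, 1.0) == 1.0          # all killing indirect

    def test_worked_values_at_sf_point_one(self):
        p = rad_params(LN10, 0.0)  # SF(1) = 0.1
        assert df_indirect(p, 1.0, 0.76) == pytest.approx(0.684, rel=1e-12)
        assert sf_indirect(p, 1.0, 0.76) == pytest.approx(0.316, rel=1e-12)
        assert sf_direct(p, 1.0, 0.76) == pytest.approx(0.784, rel=1e-12)

    def test_indirect_survival_asymptote(self):
        p = rad_params(LN10, 0.0)
        assert sf_indirect(p, 1e6, 0.76) == pytest.approx(0.24, abs=1e-12)

    @given(
        params=params_st,
        n=st.floats(0.0, 50.0),
        k=st.floats(0.0, 1.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_death_fraction_conservation(self, params, n, k):
        """DF_in + DF_d equals the total death fraction 1 - SF_t."""
        total_death = 1.0 - evaluate_sf(params, n)
        df_d = (1.0 - k) * total_death
        assert abs(df_indirect(params, n, k) + df_d - total_death) < 1e-12

    @given(params=params_st, n=st.floats(0.0, 50.0), k=st.floats(0.0, 1.0))
    @settings(max_examples=300, derandomize=True)
    def test_survival_component_identity(self, params, n, k):
        """SF_in + SF_d = SF_t + 1 (algebraic identity of the split)."""
        sft = evaluate_sf(params, n)
        assert sf_indirect(params, n, k) + sf_direct(params, n, k) == pytest.approx(
            sft + 1.0, abs=1e-12
        )


class TestDabble:
    def test_coincident_curves_closed_form(self):
        p = rad_params(0.9, 0.1)
        res = dabble(p, p, DecompositionConfig(k=0.76))
        assert res.dabble == pytest.approx(0.24 / 0.76, abs=1e-12)
        assert res.df_c == pytest.approx(0.9)

    @given(
        params=params_st,
        k=st.floats(0.01, 1.0),
        level=st.floats(0.01, 0.9),
    )
    @settings(max_examples=200, derandomize=True)
    def test_coincident_closed_form_any_k(self, params, k, level):
        """Identical curves give DABBLE = (1-k)/k at any survival level."""
        res = dabble(params, params, DecompositionConfig(k=k, survival_level=level))
        assert res.dabble == pytest.approx((1.0 - k) / k, abs=1e-9)

    def test_k_one_gives_zero(self):
        p = rad_params(1.0, 0.0)
        assert dabble(p, p, DecompositionConfig(k=1.0)).dabble == pytest.approx(0.0, abs=1e-12)

    def test_k_zero_undefined(self):
        p = rad_params(1.0, 0.0)
        with pytest.raises(UndefinedStatisticError):
            dabble(p, p, DecompositionConfig(k=0.0))

    def test_independent_substitution_oracle(self):
        """High-precision hand substitution for a non-trivial pair.

        ion (alpha=2, beta=0), X-ray (alpha=0.8, beta=0.05) in units of
        1e17 radicals/L: N* = ln10/2, DF_XI = 0.76*(1-exp(-0.987308...)).
        """
        ion = rad_params(2.0, 0.0)
        xray = rad_params(0.8, 0.05)
        res = dabble(ion, xray, DecompositionConfig())
        n_star = LN10 / 2.0
        expo = 0.8 * n_star + 0.05 * n_star**2
        df_xi = 0.76 * (1.0 - math.exp(-expo))
        assert res.n_star == pytest.approx(n_star, rel=1e-12)
        assert res.df_xi == pytest.approx(df_xi, rel=1e-12)
        assert res.dabble == pytest.approx((0.9 - df_xi) / df_xi, rel=1e-12)
        assert res.dabble == pytest.approx(0.8874, abs=5e-5)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(AxisMismatchError):
            dabble(LQParameters(1.0, 0.0, "dose"), rad_params(1.0, 0.0))

    def test_monotone_decreasing_in_n_star(self):
        """More radicals needed for iso-effect => less apparent direct action."""
        xray = rad_params(0.4, 0.02)
        values = []
        for alpha in (4.0, 2.0, 1.0, 0.5):  # decreasing ion alpha => rising N*
            res = dabble(rad_params(alpha, 0.0), xray, DecompositionConfig())
            values.append((res.n_star, res.dabble))
        n_stars, dabbles = zip(*values)
        assert all(np.diff(n_stars) > 0)
        assert all(np.diff(dabbles) < 0)


class TestProfile:
    def _flat_gtable(self, g=2.5):
        from dabble import make_gvalue_table

        return make_gvalue_table(
            [(1.0, tp, g) for tp in ("1ps", "100ns")]
            + [(1000.0, tp, g) for tp in ("1ps", "100ns")]
        )

    def test_empty_collection(self, gtable):
        xray = make_curve(
            "xr", 9.4, "dose", [1, 2, 4], [math.exp(-0.2 * d) for d in (1, 2, 4)]
        )
        assert dabble_let_profile([], xray, gtable, "1ps") == []

    def test_single_identical_curve_reduces_to_closed_form(self):
        doses = [0.5, 1, 2, 3, 4, 6]
        sf = [math.exp(-(0.3 * d + 0.02 * d * d)) for d in doses]
        xray = make_curve("xr", 50.0, "dose", doses, sf)
        ion = make_curve("ion", 50.0, "dose", doses, sf)
        res = dabble_let_profile([ion], xray, self._flat_gtable(), "1ps")
        assert len(res) == 1
        assert res[0].dabble == pytest.approx(0.24 / 0.76, rel=1e-8)
        assert res[0].rbe == pytest.approx(1.0, rel=1e-8)
        assert res[0].time_point == "1ps"

    def test_failures_collected_with_partial_results(self, gtable):
        doses = [0.5, 1, 2, 3, 4]
        sf = [math.exp(-0.3 * d) for d in doses]
        xray = make_curve("xr", 9.4, "dose", doses, sf)
        good = make_curve("ok", 100.0, "dose", doses, [math.exp(-0.9 * d) for d in doses])
        bad = make_curve("too-high-let", 5000.0, "dose", doses, sf)  # outside G table
        with pytest.raises(CurveProcessingError) as excinfo:
            dabble_let_profile([good, bad], xray, gtable, "1ps")
        err = excinfo.value
        assert len(err.failures) == 1 and err.failures[0][0] == "too-high-let"
        assert len(err.partial_results) == 1

    def test_bad_time_point_rejected(self, gtable):
        xray = make_curve("xr", 9.4, "dose", [1, 2, 3], [0.9, 0.7, 0.5])
        with pytest.raises(ValidationError):
            dabble_let_profile([], xray, gtable, "10ns")


class TestConfig:
    def test_defaults(self):
        cfg = DecompositionConfig()
        assert cfg.k == 0.76
        assert cfg.survival_level == 0.1
        assert cfg.death_fraction == pytest.approx(0.9)

    @pytest.mark.parametrize("kwargs", [{"k": -0.1}, {"k": 1.1}, {"survival_level": 0.0}, {"survival_level": 1.0}])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DecompositionConfig(**kwargs)
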