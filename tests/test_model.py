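"""Rate-law evaluations against an independent term-sum oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliokin.model import (
    PARAM_NAMES,
    ConservationError,
    Environment,
    KineticParameters,
    ModelState,
    dcomplex_dt,
    dgd_dt,
    dhif1a_dt,
    diameter_from_volume,
    digfbp2_dt,
    free_igfi,
    rates,
    volume_from_diameter,
)
from gliokin.profiles import LN229, U87


def oracle_rates(b, c, h, gd, o2, igfi_total, p):
    """Naive sum of named terms, written independently of the package
    rate functions: every flux appears as its own literal term."""
    i = igfi_total - c
    production = p["k1"] * b * i * (1.0 - p["k2"] * b)
    binding = p["k3"] * i * b
    dissociation = p["k4"] * c
    bp2_degradation = p["kd"] * b
    hif_promotion_of_bp2 = p["k5"] * h
    db = production - binding + dissociation - bp2_degradation \
        + hif_promotion_of_bp2
    dc = binding - dissociation - p["kd"] * c
    igfi_drive = p["k6"] * i
    o2_degradation = p["k7"] * o2 * h
    basal_hill = p["k8"] * h / (p["k12"] + p["k9"] * h)
    bp2_drive = p["k10"] * b
    dh = igfi_drive - o2_degradation + basal_hill + bp2_drive
    dgd = p["v1"] + p["k11"] * h
    return np.array([db, dc, dh, dgd])


TABLE_STATE = ModelState(igfbp2=3.68, complex=2.6, hif1a=1.0, gd=3200.0)
ENV = Environment(o2_percent=21.0, igfi_total=95.1)


def test_table_state_rates_match_oracle(ln229):
    got = rates(TABLE_STATE, ENV, ln229.params)
    want = oracle_rates(3.68, 2.6, 1.0, 3200.0, 21.0, 95.1,
                        ln229.params.as_dict())
    np.testing.assert_allclose(got, want, rtol=1e-12)
    # frozen magnitudes from hand arithmetic on the parameter table
    assert got[0] == pytest.approx(10.3952, abs=5e-4)   # nM/hr
    assert got[1] == pytest.approx(-10.1440, abs=5e-4)  # nM/hr
    assert got[2] == pytest.approx(-2.45911, abs=5e-5)  # uM/hr
    assert got[3] == pytest.approx(0.5779 + 179.55, abs=1e-10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    b=st.floats(0, 500), c=st.floats(0, 95), h=st.floats(0, 50),
    gd=st.floats(0, 5e4), o2=st.floats(2, 21),
)
def test_rates_match_oracle_everywhere(b, c, h, gd, o2):
    p = LN229.params
    state = ModelState(igfbp2=b, complex=c, hif1a=h, gd=gd)
    env = Environment(o2_percent=o2, igfi_total=95.1)
    np.testing.assert_allclose(
        rates(state, env, p),
        oracle_rates(b, c, h, gd, o2, 95.1, p.as_dict()),
        rtol=1e-12, atol=1e-300)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(b=st.floats(0, 500), c=st.floats(0, 95), h=st.floats(0, 50))
def test_all_zero_constants_give_zero_rates(b, c, h):
    p = KineticParameters(**{n: 0.0 for n in PARAM_NAMES})
    state = ModelState(igfbp2=b, complex=c, hif1a=h, gd=1.0)
    assert np.all(rates(state, ENV, p) == 0.0)


class TestFreeIgfi:
    @pytest.mark.parametrize("total,cplx,expected", [
        (95.1, 2.6, 92.5),
        (10.0, 10.0, 0.0),
        (10.0, 0.0, 10.0),
    ])
    def test_conservation_split(self, total, cplx, expected):
        assert free_igfi(total, cplx) == pytest.approx(expected)

    def test_violation_names_both_values(self):
        with pytest.raises(ConservationError, match="11.*10"):
            free_igfi(10.0, 11.0)


class TestSingleTermExamples:
    def test_hif_promotion_only(self, ln229):
        p = KineticParameters(**{**{n: 0.0 for n in PARAM_NAMES},
                                 "k5": 9.5495})
        state = ModelState(igfbp2=0, complex=0, hif1a=1.0, gd=0)
        assert digfbp2_dt(state, ENV, p) == pytest.approx(9.5495)

    def test_complex_dissociation_only(self):
        p = KineticParameters(**{**{n: 0.0 for n in PARAM_NAMES},
                                 "k4": 0.0007})
        state = ModelState(igfbp2=0, complex=2.6, hif1a=0, gd=0)
        assert dcomplex_dt(state, ENV, p) == pytest.approx(-0.00182)

    def test_strict_printed_dissociation_uses_binding_constant(self):
        p = KineticParameters(**{**{n: 0.0 for n in PARAM_NAMES},
                                 "k3": 0.5, "k4": 0.0007})
        state = ModelState(igfbp2=0, complex=2.0, hif1a=0, gd=0)
        assert dcomplex_dt(state, ENV, p) == pytest.approx(-0.0014)
        assert dcomplex_dt(state, ENV, p, strict_printed_dissociation=True) \
            == pytest.approx(-1.0)

    def test_hif_rate_vanishes_at_zero_state(self, ln229):
        state = ModelState(igfbp2=0, complex=95.1, hif1a=0, gd=0)
        # free IGFI = 0 here, so every production/degradation term is 0
        assert dhif1a_dt(state, ENV, ln229.params) == 0.0

    def test_hill_term_saturates_at_k8_over_k9(self, ln229):
        p = ln229.params.with_values(k6=0.0, k7=0.0, k10=0.0)
        state = ModelState(igfbp2=0, complex=0, hif1a=1e12, gd=0)
        assert dhif1a_dt(state, ENV, p) == pytest.approx(
            p.k8 / p.k9, rel=1e-9)

    def test_singular_hill_denominator(self):
        p = KineticParameters(**{**{n: 0.0 for n in PARAM_NAMES},
                                 "k8": 1.0})
        state = ModelState(igfbp2=0, complex=0, hif1a=1.0, gd=0)
        with pytest.raises(ZeroDivisionError):
            dhif1a_dt(state, ENV, p)


class TestGrowthLaw:
    @pytest.mark.parametrize("profile,expected", [
        (LN229, 0.5779 + 179.55),   # strongly insulin-dependent line
        (U87, 2.601 + 21.6),        # weakly insulin-dependent line
    ])
    def test_growth_at_unit_hif(self, profile, expected):
        state = ModelState(igfbp2=0, complex=0, hif1a=1.0, gd=0)
        assert dgd_dt(state, profile.params) == pytest.approx(expected)

    def test_basal_growth_at_zero_hif(self, ln229):
        state = ModelState(igfbp2=0, complex=0, hif1a=0.0, gd=0)
        assert dgd_dt(state, ln229.params) == ln229.params.v1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(h1=st.floats(0, 100), h2=st.floats(0, 100))
    def test_monotone_in_hif(self, h1, h2):
        lo, hi = sorted([h1, h2])
        s_lo = ModelState(igfbp2=0, complex=0, hif1a=lo, gd=0)
        s_hi = ModelState(igfbp2=0, complex=0, hif1a=hi, gd=0)
        assert dgd_dt(s_hi, LN229.params) >= dgd_dt(s_lo, LN229.params)


class TestVolume:
    def test_unit_radius(self):
        assert volume_from_diameter(2.0) == pytest.approx(4 * math.pi / 3)

    def test_initial_spheroid(self):
        # U87 initial diameter, 170 um
        assert volume_from_diameter(170.0) == pytest.approx(
            (4.0 / 3.0) * math.pi * 85.0 ** 3, rel=1e-12)
        assert volume_from_diameter(170.0) == pytest.approx(2.572441e6,
                                                            rel=1e-6)

    def test_zero(self):
        assert volume_from_diameter(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            volume_from_diameter(-1.0)
        with pytest.raises(ValueError):
            diameter_from_volume(-1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gd=st.floats(0, 1e6))
    def test_round_trip(self, gd):
        assert diameter_from_volume(volume_from_diameter(gd)) \
            == pytest.approx(gd, rel=1e-12, abs=1e-12)


class TestTypes:
    def test_bundled_profiles_differ_only_in_growth(self):
        u, l = U87.params.as_dict(), LN229.params.as_dict()
        diff = {k for k in u if u[k] != l[k]}
        assert diff == {"v1", "k11"}
        assert (U87.initial.gd, LN229.initial.gd) == (170.0, 3200.0)
        assert U87.initial.igfbp2 == LN229.initial.igfbp2 == 3.68
        assert U87.environment.igfi_total == 95.1

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError, match="k7"):
            LN229.params.with_values(k7=-1.0)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="hif1a"):
            ModelState(igfbp2=0, complex=0, hif1a=-0.1, gd=0)

    def test_environment_warns_outside_range(self):
        with pytest.warns(UserWarning, match="outside"):
            Environment(o2_percent=30.0)
        with pytest.raises(ValueError):
            Environment(duration=0.0)

    def test_scaled_and_mapping_round_trip(self, ln229):
        p = ln229.params
        assert p.scaled("k8", 10.0).k8 == pytest.approx(0.1057)
        assert KineticParameters.from_mapping(p.as_dict()) == p
        with pytest.raises(KeyError, match="k12"):
            bad = p.as_dict()
            bad.pop("k12")
            KineticParameters.from_mapping(bad)
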