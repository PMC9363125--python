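"""Unit tests for the reaction network, profiles and parameter handling."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wntgrad import (
    ConfigurationError,
    DomainError,
    IntegrityError,
    ModelParameters,
    Scenario,
    dnfzd7_condition_params,
    effective_parameters,
    hill_repression,
    initial_hs_profile,
    initial_receptor_profile,
    nondimensionalize,
    reaction_rhs,
    redimensionalize,
    sfrp1_production_profile,
    wnt_production_profile,
)
from wntgrad.model import SPECIES, SPECIES_INDEX

P = ModelParameters()


def state(**conc):
    s = np.zeros(len(SPECIES))
    for name, v in conc.items():
        s[SPECIES_INDEX[name]] = v
    return s


class TestParameters:
    def test_defaults_match_published_table(self):
        assert P.k1 == 2.66e-6
        assert P.k1_off == 9.6e-5
        assert P.k2 == 4.33e-5
        assert P.k2_off == 4.86e-4
        assert P.k3 == 1.86e-4
        assert P.k3_off == 3.66e-3
        assert P.k4 == 2.52e-4
        assert (P.p1, P.p2, P.p3) == (1e-4, 1e-3, 10.0)
        assert (P.Kd, P.hill_n) == (1e-2, 2.0)
        assert (P.diff_coef, P.r0, P.h0_amp) == (20.0, 75.0, 1e8)
        assert (P.x_max, P.t_max) == (100.0, 1e5)

    @pytest.mark.parametrize("bad", [
        {"k1": -1.0}, {"hill_n": 0.5}, {"x_max": 0.0}, {"t_max": -5.0},
        {"wnt_source_right_edge": 30.0},  # violates source ordering
        {"bump_left": 50.0},              # violates bump ordering
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ModelParameters(**bad)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario(feedback_multiplier=-0.1)

    def test_unknown_dnfzd7_condition_rejected(self):
        with pytest.raises(ConfigurationError):
            Scenario(dnfzd7_condition="maximal")


class TestProductionProfiles:
    @pytest.mark.parametrize("x, expected", [(5.0, 1.0), (10.0, 1.0), (15.0, 0.0)])
    def test_wnt_source_indicator(self, x, expected):
        assert wnt_production_profile(x, P) == expected

    @pytest.mark.parametrize("x, expected", [(10.0, 0.0), (25.0, 1.0), (90.0, 1.0)])
    def test_sfrp1_source_indicator(self, x, expected):
        assert sfrp1_production_profile(x, P) == expected

    def test_out_of_domain_position_rejected(self):
        with pytest.raises(DomainError):
            wnt_production_profile(-1.0, P)
        with pytest.raises(DomainError):
            sfrp1_production_profile(101.0, P)

    @pytest.mark.parametrize("x, expected", [(10.0, 0.0), (25.0, 150.0), (40.0, 0.0)])
    def test_receptor_bump(self, x, expected):
        assert initial_receptor_profile(x, P) == pytest.approx(expected, abs=1e-12)

    def test_receptor_bump_scales_with_multiplier(self):
        sc = Scenario(initial_receptor_multiplier=4.0)
        assert initial_receptor_profile(25.0, P, sc) == pytest.approx(600.0)

    def test_hs_bump_peak_and_switch(self):
        assert initial_hs_profile(25.0, P, Scenario()) == pytest.approx(2e8)
        assert initial_hs_profile(5.0, P, Scenario()) == 0.0
        assert initial_hs_profile(25.0, P, Scenario(hs_enabled=False)) == 0.0

    @given(x=st.floats(0.0, 100.0))
    @settings(derandomize=True, max_examples=50)
    def test_bump_profiles_bounded(self, x):
        r = initial_receptor_profile(x, P)
        assert 0.0 <= r <= 2.0 * P.r0 + 1e-9


class TestHillRepression:
    def test_anchor_values(self):
        assert hill_repression(0.0, P) == 1.0
        assert hill_repression(P.Kd, P) == pytest.approx(0.5)
        assert hill_repression(1e9, P) == pytest.approx(0.0, abs=1e-12)

    def test_negative_signal_rejected(self):
        with pytest.raises(DomainError):
            hill_repression(-0.1, P)

    @given(st.floats(0.0, 1e3), st.floats(0.0, 1e3))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_decreasing_and_bounded(self, a, b):
        lo, hi = sorted([a, b])
        fa, fb = hill_repression(lo, P), hill_repression(hi, P)
        assert 0.0 < fb <= fa <= 1.0


class TestDnFzd7ConditionTable:
    @pytest.mark.parametrize("cond, expected", [
        ("none", (0.0, P.k1, P.k1, 0.0)),
        ("both_functions", (100 * P.p3, P.k1, P.k1, 0.0)),
        ("inactivate_only", (100 * P.p3, 0.0, 0.0, P.k1)),
        ("trap_only", (100 * P.p3, P.k1, 0.0, 0.0)),
    ])
    def test_condition_rows(self, cond, expected):
        assert tuple(dnfzd7_condition_params(cond, P)) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ConfigurationError):
            dnfzd7_condition_params("supercharged", P)


class TestEffectiveParameters:
    def test_switches_are_parameter_overrides(self):
        sc = Scenario(feedback_multiplier=5.0, initial_receptor_multiplier=4.0,
                      ligand_multiplier=1.5, sfrp1_enabled=False, hs_enabled=False,
                      dnfzd7_condition="trap_only")
        eff = effective_parameters(P, sc)
        assert eff.p3 == 50.0
        assert eff.r0 == 300.0
        assert eff.p1 == pytest.approx(1.5e-4)
        assert eff.p2 == 0.0
        assert eff.h0_amp == 0.0
        # dnFzd7 row uses the base feedback gain
        assert eff.p4 == 100 * P.p3
        assert (eff.k5, eff.k6, eff.k7) == (P.k1, 0.0, 0.0)


class TestReactionRhs:
    def test_zero_state_only_production_survives(self):
        d_source = reaction_rhs(state(), 5.0, P, Scenario())
        d_far = reaction_rhs(state(), 50.0, P, Scenario())
        assert d_source[SPECIES_INDEX["W"]] == pytest.approx(P.p1)
        assert d_source[SPECIES_INDEX["S"]] == 0.0
        assert d_far[SPECIES_INDEX["W"]] == 0.0
        assert d_far[SPECIES_INDEX["S"]] == pytest.approx(P.p2)  # hill(0) = 1
        mask = np.ones(len(SPECIES), dtype=bool)
        mask[[SPECIES_INDEX["W"], SPECIES_INDEX["S"]]] = False
        assert np.all(d_source[mask] == 0.0)

    def test_zero_state_zero_production_gives_zero_vector(self):
        sc = Scenario(ligand_multiplier=0.0, sfrp1_enabled=False)
        d = reaction_rhs(state(), 5.0, P, sc)
        assert np.all(d == 0.0)

    def test_ligand_receptor_binding_stoichiometry(self):
        # W=1 nM meets R=75 nM outside both sources
        sc = Scenario(sfrp1_enabled=False)
        d = reaction_rhs(state(W=1.0, R=75.0), 50.0, P, sc)
        rate = P.k1 * 1.0 * 75.0**2
        assert d[SPECIES_INDEX["WR2"]] == pytest.approx(rate)          # 1.496e-2
        assert d[SPECIES_INDEX["R"]] == pytest.approx(-2.0 * rate)     # two receptors consumed
        assert d[SPECIES_INDEX["W"]] == pytest.approx(-rate)

    def test_internalization_drives_signal_and_feedback(self):
        d = reaction_rhs(state(WR2=1.0), 50.0, P, Scenario())
        assert d[SPECIES_INDEX["omega"]] == pytest.approx(2.52e-4)
        assert d[SPECIES_INDEX["R"]] == pytest.approx(
            P.p3 * P.k4 * 1.0 + 2.0 * P.k1_off)  # feedback + dissociation (2 R back)
        assert d[SPECIES_INDEX["WR2"]] == pytest.approx(-(P.k1_off + P.k4))

    def test_nan_and_negative_inputs_named(self):
        bad = state(W=1.0)
        bad[SPECIES_INDEX["S"]] = np.nan
        with pytest.raises(IntegrityError, match="'S'"):
            reaction_rhs(bad, 5.0, P, Scenario())
        bad = state(R=-1.0)
        with pytest.raises(IntegrityError, match="'R'"):
            reaction_rhs(bad, 5.0, P, Scenario())

    def test_moiety_stoichiometry_closes(self):
        """Weighted column sums of the rhs vanish for conserved moieties."""
        rng = np.random.default_rng(0)
        sc = Scenario(dnfzd7_condition="both_functions")
        eff = effective_parameters(P, sc)
        weights = {
            "hs": {"H": 1, "SH": 1, "WSH": 1},
            "fzd7_minus_feedback": {"R": 1, "WR2": 2, "RD": 1, "WRD": 1},
            "dnfzd7": {"Dn": 1, "RD": 1, "D2": 2, "WD2": 2, "WRD": 1},
        }
        for _ in range(20):
            s = state(**{name: rng.uniform(0, 10) for name in SPECIES[:-1]})
            d = reaction_rhs(s, 50.0, P, sc)
            internal = eff.k4 * s[SPECIES_INDEX["WR2"]]
            hs_flux = sum(w * d[SPECIES_INDEX[n]] for n, w in weights["hs"].items())
            assert hs_flux == pytest.approx(0.0, abs=1e-12)
            fz = sum(w * d[SPECIES_INDEX[n]]
                     for n, w in weights["fzd7_minus_feedback"].items())
            assert fz == pytest.approx((eff.p3 - 2.0) * internal, rel=1e-9)
            dn = sum(w * d[SPECIES_INDEX[n]] for n, w in weights["dnfzd7"].items())
            assert dn == pytest.approx(eff.p4 * internal, rel=1e-9)


class TestNondimensionalization:
    def test_printed_scale_factors(self):
        s = nondimensionalize(P)
        assert s.c_star == pytest.approx(10.0)          # p1 * t_max
        assert s.scaled["k4"] == pytest.approx(25.2)    # k4 * t_max
        assert s.scaled["p1"] == pytest.approx(1.0)
        assert s.scaled["diff_coef"] == pytest.approx(0.25)

    def test_round_trip_recovers_parameters(self):
        back = redimensionalize(nondimensionalize(P))
        import dataclasses
        for f in dataclasses.fields(ModelParameters):
            a, b = getattr(P, f.name), getattr(back, f.name)
            assert b == pytest.approx(a, rel=1e-12), f.name
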