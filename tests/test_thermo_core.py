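"""Microstate enumeration, energies, Boltzmann weights and ensembles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemestates import (
    BOLTZMANN_MEV_PER_K,
    Conditions,
    Microstate,
    ThermoParams,
    ensemble,
    ensemble_fractions,
    log_weight,
    microstate_energy,
    microstate_pka,
)
from hemestates.thermo_core import HEME_PAIRS, HEMES, MICROSTATES

from conftest import brute_weights


def make_params(g_ox, i_redox=0.0, g_h=500.0, i_bohr=0.0, T=288.15):
    """Convenience builder with scalar broadcast."""
    g = g_ox if isinstance(g_ox, dict) else {h: g_ox for h in HEMES}
    i = i_redox if isinstance(i_redox, dict) else {p: i_redox for p in HEME_PAIRS}
    b = i_bohr if isinstance(i_bohr, dict) else {h: i_bohr for h in HEMES}
    return ThermoParams(g_ox=g, i_redox=i, g_h=g_h, i_bohr=b, temperature=T)


params_strategy = st.builds(
    make_params,
    g_ox=st.fixed_dictionaries({h: st.floats(-300, 100) for h in HEMES}),
    i_redox=st.fixed_dictionaries({p: st.floats(-60, 80) for p in HEME_PAIRS}),
    g_h=st.floats(200, 800),
    i_bohr=st.fixed_dictionaries({h: st.floats(-120, 60) for h in HEMES}),
)


class TestMicrostates:
    def test_sixteen_unique_states(self):
        assert len(MICROSTATES) == 16
        assert len({m.label for m in MICROSTATES}) == 16

    def test_labels_and_stages(self):
        assert Microstate(frozenset(), False).label == "P0H"
        assert Microstate(frozenset({"III"}), False).label == "P3H"
        assert Microstate(frozenset({"I", "IV"}), False).label == "P14H"
        m = Microstate(frozenset({"I", "III", "IV"}), True)
        assert m.label == "P134"
        assert m.stage == 3
        assert all(m.stage in (0, 1, 2, 3) for m in MICROSTATES)

    def test_unknown_heme_rejected(self):
        with pytest.raises(ValueError, match="unknown heme"):
            Microstate(frozenset({"II"}))


class TestThermoParams:
    def test_fixture_values_transcribed(self, ppcA_Gu):
        assert ppcA_Gu.g_ox == {"I": -59, "III": -82, "IV": -66}
        assert ppcA_Gu.pair_energy("I", "III") == 28
        assert ppcA_Gu.pair_energy("III", "I") == 28  # symmetric access
        assert ppcA_Gu.g_h == 523
        assert ppcA_Gu.i_bohr["IV"] == -77
        assert ppcA_Gu.temperature == 288.15

    def test_json_roundtrip_bit_exact(self, tmp_path, ppcA_Gu):
        p = make_params({"I": -59.123456789, "III": 0.1 + 0.2, "IV": -66.0},
                        i_redox={pair: 17.000000001 for pair in HEME_PAIRS})
        path = tmp_path / "params.json"
        p.to_json(path)
        q = ThermoParams.from_json(path)
        assert q == p
        assert q.g_ox["III"] == 0.1 + 0.2  # exactly, not approximately

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            make_params(-59.0, T=0.0)
        with pytest.raises(ValueError, match="g_ox"):
            ThermoParams(g_ox={"I": 0, "III": 0}, i_redox={p: 0 for p in HEME_PAIRS},
                         g_h=500, i_bohr={h: 0 for h in HEMES})
        with pytest.raises(ValueError, match="pair"):
            ThermoParams(g_ox={h: 0 for h in HEMES},
                         i_redox={"I-III": 0, "I-IV": 0, "I-II": 0},
                         g_h=500, i_bohr={h: 0 for h in HEMES})


class TestMicrostateEnergy:
    def test_reference_state_is_zero(self, ppcA_Gu):
        assert microstate_energy(ppcA_Gu, Microstate(frozenset())) == 0.0

    @pytest.mark.parametrize("ox, expected", [
        ({"III"}, -82.0),                 # single-heme energy = g_ox
        ({"I", "III"}, -59 - 82 + 28),    # pair adds its interaction
        ({"I", "III", "IV"}, -59 - 82 - 66 + 28 + 17 + 32),
    ])
    def test_protonated_energies(self, ppcA_Gu, ox, expected):
        assert microstate_energy(ppcA_Gu, Microstate(frozenset(ox))) == pytest.approx(expected)

    def test_deprotonation_adds_gh_and_bohr(self, ppcA_Gu):
        m = Microstate(frozenset({"IV"}), True)
        assert microstate_energy(ppcA_Gu, m) == pytest.approx(-66 + 523 - 77)


class TestLogWeight:
    def test_reference_state(self, ppcA_Gu):
        m = Microstate(frozenset())
        assert log_weight(ppcA_Gu, m, Conditions(123.0, 7.0)) == 0.0

    def test_nernst_midpoint(self):
        p = make_params(-100.0, g_h=1e6)
        m = Microstate(frozenset({"I"}))
        assert log_weight(p, m, Conditions(-100.0, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_heme_iii_at_its_potential(self, ppcA_Gu):
        m = Microstate(frozenset({"III"}))
        assert log_weight(ppcA_Gu, m, Conditions(-82.0, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_protonation_ratio_is_ten_to_ph_minus_pka(self, ppcA_Gu):
        c = Conditions(-50.0, 7.3)
        for ox in (frozenset(), frozenset({"I", "IV"})):
            lw_d = log_weight(ppcA_Gu, Microstate(ox, True), c)
            lw_p = log_weight(ppcA_Gu, Microstate(ox, False), c)
            pka = microstate_pka(ppcA_Gu, ox)
            assert lw_d - lw_p == pytest.approx((c.ph - pka) * math.log(10), rel=1e-12)


class TestEnsemble:
    def test_normalization_on_grid(self, all_fixture_params):
        e = np.arange(-500.0, 501.0, 125.0)
        ph = np.arange(0.0, 14.5, 2.0)
        for p in all_fixture_params.values():
            f = ensemble_fractions(p, e[:, None], ph[None, :])
            assert f.shape == (len(e), len(ph), 16)
            np.testing.assert_allclose(f.sum(axis=-1), 1.0, atol=1e-12)
            assert (f >= 0).all() and (f <= 1).all()

    def test_fully_reduced_dominates_at_low_potential(self, ppcA_Gu):
        frac = ensemble(ppcA_Gu, Conditions(-500.0, 5.0))
        assert frac[Microstate(frozenset())] > 0.99

    def test_deprotonated_fully_oxidized_dominates_at_high_potential(self, ppcA_Gu):
        # pKa_ox ~ 6.1 < 7, so P134 dominates; its fraction is bounded by the
        # protonation equilibrium, 10^(7-6.07)/(1+10^(7-6.07)) ~ 0.895
        frac = ensemble(ppcA_Gu, Conditions(500.0, 7.0))
        p134 = frac[Microstate(frozenset(HEMES), True)]
        assert p134 == max(frac.values())
        assert p134 > 0.85

    def test_no_overflow_at_extremes(self, ppcA_Gu):
        f = ensemble_fractions(ppcA_Gu, np.array([-1000.0, 1000.0]),
                               np.array([0.0, 14.0]))
        assert np.isfinite(f).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(params=params_strategy, e=st.floats(-400, 300), ph=st.floats(2, 12))
    def test_matches_enumeration_oracle(self, params, e, ph):
        expected = brute_weights(params, e, ph)
        got = ensemble(params, Conditions(e, ph))
        for m, frac in got.items():
            assert frac == pytest.approx(expected[(m.ox_set, m.deprotonated)],
                                         abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(params=params_strategy, e=st.floats(-400, 300), ph=st.floats(2, 12))
    def test_detailed_balance(self, params, e, ph):
        kt = BOLTZMANN_MEV_PER_K * params.temperature
        got = ensemble(params, Conditions(e, ph))
        # one-heme oxidation flip
        a = Microstate(frozenset({"III"}))
        b = Microstate(frozenset({"III", "IV"}))
        dg = microstate_energy(params, b) - microstate_energy(params, a)
        assert got[b] / got[a] == pytest.approx(math.exp((e - dg) / kt), rel=1e-9)
        # protonation flip
        c = Microstate(frozenset({"III"}), True)
        pka = microstate_pka(params, {"III"})
        assert got[c] / got[a] == pytest.approx(10 ** (ph - pka), rel=1e-9)

    def test_permutation_equivariance(self):
        # swap the roles of hemes I and IV everywhere and verify the
        # ensemble permutes accordingly
        base = make_params({"I": -59, "III": -82, "IV": -66},
                           i_redox={frozenset({"I", "III"}): 28,
                                    frozenset({"I", "IV"}): 17,
                                    frozenset({"III", "IV"}): 32},
                           i_bohr={"I": -52, "III": -47, "IV": -77})
        swapped = make_params({"I": -66, "III": -82, "IV": -59},
                              i_redox={frozenset({"I", "III"}): 32,
                                       frozenset({"I", "IV"}): 17,
                                       frozenset({"III", "IV"}): 28},
                              i_bohr={"I": -77, "III": -47, "IV": -52})
        c = Conditions(-70.0, 7.5)
        fa = ensemble(base, c)
        fb = ensemble(swapped, c)
        perm = {"I": "IV", "III": "III", "IV": "I"}
        for m, frac in fa.items():
            m2 = Microstate(frozenset(perm[h] for h in m.ox_set), m.deprotonated)
            assert fb[m2] == pytest.approx(frac, rel=1e-12)


class TestMicrostatePka:
    def test_published_limits(self, ppcA_Gu):
        assert microstate_pka(ppcA_Gu, frozenset()) == pytest.approx(9.15, abs=0.01)
        assert microstate_pka(ppcA_Gu, HEMES) == pytest.approx(6.07, abs=0.01)

    def test_no_bohr_coupling_means_constant_pka(self):
        p = make_params(-80.0, i_redox=20.0, g_h=500.0, i_bohr=0.0)
        import itertools
        pkas = {microstate_pka(p, frozenset(c))
                for n in range(4) for c in itertools.combinations(HEMES, n)}
        assert len({round(v, 12) for v in pkas}) == 1
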