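"""Shared fixtures and independent brute-force oracles.

The oracle functions below re-derive ensemble quantities by direct
enumeration with plain ``math`` arithmetic, deliberately avoiding the
package's vectorized code paths, so they can serve as independent checks.
"""

from __future__ import annotations

import itertools
import math

import pytest

from hemestates import ThermoParams, fixture_params, synthetic_probes

KB = 0.08617333262  # meV/K

HEMES = ("I", "III", "IV")
PAIRS = (("I", "III"), ("I", "IV"), ("III", "IV"))


@pytest.fixture(scope="session")
def ppcA_Gu() -> ThermoParams:
    return fixture_params("ppcA_Gu")


@pytest.fixture(scope="session")
def ppcB_Gu() -> ThermoParams:
    return fixture_params("ppcB_Gu")


@pytest.fixture(scope="session")
def all_fixture_params() -> dict[str, ThermoParams]:
    return {name: fixture_params(name)
            for name in ("ppcA_Gu", "ppcB_Gu", "ppcA_Gs", "ppcB_Gs")}


@pytest.fixture(scope="session")
def probes():
    return synthetic_probes()


# -- oracles --------------------------------------------------------------

def brute_energy(params: ThermoParams, ox: frozenset, deprot: bool) -> float:
    e = sum(params.g_ox[h] for h in ox)
    for a, b in PAIRS:
        if a in ox and b in ox:
            e += params.pair_energy(a, b)
    if deprot:
        e += params.g_h + sum(params.i_bohr[h] for h in ox)
    return e


def brute_states():
    for n in range(4):
        for combo in itertools.combinations(HEMES, n):
            for deprot in (False, True):
                yield frozenset(combo), deprot


def brute_weights(params: ThermoParams, e: float, ph: float) -> dict:
    kt = KB * params.temperature
    w = {}
    for ox, deprot in brute_states():
        lw = (len(ox) * e - brute_energy(params, ox, deprot)) / kt
        if deprot:
            lw += math.log(10.0) * ph
        w[(ox, deprot)] = math.exp(lw)
    z = sum(w.values())
    return {k: v / z for k, v in w.items()}


def brute_heme_fraction(params: ThermoParams, heme: str, e: float, ph: float) -> float:
    w = brute_weights(params, e, ph)
    return sum(v for (ox, _), v in w.items() if heme in ox)


def brute_stage_conditional(params: ThermoParams, heme: str, stage: int,
                            ph: float) -> float:
    kt = KB * params.temperature
    num = den = 0.0
    for ox, deprot in brute_states():
        if len(ox) != stage:
            continue
        lw = -brute_energy(params, ox, deprot) / kt
        if deprot:
            lw += math.log(10.0) * ph
        w = math.exp(lw)
        den += w
        if heme in ox:
            num += w
    return num / den


def brute_stage_protonated_fraction(params: ThermoParams, stage: int,
                                    ph: float) -> float:
    """Protonated population of one oxidation stage, by enumeration."""
    kt = KB * params.temperature
    prot = tot = 0.0
    for ox, deprot in brute_states():
        if len(ox) != stage:
            continue
        lw = -brute_energy(params, ox, deprot) / kt
        if deprot:
            lw += math.log(10.0) * ph
        w = math.exp(lw)
        tot += w
        if not deprot:
            prot += w
    return prot / tot


def brute_stage_pka_bisect(params: ThermoParams, stage: int,
                           lo: float = -5.0, hi: float = 25.0,
                           tol: float = 1e-12) -> float:
    """pH at which the stage's protonated and deprotonated populations are
    equal, found by bisection on the enumerated ensemble."""
    def f(ph: float) -> float:
        return brute_stage_protonated_fraction(params, stage, ph) - 0.5

    assert f(lo) > 0 > f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
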