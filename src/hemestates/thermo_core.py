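"""Exact 16-microstate thermodynamics of a triheme, one-proton-center cytochrome.

A triheme cytochrome with a single acid-base ("redox-Bohr") center has
2^3 x 2 = 16 microstates: each heme is reduced or oxidized, and the Bohr
center is protonated or deprotonated.  The free energy of a microstate,
relative to the fully reduced protonated protein, is additive:

    G(m) = sum_{i oxidized} g_ox[i]
         + sum_{pairs {i,j} oxidized} i_redox[{i,j}]
         + deprotonated * (g_H + sum_{i oxidized} i_bohr[i])

with all energies in meV.  Because each heme carries one electron, a
potential of 1 mV vs SHE corresponds to 1 meV per oxidation, so solution
potential and pH enter the Boltzmann log-weight as

    ln w(m) = (n_ox * E - G(m)) / kT + deprotonated * ln(10) * pH

Positive g_ox disfavors oxidation at E = 0 (g_ox equals the heme's
reduction potential in the fully reduced, protonated protein); positive
heme-heme interactions mean that oxidizing one heme raises the apparent
potential required to oxidize its neighbor; negative heme-proton (redox-
Bohr) interactions mean deprotonation stabilizes the oxidized hemes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BOLTZMANN_MEV_PER_K",
    "HEMES",
    "HEME_ALIASES",
    "HEME_PAIRS",
    "ThermoParams",
    "Microstate",
    "Conditions",
    "MICROSTATES",
    "microstate_energy",
    "log_weight",
    "ensemble",
    "ensemble_fractions",
    "microstate_pka",
    "load_params",
    "fixture_params",
    "FIXTURE_PROTEINS",
]

#: Boltzmann constant in meV/K (CODATA).
BOLTZMANN_MEV_PER_K = 0.08617333262

#: Heme labels follow the tetraheme-cytochrome-c3 numbering convention in
#: which the missing heme is "II"; numeric aliases are used in microstate
#: labels such as P134.
HEMES: tuple[str, ...] = ("I", "III", "IV")
HEME_ALIASES: dict[str, int] = {"I": 1, "III": 3, "IV": 4}
HEME_PAIRS: tuple[frozenset[str], ...] = (
    frozenset({"I", "III"}),
    frozenset({"I", "IV"}),
    frozenset({"III", "IV"}),
)

_PAIR_KEYS = {frozenset({"I", "III"}): "I-III",
              frozenset({"I", "IV"}): "I-IV",
              frozenset({"III", "IV"}): "III-IV"}


def _check_heme(label: str) -> str:
    if label not in HEMES:
        raise ValueError(f"unknown heme label {label!r}; expected one of {HEMES}")
    return label


def _normalize_pair_map(i_redox: Mapping) -> dict[frozenset, float]:
    """Accept 'I-III'-style keys, tuples or frozensets; return frozenset keys."""
    out: dict[frozenset, float] = {}
    for key, value in i_redox.items():
        if isinstance(key, str):
            parts = key.split("-")
            if len(parts) != 2:
                raise ValueError(f"bad heme-pair key {key!r}")
            pair = frozenset(parts)
        else:
            pair = frozenset(key)
        if pair not in HEME_PAIRS:
            raise ValueError(f"bad heme pair {key!r}; expected pairs of {HEMES}")
        out[pair] = float(value)
    if set(out) != set(HEME_PAIRS):
        raise ValueError("i_redox must define exactly the pairs I-III, I-IV, III-IV")
    return out


@dataclass(frozen=True)
class ThermoParams:
    """The 10 thermodynamic parameters of a triheme cytochrome, in meV.

    Parameters
    ----------
    g_ox
        Oxidation energy per heme; numerically the heme's reduction
        potential (mV vs SHE) in the fully reduced, protonated protein.
    i_redox
        Symmetric heme-heme redox interaction energies for the three
        pairs; keys may be "I-III" strings or frozensets.
    g_h
        Deprotonation energy of the redox-Bohr center in the fully
        reduced protein.
    i_bohr
        Redox-Bohr (heme-proton) interaction energy per heme.
    temperature
        Absolute temperature in kelvin; default 288.15 K (15 degC, the
        temperature at which titrations of these proteins are run).
    protein
        Optional display name.
    """

    g_ox: Mapping[str, float]
    i_redox: Mapping
    g_h: float
    i_bohr: Mapping[str, float]
    temperature: float = 288.15
    protein: str = ""

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if set(self.g_ox) != set(HEMES):
            raise ValueError(f"g_ox must define exactly hemes {HEMES}")
        if set(self.i_bohr) != set(HEMES):
            raise ValueError(f"i_bohr must define exactly hemes {HEMES}")
        object.__setattr__(self, "g_ox", {h: float(self.g_ox[h]) for h in HEMES})
        object.__setattr__(self, "i_bohr", {h: float(self.i_bohr[h]) for h in HEMES})
        object.__setattr__(self, "i_redox", _normalize_pair_map(self.i_redox))
        object.__setattr__(self, "g_h", float(self.g_h))
        object.__setattr__(self, "temperature", float(self.temperature))

    @property
    def kt(self) -> float:
        """Thermal energy kT in meV."""
        return BOLTZMANN_MEV_PER_K * self.temperature

    def pair_energy(self, a: str, b: str) -> float:
        return self.i_redox[frozenset({_check_heme(a), _check_heme(b)})]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "temperature_K": self.temperature,
            "g_ox": dict(self.g_ox),
            "i_redox": {_PAIR_KEYS[p]: v for p, v in sorted(
                self.i_redox.items(), key=lambda kv: _PAIR_KEYS[kv[0]])},
            "g_H": self.g_h,
            "i_bohr": dict(self.i_bohr),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ThermoParams":
        return cls(
            g_ox=d["g_ox"],
            i_redox=d["i_redox"],
            g_h=d["g_H"],
            i_bohr=d["i_bohr"],
            temperature=d.get("temperature_K", 288.15),
            protein=d.get("protein", ""),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ThermoParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def as_vector(self) -> np.ndarray:
        """Pack the 10 parameters in the canonical order.

        Order: g_ox(I, III, IV), i_redox(I-III, I-IV, III-IV), g_H,
        i_bohr(I, III, IV).
        """
        return np.array(
            [self.g_ox[h] for h in HEMES]
            + [self.i_redox[p] for p in HEME_PAIRS]
            + [self.g_h]
            + [self.i_bohr[h] for h in HEMES]
        )

    @classmethod
    def from_vector(cls, theta: Iterable[float], temperature: float = 288.15,
                    protein: str = "") -> "ThermoParams":
        t = np.asarray(list(theta), dtype=float)
        if t.shape != (10,):
            raise ValueError("parameter vector must have length 10")
        return cls(
            g_ox={h: t[i] for i, h in enumerate(HEMES)},
            i_redox={p: t[3 + i] for i, p in enumerate(HEME_PAIRS)},
            g_h=t[6],
            i_bohr={h: t[7 + i] for i, h in enumerate(HEMES)},
            temperature=temperature,
            protein=protein,
        )


PARAM_NAMES: tuple[str, ...] = (
    "g_ox[I]", "g_ox[III]", "g_ox[IV]",
    "i_redox[I-III]", "i_redox[I-IV]", "i_redox[III-IV]",
    "g_H",
    "i_bohr[I]", "i_bohr[III]", "i_bohr[IV]",
)


@dataclass(frozen=True)
class Microstate:
    """One of the 16 microstates: an oxidized-heme set and a protonation flag."""

    ox_set: frozenset[str]
    deprotonated: bool = False

    def __post_init__(self) -> None:
        ox = frozenset(_check_heme(h) for h in self.ox_set)
        object.__setattr__(self, "ox_set", ox)

    @property
    def stage(self) -> int:
        """Oxidation stage S0-S3: the number of oxidized hemes."""
        return len(self.ox_set)

    @property
    def label(self) -> str:
        digits = "".join(str(a) for a in sorted(HEME_ALIASES[h] for h in self.ox_set))
        return "P" + (digits or "0") + ("" if self.deprotonated else "H")


def _enumerate_microstates() -> tuple[Microstate, ...]:
    states = []
    for n in range(4):
        for combo in itertools.combinations(HEMES, n):
            for deprot in (False, True):
                states.append(Microstate(frozenset(combo), deprot))
    # order by (stage, label) so argmax tie-breaks resolve to lower stages
    return tuple(sorted(states, key=lambda m: (m.stage, m.label)))


#: The canonical, immutable list of all 16 microstates, ordered by stage.
MICROSTATES: tuple[Microstate, ...] = _enumerate_microstates()
MICROSTATE_LABELS: tuple[str, ...] = tuple(m.label for m in MICROSTATES)

# Structure matrices reused by every ensemble computation: which hemes and
# heme pairs are oxidized in each microstate, and its protonation flag.
_OX = np.array([[h in m.ox_set for h in HEMES] for m in MICROSTATES], dtype=float)
_PAIR = np.array([[p <= m.ox_set for p in HEME_PAIRS] for m in MICROSTATES], dtype=float)
_DEPROT = np.array([m.deprotonated for m in MICROSTATES], dtype=float)
_NOX = _OX.sum(axis=1)


@dataclass(frozen=True)
class Conditions:
    """Solution conditions: redox potential (mV vs SHE) and pH."""

    potential: float
    ph: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.potential) and math.isfinite(self.ph)):
            raise ValueError("potential and pH must be finite")


def _energy_vector(params: ThermoParams) -> np.ndarray:
    """G(m) for all 16 microstates, meV, in MICROSTATES order."""
    g = np.array([params.g_ox[h] for h in HEMES])
    i = np.array([params.i_redox[p] for p in HEME_PAIRS])
    b = np.array([params.i_bohr[h] for h in HEMES])
    return _OX @ g + _PAIR @ i + _DEPROT * (params.g_h + _OX @ b)


def microstate_energy(params: ThermoParams, m: Microstate) -> float:
    """Free energy of microstate ``m`` relative to P0H (fully reduced,
    protonated), in meV.  The proton chemical potential is not included."""
    e = sum(params.g_ox[h] for h in m.ox_set)
    e += sum(params.i_redox[p] for p in HEME_PAIRS if p <= m.ox_set)
    if m.deprotonated:
        e += params.g_h + sum(params.i_bohr[h] for h in m.ox_set)
    return e


def log_weight(params: ThermoParams, m: Microstate, c: Conditions) -> float:
    """Natural log of the Boltzmann weight of ``m`` relative to P0H.

    Guarantees: at fixed ox_set the deprotonated/protonated population
    ratio is 10**(pH - pKa(ox_set)); for a lone heme with zero
    interactions the oxidized/reduced ratio is exp((E - g_ox)/kT).
    """
    kt = params.kt
    lw = (m.stage * c.potential - microstate_energy(params, m)) / kt
    # the deprotonation part of G is already in microstate_energy; add the
    # proton chemical-potential term
    if m.deprotonated:
        lw += math.log(10.0) * c.ph
    return lw


def _log_weights(params: ThermoParams, potential, ph) -> np.ndarray:
    """Vectorized log-weights; broadcasts over potential/pH arrays.

    Returns an array of shape broadcast(potential, ph).shape + (16,).
    """
    e = np.asarray(potential, dtype=float)[..., None]
    p = np.asarray(ph, dtype=float)[..., None]
    g = _energy_vector(params)
    return (_NOX * e - g) / params.kt + _DEPROT * math.log(10.0) * p


def ensemble_fractions(params: ThermoParams, potential, ph) -> np.ndarray:
    """Normalized molar fractions of the 16 microstates (log-sum-exp).

    ``potential`` and ``ph`` may be scalars or broadcastable arrays; the
    last axis of the result indexes :data:`MICROSTATES`.
    """
    lw = _log_weights(params, potential, ph)
    lw -= lw.max(axis=-1, keepdims=True)
    w = np.exp(lw)
    return w / w.sum(axis=-1, keepdims=True)


def ensemble(params: ThermoParams, c: Conditions) -> dict[Microstate, float]:
    """Molar fraction of every microstate at the given conditions."""
    f = ensemble_fractions(params, c.potential, c.ph)
    return dict(zip(MICROSTATES, np.atleast_1d(np.squeeze(f))))


def microstate_pka(params: ThermoParams, ox_set: Iterable[str]) -> float:
    """pKa of the redox-Bohr center when exactly ``ox_set`` is oxidized.

    pKa(ox_set) = (g_H + sum_{i in ox_set} i_bohr[i]) / (kT ln 10).
    """
    ox = frozenset(_check_heme(h) for h in ox_set)
    num = params.g_h + sum(params.i_bohr[h] for h in ox)
    return num / (params.kt * math.log(10.0))


# -- bundled parameter sets ----------------------------------------------

FIXTURE_PROTEINS: tuple[str, ...] = ("ppcA_Gu", "ppcB_Gu", "ppcA_Gs", "ppcB_Gs")


def load_params(path: str | Path) -> ThermoParams:
    """Load a parameter file (JSON with keys protein, temperature_K, g_ox,
    i_redox, g_H, i_bohr)."""
    return ThermoParams.from_json(Path(path))


def fixture_params(protein: str) -> ThermoParams:
    """Return the published parameter set for one of the four bundled
    proteins: ppcA_Gu, ppcB_Gu, ppcA_Gs, ppcB_Gs."""
    if protein not in FIXTURE_PROTEINS:
        raise ValueError(f"unknown protein {protein!r}; expected one of {FIXTURE_PROTEINS}")
    from importlib.resources import files

    text = (files("hemestates") / "data" / f"{protein}.json").read_text()
    return ThermoParams.from_dict(json.loads(text))
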