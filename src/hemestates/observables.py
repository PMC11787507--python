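"""Derived redox observables of the 16-state ensemble.

Everything here is a marginal or conditional of the microstate ensemble in
:mod:`hemestates.thermo_core`: per-heme oxidation curves against solution
potential, oxidation fractions conditional on the NMR-resolved oxidation
stage, macroscopic pKa values of the redox-Bohr center per stage, heme
midpoint potentials, and the sequence of dominant microstates along an
oxidation route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .thermo_core import (
    HEMES,
    MICROSTATES,
    MICROSTATE_LABELS,
    Conditions,
    ThermoParams,
    _DEPROT,
    _NOX,
    _OX,
    _energy_vector,
    ensemble_fractions,
    microstate_pka,
)

__all__ = [
    "OxidationCurve",
    "PkaTable",
    "heme_oxidation_fraction",
    "oxidation_curve",
    "stage_conditional_fraction",
    "stage_pka",
    "delta_pka",
    "pka_table",
    "midpoint_potential",
    "deprotonated_potentials",
    "dominant_microstate_route",
]


def _heme_index(heme: str) -> int:
    try:
        return HEMES.index(heme)
    except ValueError:
        raise ValueError(f"unknown heme label {heme!r}; expected one of {HEMES}") from None


@dataclass(frozen=True)
class OxidationCurve:
    """Fraction of one heme oxidized along a potential grid at fixed pH."""

    heme: str
    potential_mv: np.ndarray
    fraction: np.ndarray
    ph: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.potential_mv, dtype=float)
        frac = np.asarray(self.fraction, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("potential grid must be 1-D and strictly increasing")
        if frac.shape != grid.shape or np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
            raise ValueError("fractions must match the grid and lie in [0, 1]")
        object.__setattr__(self, "potential_mv", grid)
        object.__setattr__(self, "fraction", frac)


@dataclass(frozen=True)
class PkaTable:
    """Macroscopic pKa of the redox-Bohr center per oxidation stage."""

    protein: str
    stage_pkas: tuple[float, float, float, float]

    @property
    def delta_pka(self) -> float:
        return self.stage_pkas[0] - self.stage_pkas[3]


def heme_oxidation_fraction(params: ThermoParams, heme: str, c: Conditions) -> float:
    """Marginal probability that ``heme`` is oxidized at conditions ``c``."""
    j = _heme_index(heme)
    f = ensemble_fractions(params, c.potential, c.ph)
    return float(f @ _OX[:, j])


def oxidation_curve(params: ThermoParams, heme: str, e_grid, ph: float) -> OxidationCurve:
    """Oxidation fraction of ``heme`` on a potential grid (vectorized)."""
    j = _heme_index(heme)
    grid = np.asarray(e_grid, dtype=float)
    f = ensemble_fractions(params, grid, ph) @ _OX[:, j]
    return OxidationCurve(heme=heme, potential_mv=grid, fraction=f, ph=float(ph))


def _stage_log_weights(params: ThermoParams, stage: int, ph: float) -> np.ndarray:
    # within a stage all microstates share n_ox, so the potential term is a
    # common factor and cancels on normalization
    mask = _NOX == stage
    g = _energy_vector(params)[mask]
    return -g / params.kt + _DEPROT[mask] * math.log(10.0) * ph


def stage_conditional_fraction(params: ThermoParams, heme: str, stage: int,
                               ph: float) -> float:
    """P(heme oxidized | oxidation stage) at the given pH.

    This is the quantity the stage-resolved NMR experiment sees: the
    ensemble restricted to microstates with ``stage`` oxidized hemes.  It
    is independent of the solution potential.
    """
    if stage not in (0, 1, 2, 3):
        raise ValueError("stage must be 0, 1, 2 or 3")
    j = _heme_index(heme)
    mask = _NOX == stage
    lw = _stage_log_weights(params, stage, ph)
    w = np.exp(lw - lw.max())
    return float((w @ _OX[mask, j]) / w.sum())


def stage_pka(params: ThermoParams, stage: int) -> float:
    """Macroscopic pKa of the redox-Bohr center at one oxidation stage.

    The stage's apparent acidity constant is the Boltzmann average of the
    microscopic Ka over the stage's protonated microstates:

        Ka_n = sum_ox w0(ox) 10**(-pKa(ox)) / sum_ox w0(ox),
        w0(ox) = exp(-G(ox, protonated)/kT),  |ox| = n.
    """
    if stage not in (0, 1, 2, 3):
        raise ValueError("stage must be 0, 1, 2 or 3")
    mask = (_NOX == stage) & (_DEPROT == 0)
    g = _energy_vector(params)[mask]
    logw = -g / params.kt
    logw -= logw.max()
    w = np.exp(logw)
    pkas = np.array([microstate_pka(params, m.ox_set)
                     for m, keep in zip(MICROSTATES, mask) if keep])
    ka = (w @ np.power(10.0, -pkas)) / w.sum()
    return float(-math.log10(ka))


def delta_pka(params: ThermoParams) -> float:
    """Total redox-Bohr effect: stage-0 minus stage-3 macroscopic pKa.

    Equals -sum_i i_bohr[i] / (kT ln 10) exactly, so negative heme-proton
    couplings give a positive pKa drop on full oxidation.
    """
    return stage_pka(params, 0) - stage_pka(params, 3)


def pka_table(params: ThermoParams) -> PkaTable:
    return PkaTable(protein=params.protein,
                    stage_pkas=tuple(stage_pka(params, n) for n in range(4)))


def midpoint_potential(params: ThermoParams, heme: str, ph: float,
                       bracket: tuple[float, float] = (-1000.0, 1000.0)) -> float:
    """Potential (mV vs SHE) at which ``heme`` is half oxidized at ``ph``.

    Root of the (monotone) oxidation-fraction curve; raises if the curve
    does not cross 1/2 inside ``bracket``.
    """
    j = _heme_index(heme)

    def f(e: float) -> float:
        return float(ensemble_fractions(params, e, ph) @ _OX[:, j]) - 0.5

    lo, hi = bracket
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"oxidation fraction of heme {heme} does not cross "
                         f"1/2 inside [{lo}, {hi}] mV")
    return float(brentq(f, lo, hi, xtol=1e-3))


def deprotonated_potentials(params: ThermoParams) -> dict[str, float]:
    """Heme reduction potentials in the deprotonated protein: the protonated
    value plus the heme's redox-Bohr interaction, per heme."""
    return {h: params.g_ox[h] + params.i_bohr[h] for h in HEMES}


def dominant_microstate_route(params: ThermoParams, ph: float, e_grid) -> list[str]:
    """Sequence of globally dominant microstates along an oxidation sweep.

    ``e_grid`` must be increasing and span the full oxidation range (total
    oxidation < 1% at its low end and > 99% at its high end).  Returns the
    deduplicated labels of the most-populated microstate at each grid
    potential; at ties the lower-stage microstate wins.
    """
    grid = np.asarray(e_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("e_grid must be 1-D and strictly increasing")
    f = ensemble_fractions(params, grid, ph)
    total_ox = (f @ _NOX) / 3.0
    if total_ox[0] > 0.01 or total_ox[-1] < 0.99:
        raise ValueError(
            "e_grid does not span full oxidation (need <1% oxidized at the "
            f"low end and >99% at the high end; got {total_ox[0]:.3f} and "
            f"{total_ox[-1]:.3f})")
    # MICROSTATES is ordered by stage, and argmax returns the first maximum,
    # so ties break toward the lower-stage state
    idx = np.argmax(f, axis=-1)
    route: list[str] = []
    for i in idx:
        lab = MICROSTATE_LABELS[i]
        if not route or route[-1] != lab:
            route.append(lab)
    return route
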