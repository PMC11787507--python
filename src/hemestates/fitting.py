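"""Simultaneous weighted least-squares fit of the 10 thermodynamic
parameters to combined NMR and visible-titration data.

The stage-resolved NMR shifts constrain every energy *difference* between
microstates but are invariant to a uniform shift of all three oxidation
energies (one can add a constant to every g_ox and the same constant to
the solution potential without changing any stage-restricted population).
The visible titration, measured against an absolute potential scale, pins
that gauge freedom; the two datasets are therefore fitted together, each
record weighted by the inverse of its stated uncertainty.

Free parameters: the 10 thermodynamic energies plus, per methyl probe, the
oxidized-state shifts for the protonated and deprotonated forms of the
redox-Bohr center (the reduced-state shift is fixed from stage-0 data and
is not fitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .nmr_model import MethylProbe
from .thermo_core import (
    HEMES,
    HEME_PAIRS,
    PARAM_NAMES,
    ThermoParams,
    _DEPROT,
    _NOX,
    _OX,
    _PAIR,
)

__all__ = [
    "FitProblem",
    "FitResult",
    "IdentifiabilityError",
    "simultaneous_fit",
    "standard_errors",
    "multi_start",
    "default_initial_params",
]

_LN10 = math.log(10.0)

#: Default optimizer bounds per thermodynamic parameter, meV.
DEFAULT_BOUNDS = {
    "g_ox": (-500.0, 500.0),
    "i_redox": (-200.0, 200.0),
    "g_H": (0.0, 1500.0),
    "i_bohr": (-300.0, 300.0),
}
_SHIFT_BOUNDS = (-100.0, 100.0)


class IdentifiabilityError(ValueError):
    """Raised when the requested parameters cannot be determined from the
    supplied data (e.g. absolute potentials from NMR data alone)."""


@dataclass
class FitProblem:
    """Inputs of a simultaneous NMR + visible fit.

    Parameters
    ----------
    nmr
        DataFrame with columns probe_id, heme, stage, pH, shift_ppm,
        sigma_ppm (stages 1-3).
    visible
        DataFrame with columns pH, potential_mV, reduced_fraction, sigma.
    probes
        Probe definitions; ``delta_red`` is fixed, the oxidized shifts act
        as initial guesses for the nuisance parameters.
    init
        Initial thermodynamic parameters; if None a data-driven default is
        used (see :func:`default_initial_params`).
    free
        Optional map parameter-name -> bool; parameters absent from the
        map are free.  Names as in ``PARAM_NAMES``.
    nmr_weight
        Optional multiplier on the NMR block's weights (default 1: plain
        inverse-variance weighting, no inter-dataset rebalancing).
    """

    nmr: pd.DataFrame
    visible: pd.DataFrame
    probes: list[MethylProbe]
    init: ThermoParams | None = None
    free: dict[str, bool] = field(default_factory=dict)
    nmr_weight: float = 1.0
    temperature: float = 288.15
    ftol: float = 1e-12
    xtol: float = 1e-10
    max_nfev: int = 500 * 30


@dataclass
class FitResult:
    """Outcome of a simultaneous fit."""

    params: ThermoParams
    probes: list[MethylProbe]
    theta: np.ndarray
    param_names: tuple[str, ...]
    free_mask: np.ndarray
    se: np.ndarray
    residuals: np.ndarray
    chi2: float
    reduced_chi2: float
    converged: bool
    message: str
    n_eval: int
    n_data: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "probes": [vars(p) for p in self.probes],
            "standard_errors": {n: (None if not f else s)
                                for n, f, s in zip(self.param_names,
                                                   self.free_mask,
                                                   self.se)},
            "chi2": self.chi2,
            "reduced_chi2": self.reduced_chi2,
            "converged": self.converged,
            "message": self.message,
            "n_data": self.n_data,
        }


def _nuisance_names(probes: list[MethylProbe]) -> tuple[str, ...]:
    names: list[str] = []
    for p in probes:
        names += [f"delta_ox_prot[{p.id}]", f"delta_ox_deprot[{p.id}]"]
    return tuple(names)


def default_initial_params(visible: pd.DataFrame,
                           temperature: float = 288.15) -> ThermoParams:
    """Data-driven starting point: every oxidation energy at the visible
    curve's half-reduction potential, heme-heme interactions at +20 meV,
    g_H at 500 meV and redox-Bohr interactions at -30 meV."""
    e_half = 0.0
    if len(visible):
        # use a single-pH slice so the curve is monotone for interpolation
        sub = visible[visible["pH"] == visible["pH"].min()]
        sub = sub.sort_values("potential_mV")
        e = sub["potential_mV"].to_numpy(float)
        f = sub["reduced_fraction"].to_numpy(float)
        # reduced fraction decreases with E; interpolate the 1/2 crossing
        e_half = float(np.interp(0.5, f[::-1], e[::-1]))
    return ThermoParams(
        g_ox={h: e_half for h in HEMES},
        i_redox={p: 20.0 for p in HEME_PAIRS},
        g_h=500.0,
        i_bohr={h: -30.0 for h in HEMES},
        temperature=temperature,
    )


class _Model:
    """Vectorized residual evaluator shared by fit and covariance code."""

    def __init__(self, problem: FitProblem):
        nmr, vis, probes = problem.nmr, problem.visible, problem.probes
        self.probes = probes
        self.kt = 0.08617333262 * problem.temperature
        by_id = {p.id: j for j, p in enumerate(probes)}
        unknown = set(nmr["probe_id"]) - set(by_id)
        if unknown:
            raise ValueError(f"NMR records reference unknown probes {sorted(unknown)}")
        self.probe_idx = nmr["probe_id"].map(by_id).to_numpy(int)
        self.stage = nmr["stage"].to_numpy(int)
        self.ph = nmr["pH"].to_numpy(float)
        self.obs_shift = nmr["shift_ppm"].to_numpy(float)
        self.sigma_shift = nmr["sigma_ppm"].to_numpy(float)
        if np.any(self.sigma_shift <= 0):
            raise ValueError("NMR uncertainties must be positive")
        self.vis_e = vis["potential_mV"].to_numpy(float)
        self.vis_ph = vis["pH"].to_numpy(float)
        self.obs_red = vis["reduced_fraction"].to_numpy(float)
        self.sigma_red = vis["sigma"].to_numpy(float)
        if np.any(self.sigma_red <= 0):
            raise ValueError("visible uncertainties must be positive")
        self.w_nmr = math.sqrt(problem.nmr_weight)
        # stage-restriction mask per NMR record (n_rec, 16)
        self.stage_ok = _NOX[None, :] == self.stage[:, None]
        # which microstates have the record's probe heme oxidized
        heme_idx = np.array([HEMES.index(p.heme) for p in probes])
        self.rec_ox = _OX[:, heme_idx[self.probe_idx]].T.astype(bool)  # (n_rec,16)
        self.delta_red = np.array([p.delta_red for p in probes])

    @property
    def n_data(self) -> int:
        return len(self.obs_shift) + len(self.obs_red)

    def _energies(self, theta10: np.ndarray) -> np.ndarray:
        g, i, gh, b = theta10[:3], theta10[3:6], theta10[6], theta10[7:]
        return _OX @ g + _PAIR @ i + _DEPROT * (gh + _OX @ b)

    def predict_nmr(self, theta10: np.ndarray, nuis: np.ndarray) -> np.ndarray:
        G = self._energies(theta10)
        lw = (-G / self.kt)[None, :] + np.outer(self.ph * _LN10, _DEPROT)
        lw = np.where(self.stage_ok, lw, -np.inf)
        lw -= lw.max(axis=1, keepdims=True)
        w = np.exp(lw)
        w /= w.sum(axis=1, keepdims=True)
        dox_prot = nuis[0::2][self.probe_idx]
        dox_deprot = nuis[1::2][self.probe_idx]
        red = self.delta_red[self.probe_idx]
        shifts = np.where(
            self.rec_ox,
            np.where(_DEPROT[None, :].astype(bool), dox_deprot[:, None],
                     dox_prot[:, None]),
            red[:, None],
        )
        return (w * shifts).sum(axis=1)

    def predict_visible(self, theta10: np.ndarray) -> np.ndarray:
        G = self._energies(theta10)
        lw = (np.outer(self.vis_e, _NOX) - G[None, :]) / self.kt \
            + np.outer(self.vis_ph * _LN10, _DEPROT)
        lw -= lw.max(axis=1, keepdims=True)
        w = np.exp(lw)
        w /= w.sum(axis=1, keepdims=True)
        return 1.0 - (w @ _NOX) / 3.0

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        t10, nuis = theta[:10], theta[10:]
        r_nmr = (self.obs_shift - self.predict_nmr(t10, nuis)) / self.sigma_shift
        r_vis = (self.obs_red - self.predict_visible(t10)) / self.sigma_red
        return np.concatenate([self.w_nmr * r_nmr, r_vis])


def _assemble_theta0(problem: FitProblem) -> tuple[np.ndarray, tuple[str, ...]]:
    init = problem.init or default_initial_params(problem.visible,
                                                  problem.temperature)
    nuis0 = []
    for p in problem.probes:
        nuis0 += [p.delta_ox_prot, p.delta_ox_deprot]
    names = PARAM_NAMES + _nuisance_names(problem.probes)
    return np.concatenate([init.as_vector(), nuis0]), names


def _bounds(problem: FitProblem, names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for n in names:
        if n.startswith("g_ox"):
            b = DEFAULT_BOUNDS["g_ox"]
        elif n.startswith("i_redox"):
            b = DEFAULT_BOUNDS["i_redox"]
        elif n == "g_H":
            b = DEFAULT_BOUNDS["g_H"]
        elif n.startswith("i_bohr"):
            b = DEFAULT_BOUNDS["i_bohr"]
        else:
            b = _SHIFT_BOUNDS
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


def _free_mask(problem: FitProblem, names: tuple[str, ...]) -> np.ndarray:
    return np.array([problem.free.get(n, True) for n in names], dtype=bool)


def simultaneous_fit(problem: FitProblem, *, theta0: np.ndarray | None = None,
                     seed: int | None = None) -> FitResult:
    """Fit the thermodynamic and nuisance parameters by weighted least
    squares (bounded trust-region reflective).

    Deterministic for identical inputs and initialization.  A problem with
    no visible data cannot determine absolute oxidation energies and
    raises :class:`IdentifiabilityError` when any g_ox is free.
    """
    if not len(problem.nmr) and not len(problem.visible):
        raise ValueError("both datasets are empty")
    names_all = PARAM_NAMES + _nuisance_names(problem.probes)
    free = _free_mask(problem, names_all)
    if not len(problem.visible) and any(
            free[i] for i, n in enumerate(names_all) if n.startswith("g_ox")):
        raise IdentifiabilityError(
            "absolute oxidation energies are unidentifiable from NMR data "
            "alone: stage-restricted populations are invariant to a uniform "
            "shift of g_ox[I], g_ox[III], g_ox[IV]; add a visible titration "
            "or fix the g_ox gauge")
    model = _Model(problem)
    full0, names = _assemble_theta0(problem)
    if theta0 is not None:
        full0 = np.asarray(theta0, dtype=float).copy()
    lo, hi = _bounds(problem, names)
    full0 = np.clip(full0, lo, hi)

    fixed = full0.copy()

    def resid(free_theta: np.ndarray) -> np.ndarray:
        theta = fixed.copy()
        theta[free] = free_theta
        return model.residuals(theta)

    sol = least_squares(resid, full0[free], bounds=(lo[free], hi[free]),
                        method="trf", ftol=problem.ftol, xtol=problem.xtol,
                        gtol=1e-12, max_nfev=problem.max_nfev)
    theta = fixed.copy()
    theta[free] = sol.x
    n_free = int(free.sum())
    dof = max(model.n_data - n_free, 1)
    chi2 = float(2 * sol.cost)
    red_chi2 = chi2 / dof

    se = np.zeros_like(theta)
    if n_free:
        J = sol.jac
        JtJ = J.T @ J
        sv = np.linalg.svd(JtJ, compute_uv=False)
        if sv[0] <= 0 or sv[-1] / sv[0] < 1e-13:
            _, _, vt = np.linalg.svd(J, full_matrices=False)
            null = vt[-1]
            worst = np.array(names)[free][np.argsort(-np.abs(null))[:3]]
            raise IdentifiabilityError(
                "singular Jacobian at the optimum; the combination of "
                f"parameters {', '.join(worst)} is unidentifiable from the "
                "supplied data")
        cov = np.linalg.inv(JtJ) * red_chi2
        se[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))

    params = ThermoParams.from_vector(theta[:10], temperature=problem.temperature,
                                      protein=problem.init.protein if problem.init else "")
    probes = [MethylProbe(id=p.id, heme=p.heme, delta_red=p.delta_red,
                          delta_ox_prot=theta[10 + 2 * j],
                          delta_ox_deprot=theta[10 + 2 * j + 1])
              for j, p in enumerate(problem.probes)]
    return FitResult(params=params, probes=probes, theta=theta,
                     param_names=names, free_mask=free, se=se,
                     residuals=model.residuals(theta), chi2=chi2,
                     reduced_chi2=red_chi2, converged=bool(sol.success),
                     message=sol.message, n_eval=int(sol.nfev),
                     n_data=model.n_data, seed=seed)


def standard_errors(result: FitResult) -> dict[str, float]:
    """Asymptotic standard errors of the free parameters (meV / ppm),
    scaled by the reduced chi-square."""
    return {n: float(s) for n, f, s in
            zip(result.param_names, result.free_mask, result.se) if f}


#: Scale of the random perturbations used by multi-start, per block (meV/ppm).
_PERTURB = {"g_ox": 30.0, "i_redox": 15.0, "g_H": 50.0, "i_bohr": 20.0,
            "shift": 1.0}


def multi_start(problem: FitProblem, n_starts: int = 5,
                seed: int = 20241214) -> FitResult:
    """Best of ``n_starts`` fits from randomly perturbed initializations.

    The first start is the unperturbed default; the rest add uniform
    perturbations (scales per parameter block).  Deterministic given
    ``seed``; with ``n_starts=1`` this is exactly :func:`simultaneous_fit`.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    full0, names = _assemble_theta0(problem)
    scales = np.array([
        _PERTURB["g_ox"] if n.startswith("g_ox")
        else _PERTURB["i_redox"] if n.startswith("i_redox")
        else _PERTURB["g_H"] if n == "g_H"
        else _PERTURB["i_bohr"] if n.startswith("i_bohr")
        else _PERTURB["shift"]
        for n in names])
    best: FitResult | None = None
    for k in range(n_starts):
        theta0 = full0 if k == 0 else full0 + rng.uniform(-1, 1, full0.size) * scales
        res = simultaneous_fit(problem, theta0=theta0, seed=seed)
        if best is None or res.chi2 < best.chi2:
            best = res
    return best
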