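"""Forward model for stage-resolved heme-methyl chemical shifts.

Intramolecular electron exchange is fast on the NMR time scale while
intermolecular exchange is slow, so a partially oxidized sample shows one
signal per heme methyl per oxidation stage, at the population-weighted
average position over the stage's microstates.  A probe on a reduced heme
resonates at its diamagnetic shift ``delta_red`` (taken independent of pH
and of the oxidation of the other hemes); on an oxidized heme it resonates
at ``delta_ox_prot`` or ``delta_ox_deprot`` depending on the protonation
of the redox-Bohr center — that protonation sensitivity is what makes the
stage-3 shift pH-dependent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .thermo_core import HEMES, MICROSTATES, ThermoParams, _DEPROT, _NOX, _OX, _energy_vector

__all__ = [
    "MethylProbe",
    "load_probes",
    "synthetic_probes",
    "predicted_shift",
    "predicted_shifts",
    "oxidation_fraction_from_shifts",
    "NMR_COLUMNS",
]

#: Canonical column layout of an NMR shift dataset.
NMR_COLUMNS = ("probe_id", "heme", "stage", "pH", "shift_ppm", "sigma_ppm")


@dataclass(frozen=True)
class MethylProbe:
    """A heme-methyl reporter with its three limiting shifts (ppm)."""

    id: str
    heme: str
    delta_red: float
    delta_ox_prot: float
    delta_ox_deprot: float

    def __post_init__(self) -> None:
        if self.heme not in HEMES:
            raise ValueError(f"unknown heme label {self.heme!r}")


def load_probes(path: str | Path) -> list[MethylProbe]:
    """Read probe definitions from a JSON file with a ``probes`` list."""
    d = json.loads(Path(path).read_text())
    return [MethylProbe(id=p["id"], heme=p["heme"], delta_red=p["delta_red"],
                        delta_ox_prot=p["delta_ox_prot"],
                        delta_ox_deprot=p["delta_ox_deprot"])
            for p in d["probes"]]


def synthetic_probes() -> list[MethylProbe]:
    """The bundled synthetic probe set (invented but realistic shifts)."""
    from importlib.resources import files

    d = json.loads((files("hemestates") / "data" / "probes_synthetic.json").read_text())
    return [MethylProbe(id=p["id"], heme=p["heme"], delta_red=p["delta_red"],
                        delta_ox_prot=p["delta_ox_prot"],
                        delta_ox_deprot=p["delta_ox_deprot"])
            for p in d["probes"]]


def _probe_state_shifts(probe: MethylProbe) -> np.ndarray:
    """Shift of the probe in each of the 16 microstates, ppm."""
    j = HEMES.index(probe.heme)
    ox = _OX[:, j].astype(bool)
    shifts = np.full(len(MICROSTATES), probe.delta_red)
    shifts[ox & (_DEPROT == 0)] = probe.delta_ox_prot
    shifts[ox & (_DEPROT == 1)] = probe.delta_ox_deprot
    return shifts


def predicted_shift(params: ThermoParams, probe: MethylProbe, stage: int,
                    ph: float) -> float:
    """Observed shift of ``probe`` at oxidation stage ``stage`` and ``ph``.

    Population-weighted average over the stage-restricted ensemble; stage 0
    returns ``delta_red`` for every pH.
    """
    if stage not in (0, 1, 2, 3):
        raise ValueError("stage must be 0, 1, 2 or 3")
    if stage == 0:
        return probe.delta_red
    mask = _NOX == stage
    g = _energy_vector(params)[mask]
    lw = -g / params.kt + _DEPROT[mask] * math.log(10.0) * ph
    w = np.exp(lw - lw.max())
    return float((w @ _probe_state_shifts(probe)[mask]) / w.sum())


def predicted_shifts(params: ThermoParams, probes: list[MethylProbe],
                     records: pd.DataFrame) -> np.ndarray:
    """Vectorized forward model for a whole dataset.

    ``records`` needs columns probe_id, stage, pH; rows are evaluated
    against the matching probe in ``probes``.
    """
    by_id = {p.id: p for p in probes}
    out = np.empty(len(records))
    for k, (pid, stage, ph) in enumerate(
            zip(records["probe_id"], records["stage"], records["pH"])):
        out[k] = predicted_shift(params, by_id[pid], int(stage), float(ph))
    return out


def oxidation_fraction_from_shifts(observed: float, delta_red: float,
                                   delta_ox: float) -> float:
    """Experimental-style normalization of a shift to an oxidation fraction,
    (observed - delta_red)/(delta_ox - delta_red), clipped to [0, 1].

    Diagnostic only; the fit never uses it.
    """
    span = delta_ox - delta_red
    if span == 0:
        raise ValueError("degenerate probe: delta_ox equals delta_red")
    return float(np.clip((observed - delta_red) / span, 0.0, 1.0))
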