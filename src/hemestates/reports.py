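"""Tabular and CSV reports: parameter matrices, pKa ladders, and
curve exports."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import FitResult
from .observables import pka_table
from .thermo_core import (
    HEMES,
    MICROSTATE_LABELS,
    ThermoParams,
    _OX,
    ensemble_fractions,
)

__all__ = ["report_pka_table", "report_params_table", "report_curves"]

_ROW_LABELS = {"I": "Heme I", "III": "Heme III", "IV": "Heme IV"}


def report_pka_table(params_list: list[ThermoParams]) -> pd.DataFrame:
    """Per-protein macroscopic pKa of the redox-Bohr center at oxidation
    stages 0-3, plus the total redox-Bohr effect (stage0 - stage3).

    Full precision; round for display with ``DataFrame.round(1)``.
    """
    rows = []
    for p in params_list:
        t = pka_table(p)
        rows.append({"protein": p.protein or "?",
                     **{f"stage_{n}": t.stage_pkas[n] for n in range(4)},
                     "delta_pKa": t.delta_pka})
    cols = ["protein", "stage_0", "stage_1", "stage_2", "stage_3", "delta_pKa"]
    return pd.DataFrame(rows, columns=cols)


def _fmt(value: float, se: float | None) -> str:
    v = f"{value:.0f}"
    return f"{v} ({se:.0f})" if se is not None else v


def report_params_table(params: ThermoParams,
                        se: dict[str, float] | None = None) -> pd.DataFrame:
    """Upper-triangular energy matrix in the conventional layout: heme
    oxidation energies and the Bohr-center deprotonation energy on the
    diagonal (marked with ``*``), heme-heme and heme-proton interaction
    energies off-diagonal, all in meV.  Standard errors, when given (keys
    as in ``PARAM_NAMES``), are appended in parentheses."""
    se = se or {}
    cols = ["Heme I", "Heme III", "Heme IV", "Redox-Bohr center"]
    grid = [["" for _ in cols] for _ in range(4)]
    for i, hi in enumerate(HEMES):
        grid[i][i] = "*" + _fmt(params.g_ox[hi], se.get(f"g_ox[{hi}]"))
        for j, hj in enumerate(HEMES):
            if j > i:
                key = f"i_redox[{hi}-{hj}]"
                grid[i][j] = _fmt(params.pair_energy(hi, hj), se.get(key))
        grid[i][3] = _fmt(params.i_bohr[hi], se.get(f"i_bohr[{hi}]"))
    grid[3][3] = "*" + _fmt(params.g_h, se.get("g_H"))
    return pd.DataFrame(grid, index=[_ROW_LABELS[h] for h in HEMES]
                        + ["Redox-Bohr center"], columns=cols)


def report_fit_params_table(result: FitResult) -> pd.DataFrame:
    """Parameter matrix of a fit result with its standard errors."""
    from .fitting import standard_errors

    return report_params_table(result.params, standard_errors(result))


def report_curves(params: ThermoParams, e_grid=None, ph: float = 7.0) -> pd.DataFrame:
    """Heme oxidation fractions and microstate molar fractions on a
    potential grid (default -300..+150 mV, 1 mV steps, pH 7)."""
    grid = np.arange(-300.0, 150.5, 1.0) if e_grid is None else np.asarray(e_grid, float)
    frac = ensemble_fractions(params, grid, ph)
    out = pd.DataFrame({"potential_mV": grid})
    for j, h in enumerate(HEMES):
        out[f"frac_ox_{h}"] = frac @ _OX[:, j]
    out["frac_reduced_total"] = 1.0 - (frac @ _OX.sum(axis=1)) / 3.0
    for k, lab in enumerate(MICROSTATE_LABELS):
        out[lab] = frac[:, k]
    return out
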