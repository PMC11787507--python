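"""Forward model for potentiometric redox titrations followed by visible
spectroscopy.

The optical signal (alpha-band area between isosbestic points) does not
resolve individual hemes, so the observable is the total reduced fraction
with equal weight per heme:

    f_red(E, pH) = 1 - mean_i P(heme i oxidized | E, pH)

The measurement error is 3% of the optical signal, with a small floor so
that fully oxidized points do not get infinite weight in the fit.
"""

from __future__ import annotations

import numpy as np

from .thermo_core import Conditions, ThermoParams, _OX, ensemble_fractions

__all__ = [
    "predicted_reduced_fraction",
    "predicted_reduced_fractions",
    "visible_sigma",
    "VIS_COLUMNS",
    "RELATIVE_ERROR",
    "SIGNAL_FLOOR",
]

#: Canonical column layout of a visible-titration dataset.
VIS_COLUMNS = ("pH", "potential_mV", "reduced_fraction", "sigma")

#: Relative optical error of a titration point (3% of signal).
RELATIVE_ERROR = 0.03
#: Signal floor used when computing uncertainties near full oxidation.
SIGNAL_FLOOR = 0.05


def predicted_reduced_fraction(params: ThermoParams, c: Conditions) -> float:
    """Total reduced fraction of the three hemes at conditions ``c``."""
    f = ensemble_fractions(params, c.potential, c.ph)
    return float(1.0 - (f @ _OX.sum(axis=1)) / 3.0)


def predicted_reduced_fractions(params: ThermoParams, potential, ph) -> np.ndarray:
    """Vectorized reduced fraction over broadcastable potential/pH arrays."""
    f = ensemble_fractions(params, potential, ph)
    return 1.0 - (f @ _OX.sum(axis=1)) / 3.0


def visible_sigma(reduced_fraction) -> np.ndarray | float:
    """Uncertainty of a titration point: 3% of the signal, floored at 3% of
    ``SIGNAL_FLOOR`` so fully oxidized points keep finite weight."""
    frac = np.asarray(reduced_fraction, dtype=float)
    sig = RELATIVE_ERROR * np.maximum(frac, SIGNAL_FLOOR)
    return float(sig) if np.isscalar(reduced_fraction) else sig
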