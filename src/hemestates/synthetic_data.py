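"""Synthetic NMR and visible-titration datasets with the statistical
structure the fit assumes.

The generator reproduces the layout of the real experiments: stage-resolved
heme-methyl shifts on a pH grid from 6 to 9 in steps of 0.5 for oxidation
stages 1-3 (stage 0 fixes the reduced-state shifts and carries no free
information), and potentiometric titrations at pH 7 and 8 on a potential
grid from -250 to +50 mV in 15 mV steps.  Noise is Gaussian and
independent: a flat sigma in ppm for the shifts (default 0.005 ppm, the
order of a linewidth-derived uncertainty) and 3%-of-signal for the optical
points.  All randomness flows through one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nmr_model import NMR_COLUMNS, MethylProbe, predicted_shift, synthetic_probes
from .thermo_core import ThermoParams, fixture_params, FIXTURE_PROTEINS
from .visible_model import VIS_COLUMNS, predicted_reduced_fractions, visible_sigma

__all__ = ["GeneratorSpec", "generate_nmr", "generate_visible",
           "make_fixture_bundle"]

DEFAULT_NMR_PH = tuple(np.arange(6.0, 9.01, 0.5))
DEFAULT_VIS_POTENTIALS = tuple(np.arange(-250.0, 50.1, 15.0))
DEFAULT_VIS_PH = (7.0, 8.0)


@dataclass
class GeneratorSpec:
    """Truth parameters plus experimental design for one synthetic study."""

    params: ThermoParams
    probes: list[MethylProbe] = field(default_factory=synthetic_probes)
    nmr_ph: tuple[float, ...] = DEFAULT_NMR_PH
    vis_potentials: tuple[float, ...] = DEFAULT_VIS_POTENTIALS
    vis_ph: tuple[float, ...] = DEFAULT_VIS_PH
    nmr_sigma_ppm: float = 0.005
    visible_noise: bool = True
    seed: int = 20241214

    def __post_init__(self) -> None:
        if self.nmr_sigma_ppm < 0:
            raise ValueError("noise sigma must be nonnegative")
        if not (len(self.nmr_ph) and len(self.vis_potentials) and len(self.vis_ph)):
            raise ValueError("design grids must be nonempty")


def generate_nmr(spec: GeneratorSpec) -> pd.DataFrame:
    """One record per (probe, stage 1-3, pH): forward shift plus N(0, sigma).

    With ``nmr_sigma_ppm == 0`` the dataset equals the forward predictions
    exactly and the sigma column falls back to 1.0 so the records still
    carry finite least-squares weights.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for probe in spec.probes:
        for stage in (1, 2, 3):
            for ph in spec.nmr_ph:
                shift = predicted_shift(spec.params, probe, stage, float(ph))
                rows.append((probe.id, probe.heme, stage, float(ph), shift,
                             spec.nmr_sigma_ppm if spec.nmr_sigma_ppm > 0 else 1.0))
    df = pd.DataFrame(rows, columns=NMR_COLUMNS)
    if spec.nmr_sigma_ppm > 0:
        df["shift_ppm"] += rng.normal(0.0, spec.nmr_sigma_ppm, len(df))
    return df


def generate_visible(spec: GeneratorSpec) -> pd.DataFrame:
    """One record per (potential, pH): forward reduced fraction with
    3%-of-signal Gaussian noise, clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed + 1)
    e = np.asarray(spec.vis_potentials, dtype=float)
    rows = []
    for ph in spec.vis_ph:
        frac = predicted_reduced_fractions(spec.params, e, float(ph))
        if spec.visible_noise:
            frac = np.clip(frac + rng.normal(0.0, visible_sigma(frac)), 0.0, 1.0)
        for ei, fi in zip(e, frac):
            rows.append((float(ph), float(ei), float(fi),
                         float(visible_sigma(fi))))
    return pd.DataFrame(rows, columns=VIS_COLUMNS)


def make_fixture_bundle(protein: str, out_dir: str | Path,
                        seed: int = 20241214,
                        nmr_sigma_ppm: float = 0.005,
                        visible_noise: bool = True) -> Path:
    """Write a complete synthetic study for one bundled protein.

    Produces ``params.json`` (truth), ``probes.json`` (truth shifts),
    ``nmr.csv``, ``vis.csv`` and a ``manifest.json`` recording the seed and
    noise settings, so a recovery test can compare fit against truth.
    """
    if protein not in FIXTURE_PROTEINS:
        raise ValueError(f"unknown protein {protein!r}; expected one of {FIXTURE_PROTEINS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = fixture_params(protein)
    spec = GeneratorSpec(params=params, seed=seed, nmr_sigma_ppm=nmr_sigma_ppm,
                         visible_noise=visible_noise)
    params.to_json(out / "params.json")
    (out / "probes.json").write_text(json.dumps(
        {"probes": [vars(p) for p in spec.probes]}, indent=2) + "\n")
    generate_nmr(spec).to_csv(out / "nmr.csv", index=False)
    generate_visible(spec).to_csv(out / "vis.csv", index=False)
    manifest = {
        "protein": protein,
        "seed": seed,
        "nmr_sigma_ppm": nmr_sigma_ppm,
        "visible_noise": visible_noise,
        "truth": params.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
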