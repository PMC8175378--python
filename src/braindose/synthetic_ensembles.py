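"""Deterministic synthetic SEP ensembles and test response functions.

Real SEP event catalogs are diverse in intensity and spectral slope; the
generator here emulates that diversity with power-law event spectra
whose index gamma is drawn uniformly from a range (default 2..4, falling
spectra) and whose normalization I0 at a 30 MeV reference energy is
drawn log-uniformly over several decades.  Every draw is driven by an
explicit seed, so ensembles are bit-reproducible.

``make_synthetic_brf`` builds the three response shapes used as
analysis oracles: a delta (one nonzero bin), a flat window, and a
Bragg-like threshold + single-peak curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .head_transport import ResponseFunction, ShieldConfig
from .spectra import (EnergyGrid, ParticleSpectrum, SEPShape,
                      get_species, sep_spectrum)


class EnsembleSpecError(ValueError):
    """Raised for invalid ensemble specifications."""


@dataclass
class EnsembleSpec:
    """Specification of a synthetic SEP event ensemble.

    ``i0_log10_range`` spans the event normalizations at ``e_ref`` in
    log10 units (default 1e4..1e8 particles cm^-2 sr^-1 MeV^-1, matching
    the spread of large historical events).  The seed is mandatory.
    """

    seed: int
    n_events: int = 53
    gamma_range: tuple[float, float] = (2.0, 4.0)
    i0_log10_range: tuple[float, float] = (4.0, 8.0)
    e_ref: float = 30.0
    e_roll_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.n_events < 3:
            raise EnsembleSpecError("need n_events >= 3")
        lo, hi = self.gamma_range
        if not (0 < lo <= hi < 10):
            raise EnsembleSpecError("gamma range must lie within (0, 10)")
        if self.i0_log10_range[0] > self.i0_log10_range[1]:
            raise EnsembleSpecError("invalid i0 range")
        if self.e_roll_range is not None:
            rlo, rhi = self.e_roll_range
            if not (0 < rlo <= rhi):
                raise EnsembleSpecError("invalid rollover range")


def make_sep_ensemble(spec: EnsembleSpec,
                      grid: Optional[EnergyGrid] = None
                      ) -> list[ParticleSpectrum]:
    """Draw a reproducible ensemble of fluence-mode SEP spectra."""
    if grid is None:
        grid = EnergyGrid.default()
    rng = np.random.default_rng(spec.seed)
    gammas = rng.uniform(*spec.gamma_range, size=spec.n_events)
    i0s = 10.0 ** rng.uniform(*spec.i0_log10_range, size=spec.n_events)
    rolls = (rng.uniform(*spec.e_roll_range, size=spec.n_events)
             if spec.e_roll_range is not None else [None] * spec.n_events)
    events = []
    for i0, gamma, roll in zip(i0s, gammas, rolls):
        shape = SEPShape(i0=float(i0), gamma=float(gamma),
                         e_ref=spec.e_ref,
                         e_roll=None if roll is None else float(roll))
        events.append(sep_spectrum(shape, grid))
    return events


def make_synthetic_brf(kind: str, params: Optional[dict] = None,
                       grid: Optional[EnergyGrid] = None
                       ) -> ResponseFunction:
    """Construct an oracle response function of a given kind.

    kinds:
      * ``delta``: single nonzero bin nearest ``e_r`` with integrated
        area ``area`` (µGy per unit fluence x MeV);
      * ``flat``: constant ``height`` on the window [e_lo, e_hi];
      * ``bragg``: zero below ``e_threshold``, rising to one interior
        maximum at ``e_peak`` then declining as a power law.
    """
    params = dict(params or {})
    if grid is None:
        grid = EnergyGrid.default()
    e = grid.centers
    values = np.zeros_like(e)
    if kind == "delta":
        e_r = float(params.get("e_r", 100.0))
        area = float(params.get("area", 1.0))
        idx = int(np.argmin(np.abs(np.log(e) - np.log(e_r))))
        values[idx] = area / grid.widths[idx]
    elif kind == "flat":
        e_lo = float(params.get("e_lo", 30.0))
        e_hi = float(params.get("e_hi", 300.0))
        height = float(params.get("height", 1.0))
        values[(e >= e_lo) & (e <= e_hi)] = height
    elif kind == "bragg":
        e_th = float(params.get("e_threshold", 30.0))
        e_peak = float(params.get("e_peak", 80.0))
        peak = float(params.get("peak_value", 1.0))
        decline = float(params.get("decline_index", 1.5))
        rise = (e > e_th) & (e <= e_peak)
        values[rise] = peak * (np.log(e[rise] / e_th)
                               / np.log(e_peak / e_th))
        tail = e > e_peak
        values[tail] = peak * (e[tail] / e_peak) ** (-decline)
    else:
        raise EnsembleSpecError(
            f"unknown synthetic BRF kind {kind!r}; "
            "use 'delta', 'flat' or 'bragg'")
    return ResponseFunction(
        region=str(params.get("region", "head")),
        shield=ShieldConfig(float(params.get("shield_cm", 0.0))),
        species=get_species(str(params.get("species", "H"))),
        grid=grid, values=values, provenance=f"synthetic-{kind}")
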