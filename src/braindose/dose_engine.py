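"""Fold response functions with particle spectra to obtain doses.

The central operation is the energy fold

    dose = integral over E of  BRF(E) * F(E) dE ,

evaluated as a trapezoid rule in log energy (the integrand is multiplied
by E and integrated against d ln E), which is accurate for the power-law
like spectra involved.  A flux-mode spectrum yields a dose *rate*
(µGy/s, or µGy/day summed over species for GCR); a fluence-mode SEP
event spectrum yields an absolute event dose (reported in cGy).  Both
BRF and spectrum are per steradian by declared convention, so their
product integrates the steradian away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .head_transport import ResponseFunction
from .spectra import (FLUENCE, FLUX, EnergyGrid, GCRParams, ParticleSpectrum,
                      gcr_flux)

log = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0
UGY_TO_CGY = 1e-4


class UnitModeError(ValueError):
    """Raised when flux/fluence modes or species are mixed incorrectly."""


@dataclass
class DoseResult:
    """One folded dose value with its unit and provenance."""

    value: float
    unit: str  # "uGy/s", "uGy/day", "uGy", "cGy"
    region: str
    shield: str
    species: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise UnitModeError("dose must be >= 0")


def _integrate(values: np.ndarray, energies: np.ndarray) -> float:
    """Trapezoid of ``values`` over energy, taken in log-energy space."""
    return float(np.trapezoid(values * energies, x=np.log(energies)))


def fold(rf: ResponseFunction, spectrum: ParticleSpectrum) -> DoseResult:
    """Fold one response function with one spectrum.

    The response function is log-linearly interpolated onto the spectrum
    grid when the grids differ (zero fill outside its support).  Flux
    mode gives µGy/s; fluence mode gives µGy.
    """
    if rf.species != spectrum.species:
        raise UnitModeError(
            f"species mismatch: BRF is {rf.species.name}, "
            f"spectrum is {spectrum.species.name}")
    if rf.grid != spectrum.grid:
        rf = rf.interpolated_to(spectrum.grid)
    e = spectrum.grid.centers
    value = _integrate(rf.values * spectrum.values, e)
    unit = "uGy/s" if spectrum.mode == FLUX else "uGy"
    return DoseResult(
        value=value, unit=unit, region=rf.region, shield=rf.shield.label,
        species=rf.species.name,
        provenance={"mode": spectrum.mode, "brf": rf.provenance,
                    "n_bins": spectrum.grid.n_bins})


def gcr_dose_rate(rfs: Mapping[str, ResponseFunction], params: GCRParams,
                  grid: Optional[EnergyGrid] = None) -> DoseResult:
    """Total GCR dose rate in µGy/day, summed over species.

    ``rfs`` maps species name to its response function; every species in
    ``params.species`` must be present.
    """
    missing = [s for s in params.species if s not in rfs]
    if missing:
        raise UnitModeError(f"missing response functions for {missing}")
    per_species: dict[str, float] = {}
    region = shield = None
    for name in params.species:
        rf = rfs[name]
        spec = gcr_flux(params, name, grid if grid is not None else rf.grid)
        res = fold(rf, spec)
        per_species[name] = res.value * SECONDS_PER_DAY
        region, shield = res.region, res.shield
    total = float(sum(per_species.values()))
    return DoseResult(
        value=total, unit="uGy/day", region=region or "head",
        shield=shield or "none", species="total",
        provenance={"phi_MV": params.phi, "per_species_uGy_day": per_species})


def sep_event_dose(rf: ResponseFunction,
                   event: ParticleSpectrum) -> DoseResult:
    """Absolute dose (cGy) from one event-integrated SEP fluence spectrum."""
    if event.mode != FLUENCE:
        raise UnitModeError(
            "sep_event_dose needs a fluence-mode spectrum; "
            f"got mode={event.mode!r}")
    res = fold(rf, event)
    return DoseResult(
        value=res.value * UGY_TO_CGY, unit="cGy", region=res.region,
        shield=res.shield, species=res.species, provenance=res.provenance)


# ---------------------------------------------------------------------------
# event-dose tables and shielding statistics
# ---------------------------------------------------------------------------

@dataclass
class EventDoseTable:
    """Events x scenarios matrix of SEP doses (cGy)."""

    doses: pd.DataFrame  # index: event labels, columns: scenario labels
    unit: str = "cGy"

    def __post_init__(self) -> None:
        if (self.doses.to_numpy(dtype=float) < 0).any():
            raise UnitModeError("event doses must be >= 0")

    @property
    def events(self) -> list[str]:
        return list(self.doses.index)

    @property
    def scenarios(self) -> list[str]:
        return list(self.doses.columns)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# unit={self.unit}\n")
            self.doses.to_csv(fh, index_label="event")

    @classmethod
    def from_csv(cls, path) -> "EventDoseTable":
        unit = "cGy"
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                if "unit=" in line:
                    unit = line.split("unit=")[1].split()[0].strip()
            else:
                body_start = i
                break
        from io import StringIO
        df = pd.read_csv(StringIO("".join(lines[body_start:])),
                         index_col="event")
        df.index.name = None
        return cls(df.astype(float), unit=unit)


def dose_table(events: Mapping[str, ParticleSpectrum],
               scenarios: Mapping[str, ResponseFunction]) -> EventDoseTable:
    """Compute the full events x scenarios SEP dose matrix (cGy)."""
    data = {
        scen: [sep_event_dose(rf, ev).value for ev in events.values()]
        for scen, rf in scenarios.items()
    }
    df = pd.DataFrame(data, index=list(events.keys()), dtype=float)
    return EventDoseTable(df)


def reduction_stats(table: EventDoseTable, baseline: str,
                    scenario: str) -> tuple[pd.Series, float]:
    """Per-event fractional dose reduction and its mean in percent.

    fraction_i = 1 - D_i(scenario) / D_i(baseline).  Events with zero
    baseline dose are excluded with a warning.
    """
    for col in (baseline, scenario):
        if col not in table.doses.columns:
            raise KeyError(f"scenario {col!r} not in table")
    base = table.doses[baseline]
    other = table.doses[scenario]
    usable = base > 0
    if not usable.all():
        excluded = list(base.index[~usable])
        log.warning("excluding %d event(s) with zero baseline dose: %s",
                    len(excluded), excluded)
    fractions = 1.0 - other[usable] / base[usable]
    return fractions, float(fractions.mean() * 100.0)
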