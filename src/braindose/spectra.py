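"""Energy grids, particle species, and GCR/SEP particle spectra.

Two kinds of spectra feed the dose chain:

* galactic cosmic rays (GCR): a quasi-steady differential flux
  (particles cm^-2 sr^-1 MeV^-1 s^-1) modulated by solar activity through
  the solar modulation potential Phi (MV).  The flux is computed with the
  force-field approximation applied to an analytic proton local
  interstellar spectrum (LIS); heavy ions are scaled by fixed abundance
  ratios.  Large Phi (solar maximum) suppresses the low-energy flux.
* solar energetic particle (SEP) events: an event time-integrated fluence
  (particles cm^-2 sr^-1 MeV^-1), modelled as a falling power law with an
  optional exponential rollover.

Energies are kinetic energy per nucleon throughout; the transport chain
cuts off particles above 10 GeV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

#: hard upper energy cutoff (MeV); particles above it do not contribute
ENERGY_CUTOFF_MEV = 10_000.0

#: nucleon rest energy, MeV
NUCLEON_REST_MEV = 938.272


class SpectrumValidationError(ValueError):
    """Raised when a spectrum, grid or spectrum file violates an invariant."""


# ---------------------------------------------------------------------------
# energy grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing energy-bin edges (MeV) with geometric centers."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise SpectrumValidationError("grid needs at least two edges")
        if not np.all(np.isfinite(edges)) or np.any(edges <= 0):
            raise SpectrumValidationError("grid edges must be finite and > 0")
        if np.any(np.diff(edges) <= 0):
            raise SpectrumValidationError("grid edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers (always inside their bins)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @classmethod
    def default(cls, n_bins: int = 128, e_min: float = 1.0,
                e_max: float = ENERGY_CUTOFF_MEV) -> "EnergyGrid":
        """Log-spaced grid, 1 MeV to 10 GeV by default."""
        return cls(np.geomspace(e_min, e_max, n_bins + 1))

    @classmethod
    def from_centers(cls, centers: Sequence[float]) -> "EnergyGrid":
        """Reconstruct edges as geometric midpoints of given bin centers."""
        c = np.asarray(centers, dtype=float)
        if c.ndim != 1 or c.size < 2:
            raise SpectrumValidationError("need at least two bin centers")
        inner = np.sqrt(c[:-1] * c[1:])
        first = c[0] ** 2 / inner[0]
        last = c[-1] ** 2 / inner[-1]
        return cls(np.concatenate([[first], inner, [last]]))

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, EnergyGrid)
                and self.edges.shape == other.edges.shape
                and bool(np.allclose(self.edges, other.edges, rtol=1e-12)))


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A primary GCR/SEP ion: charge number Z and mass number A."""

    name: str
    z: int
    a: int

    def __post_init__(self) -> None:
        if self.z < 1 or self.a < self.z:
            raise SpectrumValidationError(
                f"invalid species {self.name}: need Z >= 1 and A >= Z")


SPECIES: dict[str, Species] = {
    "H": Species("H", 1, 1),
    "He": Species("He", 2, 4),
    "C": Species("C", 6, 12),
    "N": Species("N", 7, 14),
    "Fe": Species("Fe", 26, 56),
}


def get_species(name: str) -> Species:
    try:
        return SPECIES[name]
    except KeyError:
        raise SpectrumValidationError(
            f"unsupported species {name!r}; supported: {sorted(SPECIES)}"
        ) from None


# ---------------------------------------------------------------------------
# particle spectrum container
# ---------------------------------------------------------------------------

FLUX = "flux"        # particles cm^-2 sr^-1 MeV^-1 s^-1
FLUENCE = "fluence"  # particles cm^-2 sr^-1 MeV^-1 (event time-integrated)


@dataclass
class ParticleSpectrum:
    """Energy-binned differential flux (GCR) or event fluence (SEP)."""

    species: Species
    grid: EnergyGrid
    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.mode not in (FLUX, FLUENCE):
            raise SpectrumValidationError(
                f"mode must be {FLUX!r} or {FLUENCE!r}, got {self.mode!r}")
        if self.values.shape != (self.grid.n_bins,):
            raise SpectrumValidationError(
                f"values length {self.values.size} != n_bins {self.grid.n_bins}")
        if not np.all(np.isfinite(self.values)):
            raise SpectrumValidationError("spectrum values must be finite")
        if np.any(self.values < 0):
            raise SpectrumValidationError("spectrum values must be >= 0")

    def scaled(self, factor: float) -> "ParticleSpectrum":
        return ParticleSpectrum(self.species, self.grid,
                                self.values * factor, self.mode)

    def value_at(self, energy: float | np.ndarray) -> np.ndarray:
        """Interpolate the spectrum at arbitrary energies.

        Log-log interpolation where the spectrum is positive (exact for
        power laws); zero outside the grid support.
        """
        e = np.atleast_1d(np.asarray(energy, dtype=float))
        c = self.grid.centers
        out = np.zeros_like(e)
        inside = (e >= c[0]) & (e <= c[-1])
        if np.any(inside) and np.any(self.values > 0):
            pos = self.values > 0
            if np.all(pos):
                out[inside] = np.exp(np.interp(np.log(e[inside]), np.log(c),
                                               np.log(self.values)))
            else:  # zeros present: interpolate linearly in log-energy
                out[inside] = np.interp(np.log(e[inside]), np.log(c),
                                        self.values)
        return out if np.ndim(energy) else float(out[0])


# ---------------------------------------------------------------------------
# GCR force-field model
# ---------------------------------------------------------------------------

def _load_lis_params() -> dict:
    with resources.files("braindose.data").joinpath("lis_params.json").open() as fh:
        return json.load(fh)


_LIS = _load_lis_params()


@dataclass
class GCRParams:
    """Solar-modulation state and composition for the GCR model.

    phi is the solar modulation potential in MV; the parameterization is
    documented for 300-1200 MV (solar minimum to maximum).
    """

    phi: float = 300.0
    species: tuple[str, ...] = ("H", "He", "C", "N", "Fe")
    lis_id: str = _LIS["id"]
    abundances: dict = field(
        default_factory=lambda: dict(_LIS["abundance_relative_to_H"]))

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise SpectrumValidationError("phi must be > 0 (MV)")


def proton_lis(energy_mev: np.ndarray) -> np.ndarray:
    """Analytic proton LIS, particles cm^-2 sr^-1 MeV^-1 s^-1.

    J(P) = c1 P^-c2 / (1 + c3 P^-c4), with P = sqrt(T(T+2 Tr)) in GeV and
    T the kinetic energy per nucleon; converted from the native
    m^-2 sr^-1 s^-1 GeV^-1 to cm^-2 sr^-1 s^-1 MeV^-1 (factor 1e-7).
    """
    t = np.asarray(energy_mev, dtype=float) / 1e3  # GeV/nuc
    tr = _LIS["nucleon_rest_energy_GeV"]
    p = np.sqrt(t * (t + 2.0 * tr))
    j = _LIS["c1"] * p ** (-_LIS["c2"]) / (1.0 + _LIS["c3"] * p ** (-_LIS["c4"]))
    return j * 1e-7


def gcr_flux(params: GCRParams, species: Species | str,
             grid: Optional[EnergyGrid] = None) -> ParticleSpectrum:
    """Modulated GCR differential flux for one species (force field).

    The interstellar spectrum is shifted in energy per nucleon by
    (Z/A) * Phi and suppressed by the Liouville factor
    E(E+2m) / ((E+dE)(E+dE+2m)); flux above 10 GeV is cut to zero.
    """
    if isinstance(species, str):
        species = get_species(species)
    if species.name not in SPECIES:
        raise SpectrumValidationError(f"unsupported species {species.name!r}")
    if grid is None:
        grid = EnergyGrid.default()
    e = grid.centers  # MeV per nucleon
    shift = species.z / species.a * params.phi  # MV -> MeV per nucleon
    m = NUCLEON_REST_MEV
    lis = proton_lis(e + shift) * params.abundances.get(species.name, 0.0)
    liouville = (e * (e + 2 * m)) / ((e + shift) * (e + shift + 2 * m))
    values = lis * liouville
    values[e > ENERGY_CUTOFF_MEV] = 0.0
    return ParticleSpectrum(species, grid, values, FLUX)


# ---------------------------------------------------------------------------
# SEP power-law event spectra
# ---------------------------------------------------------------------------

@dataclass
class SEPShape:
    """Power-law SEP event-fluence shape with optional rollover.

    fluence(E) = i0 * (E/e_ref)^-gamma * exp(-E/e_roll); gamma is stored
    positive for a falling spectrum (typical events: gamma in 2..4).
    """

    i0: float
    gamma: float
    e_ref: float = 30.0
    e_roll: Optional[float] = None

    def __post_init__(self) -> None:
        if self.i0 < 0:
            raise SpectrumValidationError("i0 must be >= 0")
        if self.e_ref <= 0:
            raise SpectrumValidationError("e_ref must be > 0 (MeV)")
        if self.e_roll is not None and self.e_roll <= 0:
            raise SpectrumValidationError("e_roll must be > 0 (MeV)")


def sep_spectrum(shape: SEPShape, grid: Optional[EnergyGrid] = None,
                 species: Species | str = "H") -> ParticleSpectrum:
    """Event time-integrated fluence spectrum from a power-law shape."""
    if isinstance(species, str):
        species = get_species(species)
    if grid is None:
        grid = EnergyGrid.default()
    e = grid.centers
    values = shape.i0 * (e / shape.e_ref) ** (-shape.gamma)
    if shape.e_roll is not None:
        values = values * np.exp(-e / shape.e_roll)
    return ParticleSpectrum(species, grid, values, FLUENCE)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_UNITS = {
    FLUX: "particles cm^-2 sr^-1 MeV^-1 s^-1",
    FLUENCE: "particles cm^-2 sr^-1 MeV^-1",
}


def write_spectrum(spectrum: ParticleSpectrum, path) -> None:
    """Write a spectrum as delimited text with a units/mode header."""
    with open(path, "w") as fh:
        fh.write(f"# species={spectrum.species.name}\n")
        fh.write(f"# mode={spectrum.mode}\n")
        fh.write(f"# units={_UNITS[spectrum.mode]}\n")
        fh.write("# convention=per-steradian; kinetic energy per nucleon\n")
        fh.write("energy_MeV,value\n")
        for e, v in zip(spectrum.grid.centers, spectrum.values):
            fh.write(f"{float(e)!r},{float(v)!r}\n")


def read_spectrum(path) -> ParticleSpectrum:
    """Read a spectrum file; validates headers, ordering and signs."""
    headers: dict[str, str] = {}
    energies: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    headers[key.strip()] = val.strip()
                continue
            if line.lower().startswith("energy"):
                continue
            parts = line.split(",")
            try:
                e, v = float(parts[0]), float(parts[1])
            except (IndexError, ValueError):
                raise SpectrumValidationError(
                    f"{path}: malformed row at line {lineno}: {line!r}") from None
            if v < 0:
                raise SpectrumValidationError(
                    f"{path}: negative value at line {lineno} (E={e} MeV)")
            if energies and e <= energies[-1]:
                raise SpectrumValidationError(
                    f"{path}: non-monotonic energy at line {lineno} (E={e} MeV)")
            energies.append(e)
            values.append(v)
    if "mode" not in headers:
        raise SpectrumValidationError(f"{path}: missing '# mode=' header")
    if headers["mode"] not in (FLUX, FLUENCE):
        raise SpectrumValidationError(
            f"{path}: mode must be flux or fluence, got {headers['mode']!r}")
    species = get_species(headers.get("species", "H"))
    grid = EnergyGrid.from_centers(energies)
    return ParticleSpectrum(species, grid, np.array(values), headers["mode"])
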