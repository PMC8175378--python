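"""Synthetic brain response functions from a 1-D CSDA slab model.

A brain response function (BRF) gives the dose (µGy) deposited in a brain
region per unit incident particle fluence (particles cm^-2 sr^-1 MeV^-1)
as a function of primary energy.  Reference BRFs come from full Monte
Carlo transport through a CT-derived head; this module provides a
deliberately simple deterministic stand-in so the whole analysis chain is
runnable and testable without external data, plus readers/writers for
externally supplied BRF tables.

The stand-in uses the continuous-slowing-down approximation (CSDA): a
power-law range-energy relation R(E) = alpha * E^p in water-equivalent
areal density.  A primary traverses shield + cranium + tissue overburden
and deposits energy in contiguous 0.5 g/cm^2 scoring layers whose depths
and weights define each region.  There are no nuclear interactions,
secondaries or neutrons, so the stand-in underestimates the high-energy
response; its purpose is correct thresholds and Bragg-peak shape, not
absolute dose fidelity.

Ions are scaled from protons at equal energy per nucleon: stopping power
(hence effective depth) scales by Z^2/A and deposited energy by A.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .spectra import EnergyGrid, Species, get_species

log = logging.getLogger(__name__)

# CSDA power law for water/tissue: R [g/cm^2] = ALPHA * E[MeV]^P.
# Chosen to track published proton CSDA ranges to a few percent over
# 10-250 MeV (e.g. ~7.6 g/cm^2 at 100 MeV vs the tabulated 7.72).
CSDA_ALPHA = 2.2e-3
CSDA_P = 1.77

ALUMINIUM_DENSITY = 2.70  # g/cm^3

# 1 MeV per gram = 1.602e-10 Gy = 1.602e-4 µGy
MEV_PER_GRAM_TO_UGY = 1.602176634e-4

# Generated BRFs are dose per unit *per-steradian* fluence for isotropic
# exposure: planar-slab dose per unit planar fluence times 4*pi sr.
SOLID_ANGLE_SR = 4.0 * np.pi

#: thickness of each scoring layer, g/cm^2
SCORING_SLAB_G_CM2 = 0.5

REGIONS = ("head", "frontal", "parietal", "temporal", "occipital",
           "hippocampus")


class TransportError(ValueError):
    """Raised on invalid head/shield configuration or BRF files."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShieldConfig:
    """Aluminium slab shield; areal density = thickness * 2.70 g/cm^3."""

    thickness_cm: float = 0.0
    material: str = "aluminium"

    def __post_init__(self) -> None:
        if self.thickness_cm < 0:
            raise TransportError("shield thickness must be >= 0")

    @property
    def areal_density(self) -> float:
        return self.thickness_cm * ALUMINIUM_DENSITY

    @property
    def label(self) -> str:
        if self.thickness_cm == 0:
            return "none"
        mm = self.thickness_cm * 10.0
        return f"{mm:g}mm" if mm < 10 else f"{self.thickness_cm:g}cm"


#: the shield set used throughout: none, 2 mm, 5 mm, 2 cm, 5 cm, 10 cm Al
STANDARD_SHIELDS: dict[str, ShieldConfig] = {
    "none": ShieldConfig(0.0),
    "2mm": ShieldConfig(0.2),
    "5mm": ShieldConfig(0.5),
    "2cm": ShieldConfig(2.0),
    "5cm": ShieldConfig(5.0),
    "10cm": ShieldConfig(10.0),
}


def _load_region_depths() -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    path = resources.files("braindose.data").joinpath("region_depths.csv")
    with path.open() as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#") and r[0] != "region"]
    for region, depth, weight in rows:
        out.setdefault(region, []).append((float(depth), float(weight)))
    return out


@dataclass
class HeadModel:
    """Cranium plus per-region tissue depth distributions.

    Each region is a list of (depth g/cm^2, weight) scoring layers beyond
    the cranium; weights sum to one.  The frontal lobe sits shallowest,
    the hippocampus deepest (it is embedded in the temporal lobe).
    """

    cranium_thickness_mm: float = 6.5
    cranium_density: float = 1.6  # g/cm^3, skull-average
    regions: dict[str, list[tuple[float, float]]] = field(
        default_factory=_load_region_depths)

    def __post_init__(self) -> None:
        for region, dist in self.regions.items():
            if not dist:
                raise TransportError(f"empty depth distribution for {region!r}")
            weights = np.array([w for _, w in dist])
            if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
                raise TransportError(
                    f"weights for {region!r} must be >= 0 and sum to 1")
        lobes = [r for r in ("frontal", "parietal", "temporal", "occipital")
                 if r in self.regions]
        if "hippocampus" in self.regions and lobes:
            hippo = self.mean_depth("hippocampus")
            if any(hippo <= self.mean_depth(r) for r in lobes):
                raise TransportError("hippocampus must be the deepest region")
        if "frontal" in self.regions:
            if any(self.mean_depth("frontal") > self.mean_depth(r)
                   for r in lobes):
                raise TransportError("frontal lobe must be the shallowest lobe")

    @property
    def cranium_areal_density(self) -> float:
        return self.cranium_thickness_mm / 10.0 * self.cranium_density

    def mean_depth(self, region: str) -> float:
        dist = self.regions[region]
        return float(sum(d * w for d, w in dist))


# ---------------------------------------------------------------------------
# CSDA range and transmission
# ---------------------------------------------------------------------------

def csda_range(energy_mev, material: str = "water"):
    """Water-equivalent CSDA range (g/cm^2) of a proton of energy E.

    Aluminium, bone and tissue are treated through density-scaled
    water-equivalent areal density, so all materials share the water
    coefficients here.
    """
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e < 0):
        raise TransportError("energy must be >= 0")
    r = CSDA_ALPHA * e ** CSDA_P
    return r if np.ndim(energy_mev) else float(r)

def _inverse_range(r):
    r = np.asarray(r, dtype=float)
    e = np.power(np.clip(r, 0.0, None) / CSDA_ALPHA, 1.0 / CSDA_P)
    return e


def transmit(energy_mev, depth_g_cm2: float, material: str = "water"):
    """Residual proton energy after a slab; 0 means stopped.

    Satisfies R(E_out) = R(E_in) - depth whenever the particle survives.
    """
    if depth_g_cm2 < 0:
        raise TransportError("depth must be >= 0")
    residual = csda_range(energy_mev, material) - depth_g_cm2
    out = np.where(np.asarray(residual) > 0, _inverse_range(residual), 0.0)
    return out if np.ndim(energy_mev) else float(out)


# ---------------------------------------------------------------------------
# response-function container and generation
# ---------------------------------------------------------------------------

@dataclass
class ResponseFunction:
    """Dose (µGy) per unit fluence (cm^-2 sr^-1 MeV^-1) vs. energy."""

    region: str
    shield: ShieldConfig
    species: Species
    grid: EnergyGrid
    values: np.ndarray
    provenance: str = "csda-standin"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (self.grid.n_bins,):
            raise TransportError(
                f"BRF length {self.values.size} != n_bins {self.grid.n_bins}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise TransportError("BRF values must be finite and >= 0")

    def threshold_energy(self) -> float:
        """Lowest grid energy with a nonzero response (inf if all zero)."""
        nz = np.nonzero(self.values > 0)[0]
        return float(self.grid.centers[nz[0]]) if nz.size else float("inf")

    def interpolated_to(self, grid: EnergyGrid) -> "ResponseFunction":
        """Log-energy linear interpolation onto a new grid, zero-filled."""
        vals = np.interp(np.log(grid.centers), np.log(self.grid.centers),
                         self.values, left=0.0, right=0.0)
        return ResponseFunction(self.region, self.shield, self.species,
                                grid, vals,
                                provenance=self.provenance + "+interpolated")


def generate_brf(head: HeadModel, shield: ShieldConfig,
                 species: Species | str = "H",
                 grid: Optional[EnergyGrid] = None,
                 region: str = "head",
                 slab_g_cm2: float = SCORING_SLAB_G_CM2) -> ResponseFunction:
    """Generate a stand-in BRF for one region/shield/species.

    For each scoring layer [d - t/2, d + t/2] beyond shield + cranium, the
    deposited dose per primary is (E_in_layer - E_out_layer) * A / t; the
    region BRF is the weight-averaged layer dose, converted to µGy per
    unit per-steradian fluence.  Contiguous layers make the weighted sum
    telescope, giving a single interior (Bragg-region) maximum.
    """
    if isinstance(species, str):
        species = get_species(species)
    if region not in head.regions:
        raise TransportError(
            f"unknown region {region!r}; have {sorted(head.regions)}")
    if grid is None:
        grid = EnergyGrid.default()
    dist = head.regions[region]
    upstream = shield.areal_density + head.cranium_areal_density
    # ion scaling: stopping ~ Z^2/A at equal E/nucleon -> scale depths
    depth_scale = species.z ** 2 / species.a
    e = grid.centers
    dose = np.zeros_like(e)
    for depth, weight in dist:
        d_in = max(upstream + depth - slab_g_cm2 / 2.0, 0.0) * depth_scale
        d_out = (upstream + depth + slab_g_cm2 / 2.0) * depth_scale
        e_in = transmit(e, d_in)
        e_out = transmit(e, d_out)
        dose += weight * (e_in - e_out) * species.a / slab_g_cm2
    values = dose * MEV_PER_GRAM_TO_UGY * SOLID_ANGLE_SR
    return ResponseFunction(region, shield, species, grid, values)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

BRF_UNITS = "uGy per (particles cm^-2 sr^-1 MeV^-1)"


def write_brf(rf: ResponseFunction, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# region={rf.region}\n")
        fh.write(f"# shield_cm_al={rf.shield.thickness_cm!r}\n")
        fh.write(f"# species={rf.species.name}\n")
        fh.write(f"# units={BRF_UNITS}\n")
        fh.write(f"# provenance={rf.provenance}\n")
        fh.write("# convention=isotropic per-steradian fluence\n")
        fh.write("energy_MeV,brf_uGy_per_unit_fluence\n")
        for e, v in zip(rf.grid.centers, rf.values):
            fh.write(f"{float(e)!r},{float(v)!r}\n")


def read_brf(path, grid: Optional[EnergyGrid] = None) -> ResponseFunction:
    """Read a BRF file; optionally interpolate onto a target grid.

    Interpolation (log-energy linear) is flagged in the provenance and
    logged at WARNING level.
    """
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
                energies.append(float(parts[0]))
                values.append(float(parts[1]))
            except (IndexError, ValueError):
                raise TransportError(
                    f"{path}: malformed row at line {lineno}: {line!r}") from None
    if "units" not in headers:
        raise TransportError(f"{path}: missing '# units=' header")
    if headers["units"] != BRF_UNITS:
        raise TransportError(
            f"{path}: unit mismatch: {headers['units']!r} != {BRF_UNITS!r}")
    region = headers.get("region", "head")
    if region not in REGIONS:
        raise TransportError(
            f"{path}: unknown region {region!r}; supported: {REGIONS}")
    rf = ResponseFunction(
        region=region,
        shield=ShieldConfig(float(headers.get("shield_cm_al", 0.0))),
        species=get_species(headers.get("species", "H")),
        grid=EnergyGrid.from_centers(energies),
        values=np.array(values),
        provenance=headers.get("provenance", "file"),
    )
    if grid is not None and rf.grid != grid:
        log.warning("BRF %s interpolated from %d-bin grid onto %d-bin grid",
                    path, rf.grid.n_bins, grid.n_bins)
        rf = rf.interpolated_to(grid)
    return rf
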