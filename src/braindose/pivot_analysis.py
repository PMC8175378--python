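"""Pivot-energy analysis: correlation scan and linear dose predictor.

SEP event spectra vary in both intensity and spectral slope, so the dose
they deposit behind a given shield is not predictable from intensity at
an arbitrary energy.  There is, however, a *pivot energy* at which the
event fluence alone determines the dose: softening the spectrum removes
dose carried by particles above the pivot but adds an exactly
compensating amount below it.  Operationally the pivot is found by
scanning the Pearson correlation between per-event fluence at each
candidate energy and the per-event dose, and taking the maximizing
energy.  At the pivot, dose vs. fluence is fitted with an ordinary
least-squares line

    D [cGy] = a * I_pivot + b ,

whose coefficients form the ready-to-use forecasting function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dose_engine import _integrate
from .head_transport import ResponseFunction
from .spectra import ParticleSpectrum

#: candidate pivot energies default to the grid restricted to this window
CANDIDATE_WINDOW_MEV = (10.0, 1000.0)


class DegenerateDataError(ValueError):
    """Raised for constant inputs or under-sized ensembles."""


@dataclass
class PivotScanResult:
    """Pearson correlation vs. candidate energy, plus the chosen pivot."""

    energies: np.ndarray
    pcc: np.ndarray
    pivot_energy: float
    scenario: str = ""

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.pcc = np.asarray(self.pcc, dtype=float)
        if np.any(np.abs(self.pcc) > 1 + 1e-12):
            raise DegenerateDataError("pcc values must lie in [-1, 1]")
        if not np.any(np.isclose(self.energies, self.pivot_energy)):
            raise DegenerateDataError(
                "pivot energy must be one of the candidate energies")


@dataclass
class PivotFit:
    """OLS fit D = a*I + b with standard errors and explained variance."""

    a: float
    a_se: float
    b: float
    b_se: float
    r_squared: float
    n_events: int

    def predict(self, fluence) -> np.ndarray:
        return self.a * np.asarray(fluence, dtype=float) + self.b


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DegenerateDataError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def fit_pivot_law(fluences_at_pivot: Sequence[float],
                  doses: Sequence[float]) -> PivotFit:
    """Unweighted OLS of dose on fluence with residual-based standard errors."""
    x = np.asarray(fluences_at_pivot, dtype=float)
    y = np.asarray(doses, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("need >= 3 (fluence, dose) pairs")
    if np.ptp(x) == 0:
        raise DegenerateDataError("degenerate design: all fluences equal")
    res = stats.linregress(x, y)
    return PivotFit(
        a=float(res.slope), a_se=float(res.stderr),
        b=float(res.intercept), b_se=float(res.intercept_stderr),
        r_squared=float(res.rvalue ** 2), n_events=int(x.size))


def _relative_rms_residual(x: np.ndarray, y: np.ndarray) -> float:
    """RMS residual of the OLS line, relative to the mean dose."""
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    scale = float(np.mean(np.abs(y))) or 1.0
    return float(np.sqrt(np.mean(resid ** 2)) / scale)


def pcc_scan(events: Sequence[ParticleSpectrum], doses: Sequence[float],
             energies: Optional[Sequence[float]] = None,
             scenario: str = "") -> PivotScanResult:
    """Scan Pearson correlation of dose vs. fluence over candidate energies.

    Pivot selection: maximum Pcc; ties (within 1e-9) broken by smallest
    relative RMS residual of the linear fit, then by lowest energy.
    """
    doses = np.asarray(doses, dtype=float)
    if len(events) < 3 or doses.size != len(events):
        raise DegenerateDataError("need >= 3 events with one dose each")
    if energies is None:
        c = events[0].grid.centers
        lo, hi = CANDIDATE_WINDOW_MEV
        energies = c[(c >= lo) & (c <= hi)]
    energies = np.sort(np.asarray(energies, dtype=float))
    fluence = np.array([[ev.value_at(e) for e in energies] for ev in events])
    pcc = np.array([pearson(fluence[:, j], doses)
                    for j in range(energies.size)])
    best = np.max(pcc)
    tied = np.nonzero(pcc >= best - 1e-9)[0]
    if tied.size > 1:
        rms = np.array([_relative_rms_residual(fluence[:, j], doses)
                        for j in tied])
        # argmin takes the first (lowest-energy) index on residual ties
        tied = tied[np.isclose(rms, rms.min(), rtol=0, atol=1e-12)]
    pivot = float(energies[tied[0]])
    return PivotScanResult(energies=energies, pcc=pcc, pivot_energy=pivot,
                           scenario=scenario)


def analytic_pivot_oracle(rf: ResponseFunction,
                          gamma_grid: Optional[Sequence[float]] = None,
                          e_ref: float = 30.0,
                          candidates: Optional[Sequence[float]] = None
                          ) -> float:
    """Pivot energy from the slope-insensitivity definition (test oracle).

    For a pure power-law ensemble I(E) = I0 (E/e_ref)^-gamma, the dose is
    I0 * g(gamma) with g(gamma) = integral BRF(E) (E/e_ref)^-gamma dE, so

        log dose - log fluence(E) = log g(gamma) + gamma log(E/e_ref)

    depends on gamma alone.  The pivot is the energy minimizing the
    spread of this quantity over the gamma grid (brute-force search).
    """
    if gamma_grid is None:
        gamma_grid = np.linspace(2.0, 4.0, 9)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    c = rf.grid.centers
    if candidates is None:
        lo, hi = CANDIDATE_WINDOW_MEV
        candidates = c[(c >= lo) & (c <= hi)]
    candidates = np.asarray(candidates, dtype=float)
    log_g = np.array([
        np.log(_integrate(rf.values * (c / e_ref) ** (-g), c))
        for g in gamma_grid
    ])
    # spread over gamma of log_g + gamma*log(E/e_ref), per candidate energy
    h = log_g[:, None] + gamma_grid[:, None] * np.log(candidates / e_ref)[None, :]
    spread = np.ptp(h, axis=0)
    return float(candidates[int(np.argmin(spread))])
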