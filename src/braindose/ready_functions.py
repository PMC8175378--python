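"""Operational SEP dose forecasting from the packaged ready functions.

The package ships two transcribed result tables as plain-text data:

* a registry of fitted linear dose predictors ("ready functions"), one
  per scenario — whole head under six aluminium shield depths (none,
  2 mm, 5 mm, 2 cm, 5 cm, 10 cm) and five brain regions behind 2 mm —
  each with its pivot energy (MeV), slope ``a`` (cGy sr cm^2 MeV, stored
  with the x1e6 printing convention), intercept ``b`` (cGy),
  uncertainties and fit R^2;
* a fixture of doses (cGy) from 35 large historical SEP events under the
  same scenarios, used for shielding-reduction statistics and for
  flagging events against the short-term CNS exposure limit
  (SPEL, 50 cGy in 30 days).

``predict_dose`` turns an observed event fluence at the pivot energy
directly into a brain dose in cGy: D = a * I_pivot + b.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .dose_engine import EventDoseTable

REGISTRY_FILE = "table2_ready_functions.csv"
FIXTURE_FILE = "table1_sep_event_doses.csv"

#: registry scenario keys: (region, shield-label)
SHIELD_LABELS = ("none", "2mm", "5mm", "2cm", "5cm", "10cm")


class UnknownScenarioError(KeyError):
    """Raised when a (region, shield) pair is not in the registry."""


@dataclass(frozen=True)
class ReadyFunction:
    """One fitted predictor D[cGy] = a * I_pivot + b for one scenario."""

    region: str
    shield: str
    pivot_energy_mev: float
    a: float          # cGy sr cm^2 MeV (SI-consistent, x1e-6 resolved)
    a_se: float
    b: float          # cGy
    b_se: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.pivot_energy_mev <= 0 or self.a <= 0:
            raise ValueError("pivot energy and slope must be > 0")
        if not 0 < self.r_squared <= 1:
            raise ValueError("r_squared must be in (0, 1]")

    def predict(self, fluence: float) -> float:
        """Dose in cGy from the event fluence at the pivot energy."""
        if fluence < 0:
            raise ValueError("fluence must be >= 0")
        return self.a * fluence + self.b


def _normalize_shield(shield: str) -> str:
    s = shield.lower().replace(" ", "").replace("al", "").strip()
    if s in ("", "0", "0mm", "0cm", "noshield", "none", "without"):
        return "none"
    if s in SHIELD_LABELS:
        return s
    raise UnknownScenarioError(
        f"unknown shield {shield!r}; known: {SHIELD_LABELS}")


def _read_packaged_csv(name: str) -> str:
    return resources.files("braindose.data").joinpath(name).read_text()


def _load_registry() -> dict[tuple[str, str], ReadyFunction]:
    text = _read_packaged_csv(REGISTRY_FILE)
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    df = pd.read_csv(StringIO(body))
    registry = {}
    for row in df.itertuples(index=False):
        rf = ReadyFunction(
            region=row.region, shield=row.shield,
            pivot_energy_mev=float(row.pivot_energy_MeV),
            a=float(row.a_x1e6) * 1e-6, a_se=float(row.a_err_x1e6) * 1e-6,
            b=float(row.b_cGy), b_se=float(row.b_err_cGy),
            r_squared=float(row.r_squared))
        registry[(rf.region, rf.shield)] = rf
    return registry


_REGISTRY = _load_registry()


def registry() -> dict[tuple[str, str], ReadyFunction]:
    """The full scenario -> ReadyFunction mapping (11 scenarios)."""
    return dict(_REGISTRY)


def lookup(region: str, shield: str = "2mm") -> ReadyFunction:
    """Fetch the ready function for one (region, shield) scenario."""
    key = (region.lower().strip(), _normalize_shield(shield))
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownScenarioError(
            f"no ready function for region={region!r}, shield={shield!r}; "
            f"available: {sorted(_REGISTRY)}") from None


def predict_dose(region: str, shield: str, fluence_at_pivot: float) -> float:
    """Forecast the SEP event dose (cGy) from fluence at the pivot energy.

    ``fluence_at_pivot`` is in particles cm^-2 sr^-1 MeV^-1 at the
    scenario's pivot energy.
    """
    return lookup(region, shield).predict(fluence_at_pivot)


def table1_fixture() -> EventDoseTable:
    """The packaged 35-event dose table (cGy), at printed precision."""
    text = _read_packaged_csv(FIXTURE_FILE)
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    df = pd.read_csv(StringIO(body), index_col="event").astype(float)
    return EventDoseTable(df)


def data_checksums() -> dict[str, str]:
    """SHA-256 of the packaged data files (transcription integrity)."""
    out = {}
    for name in (REGISTRY_FILE, FIXTURE_FILE):
        digest = hashlib.sha256(
            _read_packaged_csv(name).encode()).hexdigest()
        out[name] = digest
    return out


# ---------------------------------------------------------------------------
# exposure-limit flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LimitPolicy:
    """Short-term CNS space-permissible exposure limit (SPEL)."""

    limit_cgy: float = 50.0
    window: str = "30 days"

    def __post_init__(self) -> None:
        if self.limit_cgy <= 0:
            raise ValueError("limit must be > 0")


def exceeds_limit(table: EventDoseTable,
                  policy: LimitPolicy = LimitPolicy()) -> pd.DataFrame:
    """Boolean flags, per table cell, for doses strictly above the limit."""
    if table.unit != "cGy":
        raise ValueError(f"table unit must be cGy, got {table.unit!r}")
    return table.doses > policy.limit_cgy
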