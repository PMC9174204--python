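"""Per-eye ONH parameter vector: the six axonal parameter families.

Families and units:

* ``bnfl``  – border NFL, mm: distance from each Bruch's membrane
  termination to the ILM along the BMO reference-plane normal (8 regions).
* ``pnfl``  – peripapillary NFL, mm: ILM to NFL-posterior thickness at
  1.7 mm from the BMO centre (8 regions).
* ``mrw``   – minimum rim width, mm (8 regions).
* ``mra``   – minimum rim area, mm^2 (8 regions).
* ``plt``   – prelamina thickness, mm (8 sector midpoints + centre).
* ``plv``   – prelamina volume, mm^3 (scalar).

Missing values are ``nan``; family means are taken over non-missing
regions and are never silently zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import PRELAMINA_REGIONS, REGIONS

#: Regional families (name -> unit) in canonical output order.
REGIONAL_FAMILIES = {"bnfl": "mm", "pnfl": "mm", "mrw": "mm", "mra": "mm2"}


def _nanmean(values: dict[str, float]) -> float:
    arr = np.array([values[r] for r in REGIONS], dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


@dataclass
class ONHParameters:
    """Fully regional per-eye morphometry result (35 scalar slots)."""

    bnfl: dict[str, float]
    pnfl: dict[str, float]
    mrw: dict[str, float]
    mra: dict[str, float]
    plt: dict[str, float]  # 8 sectors + "centre"
    plv: float
    provenance: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in ("bnfl", "pnfl", "mrw", "mra"):
            fam = getattr(self, name)
            missing = [r for r in REGIONS if r not in fam]
            if missing:
                raise ValueError(f"{name} missing regions {missing}")
        missing = [r for r in PRELAMINA_REGIONS if r not in self.plt]
        if missing:
            raise ValueError(f"plt missing regions {missing}")

    @property
    def bnfl_mean(self) -> float:
        return _nanmean(self.bnfl)

    @property
    def pnfl_mean(self) -> float:
        return _nanmean(self.pnfl)

    @property
    def mrw_mean(self) -> float:
        return _nanmean(self.mrw)

    @property
    def mra_mean(self) -> float:
        return _nanmean(self.mra)

    def to_series(self) -> pd.Series:
        """Flatten to the canonical column layout used by the cohort table."""
        out: dict[str, float] = {}
        for fam in REGIONAL_FAMILIES:
            values = getattr(self, fam)
            for r in REGIONS:
                out[f"{fam}_{r}"] = values[r]
            out[f"{fam}_mean"] = getattr(self, f"{fam}_mean")
        for r in PRELAMINA_REGIONS:
            out[f"plt_{r}"] = self.plt[r]
        out["plv"] = self.plv
        return pd.Series(out)

    @classmethod
    def from_series(cls, s: pd.Series) -> "ONHParameters":
        def fam(name: str) -> dict[str, float]:
            return {r: float(s[f"{name}_{r}"]) for r in REGIONS}

        plt = {r: float(s[f"plt_{r}"]) for r in PRELAMINA_REGIONS}
        return cls(bnfl=fam("bnfl"), pnfl=fam("pnfl"), mrw=fam("mrw"),
                   mra=fam("mra"), plt=plt, plv=float(s["plv"]))


#: All parameter column names, in cohort-table order.
PARAMETER_COLUMNS: tuple[str, ...] = tuple(
    [f"{fam}_{r}" for fam in REGIONAL_FAMILIES for r in list(REGIONS) + ["mean"]]
    + [f"plt_{r}" for r in PRELAMINA_REGIONS]
    + ["plv"]
)
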