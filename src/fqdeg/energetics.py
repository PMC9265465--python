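"""MM/PBSA free-energy bookkeeping.

End-point binding free energies decompose as

* ``G_bind = G_complex - G_free_protein - G_free_ligand``
* per species, ``G = E_gas - T * S_gas + G_solvation``
* ``G_solvation = G_polar + G_nonpolar``

All energies are kJ/mol; entropies are kJ/mol/K so that T*S is kJ/mol.
This module performs the arithmetic and validates that records supplied
with component-level detail actually satisfy the identities — it does not
run any PB/SA solver or parse trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesEnergy",
    "EnergyRecord",
    "binding_free_energy",
    "species_free_energy",
    "validate_record",
    "records_from_csv",
    "SIMULATION_TEMPERATURES",
]

#: Composting-stage simulation temperature presets (K): mesophilic 35 C,
#: thermophilic 55 C.
SIMULATION_TEMPERATURES = (308.0, 328.0)


def species_free_energy(E_gas: float, T: float, S_gas: float,
                        G_polar: float, G_nonpolar: float) -> float:
    """``G = E_gas - T*S_gas + G_polar + G_nonpolar`` (kJ/mol)."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    vals = (E_gas, T, S_gas, G_polar, G_nonpolar)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("non-finite energy component")
    return E_gas - T * S_gas + G_polar + G_nonpolar


@dataclass(frozen=True)
class SpeciesEnergy:
    """Total free energy of one species, optionally with its components."""

    G_total: float
    E_gas: Optional[float] = None
    T: Optional[float] = None
    S_gas: Optional[float] = None
    G_polar: Optional[float] = None
    G_nonpolar: Optional[float] = None

    @property
    def has_components(self) -> bool:
        return None not in (self.E_gas, self.T, self.S_gas,
                            self.G_polar, self.G_nonpolar)

    def component_residual(self) -> Optional[float]:
        """G_total minus the component reconstruction; None without components."""
        if not self.has_components:
            return None
        return self.G_total - species_free_energy(
            self.E_gas, self.T, self.S_gas, self.G_polar, self.G_nonpolar)

    @classmethod
    def from_components(cls, E_gas, T, S_gas, G_polar, G_nonpolar) -> "SpeciesEnergy":
        return cls(species_free_energy(E_gas, T, S_gas, G_polar, G_nonpolar),
                   E_gas, T, S_gas, G_polar, G_nonpolar)


@dataclass(frozen=True)
class EnergyRecord:
    """Complex / free protein / free ligand energies for one binding event."""

    name: str
    complex: SpeciesEnergy
    protein: SpeciesEnergy
    ligand: SpeciesEnergy


def binding_free_energy(record: EnergyRecord) -> float:
    """``G_bind = G_complex - G_free_protein - G_free_ligand``."""
    return record.complex.G_total - record.protein.G_total - record.ligand.G_total


def validate_record(record: EnergyRecord, tol: float = 1e-6) -> dict:
    """Check the decomposition identities; report residuals, never raise."""
    checks = {}
    for species_name in ("complex", "protein", "ligand"):
        sp: SpeciesEnergy = getattr(record, species_name)
        res = sp.component_residual()
        checks[f"{species_name}_components"] = {
            "checked": res is not None,
            "residual": res,
            "ok": (res is None) or abs(res) <= tol,
        }
    gbind = binding_free_energy(record)
    return {
        "record": record.name,
        "G_bind": gbind,
        "checks": checks,
        "all_ok": all(c["ok"] for c in checks.values()),
    }


def records_from_csv(path) -> list[EnergyRecord]:
    """Read records from `record,species,E_gas,T,S_gas,G_polar,G_nonpolar,G_total`.

    Component columns may be blank; G_total is required.  Entropy is in
    kJ/mol/K.
    """
    df = pd.read_csv(path)
    needed = {"record", "species", "G_total"}
    if not needed <= set(df.columns):
        raise ValueError(f"energies CSV needs columns {sorted(needed)}")

    def species(sub: pd.DataFrame, which: str) -> SpeciesEnergy:
        row = sub[sub["species"] == which]
        if len(row) != 1:
            raise ValueError(f"record needs exactly one {which!r} row")
        row = row.iloc[0]

        def get(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        return SpeciesEnergy(G_total=float(row["G_total"]), E_gas=get("E_gas"),
                             T=get("T"), S_gas=get("S_gas"),
                             G_polar=get("G_polar"), G_nonpolar=get("G_nonpolar"))

    out = []
    for name, sub in df.groupby("record", sort=False):
        out.append(EnergyRecord(name=str(name),
                                complex=species(sub, "complex"),
                                protein=species(sub, "protein"),
                                ligand=species(sub, "ligand")))
    return out
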