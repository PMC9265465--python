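"""CoMFA-style steric and electrostatic molecular-field descriptors.

Pre-aligned 3-D conformers are probed on a rectangular lattice.  At every
grid point two interaction energies with a probe atom are evaluated:

* steric: Lennard-Jones 6-12 energy against an sp3-carbon probe,
  ``E = sum_i eps_i [(rmin_i / r)^12 - 2 (rmin_i / r)^6]`` with
  Lorentz-Berthelot-style combination (``rmin_i = R_i + R_probe``,
  ``eps_i = sqrt(e_i * e_probe)``);
* electrostatic: Coulomb energy with a +1 e probe charge and a linear
  distance-dependent dielectric, ``E = k q_i q_probe / r^2``.

Both fields are clamped to a cutoff (default 125.4 kJ/mol, i.e. 30
kcal/mol); grid points sterically excluded for a molecule carry no useful
electrostatic information and are, by convention, replaced by the column
mean over all molecules when the per-molecule blocks are assembled into one
descriptor matrix.  Alignment and partial charges are input conditions; the
module computes neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Conformer",
    "GridSpec",
    "FieldBlock",
    "DEFAULT_PROBE",
    "VDW_DEFAULTS",
    "build_grid",
    "steric_field",
    "electrostatic_field",
    "assemble_descriptors",
    "conformers_from_sdf",
]

#: Coulomb constant in kJ mol^-1 A e^-2.
COULOMB_K = 1389.35458

#: Default field clamp, kJ/mol (30 kcal/mol).
DEFAULT_CUTOFF = 125.4

#: Per-element vdW radius (A) and LJ well depth (kJ/mol); Tripos-like values.
VDW_DEFAULTS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.042),
    "C": (1.70, 0.457),
    "N": (1.55, 0.711),
    "O": (1.52, 0.879),
    "F": (1.47, 0.255),
    "P": (1.80, 0.836),
    "S": (1.80, 1.046),
    "Cl": (1.75, 0.983),
    "Br": (1.85, 1.360),
    "I": (1.98, 1.670),
}


@dataclass(frozen=True)
class Probe:
    """Probe atom: sp3 carbon with +1 e charge by default."""

    radius: float = 1.70       # A
    well_depth: float = 0.457  # kJ/mol
    charge: float = 1.0        # e


DEFAULT_PROBE = Probe()


@dataclass(frozen=True)
class Conformer:
    """One aligned molecule: elements, coordinates, charges, vdW parameters."""

    symbols: tuple
    coords: np.ndarray          # (n_atoms, 3), A
    charges: np.ndarray         # (n_atoms,), e
    vdw_radius: np.ndarray      # (n_atoms,), A
    vdw_well_depth: np.ndarray  # (n_atoms,), kJ/mol

    def __init__(self, symbols, coords, charges=None, vdw_radius=None,
                 vdw_well_depth=None):
        symbols = tuple(symbols)
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        n = len(symbols)
        if coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {coords.shape}")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinate")
        if charges is None:
            charges = np.full(n, np.nan)
        charges = np.asarray(charges, dtype=float)
        if vdw_radius is None or vdw_well_depth is None:
            try:
                params = [VDW_DEFAULTS[s] for s in symbols]
            except KeyError as exc:
                raise ValueError(f"no default vdW parameters for element {exc}") from exc
            vdw_radius = np.array([p[0] for p in params])
            vdw_well_depth = np.array([p[1] for p in params])
        vdw_radius = np.asarray(vdw_radius, dtype=float)
        vdw_well_depth = np.asarray(vdw_well_depth, dtype=float)
        for name, arr in (("charges", charges), ("vdw_radius", vdw_radius),
                          ("vdw_well_depth", vdw_well_depth)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        if not (np.isfinite(vdw_radius).all() and np.isfinite(vdw_well_depth).all()):
            raise ValueError("non-finite vdW parameter")
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "vdw_radius", vdw_radius)
        object.__setattr__(self, "vdw_well_depth", vdw_well_depth)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def translated(self, t) -> "Conformer":
        return Conformer(self.symbols, self.coords + np.asarray(t, float),
                         self.charges, self.vdw_radius, self.vdw_well_depth)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice: origin corner, isotropic spacing, point counts."""

    origin: tuple
    spacing: float
    dims: tuple  # (nx, ny, nz)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points in raster (x-fastest-last / C) order, shape (N, 3)."""
        ox, oy, oz = self.origin
        nx, ny, nz = self.dims
        xs = ox + self.spacing * np.arange(nx)
        ys = oy + self.spacing * np.arange(ny)
        zs = oz + self.spacing * np.arange(nz)
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class FieldBlock:
    """Steric and electrostatic energies of one molecule on one grid."""

    grid: GridSpec
    steric: np.ndarray
    electrostatic: np.ndarray
    excluded: np.ndarray  # bool mask: steric clamp reached
    cutoff: float = DEFAULT_CUTOFF


def build_grid(conformers: Sequence[Conformer], spacing: float = 2.0,
               margin: float = 4.0) -> GridSpec:
    """Smallest lattice enclosing all conformers with the given margin.

    Deterministic for a fixed conformer order; translating every molecule by
    t shifts the origin by exactly t.
    """
    if not conformers:
        raise ValueError("need at least one conformer")
    all_xyz = np.vstack([c.coords for c in conformers])
    lo = all_xyz.min(axis=0) - margin
    hi = all_xyz.max(axis=0) + margin
    dims = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


def _distances(grid_points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    diff = grid_points[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def steric_field(conformer: Conformer, grid: GridSpec,
                 probe: Probe = DEFAULT_PROBE,
                 cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Lennard-Jones 6-12 probe energies, clamped to +-cutoff.

    Grid points coincident with an atom are finite by construction (the
    clamp applies before summation overflow can matter).
    """
    r = _distances(grid.points(), conformer.coords)
    rmin = conformer.vdw_radius + probe.radius
    eps = np.sqrt(conformer.vdw_well_depth * probe.well_depth)
    with np.errstate(divide="ignore", over="ignore"):
        # distance floor keeps coincident points finite; clamp applies after the sum
        ratio6 = (rmin[None, :] / np.maximum(r, 1e-12)) ** 6
        e = eps[None, :] * (ratio6 ** 2 - 2.0 * ratio6)
    total = e.sum(axis=1)
    return np.clip(total, -cutoff, cutoff)


def electrostatic_field(conformer: Conformer, grid: GridSpec,
                        probe_charge: float = 1.0,
                        cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Coulomb probe energies with distance-dependent dielectric eps(r) = r.

    With eps(r) = r the pair energy falls off as ``k q_i q_p / r^2``.
    Values are clamped to +-cutoff; cross-molecule mean replacement at
    sterically excluded points happens in :func:`assemble_descriptors`.
    """
    if np.isnan(conformer.charges).any():
        i = int(np.flatnonzero(np.isnan(conformer.charges))[0])
        raise ValueError(f"missing partial charge on atom {i} ({conformer.symbols[i]})")
    r = _distances(grid.points(), conformer.coords)
    with np.errstate(divide="ignore", over="ignore"):
        e = COULOMB_K * probe_charge * conformer.charges[None, :] / \
            np.maximum(r, 1e-12) ** 2
    total = e.sum(axis=1)
    return np.clip(total, -cutoff, cutoff)


def compute_field_block(conformer: Conformer, grid: GridSpec,
                        probe: Probe = DEFAULT_PROBE,
                        cutoff: float = DEFAULT_CUTOFF) -> FieldBlock:
    s = steric_field(conformer, grid, probe, cutoff)
    e = electrostatic_field(conformer, grid, probe.charge, cutoff)
    return FieldBlock(grid=grid, steric=s, electrostatic=e,
                      excluded=s >= cutoff - 1e-9, cutoff=cutoff)


def assemble_descriptors(blocks: Sequence[FieldBlock],
                         drop_constant: bool = True,
                         mean_replace_excluded: bool = True,
                         std_tol: float = 1e-6):
    """Stack per-molecule field blocks into one descriptor matrix.

    Column order is deterministic: the full steric block (grid raster
    order), then the full electrostatic block.  Electrostatic values at
    sterically excluded points are replaced by the column mean over the
    non-excluded molecules (the usual CoMFA convention), unless disabled.
    Near-constant columns (sd < ``std_tol``) are dropped.

    Returns
    -------
    X : (n_molecules, n_kept) ndarray
    kept : ndarray of kept column indices into the unfiltered 2*N matrix
    n_dropped : int
    """
    if not blocks:
        raise ValueError("no field blocks")
    grid0 = blocks[0].grid
    if any(b.grid != grid0 for b in blocks):
        raise ValueError("all field blocks must share one grid")
    S = np.vstack([b.steric for b in blocks])
    E = np.vstack([b.electrostatic for b in blocks])
    if mean_replace_excluded:
        excl = np.vstack([b.excluded for b in blocks])
        ok = ~excl
        counts = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            col_mean = np.where(counts > 0, (E * ok).sum(axis=0) / np.maximum(counts, 1),
                                E.mean(axis=0))
        E = np.where(excl, col_mean[None, :], E)
    X = np.hstack([S, E])
    if not drop_constant:
        return X, np.arange(X.shape[1]), 0
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd >= std_tol)
    return X[:, kept], kept, X.shape[1] - kept.size


def conformers_from_sdf(path, charge_prop: str = "atom.dprop.PartialCharge"):
    """Read aligned conformers (and optional per-atom charges) from an SDF.

    Requires rdkit.  Charges are taken from the given atom property when
    present, else from `_GasteigerCharge`-style atom properties, else left
    missing (NaN) so that the electrostatic stage errors out explicitly.
    """
    from rdkit import Chem  # deferred: coordinate I/O only

    out = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=False):
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(mol.GetNumAtoms())])
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        charges = []
        for a in mol.GetAtoms():
            if a.HasProp(charge_prop):
                charges.append(float(a.GetProp(charge_prop)))
            elif a.HasProp("_GasteigerCharge"):
                charges.append(float(a.GetProp("_GasteigerCharge")))
            else:
                charges.append(np.nan)
        out.append(Conformer(symbols, coords, np.array(charges)))
    if not out:
        raise ValueError(f"no readable molecules in {path}")
    return out
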