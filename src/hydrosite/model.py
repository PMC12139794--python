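"""Core domain types and thermodynamic conversions.

The central quantity of the package is the excess chemical potential of
water, written WT ("work to transfer"): the free-energy change of moving a
water molecule from bulk solvent to a position ``x`` near a fixed solute.
For an equilibrium simulation it is related to the local water-oxygen
number density by

    WT(x) = -kT * ln( rho(x) / rho_bulk )

so favorable (negative) WT means the position is occupied more densely
than bulk water.  All coordinates are in Angstrom, energies in kcal/mol,
densities in molecules/A^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "ValidationError",
    "FormatError",
    "DegenerateGeometryError",
    "ThermoParams",
    "SoluteStructure",
    "WaterTrajectory",
    "WTResult",
    "as_point",
    "make_thermo",
    "wt_to_density_ratio",
    "density_ratio_to_wt",
    "water_number_density",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.01528

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(RuntimeError):
    """Raised when a file cannot be parsed in the expected format."""


class DegenerateGeometryError(RuntimeError):
    """Raised when a geometric operation is numerically ill-posed
    (e.g. superposing onto a collinear atom selection)."""


def as_point(p) -> np.ndarray:
    """Coerce *p* to a finite (3,) float64 array."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.shape != (3,):
        raise ValidationError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("point has non-finite components")
    return arr


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and bulk-density reference for WT conversions.

    Parameters
    ----------
    temperature:
        Absolute temperature in K.  Must be positive.
    rho_bulk:
        Bulk water-oxygen number density in molecules/A^3.  The default
        0.033 is the standard value for liquid water at ambient
        conditions.
    """

    temperature: float = 300.0
    rho_bulk: float = 0.033

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValidationError("temperature must be > 0 K")
        if not (self.rho_bulk > 0):
            raise ValidationError("rho_bulk must be > 0 A^-3")

    @property
    def kT(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return KB_KCAL_PER_MOL_K * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kT in mol/kcal."""
        return 1.0 / self.kT


def make_thermo(temperature: float = 300.0, rho_bulk: float = 0.033) -> ThermoParams:
    """Construct validated :class:`ThermoParams`."""
    return ThermoParams(temperature=float(temperature), rho_bulk=float(rho_bulk))


def wt_to_density_ratio(wt: float, thermo: ThermoParams) -> float:
    """Local-to-bulk density ratio rho(x)/rho_bulk implied by a WT value.

    Strictly decreasing in *wt*; equals 1 at wt = 0.
    """
    return math.exp(-wt / thermo.kT)


def density_ratio_to_wt(ratio: float, thermo: ThermoParams) -> float:
    """Inverse of :func:`wt_to_density_ratio`: WT = -kT ln(ratio)."""
    if not (ratio > 0):
        raise ValidationError("density ratio must be > 0")
    return -thermo.kT * math.log(ratio)


def water_number_density(mass_density_g_cm3: float = 0.997) -> float:
    """Number density of liquid water in molecules/A^3.

    Computed from the mass density (default 0.997 g/cm^3, water near
    300 K); the conventional rounded value is 0.033 A^-3.
    """
    if not (mass_density_g_cm3 > 0):
        raise ValidationError("mass density must be > 0")
    per_cm3 = mass_density_g_cm3 / WATER_MOLAR_MASS * AVOGADRO
    return per_cm3 * 1e-24  # 1 cm^3 = 1e24 A^3


@dataclass
class SoluteStructure:
    """Heavy-atom coordinates and identity of the fixed solute.

    ``coords`` is an (N, 3) float array in Angstrom; the parallel lists
    carry per-atom PDB-style metadata.
    """

    coords: np.ndarray
    atom_names: list[str]
    residue_names: list[str]
    residue_ids: list[int]
    chain_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        for name in ("atom_names", "residue_names", "residue_ids", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length does not match coords ({n})")

    def __len__(self) -> int:
        return len(self.coords)

    def chain(self, chain_id: str) -> "SoluteStructure":
        """Sub-structure restricted to one chain."""
        idx = [i for i, c in enumerate(self.chain_ids) if c == chain_id]
        if not idx:
            raise ValidationError(f"no atoms in chain {chain_id!r}")
        return SoluteStructure(
            coords=self.coords[idx],
            atom_names=[self.atom_names[i] for i in idx],
            residue_names=[self.residue_names[i] for i in idx],
            residue_ids=[self.residue_ids[i] for i in idx],
            chain_ids=[self.chain_ids[i] for i in idx],
        )

    @property
    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: list[str] = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class WaterTrajectory:
    """Water-oxygen positions per frame, in a fixed solute-aligned frame.

    ``frames`` is a list of (M_i, 3) arrays; frames may contain different
    numbers of waters (e.g. after shell filtering or synthetic occupancy
    draws).
    """

    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValidationError("a trajectory needs at least one frame")
        self.frames = [
            np.asarray(f, dtype=np.float64).reshape(-1, 3) for f in self.frames
        ]
        self._stacked: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_points(self) -> int:
        return sum(len(f) for f in self.frames)

    def stacked(self) -> np.ndarray:
        """All water positions concatenated into one (total, 3) array.

        Cached; frame identity is not preserved (the density estimators
        only need the pooled point cloud plus ``n_frames``).
        """
        if self._stacked is None:
            nonempty = [f for f in self.frames if len(f)] or [np.empty((0, 3))]
            self._stacked = np.concatenate(nonempty, axis=0)
        return self._stacked


@dataclass(frozen=True)
class WTResult:
    """Boltzmann-averaged WT for one reference position.

    ``density_ratio`` is always exp(-wt/kT) for the thermo used to
    produce the result; ``total_selected_count`` is the summed water
    count of the selected fine voxels.
    """

    reference: np.ndarray
    wt: float
    n_selected_voxels: int
    total_selected_count: int
    density_ratio: float
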