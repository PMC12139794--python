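"""Reading and writing the structure/trajectory/site formats of the pipeline.

PDB is the canonical interchange format (ATOM/HETATM, MODEL/ENDMDL);
mmCIF is supported read-only through gemmi, XYZ and any binary MD format
through MDAnalysis.  Site tables go out as PDB (WT in the B-factor
column) or CSV.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .model import (
    FormatError,
    SoluteStructure,
    ValidationError,
    WaterTrajectory,
)

__all__ = [
    "DEFAULT_WATER_NAMES",
    "ION_NAMES",
    "StructureRecord",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_sites",
    "read_sites_csv",
    "pdb_atom_line",
]

#: Residue names recognized as water across common PDB dialects.
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

#: Monoatomic ions and common crystallization additives excluded from
#: both the solute and the water list.
ION_NAMES = frozenset(
    {
        "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO",
        "CD", "HG", "BR", "IOD", "CS", "LI", "RB", "SR", "BA", "F",
        "SO4", "PO4", "NO3", "GOL", "EDO", "ACT", "NH4",
    }
)

_HYDROGEN = {"H", "D"}


@dataclass
class StructureRecord:
    """One experimental (or pseudo-experimental) structure.

    ``waters`` holds water-oxygen positions only, shape (K, 3).
    """

    id: str
    solute: SoluteStructure
    waters: np.ndarray
    resolution: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("structure id must be non-empty")
        self.waters = np.asarray(self.waters, dtype=np.float64).reshape(-1, 3)


def _keep_altloc(altloc: str) -> bool:
    return altloc in ("", "\0", "A")


def read_structure(
    path: str | os.PathLike,
    water_residue_names: Iterable[str] = DEFAULT_WATER_NAMES,
    chain_filter: Iterable[str] | None = None,
) -> StructureRecord:
    """Read a PDB or mmCIF file into a :class:`StructureRecord`.

    The solute keeps every non-water, non-ion heavy atom of the selected
    chains; ``waters`` keeps only oxygen positions of water residues.
    Alternate locations other than blank/'A' are dropped.
    """
    path = Path(path)
    water_names = {n.upper() for n in water_residue_names}
    chains = set(chain_filter) if chain_filter is not None else None
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models found in {path}")

    coords, names, resnames, resids, chain_ids = [], [], [], [], []
    waters = []
    model = st[0]
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            rname = res.name.upper()
            for atom in res:
                if not _keep_altloc(atom.altloc):
                    continue
                element = atom.element.name.upper()
                if rname in water_names:
                    if element == "O" or atom.name.upper().startswith("O"):
                        waters.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    continue
                if rname in ION_NAMES:
                    continue
                if element in _HYDROGEN:
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                names.append(atom.name)
                resnames.append(res.name)
                resids.append(res.seqid.num)
                chain_ids.append(chain.name)

    if not coords:
        raise ValidationError(f"no solute atoms left after filtering in {path}")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    solute = SoluteStructure(
        coords=np.asarray(coords),
        atom_names=names,
        residue_names=resnames,
        residue_ids=resids,
        chain_ids=chain_ids,
    )
    record_id = st.name or path.stem
    return StructureRecord(
        id=record_id, solute=solute,
        waters=np.asarray(waters).reshape(-1, 3), resolution=resolution,
    )


def _read_pdb_trajectory(
    path: Path, water_names: set[str], stride: int
) -> WaterTrajectory:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse trajectory file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models found in {path}")
    frames: list[np.ndarray] = []
    for i, model in enumerate(st):
        if i % stride:
            continue
        pts = []
        for chain in model:
            for res in chain:
                if res.name.upper() not in water_names:
                    continue
                for atom in res:
                    element = atom.element.name.upper()
                    if element == "O" or atom.name.upper().startswith("O"):
                        pts.append([atom.pos.x, atom.pos.y, atom.pos.z])
        frames.append(np.asarray(pts, dtype=np.float64).reshape(-1, 3))
    return WaterTrajectory(frames=frames)


def _read_mda_trajectory(
    path: Path, topology: Path | None, stride: int
) -> WaterTrajectory:
    # MDAnalysis handles XYZ and, when a topology is supplied, the usual
    # binary MD formats (XTC/TRR/DCD).  Water oxygens are selected by
    # element/name starting with O.
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if topology is not None:
                u = mda.Universe(str(topology), str(path))
            else:
                u = mda.Universe(str(path))
        except Exception as exc:  # MDAnalysis raises many exception types
            raise FormatError(f"cannot parse trajectory file {path}: {exc}") from exc
        sel = u.atoms[[a.name.upper().startswith("O") for a in u.atoms]]
        frames = []
        for i, _ts in enumerate(u.trajectory):
            if i % stride:
                continue
            frames.append(sel.positions.astype(np.float64).copy())
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return WaterTrajectory(frames=frames)


def read_trajectory(
    path: str | os.PathLike,
    format_hint: str | None = None,
    stride: int = 1,
    water_residue_names: Iterable[str] = DEFAULT_WATER_NAMES,
    topology: str | os.PathLike | None = None,
) -> WaterTrajectory:
    """Read water-oxygen frames from a multi-model PDB, XYZ, or any
    MDAnalysis-readable trajectory (the latter needs ``topology``).

    ``stride`` keeps every stride-th frame starting from the first.
    """
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt in ("pdb", "ent"):
        return _read_pdb_trajectory(
            path, {n.upper() for n in water_residue_names}, stride
        )
    return _read_mda_trajectory(
        path, Path(topology) if topology else None, stride
    )


# ---------------------------------------------------------------------------
# writers

def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resid: int,
    xyz,
    occupancy: float = 1.0,
    bfactor: float = 0.0,
    element: str = "",
    het: bool = False,
) -> str:
    """Format one fixed-width PDB ATOM/HETATM line."""
    record = "HETATM" if het else "ATOM"
    if len(name) < 4:
        name = f" {name:<3}"
    element = (element or name.strip()[0]).upper()
    x, y, z = (float(v) for v in xyz)
    return (
        f"{record:<6}{serial % 100000:>5} {name:<4} {resname:>3} "
        f"{chain[:1]:1}{resid % 10000:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {element:>2}"
    )


def _solute_lines(solute: SoluteStructure, start_serial: int = 1) -> list[str]:
    lines = []
    serial = start_serial
    for i in range(len(solute)):
        lines.append(
            pdb_atom_line(
                serial,
                solute.atom_names[i],
                solute.residue_names[i],
                solute.chain_ids[i],
                solute.residue_ids[i],
                solute.coords[i],
            )
        )
        serial += 1
    return lines


def write_structure(record: StructureRecord, path: str | os.PathLike) -> None:
    """Write solute + waters (residue HOH, chain W) as a single-model PDB."""
    lines = [f"REMARK   6 HYDROSITE STRUCTURE {record.id}"]
    lines += _solute_lines(record.solute)
    serial = len(record.solute) + 1
    for j, w in enumerate(record.waters, start=1):
        lines.append(
            pdb_atom_line(serial, "O", "HOH", "W", j, w, het=True, element="O")
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: WaterTrajectory, path: str | os.PathLike) -> None:
    """Write water-oxygen frames as a multi-model PDB (one model per frame)."""
    out = []
    for m, frame in enumerate(traj.frames, start=1):
        out.append(f"MODEL     {m:>4}")
        for j, w in enumerate(frame, start=1):
            out.append(pdb_atom_line(j, "O", "HOH", "W", j, w, het=True, element="O"))
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def write_sites(sites: Sequence, path: str | os.PathLike, format: str = "pdb") -> None:
    """Write predicted hydration sites.

    ``format="pdb"``: one HETATM oxygen per site at its mean position,
    occupancy 1.00, B-factor = WT in kcal/mol (0.00 when unscored).
    ``format="csv"``: columns id,x,y,z,wt,density_ratio,window_count.
    """
    path = Path(path)
    if format == "pdb":
        lines = ["REMARK   6 HYDROSITE PREDICTED WATER SITES (B-FACTOR = WT KCAL/MOL)"]
        for i, s in enumerate(sites, start=1):
            pos = s.mean_position if s.mean_position is not None else s.cube_center
            wt = s.wt if s.wt is not None else 0.0
            lines.append(
                pdb_atom_line(i, "O", "HOH", "W", i, pos, bfactor=wt,
                              het=True, element="O")
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y", "z", "wt", "density_ratio",
                             "window_count"])
            for i, s in enumerate(sites, start=1):
                pos = s.mean_position if s.mean_position is not None else s.cube_center
                writer.writerow(
                    [
                        i,
                        f"{pos[0]:.6f}", f"{pos[1]:.6f}", f"{pos[2]:.6f}",
                        "" if s.wt is None else f"{s.wt:.6f}",
                        "" if s.density_ratio is None else f"{s.density_ratio:.6f}",
                        s.window_count,
                    ]
                )
    else:
        raise ValidationError(f"unknown site format {format!r}")


def read_sites_csv(path: str | os.PathLike) -> "pandas.DataFrame":  # noqa: F821
    """Read a site table written by :func:`write_sites` (csv format)."""
    import pandas as pd

    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse site table {path}: {exc}") from exc
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"site table {path} lacks columns {sorted(missing)}")
    return df
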