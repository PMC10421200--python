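"""Structure and topology file I/O.

XYZ is written natively in the extended-XYZ dialect (comment line carries
``Lattice="..."`` and ``pbc="..."``) and supports multi-frame trajectories.
PDB (CRYST1 box record) and GRO (nm units) go through MDAnalysis. Topology
(bonds/angles) is exported as a plain-text table with 1-based atom indices,
matching the PDB/GRO numbering convention.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .constants import FORMAL_CHARGES
from .structures import NanoStructure

__all__ = [
    "write_xyz",
    "read_xyz",
    "read_xyz_frames",
    "write_pdb",
    "read_pdb",
    "write_gro",
    "read_gro",
    "write_topology",
    "read_topology",
    "read_structure",
    "write_structure",
]


def _xyz_comment(box, periodic) -> str:
    lat = (
        f'Lattice="{box[0]:.6f} 0.0 0.0 0.0 {box[1]:.6f} 0.0 0.0 0.0 {box[2]:.6f}"'
    )
    pbc = 'pbc="' + " ".join("T" if p else "F" for p in periodic) + '"'
    return f"{lat} {pbc}"


def write_xyz(structure: NanoStructure, path, frames=None, times=None) -> None:
    """Write a structure (or a list of position frames) as (multi-frame) XYZ."""
    frames = [structure.positions] if frames is None else frames
    with open(path, "w") as fh:
        for k, pos in enumerate(frames):
            fh.write(f"{structure.n_atoms}\n")
            comment = _xyz_comment(structure.box, structure.periodic)
            if times is not None:
                comment += f" time={times[k]:.6f}"
            fh.write(comment + "\n")
            for sp, (x, y, z) in zip(structure.species, pos):
                fh.write(f"{sp:<4s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def _parse_xyz_comment(comment: str):
    box = np.zeros(3)
    periodic = np.zeros(3, dtype=bool)
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        cell = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
        box = np.diag(cell).copy()
    m = re.search(r'pbc="([^"]+)"', comment)
    if m:
        periodic = np.array([t.upper().startswith("T") for t in m.group(1).split()])
    m = re.search(r"time=([-\d.eE+]+)", comment)
    time = float(m.group(1)) if m else None
    return box, periodic, time


def read_xyz_frames(path):
    """All frames of an (extended) XYZ file.

    Returns (species, frames, box, periodic, times).
    """
    species, frames, times = None, [], []
    box = np.zeros(3)
    periodic = np.zeros(3, dtype=bool)
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            box, periodic, time = _parse_xyz_comment(fh.readline())
            sp, pos = [], np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                sp.append(parts[0])
                pos[i] = [float(v) for v in parts[1:4]]
            species = np.array(sp, dtype=object)
            frames.append(pos)
            times.append(time)
    return species, frames, box, periodic, times


def read_xyz(path) -> NanoStructure:
    """First frame of an XYZ file as a NanoStructure (formal ZnS charges
    assigned where the species is known, 0 otherwise)."""
    species, frames, box, periodic, _ = read_xyz_frames(path)
    charges = np.array([FORMAL_CHARGES.get(s, 0.0) for s in species])
    return NanoStructure(
        species=species, positions=frames[0], charges=charges,
        box=box, periodic=periodic,
    )


def _mda_universe(structure: NanoStructure):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(structure.n_atoms, trajectory=True)
        names = [str(s) for s in structure.species]
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", [n[:2] for n in names])
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["ZNS"])
        u.atoms.positions = structure.positions
        u.dimensions = [*structure.box, 90.0, 90.0, 90.0]
    return u


def write_pdb(structure: NanoStructure, path) -> None:
    u = _mda_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_gro(structure: NanoStructure, path) -> None:
    u = _mda_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _read_mda(path, periodic) -> NanoStructure:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        species = np.array([n.strip() for n in u.atoms.names], dtype=object)
        dims = u.dimensions
        box = np.array(dims[:3]) if dims is not None else np.zeros(3)
        charges = np.array([FORMAL_CHARGES.get(s, 0.0) for s in species])
        return NanoStructure(
            species=species,
            positions=u.atoms.positions.astype(float),
            charges=charges,
            box=box,
            periodic=np.asarray(periodic, dtype=bool),
        )


def read_pdb(path, periodic=(False, False, False)) -> NanoStructure:
    return _read_mda(path, periodic)


def read_gro(path, periodic=(False, False, False)) -> NanoStructure:
    return _read_mda(path, periodic)


def write_topology(structure: NanoStructure, path) -> None:
    """Plain-text bonds/angles table (1-based atom indices)."""
    with open(path, "w") as fh:
        fh.write("# nanosorb topology; atom indices are 1-based\n")
        fh.write(f"[bonds] {len(structure.bonds)}\n")
        for i, j in structure.bonds:
            fh.write(f"{i + 1} {j + 1}\n")
        fh.write(f"[angles] {len(structure.angles)}\n")
        for i, j, k in structure.angles:
            fh.write(f"{i + 1} {j + 1} {k + 1}\n")


def read_topology(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a bonds/angles table; returns 0-based (bonds, angles) arrays."""
    bonds, angles, section = [], [], None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[bonds]"):
            section = bonds
            continue
        if line.startswith("[angles]"):
            section = angles
            continue
        section.append([int(v) - 1 for v in line.split()])
    return (
        np.array(bonds, dtype=int).reshape(-1, 2),
        np.array(angles, dtype=int).reshape(-1, 3),
    )


def fixture_path(name: str) -> Path:
    """Path to a shipped miniature fixture (mini_slab.xyz, mini_np.xyz,
    toy_sorbate.xyz and their .top topology tables)."""
    p = Path(__file__).parent / "data" / name
    if not p.exists():
        available = sorted(f.name for f in p.parent.glob("*"))
        raise FileNotFoundError(f"no fixture {name!r}; available: {available}")
    return p


def load_fixture(name: str) -> NanoStructure:
    """Load a shipped structure fixture, with its topology when present."""
    p = fixture_path(name)
    structure = read_structure(p)
    top = p.with_suffix(".top")
    if top.exists():
        structure.bonds, structure.angles = read_topology(top)
    return structure


_WRITERS = {".xyz": write_xyz, ".pdb": write_pdb, ".gro": write_gro}
_READERS = {".xyz": read_xyz, ".pdb": read_pdb, ".gro": read_gro}


def write_structure(structure: NanoStructure, path) -> None:
    """Dispatch on file extension (.xyz / .pdb / .gro)."""
    suffix = Path(path).suffix.lower()
    try:
        _WRITERS[suffix](structure, path)
    except KeyError:
        raise ValueError(f"unsupported structure format {suffix!r}") from None


def read_structure(path) -> NanoStructure:
    suffix = Path(path).suffix.lower()
    try:
        return _READERS[suffix](path)
    except KeyError:
        raise ValueError(f"unsupported structure format {suffix!r}") from None
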