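"""Zinc-blende ZnS structure builders: crystals, (110) slabs, nanoparticles.

The conventional zinc-blende cell has 4 cations on the fcc sites and 4
anions on the tetrahedral interstices; the nearest-neighbour Zn-S distance
is a*sqrt(3)/4. The (110) cleavage is the stable nonpolar surface: each
(110) atomic layer is stoichiometric (2 Zn + 2 S per surface cell), layers
are spaced a/(2*sqrt(2)), and the rectangular surface cell has edges a
(along a cubic axis) and a*sqrt(2) (along the face diagonal).

Nanoparticles are carved as spheres from the periodically repeated crystal;
singly-coordinated surface atoms are removed in one pruning pass by default
(a fixpoint mode is available). Coordination counts only heteroatomic
(Zn-S) contacts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import FORMAL_CHARGES

__all__ = [
    "LatticeSpec",
    "NanoStructure",
    "build_unit_cell",
    "build_slab_110",
    "build_nanoparticle",
    "coordination_and_prune",
    "coordination_numbers",
    "derive_topology",
    "neighbor_pairs",
    "minimum_image",
    "scan_nanoparticle_centers",
]

#: Fractional coordinates of the conventional zinc-blende basis.
_ZN_FRAC = np.array(
    [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
)
_S_FRAC = _ZN_FRAC + 0.25

#: Default heteroatomic bond cutoff (Å), between the first (2.34 Å) and
#: second (3.83 Å) neighbour shells of ZnS at a = 5.41 Å.
DEFAULT_BOND_CUTOFF = 2.9


@dataclass(frozen=True)
class LatticeSpec:
    """Cubic zinc-blende lattice specification.

    The lattice constant is not printed in most ZnS force-field papers;
    5.41 Å is the standard zinc-blende ZnS value.
    """

    a: float = 5.41  # Å
    structure: str = "zinc-blende"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fractional

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"lattice constant must be positive, got {self.a}")
        if self.structure != "zinc-blende":
            raise ValueError(f"unsupported structure tag {self.structure!r}")


@dataclass
class NanoStructure:
    """An atomistic nanostructure with optional bonded topology.

    Positions are Cartesian Å. ``box`` holds orthorhombic box lengths (Å);
    ``periodic`` flags each axis. ``bonds`` is an (m, 2) array of atom index
    pairs stored with i < j; ``angles`` is (k, 3) with the apex atom in the
    middle. ``surface`` flags under-coordinated atoms.
    """

    species: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    box: np.ndarray
    periodic: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    angles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))
    surface: np.ndarray | None = None

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 3)
        if self.surface is None:
            self.surface = np.zeros(self.n_atoms, dtype=bool)
        else:
            self.surface = np.asarray(self.surface, dtype=bool)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.bonds.size:
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise ValueError("self-bonds are not allowed")
            self.bonds = np.unique(np.sort(self.bonds, axis=1), axis=0)
        self._check_angles()

    def _check_angles(self):
        if not self.angles.size:
            return
        bond_set = {(int(i), int(j)) for i, j in self.bonds}
        for i, j, k in self.angles:
            for outer in (int(i), int(k)):
                pair = tuple(sorted((outer, int(j))))
                if pair not in bond_set:
                    raise ValueError(
                        f"angle {(i, j, k)} references unbonded pair {pair}"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def species_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.species.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def radial_extent(self, center: np.ndarray | None = None) -> float:
        """Maximal distance of any atom from ``center`` (default: centroid)."""
        if center is None:
            center = self.positions.mean(axis=0)
        return float(np.linalg.norm(self.positions - center, axis=1).max())

    def copy(self) -> "NanoStructure":
        return NanoStructure(
            species=self.species.copy(),
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            surface=self.surface.copy(),
        )

    def subset(self, keep: np.ndarray) -> "NanoStructure":
        """New structure with only the ``keep`` atoms; topology is dropped
        (indices would dangle) and should be re-derived."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return NanoStructure(
            species=self.species[keep],
            positions=self.positions[keep],
            charges=self.charges[keep],
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            surface=self.surface[keep],
        )

    def describe(self) -> dict:
        d = {
            "n_atoms": self.n_atoms,
            "species_counts": self.species_counts(),
            "total_charge": self.total_charge,
            "box": self.box.tolist(),
            "periodic": self.periodic.tolist(),
            "n_bonds": len(self.bonds),
            "n_angles": len(self.angles),
        }
        if not self.periodic.any() and self.n_atoms:
            d["radial_extent"] = self.radial_extent()
        return d


def minimum_image(dvec: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention along periodic axes."""
    dvec = np.array(dvec, dtype=float)
    for ax in range(3):
        if periodic[ax]:
            dvec[..., ax] -= box[ax] * np.round(dvec[..., ax] / box[ax])
    return dvec


def neighbor_pairs(
    positions: np.ndarray,
    box: np.ndarray,
    periodic: np.ndarray,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray]:
    """All atom pairs (i < j) within ``cutoff``, honouring mixed periodicity.

    Periodic axes are handled by tiling ±1 images, which is exact for
    cutoffs below the periodic box lengths.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if not np.any(periodic):
        tree = cKDTree(positions)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        return pairs[:, 0], pairs[:, 1]

    if n <= 1500:
        # vectorized all-pairs minimum-image search; faster than trees here
        pi, pj = np.triu_indices(n, k=1)
        d = minimum_image(positions[pi] - positions[pj], box, periodic)
        keep = (d * d).sum(axis=1) <= cutoff * cutoff
        return pi[keep], pj[keep]

    shifts = [
        np.array(s, dtype=float)
        for s in itertools.product(
            *[(-1, 0, 1) if periodic[ax] else (0,) for ax in range(3)]
        )
    ]
    ext_pos = np.concatenate([positions + s * box for s in shifts])
    ext_idx = np.tile(np.arange(n), len(shifts))
    tree = cKDTree(ext_pos)
    seen: set[tuple[int, int]] = set()
    for i, nbrs in enumerate(tree.query_ball_point(positions, cutoff)):
        for jj in nbrs:
            j = int(ext_idx[jj])
            if j == i:
                continue
            seen.add((i, j) if i < j else (j, i))
    if not seen:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    arr = np.array(sorted(seen), dtype=int)
    return arr[:, 0], arr[:, 1]


def _lattice_points(lattice: LatticeSpec, cell_range) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian coordinates and species for replicated conventional cells."""
    offsets = np.array(list(cell_range), dtype=float)
    origin = np.asarray(lattice.origin, dtype=float)
    pos, spec = [], []
    for frac, label in ((_ZN_FRAC, "Zn"), (_S_FRAC, "S")):
        p = (offsets[:, None, :] + frac[None, :, :] - origin) * lattice.a
        pos.append(p.reshape(-1, 3))
        spec.extend([label] * (len(offsets) * len(frac)))
    return np.concatenate(pos), np.array(spec, dtype=object)


def build_unit_cell(lattice: LatticeSpec) -> NanoStructure:
    """Conventional cubic zinc-blende cell: 4 Zn + 4 S, fully periodic."""
    pos, spec = _lattice_points(lattice, [(0, 0, 0)])
    pos %= lattice.a
    charges = np.array([FORMAL_CHARGES[s] for s in spec])
    return NanoStructure(
        species=spec,
        positions=pos,
        charges=charges,
        box=np.full(3, lattice.a),
        periodic=np.array([True, True, True]),
    )


def build_slab_110(
    lattice: LatticeSpec, n_x: int, n_y: int, n_layers: int
) -> NanoStructure:
    """ZnS (110) slab: periodic in X and Y, open in Z (slab normal +Z).

    X spans ``n_x`` repeats of length a along a cubic axis, Y spans ``n_y``
    repeats of a*sqrt(2) along the face diagonal, and Z stacks ``n_layers``
    stoichiometric (110) atomic layers spaced a/(2*sqrt(2)). Each layer
    contributes 2 Zn + 2 S per surface cell, so the slab holds exactly
    4*n_x*n_y*n_layers atoms. Top and bottom layers are flagged as surface.
    """
    if min(n_x, n_y, n_layers) < 1:
        raise ValueError("repeat counts must be >= 1")
    a = lattice.a
    d = a / (2.0 * np.sqrt(2.0))
    lx, ly = n_x * a, n_y * a * np.sqrt(2.0)
    z_max = (n_layers - 1) * d

    # rotated frame: x' = [001], y' = [1,-1,0]/sqrt2, z' = [110]/sqrt2
    axes = np.array(
        [
            [0.0, 0.0, 1.0],
            [1.0 / np.sqrt(2.0), -1.0 / np.sqrt(2.0), 0.0],
            [1.0 / np.sqrt(2.0), 1.0 / np.sqrt(2.0), 0.0],
        ]
    )
    r = n_y + n_layers + 2
    cells = itertools.product(range(-r, r + 1), range(-r, r + 1), range(-1, n_x + 1))
    pos, spec = _lattice_points(lattice, cells)
    rot = pos @ axes.T
    rot[:, 0] %= lx
    rot[:, 1] %= ly
    keep = (rot[:, 2] > -1e-6) & (rot[:, 2] < z_max + 1e-6)
    rot, spec = rot[keep], spec[keep]
    # fold rounding noise at the periodic edges, then deduplicate
    rot[:, 0] = np.where(rot[:, 0] > lx - 1e-6, rot[:, 0] - lx, rot[:, 0])
    rot[:, 1] = np.where(rot[:, 1] > ly - 1e-6, rot[:, 1] - ly, rot[:, 1])
    key = np.round(rot / 1e-4).astype(np.int64)
    _, uniq = np.unique(
        np.concatenate([key, (spec == "Zn")[:, None].astype(np.int64)], axis=1),
        axis=0,
        return_index=True,
    )
    rot, spec = rot[np.sort(uniq)], spec[np.sort(uniq)]

    charges = np.array([FORMAL_CHARGES[s] for s in spec])
    surface = (rot[:, 2] < d / 2) | (rot[:, 2] > z_max - d / 2)
    return NanoStructure(
        species=spec,
        positions=rot,
        charges=charges,
        box=np.array([lx, ly, n_layers * d]),
        periodic=np.array([True, True, False]),
        surface=surface,
    )


def build_nanoparticle(
    lattice: LatticeSpec,
    diameter: float,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    prune: bool = True,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
) -> NanoStructure:
    """Spherical nanoparticle carved from the replicated crystal.

    ``center`` is fractional within the conventional cell; the default
    (0, 0, 0) is a cation site, which yields a stoichiometric, charge-neutral
    cut for symmetric diameters. With ``prune`` singly-coordinated atoms are
    removed in one pass, mirroring the usual surface clean-up of carved
    particles.
    """
    if diameter <= lattice.a:
        raise ValueError("diameter must exceed the lattice constant")
    radius = diameter / 2.0
    nrep = int(np.ceil(radius / lattice.a)) + 1
    cells = itertools.product(*[range(-nrep, nrep + 1)] * 3)
    pos, spec = _lattice_points(lattice, cells)
    c = np.asarray(center, dtype=float) * lattice.a
    keep = np.linalg.norm(pos - c, axis=1) <= radius + 1e-9
    if not keep.any():
        raise ValueError("diameter too small: no atoms inside the sphere")
    pos, spec = pos[keep] - c, spec[keep]
    structure = NanoStructure(
        species=spec,
        positions=pos,
        charges=np.array([FORMAL_CHARGES[s] for s in spec]),
        box=np.full(3, 2 * radius + 2 * bond_cutoff),
        periodic=np.array([False, False, False]),
    )
    if prune:
        structure = coordination_and_prune(
            structure, bond_cutoff=bond_cutoff, min_coord=2, iterate=False
        )
    return derive_topology(structure, bond_cutoff=bond_cutoff)


def coordination_numbers(structure: NanoStructure, cutoff: float) -> np.ndarray:
    """Heteroatomic (unlike-species) neighbour counts per atom."""
    i, j = neighbor_pairs(structure.positions, structure.box, structure.periodic, cutoff)
    coord = np.zeros(structure.n_atoms, dtype=int)
    if i.size:
        hetero = structure.species[i] != structure.species[j]
        np.add.at(coord, i[hetero], 1)
        np.add.at(coord, j[hetero], 1)
    return coord


def coordination_and_prune(
    structure: NanoStructure,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF,
    min_coord: int = 2,
    iterate: bool = False,
) -> NanoStructure:
    """Remove atoms whose heteroatomic coordination is below ``min_coord``.

    A single removal pass by default: atoms that only become
    under-coordinated through the removal of their neighbours survive.
    With ``iterate`` the pass repeats to a fixpoint.
    """
    if bond_cutoff <= 0:
        raise ValueError("bond_cutoff must be positive")
    current = structure
    while True:
        coord = coordination_numbers(current, bond_cutoff)
        keep = coord >= min_coord
        if keep.all():
            return current
        current = current.subset(keep)
        if not iterate:
            return current


def derive_topology(
    structure: NanoStructure, bond_cutoff: float = DEFAULT_BOND_CUTOFF
) -> NanoStructure:
    """Derive bonds, angles and surface flags from interatomic distances.

    Bonds are all heteroatomic pairs within the cutoff (minimum image on
    periodic axes); angles are all bonded triples sharing an apex. A cutoff
    that reaches the homoatomic second-neighbour shell makes the bond graph
    ambiguous and raises.
    """
    if bond_cutoff <= 0:
        raise ValueError("bond_cutoff must be positive")
    i, j = neighbor_pairs(structure.positions, structure.box, structure.periodic, bond_cutoff)
    out = structure.copy()
    if i.size:
        homo = structure.species[i] == structure.species[j]
        if homo.any():
            raise ValueError(
                "bond cutoff reaches the homoatomic second-neighbour shell; "
                "topology would be ambiguous"
            )
    bonds = np.stack([i, j], axis=1) if i.size else np.empty((0, 2), dtype=int)
    neigh: dict[int, list[int]] = {}
    for bi, bj in bonds:
        neigh.setdefault(int(bi), []).append(int(bj))
        neigh.setdefault(int(bj), []).append(int(bi))
    angles = [
        (p, apex, q)
        for apex, nbrs in sorted(neigh.items())
        for p, q in itertools.combinations(sorted(nbrs), 2)
    ]
    out.bonds = bonds
    out.angles = np.array(angles, dtype=int) if angles else np.empty((0, 3), dtype=int)
    coord = np.zeros(structure.n_atoms, dtype=int)
    if bonds.size:
        np.add.at(coord, bonds[:, 0], 1)
        np.add.at(coord, bonds[:, 1], 1)
    out.surface = coord < 4
    out._check_angles()
    return out


def scan_nanoparticle_centers(
    lattice: LatticeSpec,
    diameter: float,
    prune: bool = True,
    centers: dict[str, tuple[float, float, float]] | None = None,
) -> dict[str, dict]:
    """Carve nanoparticles at a few high-symmetry centers and report the
    species counts and net charge of each cut (to search for neutral,
    stoichiometric particles)."""
    if centers is None:
        centers = {
            "cation-site": (0.0, 0.0, 0.0),
            "anion-site": (0.25, 0.25, 0.25),
            "bond-midpoint": (0.125, 0.125, 0.125),
            "tetrahedral-hole": (0.5, 0.5, 0.5),
        }
    report = {}
    for name, c in centers.items():
        s = build_nanoparticle(lattice, diameter, center=c, prune=prune)
        report[name] = {
            "center": c,
            "n_atoms": s.n_atoms,
            "species_counts": s.species_counts(),
            "total_charge": s.total_charge,
            "radial_extent": s.radial_extent(np.zeros(3)),
        }
    return report
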