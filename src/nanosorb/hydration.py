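"""Interfacial structure analysis: density profiles, water orientation
distributions, radial distribution functions and first-shell detection.

Density profiles come in three flavours matching how hydration layers are
usually presented around nanostructures: planar (along the slab normal z),
radial (spherical shells from a center), and nearest-surface-atom distance
(sharpens layering around rough particles). Each profile carries its bin
volumes so that sum(density * volume) recovers the mean selected-particle
count per frame exactly.

Water orientation is measured by two angles against a reference direction
(slab normal or particle radial direction): theta for the molecular dipole
(the bisector from O through the HH midpoint) and alpha for each OH bond.
Raw angle histograms of an isotropic fluid follow sin(theta); the
sin-corrected mode divides out that Jacobian so an isotropic baseline is
flat.

Input trajectories are in Å (the package's structure unit); all reported
distances and densities use nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dynamics import Trajectory
from .structures import minimum_image

__all__ = [
    "DensityProfile",
    "OrientationSamples",
    "RDFCurve",
    "density_profile",
    "orientation_angles",
    "orientation_histogram",
    "pair_rdf",
    "first_minimum",
]

_A2NM = 0.1


@dataclass
class DensityProfile:
    mode: str  # "planar-z" | "radial" | "nearest-surface"
    bins: np.ndarray  # centers, nm
    density: np.ndarray  # nm^-3 (nm^-1 for nearest-surface)
    volumes: np.ndarray  # per-bin normalization volume (nm^3 or nm)
    species: str | None
    n_mean: float  # mean selected particles per frame
    normalization: str = "per-volume"

    def __post_init__(self):
        if np.any(self.density < -1e-12):
            raise ValueError("densities must be non-negative")


@dataclass
class OrientationSamples:
    """Per-molecule dipole angles and per-bond OH angles (degrees), with
    the molecule's distance to the reference surface/center (nm)."""

    theta_deg: np.ndarray
    alpha_deg: np.ndarray  # two per molecule, flattened
    distance_nm: np.ndarray

    def __post_init__(self):
        for a in (self.theta_deg, self.alpha_deg):
            if a.size and (a.min() < -1e-9 or a.max() > 180.0 + 1e-9):
                raise ValueError("angles must lie in [0, 180] degrees")


@dataclass
class RDFCurve:
    r: np.ndarray  # nm
    g: np.ndarray
    meta: dict = field(default_factory=dict)


def _selection_indices(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    if isinstance(selection, str):
        idx = np.flatnonzero(traj.species.astype(str) == selection)
    else:
        sel = np.asarray(selection)
        idx = np.flatnonzero(sel) if sel.dtype == bool else sel.astype(int)
    if idx.size == 0:
        raise ValueError("empty selection")
    return idx


def density_profile(
    trajectory: Trajectory,
    selection=None,
    mode: str = "planar-z",
    reference=None,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> DensityProfile:
    """Time-averaged number density profile.

    ``reference``: ignored for planar-z (the box provides the cross
    section); a center point (Å) for radial; an (n, 3) array of surface
    atom positions (Å) for nearest-surface. ``bin_width`` and the returned
    bins are nm.
    """
    idx = _selection_indices(trajectory, selection)
    box_nm = trajectory.box * _A2NM
    if mode == "planar-z":
        z = trajectory.frames[:, idx, 2].ravel() * _A2NM
        top = box_nm[2] if box_nm[2] > 0 else z.max() + bin_width
        edges = np.arange(0.0, top + bin_width, bin_width)
        volumes = np.full(len(edges) - 1, box_nm[0] * box_nm[1] * bin_width)
        values = z
    elif mode == "radial":
        center = np.zeros(3) if reference is None else np.asarray(reference, float)
        d = trajectory.frames[:, idx, :] - center
        values = np.linalg.norm(d, axis=2).ravel() * _A2NM
        top = r_max if r_max is not None else values.max() + bin_width
        edges = np.arange(0.0, top + bin_width, bin_width)
        volumes = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    elif mode == "nearest-surface":
        if reference is None:
            raise ValueError("nearest-surface mode needs surface positions")
        surf = np.atleast_2d(np.asarray(reference, dtype=float))
        tree = cKDTree(surf)
        dists = [tree.query(frame[idx])[0] for frame in trajectory.frames]
        values = np.concatenate(dists) * _A2NM
        top = r_max if r_max is not None else values.max() + bin_width
        edges = np.arange(0.0, top + bin_width, bin_width)
        volumes = np.full(len(edges) - 1, bin_width)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    counts, _ = np.histogram(values, bins=edges)
    n_frames = trajectory.n_frames
    density = counts / (n_frames * volumes)
    return DensityProfile(
        mode=mode,
        bins=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        volumes=volumes,
        species=selection if isinstance(selection, str) else None,
        n_mean=float(counts.sum() / n_frames),
        normalization="per-volume" if mode != "nearest-surface" else "per-length",
    )


def _angles_deg(vectors: np.ndarray, refs: np.ndarray) -> np.ndarray:
    v = vectors / np.linalg.norm(vectors, axis=-1, keepdims=True)
    r = refs / np.linalg.norm(refs, axis=-1, keepdims=True)
    return np.rad2deg(np.arccos(np.clip((v * r).sum(axis=-1), -1.0, 1.0)))


def orientation_angles(
    trajectory: Trajectory,
    water_triples: np.ndarray,
    reference="z",
    shell: tuple[float, float] | None = None,
    surface=None,
) -> OrientationSamples:
    """Water dipole (theta) and OH-bond (alpha) angles against a reference
    direction.

    ``water_triples`` is an (m, 3) array of O, H, H atom indices. The
    reference is "z" (slab normal, +z) or ("radial", center_Å), in which
    case each molecule's own outward radial direction is used. The
    molecule distance is to the nearest atom of ``surface`` (Å) when given,
    else the planar z (or radial r) coordinate of the oxygen; ``shell``
    (nm range) filters molecules by that distance.
    """
    triples = np.asarray(water_triples, dtype=int).reshape(-1, 3)
    if triples.size == 0:
        raise ValueError("no water molecules given")
    thetas, alphas, dists = [], [], []
    radial = isinstance(reference, (tuple, list)) and reference[0] == "radial"
    center = np.asarray(reference[1], dtype=float) if radial else None
    tree = cKDTree(np.atleast_2d(surface)) if surface is not None else None
    for frame in trajectory.frames:
        o = frame[triples[:, 0]]
        h1 = frame[triples[:, 1]]
        h2 = frame[triples[:, 2]]
        dipole = 0.5 * (h1 + h2) - o
        if radial:
            ref = o - center
            dist = np.linalg.norm(ref, axis=1) * _A2NM
        else:
            ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(o), 1))
            dist = o[:, 2] * _A2NM
        if tree is not None:
            dist = tree.query(o)[0] * _A2NM
        theta = _angles_deg(dipole, ref)
        a1 = _angles_deg(h1 - o, ref)
        a2 = _angles_deg(h2 - o, ref)
        if shell is not None:
            keep = (dist >= shell[0]) & (dist <= shell[1])
        else:
            keep = np.ones(len(o), dtype=bool)
        thetas.append(theta[keep])
        alphas.append(np.column_stack((a1[keep], a2[keep])).ravel())
        dists.append(dist[keep])
    return OrientationSamples(
        theta_deg=np.concatenate(thetas),
        alpha_deg=np.concatenate(alphas),
        distance_nm=np.concatenate(dists),
    )


def orientation_histogram(
    angles_deg: np.ndarray,
    weighting: str = "raw",
    bin_width: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density over [0°, 180°], normalized to unit integral.

    ``raw`` histograms the angles as sampled (an isotropic ensemble then
    follows sin(theta)); ``sin-corrected`` divides each count by
    sin(theta) before normalizing, which flattens the isotropic baseline.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        raise ValueError("no angle samples")
    if weighting not in ("raw", "sin-corrected"):
        raise ValueError(f"unknown weighting {weighting!r}")
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if weighting == "sin-corrected":
        w = 1.0 / np.maximum(np.sin(np.deg2rad(angles_deg)), 1e-8)
        counts, _ = np.histogram(angles_deg, bins=edges, weights=w)
    else:
        counts, _ = np.histogram(angles_deg, bins=edges)
    density = counts / (counts.sum() * bin_width)
    return centers, density


def pair_rdf(
    trajectory: Trajectory,
    group_a,
    group_b,
    bin_width: float = 0.01,
    r_max: float = 1.0,
    com_a: bool = False,
) -> RDFCurve:
    """Radial distribution function g(r) between two groups with ideal-gas
    normalization in the frame's box.

    ``com_a`` collapses group A to its center of geometry each frame (the
    usual sorbent-COM convention). ``bin_width`` and ``r_max`` are nm. For
    periodic boxes ``r_max`` must stay below half the smallest periodic
    box length.
    """
    ia = _selection_indices(trajectory, group_a)
    ib = _selection_indices(trajectory, group_b)
    box, per = trajectory.box, trajectory.periodic
    r_max_a = r_max / _A2NM
    if per.any():
        half = box[per].min() / 2.0
        if r_max_a > half + 1e-9:
            raise ValueError("r_max exceeds half the smallest periodic box length")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    na_eff = 1 if com_a else len(ia)
    for frame in trajectory.frames:
        a = frame[ia].mean(axis=0, keepdims=True) if com_a else frame[ia]
        b = frame[ib]
        d = minimum_image(a[:, None, :] - b[None, :, :], box, per)
        dist = np.linalg.norm(d, axis=2)
        if not com_a and np.shares_memory(ia, ib) or (
            len(ia) == len(ib) and np.array_equal(ia, ib) and not com_a
        ):
            np.fill_diagonal(dist, np.inf)
        c, _ = np.histogram(dist.ravel() * _A2NM, bins=edges)
        counts += c
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    volume = float(np.prod(box)) * _A2NM**3
    rho_b = len(ib) / volume
    norm = trajectory.n_frames * na_eff * rho_b * shell
    return RDFCurve(
        r=0.5 * (edges[:-1] + edges[1:]),
        g=counts / norm,
        meta={"n_a": na_eff, "n_b": len(ib), "r_max": r_max},
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.concatenate((y[:pad][::-1], y, y[-pad:][::-1]))
    return np.convolve(ypad, kernel, mode="valid")


def first_minimum(profile, window: int = 3) -> float:
    """Location of the first local minimum after the first maximum of a
    density profile or RDF, after light smoothing.

    Accepts a :class:`DensityProfile`, an :class:`RDFCurve`, or an
    (x, y) pair. Raises on profiles with no interior maximum.
    """
    if isinstance(profile, DensityProfile):
        x, y = profile.bins, profile.density
    elif isinstance(profile, RDFCurve):
        x, y = profile.r, profile.g
    else:
        x, y = profile
    y = _smooth(np.asarray(y, dtype=float), window)
    x = np.asarray(x, dtype=float)
    n = len(y)
    i_max = None
    for i in range(1, n - 1):
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            i_max = i
            break
    if i_max is None:
        raise ValueError("profile has no interior maximum")
    for i in range(i_max + 1, n - 1):
        if y[i] < y[i - 1] and y[i] <= y[i + 1]:
            return float(x[i])
    raise ValueError("no local minimum found after the first maximum")
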