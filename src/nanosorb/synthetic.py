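"""Synthetic inputs with known answers.

Everything the pipeline consumes can be generated here without downloads:
single-sorbate systems over a model surface whose exact PMF is prescribed
analytically (the end-to-end oracle for the metadynamics estimators),
orientation ensembles with prescribed axial bias, and layered-fluid
trajectories with a prescribed density profile.

A single global seed fans out to independent per-generator streams via
``numpy`` SeedSequence spawning keyed by a generator tag, so adding a
generator never perturbs existing fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "SquareWellSpec",
    "HarmonicSpec",
    "DoubleWellSpec",
    "Wall93Spec",
    "ToySurfaceSystem",
    "make_toy_surface_system",
    "sample_orientations",
    "layered_fluid_trajectory",
    "two_gaussian_profile",
]

_STREAMS = {"toy-surface": 101, "orientations": 202, "layered-fluid": 303}


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[tag]])


@dataclass(frozen=True)
class SquareWellSpec:
    """Attractive square well of ``depth`` on [s_on, s_off] nm with smooth
    tanh edges (width ``edge``) and a harmonic repulsive core below the
    well so the sorbate cannot reach s = 0."""

    depth: float = 5.0  # kJ/mol
    s_on: float = 0.3  # nm
    s_off: float = 0.6  # nm
    edge: float = 0.01  # nm
    # stiff core: the wall is what makes the well "square"; thermal
    # penetration below s_on stays ~0.01 nm at 300 K
    core_k: float = 2.0e5  # kJ/mol/nm^2

    tag = "square-well"

    def energy(self, s):
        s = np.asarray(s, dtype=float)
        well = -self.depth * 0.25 * (
            (1.0 + np.tanh((s - self.s_on) / self.edge))
            * (1.0 - np.tanh((s - self.s_off) / self.edge))
        )
        core = np.where(s < self.s_on, 0.5 * self.core_k * (self.s_on - s) ** 2, 0.0)
        return well + core

    def force(self, s):
        # -dU/ds, via the analytic derivative of the two terms
        s = np.asarray(s, dtype=float)
        t_on = np.tanh((s - self.s_on) / self.edge)
        t_off = np.tanh((s - self.s_off) / self.edge)
        dwell = -self.depth * 0.25 * (
            (1.0 - t_on**2) / self.edge * (1.0 - t_off)
            - (1.0 + t_on) * (1.0 - t_off**2) / self.edge
        )
        dcore = np.where(s < self.s_on, -self.core_k * (self.s_on - s), 0.0)
        return -(dwell + dcore)


@dataclass(frozen=True)
class HarmonicSpec:
    """U = 1/2 k (s - s_min)^2."""

    k: float = 500.0  # kJ/mol/nm^2
    s_min: float = 0.5  # nm

    tag = "harmonic"

    def energy(self, s):
        return 0.5 * self.k * (np.asarray(s, dtype=float) - self.s_min) ** 2

    def force(self, s):
        return -self.k * (np.asarray(s, dtype=float) - self.s_min)


@dataclass(frozen=True)
class DoubleWellSpec:
    """Quartic double well with wells at center ± half_sep and barrier
    ``height`` between them: U = height ((x^2 - w^2)^2 / w^4), x = s - c."""

    height: float = 5.0  # kJ/mol
    center: float = 0.6  # nm
    half_sep: float = 0.25  # nm

    tag = "double-well"

    def energy(self, s):
        x = np.asarray(s, dtype=float) - self.center
        w2 = self.half_sep**2
        return self.height * (x**2 - w2) ** 2 / w2**2

    def force(self, s):
        x = np.asarray(s, dtype=float) - self.center
        w2 = self.half_sep**2
        return -self.height * 4.0 * x * (x**2 - w2) / w2**2


@dataclass(frozen=True)
class Wall93Spec:
    """9-3 surface wall: U = eps (2/15 (sigma/s)^9 - (sigma/s)^3)."""

    eps: float = 5.0  # kJ/mol
    sigma: float = 0.3  # nm

    tag = "wall-9-3"

    def energy(self, s):
        sr = self.sigma / np.asarray(s, dtype=float)
        return self.eps * ((2.0 / 15.0) * sr**9 - sr**3)

    def force(self, s):
        # -dU/ds
        s = np.asarray(s, dtype=float)
        sr = self.sigma / s
        return self.eps * ((2.0 / 15.0) * 9.0 * sr**9 - 3.0 * sr**3) / s


_POTENTIALS = {
    "square-well": SquareWellSpec,
    "harmonic": HarmonicSpec,
    "double-well": DoubleWellSpec,
    "wall-9-3": Wall93Spec,
}


@dataclass
class ToySurfaceSystem:
    """A 1-2 site sorbate over an implicit planar surface at z = 0.

    The only s-dependent energy is the prescribed external potential acting
    on the center-of-mass height s = z_COM, so the exact PMF along the COM
    CV equals the potential up to an additive constant. Two-site sorbates
    carry a stiff harmonic bond and rotate freely, which makes site-based
    CVs genuinely different from the COM CV while the adsorption free
    energy stays invariant.

    Implements the CV-system protocol of
    :func:`nanosorb.metad.run_metadynamics` (coordinates in nm, masses in
    amu, energies kJ/mol).
    """

    potential: object
    n_sites: int = 1
    site_separation: float = 0.1  # nm
    bond_k: float = 20000.0  # kJ/mol/nm^2
    mass_per_site: float = 40.0  # amu
    cv_mode: str = "com"  # "com" | "site0" | "site1"
    s_start: float = 0.8  # nm
    seed: int = 0
    surface_atoms: np.ndarray = field(
        default_factory=lambda: np.zeros((1, 3))
    )

    def __post_init__(self):
        if self.n_sites not in (1, 2):
            raise ValueError("sorbate must have 1 or 2 sites")
        if self.cv_mode not in ("com", "site0", "site1"):
            raise ValueError(f"unknown CV tag {self.cv_mode!r}")
        if self.cv_mode == "site1" and self.n_sites == 1:
            raise ValueError("site1 CV needs a two-site sorbate")

    @property
    def masses(self) -> np.ndarray:
        return np.full(3 * self.n_sites, self.mass_per_site)

    def initial_coords(self) -> np.ndarray:
        if self.n_sites == 1:
            return np.array([0.0, 0.0, self.s_start])
        h = self.site_separation / 2.0
        return np.array([0.0, 0.0, self.s_start - h, 0.0, 0.0, self.s_start + h])

    def _weights(self) -> np.ndarray:
        return np.full(self.n_sites, 1.0 / self.n_sites)

    def energy_forces(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        z = x[2::3]
        w = self._weights()
        s_com = float(w @ z)
        e = float(self.potential.energy(s_com))
        f = np.zeros_like(x)
        f_ext = float(self.potential.force(s_com))
        f[2::3] += w * f_ext
        if self.n_sites == 2:
            d = x[3:6] - x[0:3]
            r = float(np.linalg.norm(d))
            e += 0.5 * self.bond_k * (r - self.site_separation) ** 2
            fb = -self.bond_k * (r - self.site_separation) * d / r
            f[3:6] += fb
            f[0:3] -= fb
        return e, f

    def cv_value_grad(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        if self.cv_mode == "com":
            w = self._weights()
            g[2::3] = w
            return float(w @ x[2::3]), g
        k = 0 if self.cv_mode == "site0" else 1
        g[3 * k + 2] = 1.0
        return float(x[3 * k + 2]), g

    # protocol alias used by run_metadynamics
    def cv(self, x):
        return self.cv_value_grad(x)

    def exact_pmf(self, s):
        """The prescribed PMF along the COM CV (additive constant free)."""
        return self.potential.energy(s)


def make_toy_surface_system(potential, seed: int = 0, **kwargs) -> ToySurfaceSystem:
    """Build a runnable toy system from a potential spec or tag string.

    Extra keyword arguments go to the potential constructor (when a tag is
    given) or to :class:`ToySurfaceSystem` (n_sites, cv, ...).
    """
    sys_keys = {
        "n_sites", "site_separation", "bond_k", "mass_per_site", "cv_mode", "s_start"
    }
    sys_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in sys_keys}
    if isinstance(potential, str):
        try:
            potential = _POTENTIALS[potential](**kwargs)
        except KeyError:
            raise ValueError(f"unknown potential tag {potential!r}") from None
    elif kwargs:
        raise TypeError(f"unexpected arguments: {sorted(kwargs)}")
    return ToySurfaceSystem(potential=potential, seed=seed, **sys_kwargs)


def sample_orientations(
    kind: str = "isotropic",
    n: int = 1000,
    seed: int = 0,
    mu_deg: float = 65.0,
    concentration: float = 50.0,
) -> np.ndarray:
    """Unit vectors: uniform on the sphere, or with the polar angle
    concentrated around ``mu_deg`` (spread ~ 1/sqrt(concentration) rad)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _rng(seed, "orientations")
    if kind == "isotropic":
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    if kind == "axial-biased":
        theta = np.deg2rad(mu_deg) + rng.normal(size=n) / np.sqrt(concentration)
        theta = np.abs(theta)
        theta = np.where(theta > np.pi, 2 * np.pi - theta, theta)
        phi = rng.uniform(0.0, 2 * np.pi, size=n)
        sin_t = np.sin(theta)
        return np.column_stack(
            (sin_t * np.cos(phi), sin_t * np.sin(phi), np.cos(theta))
        )
    raise ValueError(f"unknown orientation kind {kind!r}")


def two_gaussian_profile(
    centers=(1.0, 2.0), widths=(0.15, 0.25), amplitudes=(2.0, 1.0), baseline: float = 0.2
):
    """A layered-fluid target density rho(z) (arbitrary units, z in nm)."""

    def rho(z):
        z = np.asarray(z, dtype=float)
        out = np.full_like(z, float(baseline))
        for c, w, a in zip(centers, widths, amplitudes):
            out = out + a * np.exp(-0.5 * ((z - c) / w) ** 2)
        return out

    return rho


def layered_fluid_trajectory(
    profile,
    n_frames: int = 20,
    seed: int = 0,
    n_particles: int = 500,
    box_nm=(3.0, 3.0, 6.0),
    species: str = "O",
) -> Trajectory:
    """Ideal particles placed frame-by-frame by inverse-transform sampling
    of a target rho(z), uniform in x and y.

    ``profile`` is a callable rho(z >= 0, nm). Returns a
    :class:`~nanosorb.dynamics.Trajectory` (positions in Å, the package's
    structure unit).
    """
    rng = _rng(seed, "layered-fluid")
    box_nm = np.asarray(box_nm, dtype=float)
    z_grid = np.linspace(0.0, box_nm[2], 2048)
    rho = np.asarray(profile(z_grid), dtype=float)
    if np.any(rho < 0):
        raise ValueError("target density must be non-negative")
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (rho[1:] + rho[:-1]) * np.diff(z_grid))))
    if cdf[-1] <= 0:
        raise ValueError("target profile has zero mass")
    cdf /= cdf[-1]
    frames = np.empty((n_frames, n_particles, 3))
    for k in range(n_frames):
        u = rng.uniform(size=n_particles)
        z = np.interp(u, cdf, z_grid)
        xy = rng.uniform(size=(n_particles, 2)) * box_nm[:2]
        frames[k] = np.column_stack((xy, z)) * 10.0  # nm -> Å
    return Trajectory(
        species=np.array([species] * n_particles, dtype=object),
        times=np.arange(n_frames, dtype=float),
        frames=frames,
        box=box_nm * 10.0,
        periodic=np.array([True, True, False]),
        provenance={"seed": seed, "generator": "layered-fluid"},
    )
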