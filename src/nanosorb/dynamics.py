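"""Desk-scale energy minimization and NVT/NVE molecular dynamics.

The engine exists to exercise the free-energy estimators on small systems,
not to replicate production solvated runs: velocity-Verlet integration with
either a velocity-rescaling thermostat (Berendsen-style scaling with a
coupling time) or Langevin (BAOAB) dynamics, a pair-list cache with skin,
frozen-atom support, and steepest-descent minimization.

Units: positions Å, time ps, energy kJ/mol, mass amu.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import ACC_UNIT, KB, mass_of
from .forcefield import ForceFieldModel
from .structures import NanoStructure, minimum_image, neighbor_pairs

__all__ = [
    "RunConfig",
    "Trajectory",
    "SystemForces",
    "minimize",
    "run_md",
    "rmsd_series",
    "kinetic_temperature",
]

#: Energy above which integration is considered diverged, kJ/mol.
DIVERGENCE_ENERGY = 1.0e6


@dataclass
class RunConfig:
    """MD run parameters. The seed fixes initial velocities and thermostat
    noise and is recorded in the trajectory provenance."""

    timestep_fs: float = 1.0
    temperature: float = 300.0
    thermostat: str | None = "velocity-rescale"  # or "langevin" or None
    tau_t_ps: float = 1.0
    friction_per_ps: float = 10.0
    n_steps: int = 1000
    seed: int = 0
    stride: int = 100
    frozen: np.ndarray | None = None  # boolean mask or index array
    neighbor_every: int = 10
    skin: float = 2.0  # Å

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.thermostat not in (None, "velocity-rescale", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")

    def digest(self) -> str:
        doc = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class Trajectory:
    """Ordered frames with provenance."""

    species: np.ndarray
    times: np.ndarray  # ps
    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    box: np.ndarray
    periodic: np.ndarray
    provenance: dict = field(default_factory=dict)
    energies: list = field(default_factory=list)  # (step, t, epot, ekin, T, ebias)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def save_xyz(self, path) -> None:
        from .fileio import write_xyz

        ref = NanoStructure(
            species=self.species,
            positions=self.frames[0],
            charges=np.zeros(self.n_atoms),
            box=self.box,
            periodic=self.periodic,
        )
        write_xyz(ref, path, frames=list(self.frames), times=self.times)

    def save_frames(self, path) -> None:
        """Compact binary frame stream (self-describing NPZ container)."""
        np.savez_compressed(
            path,
            species=self.species.astype(str),
            times=self.times,
            frames=self.frames.astype(np.float32),
            box=self.box,
            periodic=self.periodic,
            provenance=json.dumps(self.provenance),
        )

    @classmethod
    def load_frames(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                species=z["species"].astype(object),
                times=z["times"],
                frames=z["frames"].astype(float),
                box=z["box"],
                periodic=z["periodic"],
                provenance=json.loads(str(z["provenance"])),
            )

    def save_energies_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.provenance.get('seed')}\n")
            fh.write("step\ttime_ps\te_pot\te_kin\ttemperature\te_bias\n")
            for row in self.energies:
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


class SystemForces:
    """Cached force evaluator for (structure, force field).

    Bond/angle parameter arrays, per-pair LJ/charge tables and the
    exclusion filter are precomputed once; the skin-padded neighbour list
    is rebuilt every ``rebuild_every`` calls. Energies and forces agree
    with :func:`nanosorb.forcefield.evaluate_energy_forces` (the reference
    path) — this class only removes the per-call bookkeeping.
    """

    def __init__(self, structure: NanoStructure, ff: ForceFieldModel,
                 rebuild_every: int = 10, skin: float = 2.0):
        from .forcefield import _pair_lj_tables, exclusion_pairs

        ff.check_species(structure.species)
        self.structure = structure.copy()
        self.ff = ff
        self.rebuild_every = max(1, rebuild_every)
        self.skin = skin
        self._calls = 0
        self._pairs = None
        n = structure.n_atoms
        self._n = n
        excl = exclusion_pairs(structure, ff.exclusion_rule)
        self._excl_codes = np.array(sorted(i * n + j for i, j in excl), dtype=np.int64)
        self._pair_tables = lambda pi, pj: _pair_lj_tables(self.structure, ff, pi, pj)

        species = structure.species.astype(str)
        b = structure.bonds
        self._bond_kb = np.array(
            [ff.bond_params(species[i], species[j]).kb for i, j in b]
        ) if len(b) else np.empty(0)
        self._bond_r0 = np.array(
            [ff.bond_params(species[i], species[j]).r0 for i, j in b]
        ) if len(b) else np.empty(0)
        a = structure.angles
        if len(a):
            params = [ff.angle_params(species[i], species[j], species[k])
                      for i, j, k in a]
            self._angle_kt = np.array([p.k_theta for p in params])
            self._angle_t0 = np.deg2rad([p.theta0 for p in params])
        else:
            self._angle_kt = self._angle_t0 = np.empty(0)

    def _rebuild(self, positions):
        if self.ff.coulomb_scheme == "all-pairs" and not self.structure.periodic.any():
            pi, pj = np.triu_indices(self._n, k=1)
        else:
            pi, pj = neighbor_pairs(
                positions, self.structure.box, self.structure.periodic,
                self.ff.cutoff + self.skin,
            )
        if len(pi) and len(self._excl_codes):
            codes = pi.astype(np.int64) * self._n + pj
            keep = ~np.isin(codes, self._excl_codes, assume_unique=True)
            pi, pj = pi[keep], pj[keep]
        self._pairs = (pi, pj)
        if len(pi):
            self._sigma, self._eps, self._qq = self._pair_tables(pi, pj)
        else:
            self._sigma = self._eps = self._qq = np.empty(0)

    def __call__(self, positions):
        from .forcefield import _nonbonded_terms

        if self._pairs is None or self._calls % self.rebuild_every == 0:
            self._rebuild(positions)
        self._calls += 1
        st = self.structure
        st.positions = positions
        forces = np.zeros_like(positions)
        energy = 0.0

        if len(st.bonds):
            i, j = st.bonds[:, 0], st.bonds[:, 1]
            d = minimum_image(positions[i] - positions[j], st.box, st.periodic)
            r = np.sqrt((d * d).sum(axis=1))
            dr = r - self._bond_r0
            energy += float(0.5 * (self._bond_kb * dr * dr).sum())
            fvec = (-self._bond_kb * dr / r)[:, None] * d
            np.add.at(forces, i, fvec)
            np.add.at(forces, j, -fvec)

        if len(st.angles):
            ai, aj, ak = st.angles[:, 0], st.angles[:, 1], st.angles[:, 2]
            u = minimum_image(positions[ai] - positions[aj], st.box, st.periodic)
            v = minimum_image(positions[ak] - positions[aj], st.box, st.periodic)
            lu = np.sqrt((u * u).sum(axis=1))
            lv = np.sqrt((v * v).sum(axis=1))
            uh, vh = u / lu[:, None], v / lv[:, None]
            cos_t = np.clip((uh * vh).sum(axis=1), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
            dth = theta - self._angle_t0
            energy += float(0.5 * (self._angle_kt * dth * dth).sum())
            coeff = (self._angle_kt * dth / sin_t)[:, None]
            fi = coeff * (vh - cos_t[:, None] * uh) / lu[:, None]
            fk = coeff * (uh - cos_t[:, None] * vh) / lv[:, None]
            np.add.at(forces, ai, fi)
            np.add.at(forces, ak, fk)
            np.add.at(forces, aj, -(fi + fk))

        pi, pj = self._pairs
        if len(pi):
            d = minimum_image(positions[pi] - positions[pj], st.box, st.periodic)
            dist = np.sqrt((d * d).sum(axis=1))
            if self.ff.coulomb_scheme != "all-pairs":
                inside = dist <= self.ff.cutoff
            else:
                inside = slice(None)
            e_lj, f_lj, e_c, f_c = _nonbonded_terms(
                dist[inside], self._sigma[inside], self._eps[inside],
                self._qq[inside], self.ff,
            )
            energy += float(e_lj.sum() + e_c.sum())
            fvec = ((f_lj + f_c) / dist[inside])[:, None] * d[inside]
            np.add.at(forces, pi[inside], fvec)
            np.add.at(forces, pj[inside], -fvec)
        return energy, forces


def _frozen_mask(n: int, frozen) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if frozen is not None:
        frozen = np.asarray(frozen)
        if frozen.dtype == bool:
            mask = frozen.copy()
        elif frozen.size:
            mask[frozen] = True
    return mask


def minimize(
    structure: NanoStructure,
    ff: ForceFieldModel,
    max_steps: int = 4500,
    force_tol: float = 10.0,
    initial_step: float = 0.01,
    frozen=None,
    full_output: bool = False,
):
    """Steepest-descent minimization with an adaptive step.

    The move is along the normalized force direction with a trust-radius
    style step (Å) that grows on accepted moves and shrinks on rejected
    ones; the energy sequence is non-increasing by construction.
    """
    forces_of = SystemForces(structure, ff, rebuild_every=5)
    pos = structure.positions.copy()
    frozen_mask = _frozen_mask(len(pos), frozen)
    e, f = forces_of(pos)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at start of minimization")
    f[frozen_mask] = 0.0
    step = initial_step
    trace = [e]
    for _ in range(max_steps):
        fmax = np.abs(f).max() if len(f) else 0.0
        if fmax < force_tol:
            break
        trial = pos + step * f / fmax
        e_t, f_t = forces_of(trial)
        f_t[frozen_mask] = 0.0
        if np.isfinite(e_t) and e_t < e:
            pos, e, f = trial, e_t, f_t
            step = min(step * 1.2, 0.5)
            trace.append(e)
        else:
            step *= 0.5
            if step < 1e-10:
                break
    out = structure.copy()
    out.positions = pos
    if full_output:
        return out, {
            "energy": e,
            "max_force": float(np.abs(f).max()) if len(f) else 0.0,
            "n_evaluations": forces_of._calls,
            "trace": trace,
        }
    return out


def kinetic_temperature(vel: np.ndarray, masses: np.ndarray, n_dof: int | None = None) -> float:
    """Instantaneous kinetic temperature from velocities (Å/ps)."""
    ekin = 0.5 * np.sum(masses[:, None] * vel**2) / ACC_UNIT
    if n_dof is None:
        n_dof = 3 * len(vel)
    return 2.0 * ekin / (n_dof * KB) if n_dof else 0.0


def run_md(
    structure: NanoStructure,
    ff: ForceFieldModel,
    config: RunConfig,
    bias=None,
    masses: np.ndarray | None = None,
) -> Trajectory:
    """Velocity-Verlet MD with optional thermostat and bias provider.

    ``bias`` is a callable positions -> (energy, forces) whose contribution
    is added to the systematic forces each step (used by metadynamics).
    Identical seed and configuration give bit-identical trajectories.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.timestep_fs * 1e-3  # ps
    n = structure.n_atoms
    if masses is None:
        masses = np.array([mass_of(str(s)) for s in structure.species])
    frozen = _frozen_mask(n, config.frozen if config.frozen is not None else None)
    mobile = ~frozen
    n_dof = 3 * int(mobile.sum())

    pos = structure.positions.copy()
    vel = np.zeros_like(pos)
    if config.temperature > 0 and n_dof:
        sigma_v = np.sqrt(ACC_UNIT * KB * config.temperature / masses)
        vel = rng.normal(size=(n, 3)) * sigma_v[:, None]
        vel[frozen] = 0.0
        # remove net momentum of the mobile atoms
        p = (masses[mobile, None] * vel[mobile]).sum(axis=0)
        vel[mobile] -= p / masses[mobile].sum()

    forces_of = SystemForces(structure, ff,
                             rebuild_every=config.neighbor_every, skin=config.skin)

    def total_forces(x):
        e, f = forces_of(x)
        eb = 0.0
        if bias is not None:
            eb, fb = bias(x)
            f = f + fb
        f[frozen] = 0.0
        return e, eb, f

    e_pot, e_bias, f = total_forces(pos)
    inv_m = (ACC_UNIT / masses)[:, None]
    gamma = config.friction_per_ps
    if config.thermostat == "langevin" and config.temperature >= 0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1**2))
        sigma_v = np.sqrt(ACC_UNIT * KB * config.temperature / masses)

    times, frames, energies = [], [], []

    def record(step, t):
        ekin = 0.5 * np.sum(masses[mobile, None] * vel[mobile] ** 2) / ACC_UNIT
        temp = 2.0 * ekin / (n_dof * KB) if n_dof else 0.0
        energies.append((step, t, e_pot, ekin, temp, e_bias))
        times.append(t)
        frames.append(pos.copy())

    record(0, 0.0)
    for step in range(1, config.n_steps + 1):
        vel[mobile] += 0.5 * dt * f[mobile] * inv_m[mobile]
        if config.thermostat == "langevin":
            pos[mobile] += 0.5 * dt * vel[mobile]
            vel[mobile] = (
                c1 * vel[mobile]
                + c2 * sigma_v[mobile, None] * rng.normal(size=(int(mobile.sum()), 3))
            )
            pos[mobile] += 0.5 * dt * vel[mobile]
        else:
            pos[mobile] += dt * vel[mobile]
        e_pot, e_bias, f = total_forces(pos)
        vel[mobile] += 0.5 * dt * f[mobile] * inv_m[mobile]
        if config.thermostat == "velocity-rescale" and config.temperature > 0:
            temp = kinetic_temperature(vel[mobile], masses[mobile], n_dof)
            if temp > 0:
                lam = np.sqrt(
                    1.0 + (dt / config.tau_t_ps) * (config.temperature / temp - 1.0)
                )
                vel[mobile] *= lam
        if abs(e_pot) > DIVERGENCE_ENERGY:
            raise RuntimeError(
                f"energy diverged at step {step}: E_pot = {e_pot:.3g} kJ/mol"
            )
        if step % config.stride == 0 or step == config.n_steps:
            record(step, step * dt)

    # drop duplicate final frame if stride aligned
    if len(times) > 1 and times[-1] == times[-2]:
        times, frames, energies = times[:-1], frames[:-1], energies[:-1]
    return Trajectory(
        species=structure.species.copy(),
        times=np.array(times),
        frames=np.array(frames),
        box=structure.box.copy(),
        periodic=structure.periodic.copy(),
        provenance={"seed": config.seed, "config_digest": config.digest()},
        energies=energies,
    )


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered ``mobile`` onto ``reference``."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def rmsd_series(
    trajectory: Trajectory, reference: NanoStructure, superpose: bool = True
) -> np.ndarray:
    """Per-frame heavy-atom RMSD (Å) from a reference structure.

    Translation is always removed; with ``superpose`` the optimal rigid
    rotation (Kabsch) is removed as well. Returns an array of
    (time_ps, rmsd) rows.
    """
    if trajectory.n_atoms != reference.n_atoms:
        raise ValueError("atom-count mismatch between trajectory and reference")
    ref = reference.positions - reference.positions.mean(axis=0)
    out = np.empty((trajectory.n_frames, 2))
    for k, frame in enumerate(trajectory.frames):
        mob = frame - frame.mean(axis=0)
        if superpose:
            mob = mob @ _kabsch(mob, ref)
        out[k] = (trajectory.times[k], np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out
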