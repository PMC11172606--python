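"""Seeded Langevin dynamics under cubic periodic boundary conditions.

The integrator is BAOAB with a low friction (default 10 / ps, well below
water's ~50-100 / ps): the implicit solvent exerts little hydrodynamic
drag, so diffusion — and with it conformational sampling and molecular
encounters — is much faster than in explicit solvent.

Positions are integrated unwrapped (molecules stay contiguous); the
minimum-image convention applies inside every nonbonded evaluation, and
saved frames are rigidly re-wrapped per molecule around the CA centroid
so analysis never sees a split molecule.

Determinism contract: a given (system, config, seed) always produces a
bit-identical trajectory, and a checkpoint/restart continues bit-
identically, because the Gaussian noise is consumed as one sequential
stream and force summation order is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .errors import ConfigError, InstabilityError, SingularityError
from .force_field import CompiledSystem, ForceFieldParams, compile_system, preset
from .io_formats import DynState, Trajectory, write_restart

log = logging.getLogger(__name__)

KB = K.KB
F_CONV = K.F_CONV


@dataclass
class SimulationConfig:
    """Run settings; tF is the frame-to-frame simulated time."""

    tf_ps: float = 10.0
    n_frames: int = 1000
    dt_ps: float = 0.01
    temperature_K: float = 300.0
    gamma_ps: float = 10.0
    seed: int = 0
    skin: float = 2.0
    use_neighbor_list: bool = True
    params: ForceFieldParams = field(default_factory=ForceFieldParams)
    use_go: bool = True
    allow_small_tf: bool = False  # testing override of the tF >= 10 ps rule

    def __post_init__(self):
        if self.tf_ps < 10.0 and not self.allow_small_tf:
            raise ConfigError(
                f"tF = {self.tf_ps} ps is below the 10 ps minimum frame spacing")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.temperature_K <= 0:
            raise ConfigError("temperature must be positive")
        if self.dt_ps <= 0:
            raise ConfigError("timestep must be positive")
        spf = self.tf_ps / self.dt_ps
        if abs(spf - round(spf)) > 1e-9:
            raise ConfigError("tF must be an integer multiple of dt")

    @property
    def steps_per_frame(self) -> int:
        return int(round(self.tf_ps / self.dt_ps))


def minimum_image(dx, L: float):
    """Map displacement components into (-L/2, L/2]."""
    dx = np.asarray(dx, dtype=float)
    return dx - L * np.floor(dx / L + 0.5)


def build_neighbor_list(coords, box: float, rc: float, skin: float = 0.0) -> np.ndarray:
    """Cell-list pair search: all i<j pairs within rc + skin under minimum
    image, returned lexicographically sorted."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return np.empty((0, 2), dtype=np.int32)
    cut = rc + skin
    ncell = int(box // cut)
    if ncell < 3:
        # box too small for cells: direct minimum-image search
        d = coords[:, None, :] - coords[None, :, :]
        d -= box * np.floor(d / box + 0.5)
        dist = np.sqrt((d ** 2).sum(axis=2))
        iu = np.triu_indices(n, k=1)
        keep = dist[iu] < cut
        return np.column_stack([iu[0][keep], iu[1][keep]]).astype(np.int32)
    wrapped = coords - box * np.floor(coords / box)
    cell_of = np.minimum((wrapped / (box / ncell)).astype(int), ncell - 1)
    cells: dict = {}
    for i, c in enumerate(map(tuple, cell_of)):
        cells.setdefault(c, []).append(i)
    pairs = []
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    cut2 = cut * cut
    for c, members in cells.items():
        for off in offsets:
            nc = tuple((c[k] + off[k]) % ncell for k in range(3))
            other = cells.get(nc)
            if other is None:
                continue
            for i in members:
                for j in other:
                    if j <= i:
                        continue
                    d = wrapped[i] - wrapped[j]
                    d -= box * np.floor(d / box + 0.5)
                    if d @ d < cut2:
                        pairs.append((i, j))
    if not pairs:
        return np.empty((0, 2), dtype=np.int32)
    arr = np.unique(np.asarray(pairs, dtype=np.int32), axis=0)
    return arr


def minimize(system, params: ForceFieldParams | None = None, max_steps: int = 500,
             f_tol: float = 5.0, step0: float = 0.05, use_go: bool = True):
    """Clamped steepest-descent relaxation of a system's coordinates.

    Removes steric clashes before dynamics (random-coil starting
    structures routinely need this). The displacement per iteration is
    capped; the step grows on success and backtracks on an energy
    increase. Returns a new SystemModel with relaxed coordinates."""
    from .force_field import total_energy_forces

    p = params or ForceFieldParams()
    cs = compile_system(system, p, use_go=use_go)
    pos = np.ascontiguousarray(system.coords, dtype=np.float64).copy()
    e_prev = total_energy_forces(system, p, coords=pos, compiled=cs).total
    step = step0
    for _ in range(max_steps):
        rep = total_energy_forces(system, p, coords=pos, compiled=cs)
        fmax = np.linalg.norm(rep.forces, axis=1).max()
        if fmax < f_tol:
            break
        trial = pos + rep.forces * (step / fmax)
        e_new = total_energy_forces(system, p, coords=trial, compiled=cs).total
        if e_new < e_prev:
            pos = trial
            e_prev = e_new
            step = min(step * 1.2, 0.5)
        else:
            step *= 0.5
            if step < 1e-4:
                break
    out = system.copy()
    out.coords = pos
    return out


class Simulation:
    """Stateful Langevin propagator for a SystemModel.

    ``step(n)`` advances n timesteps; ``run()`` produces the fixed-count
    trajectory. ``state`` snapshots the full dynamic state for
    checkpointing."""

    def __init__(self, system, config: SimulationConfig, state: DynState | None = None):
        if system.box_L is None:
            raise ConfigError("system has no box; use with_box() or replicate_with_offset()")
        self.system = system
        self.config = config
        self.params = config.params
        self.cs: CompiledSystem = compile_system(system, self.params, use_go=config.use_go)
        self._rng = np.random.Generator(np.random.PCG64(config.seed))
        if state is None:
            self.pos = np.ascontiguousarray(system.coords, dtype=np.float64).copy()
            self.vel = self._maxwell_boltzmann()
            self.step_count = 0
            self.time_ps = 0.0
            self.frames_done = 0
        else:
            if state.positions.shape[0] != system.n_particles:
                raise ConfigError(
                    f"restart state has {state.positions.shape[0]} particles, "
                    f"system has {system.n_particles}")
            if state.params.param_hash() != self.params.param_hash():
                log.info("force-field parameters changed on restart (old %s, new %s)",
                         state.params.param_hash(), self.params.param_hash())
            self.pos = state.positions.astype(np.float64).copy()
            self.vel = state.velocities.astype(np.float64).copy()
            self._rng.bit_generator.state = state.rng_state
            self.step_count = state.step
            self.time_ps = state.time_ps
            self.frames_done = state.frames_done
        self.last_energies = None

    def _maxwell_boltzmann(self) -> np.ndarray:
        kT = KB * self.config.temperature_K
        sd = np.sqrt(kT * F_CONV / np.asarray(self.system.masses))
        return self._rng.standard_normal((self.system.n_particles, 3)) * sd[:, None]

    @property
    def state(self) -> DynState:
        return DynState(
            positions=self.pos.copy(),
            velocities=self.vel.copy(),
            rng_state=self._rng.bit_generator.state,
            step=self.step_count,
            time_ps=self.time_ps,
            params=self.params,
            frames_done=self.frames_done,
        )

    def kinetic_temperature(self) -> float:
        ke = 0.5 * (np.asarray(self.system.masses)[:, None] * self.vel ** 2).sum() / F_CONV
        return 2.0 * ke / (3.0 * self.system.n_particles * KB)

    def step(self, n_steps: int = 1) -> float:
        """Advance ``n_steps`` BAOAB steps; returns the mean kinetic
        temperature over the chunk."""
        cfg = self.config
        cs = self.cs
        p = self.params
        noise = self._rng.standard_normal((n_steps, self.system.n_particles, 3))
        c1 = np.exp(-cfg.gamma_ps * cfg.dt_ps)
        out = K._run_chunk(
            self.pos, self.vel, cs.inv_m, noise, cfg.dt_ps, c1,
            KB * cfg.temperature_K, cs.L,
            cs.sigma, cs.eps, cs.dg, p.solv_lambda, p.cutoff, p.switch_width,
            cs.bonds, cs.bond_b0, p.k_bond,
            cs.angles, cs.ang_t0, p.k_angle,
            cs.tors, cs.tor_p0, p.k_torsion,
            cs.dN, cs.dH, cs.dres, cs.dmol, cs.aO, cs.ares, cs.amol,
            p.eps_hb, p.hb_r0, p.hb_switch_start, p.hb_cutoff,
            cs.go_a, cs.go_b, cs.go_r0, cs.go_w, p.eps_go,
            cs.excl, cs.resseq, cs.mol,
            p.w_vdw_short, p.w_vdw_long, p.w_solv_short, p.w_solv_long,
            float(p.delta_short), float(p.delta_long), p.scale_14,
            cfg.skin, cfg.use_neighbor_list)
        eb, ev, es, eh, eg, sum_mvv, err, err_step, err_i, err_j = out
        if err == 1:
            raise SingularityError(
                f"overlapping particles {err_i} and {err_j} at step "
                f"{self.step_count + err_step}")
        if err == 2:
            raise InstabilityError(
                f"particle {err_i} moved more than 2 A in one step at step "
                f"{self.step_count + err_step}",
                step=self.step_count + err_step, particle=err_i)
        self.step_count += n_steps
        self.time_ps += n_steps * cfg.dt_ps
        self.last_energies = {"bonded": eb, "vdw": ev, "solvation": es,
                              "hbond": eh, "go": eg,
                              "total": eb + ev + es + eh + eg}
        return sum_mvv / (n_steps * 3.0 * self.system.n_particles * KB * F_CONV)

    def _frame_coords(self) -> np.ndarray:
        """Unwrapped coordinates, each molecule rigidly shifted so its CA
        centroid lies inside [0, L)."""
        out = self.pos.copy()
        L = self.system.box_L
        ca = np.asarray(self.system.kinds) == 2
        mol = np.asarray(self.system.mol_index)
        for m in range(self.system.n_molecules):
            sel = mol == m
            cent = out[sel & ca].mean(axis=0)
            out[sel] -= L * np.floor(cent / L)
        return out

    def run(self, checkpoint_path=None, progress_csv=None) -> Trajectory:
        """Propagate to the configured frame count (resuming after a
        restart) and return the frames produced by this call."""
        cfg = self.config
        remaining = cfg.n_frames - self.frames_done
        if remaining <= 0:
            raise ConfigError("trajectory already complete")
        n = self.system.n_particles
        frames = np.empty((remaining, n, 3))
        times = np.empty(remaining)
        rows = []
        for fi in range(remaining):
            try:
                temp = self.step(cfg.steps_per_frame)
            except (InstabilityError, SingularityError):
                if checkpoint_path is not None:
                    write_restart(self.state, checkpoint_path)
                raise
            frames[fi] = self._frame_coords()
            self.frames_done += 1
            times[fi] = self.frames_done * cfg.tf_ps
            if checkpoint_path is not None:
                write_restart(self.state, checkpoint_path)
            if progress_csv is not None:
                e = self.last_energies
                rows.append((self.frames_done, self.step_count, self.time_ps,
                             e["bonded"], e["vdw"], e["solvation"], e["hbond"],
                             e["go"], e["total"], temp))
        if progress_csv is not None:
            import pandas as pd

            pd.DataFrame(rows, columns=["frame", "step", "time_ps", "e_bonded",
                                        "e_vdw", "e_solvation", "e_hbond", "e_go",
                                        "e_total", "temperature_K"]
                         ).to_csv(progress_csv, index=False)
        traj = Trajectory(
            coords=frames,
            times=times,
            box=float(self.system.box_L),
            kinds=np.asarray(self.system.kinds, dtype=np.int8),
            res_index=np.asarray(self.system.res_index, dtype=np.int32),
            mol_index=np.asarray(self.system.mol_index, dtype=np.int32),
            masses=np.asarray(self.system.masses, dtype=np.float64),
            metadata={
                "seed": cfg.seed,
                "preset": self.params.preset_name,
                "param_hash": self.params.param_hash(),
                "tf_ps": cfg.tf_ps,
                "dt_ps": cfg.dt_ps,
                "n_frames": cfg.n_frames,
                "temperature_K": cfg.temperature_K,
                "gamma_ps": cfg.gamma_ps,
            },
            final_state=self.state,
        )
        return traj


def langevin_step(sim: Simulation) -> Simulation:
    """One BAOAB update (thin wrapper over Simulation.step)."""
    sim.step(1)
    return sim


def run(system, config: SimulationConfig, checkpoint_path=None,
        progress_csv=None) -> Trajectory:
    """Run a complete fixed-frame-count trajectory from fresh velocities."""
    return Simulation(system, config).run(checkpoint_path=checkpoint_path,
                                          progress_csv=progress_csv)


def continue_run(system, config: SimulationConfig, state: DynState,
                 checkpoint_path=None, progress_csv=None) -> Trajectory:
    """Resume from a checkpoint state; with unchanged parameters and RNG
    state the continuation is bit-identical to an uninterrupted run."""
    return Simulation(system, config, state=state).run(
        checkpoint_path=checkpoint_path, progress_csv=progress_csv)
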