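"""Langevin dynamics and the binding-simulation protocol.

Integration uses a BAOAB splitting of the Langevin equation with unit
bead masses and reduced units: the thermostat temperature is given in
reduced units and converted to kcal/mol through the force field's
energy unit (k_BT = T · ε₀).  The working temperature of 0.3 keeps
folded proteins fluctuating about their native state while a strand
explores the surface.  A binding campaign places the free strand
at one of six axis-symmetric positions 35–40 Å from the protein and runs
many independently seeded replicas per placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .forcefield import System, _eval_kernel, _pair_subset, total_energy_and_forces
from .geometry import rotation_matrix

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "langevin_step",
    "run_trajectory",
    "place_ligand",
    "run_binding_campaign",
]

MAX_STEP_DISPLACEMENT = 2.0  # Å; larger single-step moves signal instability


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling protocol parameters (reduced units)."""

    temperature: float = 0.3        # reduced units; k_BT = temperature * energy_unit
    dt: float = 0.005
    n_steps: int = 10_000_000
    save_interval: int = 1000
    friction: float = 1.0
    seed: int = 0
    salt_mM: float = 10.0
    eps_r: float = 70.0
    n_placements: int = 6
    replicas_per_placement: int = 100
    placement_distance: tuple = (35.0, 40.0)
    analysis_fraction: float = 0.2  # final fraction of frames used in analysis

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.n_steps % self.save_interval:
            raise ValueError("n_steps must be a multiple of save_interval")


@dataclass
class Trajectory:
    """Saved frames plus the per-frame energy breakdown."""

    frames: np.ndarray          # (n_frames, n_beads, 3)
    energies: np.ndarray        # (n_frames, 8) component array
    config: SimulationConfig
    seed: int
    placement: int = -1
    start_state: str = "unbound"   # "unbound" or "bound"
    stable: bool = True

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def analysis_mask(self) -> np.ndarray:
        """Boolean mask selecting the final equilibrated fraction of frames."""
        mask = np.zeros(self.n_frames, dtype=bool)
        n_keep = int(round(self.n_frames * self.config.analysis_fraction))
        if n_keep:
            mask[-n_keep:] = True
        return mask


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------

_VERLET_SKIN = 2.0  # Å; repulsion neighbor-list skin


@njit(cache=True, fastmath=True)
def _run_kernel(x, v, bonds, bond_b0, bond_k, angles, angle_t0, angle_k,
                dihedrals, dihedral_phi0, dihedral_k, dihedral_form,
                pairs, pair_kind, pair_a, pair_k, pair_zone,
                dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut,
                dt, kT, gamma, n_steps, save_every, seed, max_disp):
    """BAOAB loop with a Verlet neighbor list over the repulsion pairs.

    The list keeps every repulsion pair within cutoff + skin of the
    positions at its last rebuild and is refreshed as soon as any bead
    has moved half a skin, so evaluated forces are identical to the
    full pair loop (pairs beyond cutoff contribute exactly zero).
    """
    np.random.seed(seed)
    n = x.shape[0]
    n_save = n_steps // save_every
    frames = np.empty((n_save, n, 3))
    frame_comps = np.empty((n_save, 8))
    forces = np.zeros((n, 3))
    comps = np.zeros(8)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    half = 0.5 * dt

    m = pairs.shape[0]
    # static pairs (wells, electrostatics) are always evaluated; the
    # repulsion pairs go through the neighbor list
    n_static = 0
    for p in range(m):
        if pair_kind[p] != 4:
            n_static += 1
    static_idx = np.empty(n_static, dtype=np.int64)
    rep_idx = np.empty(m - n_static, dtype=np.int64)
    a = b = 0
    for p in range(m):
        if pair_kind[p] != 4:
            static_idx[a] = p; a += 1
        else:
            rep_idx[b] = p; b += 1
    n_rep = m - n_static
    active = np.empty(n_rep, dtype=np.int64)
    x_ref = x.copy()
    half_skin2 = (0.5 * _VERLET_SKIN) ** 2

    def _rebuild():
        cnt = 0
        for q in range(n_rep):
            p = rep_idx[q]
            i, j = pairs[p, 0], pairs[p, 1]
            rl = rep_cut * pair_a[p] + _VERLET_SKIN
            dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
            if dx * dx + dy * dy + dz * dz < rl * rl:
                active[cnt] = p; cnt += 1
        return cnt

    n_active = _rebuild()
    forces[:] = 0.0
    comps[:] = 0.0
    _eval_kernel(x, bonds, bond_b0, bond_k, angles, angle_t0, angle_k,
                 dihedrals, dihedral_phi0, dihedral_k, dihedral_form,
                 pairs[:0], pair_kind[:0], pair_a[:0], pair_k[:0], pair_zone[:0],
                 dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut,
                 -1, forces, comps)
    _pair_subset(x, pairs, pair_kind, pair_a, pair_k, static_idx, n_static,
                 dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut, forces, comps)
    _pair_subset(x, pairs, pair_kind, pair_a, pair_k, active, n_active,
                 dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut, forces, comps)

    isave = 0
    max_disp2 = max_disp * max_disp
    for step in range(1, n_steps + 1):
        noise = np.random.standard_normal((n, 3))
        for i in range(n):
            dx0 = x[i, 0]; dy0 = x[i, 1]; dz0 = x[i, 2]
            v[i, 0] += half * forces[i, 0]
            v[i, 1] += half * forces[i, 1]
            v[i, 2] += half * forces[i, 2]
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
            v[i, 0] = c1 * v[i, 0] + c2 * noise[i, 0]
            v[i, 1] = c1 * v[i, 1] + c2 * noise[i, 1]
            v[i, 2] = c1 * v[i, 2] + c2 * noise[i, 2]
            x[i, 0] += half * v[i, 0]
            x[i, 1] += half * v[i, 1]
            x[i, 2] += half * v[i, 2]
            ddx = x[i, 0] - dx0; ddy = x[i, 1] - dy0; ddz = x[i, 2] - dz0
            if ddx * ddx + ddy * ddy + ddz * ddz > max_disp2:
                return frames[:isave], frame_comps[:isave], False

        # refresh the neighbor list once any bead moved half a skin
        need = False
        for i in range(n):
            dx = x[i, 0] - x_ref[i, 0]
            dy = x[i, 1] - x_ref[i, 1]
            dz = x[i, 2] - x_ref[i, 2]
            if dx * dx + dy * dy + dz * dz > half_skin2:
                need = True
                break
        if need:
            n_active = _rebuild()
            x_ref[:] = x

        forces[:] = 0.0
        comps[:] = 0.0
        _eval_kernel(x, bonds, bond_b0, bond_k, angles, angle_t0, angle_k,
                     dihedrals, dihedral_phi0, dihedral_k, dihedral_form,
                     pairs[:0], pair_kind[:0], pair_a[:0], pair_k[:0], pair_zone[:0],
                     dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut,
                     -1, forces, comps)
        _pair_subset(x, pairs, pair_kind, pair_a, pair_k, static_idx, n_static,
                     dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut, forces, comps)
        _pair_subset(x, pairs, pair_kind, pair_a, pair_k, active, n_active,
                     dh_pref, dh_kappa, dh_cutoff, lj_cut, rep_cut, forces, comps)
        for i in range(n):
            v[i, 0] += half * forces[i, 0]
            v[i, 1] += half * forces[i, 1]
            v[i, 2] += half * forces[i, 2]
        if step % save_every == 0:
            frames[isave] = x
            frame_comps[isave] = comps
            isave += 1
    return frames, frame_comps, True


def langevin_step(coords, velocities, system: System, config: SimulationConfig,
                  rng: np.random.Generator):
    """One BAOAB update; returns new (coords, velocities).

    Deterministic given the generator state.  Raises on a per-bead
    displacement larger than 2 Å (advice: reduce the time step).
    """
    x = np.array(coords, dtype=float)
    v = np.array(velocities, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite state")
    _, f = total_energy_and_forces(x, system)
    dt, gamma = config.dt, config.friction
    kT = config.temperature * system.energy_unit
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    x0 = x.copy()
    v = v + 0.5 * dt * f
    x = x + 0.5 * dt * v
    v = c1 * v + c2 * rng.standard_normal(x.shape)
    x = x + 0.5 * dt * v
    disp = np.linalg.norm(x - x0, axis=1)
    if np.any(disp > MAX_STEP_DISPLACEMENT):
        raise RuntimeError(
            f"instability: bead moved {disp.max():.2f} Å in one step; reduce dt"
        )
    _, f = total_energy_and_forces(x, system)
    v = v + 0.5 * dt * f
    return x, v


def randomize_strand(system: System, seed: int, pivot_prob: float = 0.5,
                     min_clearance: float = 6.0, max_attempts: int = 200) -> np.ndarray:
    """Coil-randomized strand coordinates for over-dispersed starts.

    Applies random pivot rotations about backbone S–P bonds to the
    template conformation (bond lengths and angles are untouched; only
    dihedrals change) and rejects self-clashing results.  Free-strand
    equilibrium averages do not depend on the start, but chains begun
    extended versus coil-randomized approach equilibrium from opposite
    sides, so mixing both start types cancels most initialization bias
    when global relaxation is slow.
    """
    if system.na is None or system.n_protein_beads:
        raise ValueError("randomize_strand expects a free-strand system")
    rng = np.random.default_rng(seed)
    n_nt = system.na.n_nucleotides
    nt = system.na.beads.resids
    nonadj = np.abs(nt[:, None].astype(int) - nt[None, :].astype(int)) >= 2
    best = system.coords0.copy()
    for _ in range(max_attempts):
        y = system.coords0.copy()
        for k in range(1, n_nt - 1):
            if rng.random() > pivot_prob:
                continue
            i, j = 3 * k + 1, 3 * (k + 1)  # S_k - P_{k+1} bond
            rot = rotation_matrix(y[j] - y[i], rng.uniform(-np.pi, np.pi))
            y[j:] = (y[j:] - y[j]) @ rot.T + y[j]
        d = np.linalg.norm(y[:, None, :] - y[None, :, :], axis=2)
        if d[nonadj].min() > min_clearance:
            return y
        best = y
    log.warning("randomize_strand: no clash-free coil in %d attempts", max_attempts)
    return best


def run_trajectory(system: System, config: SimulationConfig,
                   coords0: np.ndarray = None, seed: int = None,
                   placement: int = -1, start_state: str = "unbound") -> Trajectory:
    """Integrate one replica and return its saved frames.

    Velocities are drawn from the Maxwell–Boltzmann distribution at the
    configured temperature; identical (system, config, seed) inputs give
    bitwise-identical trajectories.
    """
    seed = config.seed if seed is None else seed
    x = np.array(system.coords0 if coords0 is None else coords0, dtype=float)
    kT = config.temperature * system.energy_unit  # reduced T -> kcal/mol
    rng = np.random.RandomState(np.uint32(seed ^ 0x9E3779B9))
    v = rng.standard_normal(x.shape) * np.sqrt(kT)
    frames, comps, stable = _run_kernel(
        x, v, *system.kernel_args(x)[1:],
        config.dt, kT, config.friction,
        config.n_steps, config.save_interval, np.uint32(seed),
        MAX_STEP_DISPLACEMENT,
    )
    if not stable:
        log.warning("replica seed=%s unstable after %d frames", seed, len(frames))
    return Trajectory(frames=frames, energies=comps, config=config, seed=seed,
                      placement=placement, start_state=start_state, stable=stable)


# ---------------------------------------------------------------------------
# Binding protocol
# ---------------------------------------------------------------------------

def _principal_axes(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(centered.T @ centered)
    return vecs.T[::-1]  # rows: major, middle, minor axis


def placement_directions(protein_coords: np.ndarray) -> np.ndarray:
    """Six unit vectors: ± the protein's three principal axes."""
    axes = _principal_axes(protein_coords)
    return np.vstack([axes, -axes])[[0, 3, 1, 4, 2, 5]]


def place_ligand(system: System, placement_index: int,
                 rng: np.random.Generator = None,
                 distance_range: tuple = (35.0, 40.0)) -> np.ndarray:
    """Initial coordinates with the strand placed around the protein.

    The strand keeps its extended (template) conformation and is centered
    along one of six axis-symmetric directions from the protein center so
    that the minimum protein–strand bead distance falls inside
    ``distance_range``.
    """
    if not 0 <= placement_index < 6:
        raise ValueError("placement_index must be in [0, 6)")
    if system.n_protein_beads == 0 or system.na is None:
        raise ValueError("system must contain protein and strand")
    rng = rng or np.random.default_rng(0)
    prot = system.coords0[: system.n_protein_beads]
    strand = system.na.beads.xyz
    direction = placement_directions(prot)[placement_index]

    # random strand orientation, reproducible through rng
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    rot = rotation_matrix(axis, rng.uniform(0, 2 * np.pi))
    s = (strand - strand.mean(axis=0)) @ rot.T

    center = prot.mean(axis=0)
    lo, hi = distance_range
    target = 0.5 * (lo + hi)
    # bracket the offset at which the minimum inter-bead distance hits target
    for d in np.arange(target, target + 300.0, 1.0):
        pos = s + center + d * direction
        dmin = np.min(np.linalg.norm(prot[:, None, :] - pos[None, :, :], axis=2))
        if lo <= dmin <= hi:
            return np.vstack([prot, pos])
        if dmin > hi:
            # step back with finer resolution
            for dd in np.arange(d - 1.0, d, 0.05):
                pos = s + center + dd * direction
                dmin = np.min(np.linalg.norm(prot[:, None, :] - pos[None, :, :], axis=2))
                if lo <= dmin <= hi:
                    return np.vstack([prot, pos])
            break
    raise RuntimeError("could not satisfy the placement distance window")


def run_binding_campaign(system: System, config: SimulationConfig,
                         start_state: str = "unbound") -> list:
    """Run n_placements × replicas independently seeded trajectories.

    Unstable replicas are kept in the returned list but flagged
    ``stable=False`` so analyses can exclude them.  Starting bound skips
    the placement step and begins from the native pose.
    """
    trajectories = []
    seed_root = np.random.SeedSequence(config.seed)
    placements = range(config.n_placements) if start_state == "unbound" else [-1]
    replica_seeds = seed_root.generate_state(
        len(list(placements)) * config.replicas_per_placement
    ) % (2 ** 31)
    placements = range(config.n_placements) if start_state == "unbound" else [-1]
    i = 0
    for placement in placements:
        for _ in range(config.replicas_per_placement):
            seed = int(replica_seeds[i]); i += 1
            if start_state == "unbound":
                rng = np.random.default_rng(seed)
                coords0 = place_ligand(system, placement, rng,
                                       config.placement_distance)
            else:
                coords0 = system.coords0
            traj = run_trajectory(system, config, coords0=coords0, seed=seed,
                                  placement=placement, start_state=start_state)
            log.info("replica placement=%s seed=%s stable=%s frames=%d",
                     placement, seed, traj.stable, traj.n_frames)
            trajectories.append(traj)
    return trajectories
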