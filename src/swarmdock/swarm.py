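"""Particle swarm docking search with Solis–Wets local refinement.

Each particle is a point in a 7 + N_r + N_l dimensional space: the ligand
centre-of-mass translation (3), an angle/axis orientation (1 + 3, converted
to a unit quaternion when a pose is decoded) and one deformation coefficient
per receptor and ligand normal mode. The receptor stays fixed at the origin;
conformational change is a linear combination of Cartesian-frame elastic
network modes.

The velocity update is

    v ← w v + c1 r1 (p_i − ξ) + c2 r2 (p_n,i − ξ) + r3 (p_rand − ξ)

with r1, r2, r3 ~ U(0,1) per particle per iteration, p_i the particle's best,
p_n,i the best within its ring neighbourhood and p_rand a uniformly chosen
other particle. Velocities are clamped per dimension class (5 Å translation,
0.2 rad angle, 0.5 Å quaternion spatial terms, mode coefficients unclamped).
At every iteration the swarm-best particle takes one adaptive Solis–Wets
local-search step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .energy import EnergyEvaluator, TypedStructure
from .enm import ModeSet
from .structure import Structure


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm parameters; defaults follow the published docking setup except
    where noted in the docstrings."""

    population: int = 350
    neighbourhood_k: int = 114       # ring neighbours per particle
    c1: float = 2.05                 # cognitive weight
    c2: float = 2.05                 # social weight
    #: Inertial weight: not published; 0.7298 is the standard
    #: constriction-equivalent value for c1 = c2 = 2.05.
    inertia: float = 0.7298
    v_max_translation: float = 5.0   # Å per iteration
    v_max_angle: float = 0.2         # rad
    v_max_axis: float = 0.5          # quaternion spatial terms
    init_sigma_translation: float = 10.0
    init_sigma_modes: float = 3.0
    #: Iteration count is not published; 300 is the package default.
    iterations: int = 300
    repeats: int = 4
    stagnation_window: int | None = None   # stop early if no improvement
    #: Solis-Wets trials applied to the swarm-best particle per iteration.
    local_search_steps: int = 1
    #: Polish the returned best pose with a full Solis-Wets descent, the
    #: package's stand-in for post-docking force-field minimisation.
    final_local_search: bool = True
    final_local_search_max_steps: int = 3000
    final_local_search_restarts: int = 3
    #: Optional soft harmonic penalty weight on mode coefficients
    #: (weight · λ_j · β_j²); off by default.
    mode_penalty_weight: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.neighbourhood_k < self.population:
            raise ValueError("need 0 < neighbourhood_k < population")


@dataclass
class SearchSpace:
    """Dimension bookkeeping for the 7 + N_r + N_l search vector."""

    n_receptor_modes: int
    n_ligand_modes: int

    @property
    def dim(self) -> int:
        return 7 + self.n_receptor_modes + self.n_ligand_modes

    @property
    def translation(self) -> slice:
        return slice(0, 3)

    @property
    def angle(self) -> int:
        return 3

    @property
    def axis(self) -> slice:
        return slice(4, 7)

    @property
    def receptor_modes(self) -> slice:
        return slice(7, 7 + self.n_receptor_modes)

    @property
    def ligand_modes(self) -> slice:
        return slice(7 + self.n_receptor_modes, self.dim)

    def v_max_vector(self, cfg: SwarmConfig) -> np.ndarray:
        v = np.full(self.dim, np.inf)
        v[self.translation] = cfg.v_max_translation
        v[self.angle] = cfg.v_max_angle
        v[self.axis] = cfg.v_max_axis
        return v

    def local_search_sigmas(self) -> np.ndarray:
        """Initial Solis–Wets step sizes per dimension class."""
        rho = np.empty(self.dim)
        rho[self.translation] = 0.5
        rho[self.angle] = np.deg2rad(5.0)
        rho[self.axis] = 0.25
        rho[self.receptor_modes] = 0.15
        rho[self.ligand_modes] = 0.15
        return rho

    def normalise(self, x: np.ndarray) -> np.ndarray:
        """Renormalise the orientation axis to unit length (in place)."""
        norm = np.linalg.norm(x[self.axis])
        if norm > 1e-12:
            x[self.axis] /= norm
        else:
            x[self.axis] = (0.0, 0.0, 1.0)
        return x


class DockingProblem:
    """Binds typed structures, mode sets and the energy model into a single
    objective: decode a search vector to a pose, score it."""

    def __init__(self, receptor: TypedStructure, ligand: TypedStructure,
                 modes_receptor: ModeSet | None, modes_ligand: ModeSet | None,
                 n_receptor_modes: int = 0, n_ligand_modes: int = 0,
                 mode_penalty_weight: float = 0.0):
        if n_receptor_modes and (modes_receptor is None or
                                 modes_receptor.n_modes < n_receptor_modes):
            raise ValueError("not enough receptor modes")
        if n_ligand_modes and (modes_ligand is None or
                               modes_ligand.n_modes < n_ligand_modes):
            raise ValueError("not enough ligand modes")
        self.receptor, self.ligand = receptor, ligand
        self.space = SearchSpace(n_receptor_modes, n_ligand_modes)
        self.modes_r = (modes_receptor.cartesian_modes[:, :n_receptor_modes]
                        if n_receptor_modes else None)
        self.modes_l = (modes_ligand.cartesian_modes[:, :n_ligand_modes]
                        if n_ligand_modes else None)
        self.eigvals_r = (modes_receptor.eigenvalues[:n_receptor_modes]
                          if n_receptor_modes else np.zeros(0))
        self.eigvals_l = (modes_ligand.eigenvalues[:n_ligand_modes]
                          if n_ligand_modes else np.zeros(0))
        self.evaluator = EnergyEvaluator(receptor, ligand)
        self.lig_masses = ligand.structure.masses
        self.mode_penalty_weight = mode_penalty_weight

    def decode(self, x: np.ndarray):
        """Search vector → (receptor coords, ligand coords)."""
        sp = self.space
        if len(x) != sp.dim:
            raise ValueError(f"search vector has {len(x)} dims, "
                             f"expected {sp.dim}")
        rec = self.receptor.coords
        if self.modes_r is not None:
            rec = rec + (self.modes_r @ x[sp.receptor_modes]).reshape(-1, 3)
        lig = self.ligand.coords
        if self.modes_l is not None:
            lig = lig + (self.modes_l @ x[sp.ligand_modes]).reshape(-1, 3)
        axis = np.array(x[sp.axis], dtype=float)
        norm = np.linalg.norm(axis)
        axis = axis / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        rot = Rotation.from_rotvec(x[sp.angle] * axis)
        com = np.average(lig, axis=0, weights=self.lig_masses)
        lig = rot.apply(lig - com) + x[sp.translation]
        return rec, lig

    def energy(self, x: np.ndarray) -> float:
        rec, lig = self.decode(x)
        e = self.evaluator(rec, lig)
        if self.mode_penalty_weight:
            sp = self.space
            e += self.mode_penalty_weight * (
                self.eigvals_r @ x[sp.receptor_modes] ** 2
                + self.eigvals_l @ x[sp.ligand_modes] ** 2)
        return e

    def decode_batch(self, X: np.ndarray):
        """Vectorised decode of a (P, dim) stack of search vectors."""
        sp = self.space
        P = X.shape[0]
        rec = np.broadcast_to(self.receptor.coords,
                              (P,) + self.receptor.coords.shape).copy()
        if self.modes_r is not None:
            rec += (X[:, sp.receptor_modes] @ self.modes_r.T).reshape(P, -1, 3)
        lig = np.broadcast_to(self.ligand.coords,
                              (P,) + self.ligand.coords.shape).copy()
        if self.modes_l is not None:
            lig += (X[:, sp.ligand_modes] @ self.modes_l.T).reshape(P, -1, 3)
        axes = X[:, sp.axis].copy()
        norms = np.linalg.norm(axes, axis=1)
        bad = norms < 1e-12
        axes[bad] = (0.0, 0.0, 1.0)
        norms[bad] = 1.0
        rotvecs = axes / norms[:, None] * X[:, sp.angle, None]
        mats = Rotation.from_rotvec(rotvecs).as_matrix()
        w = self.lig_masses / self.lig_masses.sum()
        com = np.einsum("a,pai->pi", w, lig)
        lig = np.einsum("pij,paj->pai", mats, lig - com[:, None, :]) \
            + X[:, None, sp.translation]
        return rec, lig

    def energy_batch(self, X: np.ndarray) -> np.ndarray:
        rec, lig = self.decode_batch(np.atleast_2d(X))
        e = self.evaluator.batch(rec, lig)
        if self.mode_penalty_weight:
            sp = self.space
            e = e + self.mode_penalty_weight * (
                X[:, sp.receptor_modes] ** 2 @ self.eigvals_r
                + X[:, sp.ligand_modes] ** 2 @ self.eigvals_l)
        return e


def generate_start_points(receptor: Structure, ligand: Structure,
                          n: int = 120, margin: float = 3.0) -> np.ndarray:
    """Quasi-uniform start positions on a sphere enclosing both partners.

    A deterministic Fibonacci lattice on the sphere centred at the receptor
    mass centre, radius = receptor bounding radius + ligand bounding radius +
    margin. ``n = 1`` degenerates to the +z pole.
    """
    if n < 1:
        raise ValueError("need at least one start point")
    centre = receptor.mass_center()
    radius = receptor.bounding_radius() + ligand.bounding_radius() + margin
    if n == 1:
        return centre + radius * np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))   # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return centre + radius * pts


def filter_start_points(points: np.ndarray, reference: np.ndarray,
                        n_keep: int = 10) -> np.ndarray:
    """Local-docking helper: keep the ``n_keep`` points nearest a reference
    location (e.g. a known or predicted binding-site centroid)."""
    d = np.linalg.norm(points - np.asarray(reference, float), axis=1)
    return points[np.argsort(d)[:n_keep]]


@dataclass
class Swarm:
    positions: np.ndarray        # (P, D)
    velocities: np.ndarray       # (P, D)
    energies: np.ndarray         # (P,)
    pbest_positions: np.ndarray  # (P, D)
    pbest_energies: np.ndarray   # (P,)


def initialize_swarm(problem: DockingProblem, start: np.ndarray,
                     cfg: SwarmConfig, rng: np.random.Generator) -> Swarm:
    """Seeded swarm: translations ~ N(start, σ=10 Å), orientations uniform on
    SO(3), mode coefficients ~ N(0, σ=3), zero velocities."""
    sp = problem.space
    P = cfg.population
    pos = np.zeros((P, sp.dim))
    pos[:, sp.translation] = start + rng.normal(
        0.0, cfg.init_sigma_translation, size=(P, 3))
    rotvec = Rotation.random(P, rng=rng).as_rotvec()
    angles = np.linalg.norm(rotvec, axis=1)
    axes = np.where(angles[:, None] > 1e-12,
                    rotvec / np.maximum(angles, 1e-12)[:, None],
                    [0.0, 0.0, 1.0])
    pos[:, sp.angle] = angles
    pos[:, sp.axis] = axes
    n_modes = sp.n_receptor_modes + sp.n_ligand_modes
    if n_modes:
        pos[:, 7:] = rng.normal(0.0, cfg.init_sigma_modes, size=(P, n_modes))
    energies = problem.energy_batch(pos)
    return Swarm(positions=pos, velocities=np.zeros((P, sp.dim)),
                 energies=energies, pbest_positions=pos.copy(),
                 pbest_energies=energies.copy())


def ring_neighbourhoods(population: int, k: int) -> np.ndarray:
    """Index array (P, k): the k array-adjacent particles of each particle,
    split as evenly as possible on either side, with wraparound."""
    left = k // 2
    right = k - left
    offsets = np.concatenate([np.arange(-left, 0), np.arange(1, right + 1)])
    idx = (np.arange(population)[:, None] + offsets[None, :]) % population
    return idx


def update_velocity(position, velocity, pbest, neighbourhood_best,
                    random_particle, cfg: SwarmConfig,
                    rng: np.random.Generator, r=None):
    """One velocity update (unclamped). Works on a single particle or on a
    stacked (P, D) array; ``r`` fixes (r1, r2, r3) for testing."""
    position = np.atleast_2d(position)
    if r is None:
        r = rng.uniform(size=(3, position.shape[0]))
    r1, r2, r3 = (np.atleast_1d(np.asarray(ri, float))[:, None] for ri in r)
    v = (cfg.inertia * np.atleast_2d(velocity)
         + cfg.c1 * r1 * (np.atleast_2d(pbest) - position)
         + cfg.c2 * r2 * (np.atleast_2d(neighbourhood_best) - position)
         + r3 * (np.atleast_2d(random_particle) - position))
    return v[0] if v.shape[0] == 1 and np.ndim(velocity) == 1 else v


def clamp_velocity(velocity: np.ndarray, cfg: SwarmConfig,
                   space: SearchSpace) -> np.ndarray:
    """Symmetric per-class clamping; mode coefficients are never clamped."""
    vmax = space.v_max_vector(cfg)
    return np.clip(velocity, -vmax, vmax)


@dataclass
class LocalSearchState:
    """Adaptive state of the Solis–Wets search."""

    bias: np.ndarray
    rho: np.ndarray
    success_count: int = 0
    fail_count: int = 0
    consecutive_contractions: int = 0
    terminated: bool = False

    @classmethod
    def initial(cls, space: SearchSpace) -> "LocalSearchState":
        return cls(bias=np.zeros(space.dim), rho=space.local_search_sigmas())


def solis_wets_step(x: np.ndarray, energy: float, state: LocalSearchState,
                    energy_fn, rng: np.random.Generator):
    """One Solis–Wets trial: sample d ~ N(bias, diag ρ²), try x+d then x−d.

    Success updates the bias (0.6 b + 0.4 d, sign-matched), increments the
    success counter and zeroes the fail counter; a double failure halves the
    bias and increments the fail counter. Five straight successes double ρ;
    five straight failures halve it (one *contraction*). The state terminates
    after 5 consecutive contractions; expansions reset that count.
    """
    d = rng.normal(state.bias, state.rho)
    new_x, new_e = x, energy
    e_plus = energy_fn(x + d)
    if e_plus < energy:
        new_x, new_e = x + d, e_plus
        state.bias = 0.6 * state.bias + 0.4 * d
        state.success_count += 1
        state.fail_count = 0
    else:
        e_minus = energy_fn(x - d)
        if e_minus < energy:
            new_x, new_e = x - d, e_minus
            state.bias = 0.6 * state.bias - 0.4 * d
            state.success_count += 1
            state.fail_count = 0
        else:
            state.bias = state.bias / 2.0
            state.fail_count += 1
            state.success_count = 0
    if state.success_count >= 5:
        state.rho = state.rho * 2.0
        state.success_count = 0
        state.consecutive_contractions = 0
    elif state.fail_count >= 5:
        state.rho = state.rho / 2.0
        state.fail_count = 0
        state.consecutive_contractions += 1
        if state.consecutive_contractions >= 5:
            state.terminated = True
    return new_x, new_e, state


@dataclass
class DockingRun:
    """Outcome of one swarm run from one start point."""

    best_position: np.ndarray
    best_energy: float
    receptor_coords: np.ndarray
    ligand_coords: np.ndarray
    start_point: np.ndarray
    seed: int
    trace: list = field(default_factory=list)   # (best energy, swarm spread)


def _run_single(problem: DockingProblem, start: np.ndarray, cfg: SwarmConfig,
                seed: int) -> DockingRun:
    rng = np.random.default_rng(seed)
    sp = problem.space
    swarm = initialize_swarm(problem, start, cfg, rng)
    neigh = ring_neighbourhoods(cfg.population, cfg.neighbourhood_k)
    gbest_i = int(np.argmin(swarm.pbest_energies))
    gbest_x = swarm.pbest_positions[gbest_i].copy()
    gbest_e = float(swarm.pbest_energies[gbest_i])
    sw_state = LocalSearchState.initial(sp)
    trace = []
    stagnant = 0
    for _ in range(cfg.iterations):
        # Solis-Wets refinement of the swarm-best particle
        improved = False
        for _ in range(cfg.local_search_steps):
            if sw_state.terminated:
                sw_state = LocalSearchState.initial(sp)
            i = int(np.argmin(swarm.pbest_energies))
            x, e, sw_state = solis_wets_step(
                swarm.pbest_positions[i], swarm.pbest_energies[i],
                sw_state, problem.energy, rng)
            improved = improved or e < gbest_e - 1e-12
            if e < swarm.pbest_energies[i]:
                swarm.pbest_positions[i] = x
                swarm.pbest_energies[i] = e
        # neighbourhood bests from personal bests
        nb = neigh[np.arange(cfg.population),
                   np.argmin(swarm.pbest_energies[neigh], axis=1)]
        nbest = swarm.pbest_positions[nb]
        # random attractor, excluding self
        shift = rng.integers(1, cfg.population, size=cfg.population)
        prand_idx = (np.arange(cfg.population) + shift) % cfg.population
        prand = swarm.positions[prand_idx]
        v = update_velocity(swarm.positions, swarm.velocities,
                            swarm.pbest_positions, nbest, prand, cfg, rng)
        swarm.velocities = clamp_velocity(v, cfg, sp)
        swarm.positions = swarm.positions + swarm.velocities
        for row in swarm.positions:
            sp.normalise(row)
        swarm.energies = problem.energy_batch(swarm.positions)
        better = swarm.energies < swarm.pbest_energies
        swarm.pbest_positions[better] = swarm.positions[better]
        swarm.pbest_energies[better] = swarm.energies[better]
        i = int(np.argmin(swarm.pbest_energies))
        if swarm.pbest_energies[i] < gbest_e - 1e-12:
            improved = True
        if swarm.pbest_energies[i] < gbest_e:
            gbest_e = float(swarm.pbest_energies[i])
            gbest_x = swarm.pbest_positions[i].copy()
        spread = float(np.mean(pdist(swarm.positions[:, sp.translation]))) \
            if cfg.population > 1 else 0.0
        trace.append((gbest_e, spread))
        stagnant = 0 if improved else stagnant + 1
        if cfg.stagnation_window and stagnant >= cfg.stagnation_window:
            break
    if cfg.final_local_search:
        for _restart in range(cfg.final_local_search_restarts):
            state = LocalSearchState.initial(sp)
            for _ in range(cfg.final_local_search_max_steps):
                gbest_x, gbest_e, state = solis_wets_step(
                    gbest_x, gbest_e, state, problem.energy, rng)
                if state.terminated:
                    break
    rec, lig = problem.decode(gbest_x)
    return DockingRun(best_position=gbest_x, best_energy=gbest_e,
                      receptor_coords=rec, ligand_coords=lig,
                      start_point=np.asarray(start, float), seed=seed,
                      trace=trace)


def save_runs(runs, directory, ligand_template: Structure | None = None) -> None:
    """Write docking results: a JSON summary plus the decoded ligand poses
    as a multi-model PDB (when a template structure supplies atom metadata).
    """
    import json
    from pathlib import Path

    from .structure import merge_structures, write_structure  # noqa: F401

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary = [{
        "seed": int(r.seed),
        "best_energy": float(r.best_energy),
        "start_point": [float(v) for v in r.start_point],
        "best_position": [float(v) for v in r.best_position],
        "trace_best_energy": [float(t[0]) for t in r.trace],
        "trace_swarm_spread": [float(t[1]) for t in r.trace],
    } for r in runs]
    (directory / "runs.json").write_text(json.dumps(summary, indent=1))
    if ligand_template is not None:
        import biotite.structure as bst
        from biotite.structure.io.pdb import PDBFile

        from .structure import write_structure as _w  # reuse annotations
        arrays = []
        for r in runs:
            single = ligand_template.with_coords(r.ligand_coords)
            arr = bst.AtomArray(single.n_atoms)
            arr.coord = single.coords.astype(np.float32)
            arr.set_annotation("atom_name", single.names)
            arr.set_annotation("element", single.elements)
            arr.set_annotation("res_name", single.res_names)
            arr.set_annotation("chain_id", single.chain_ids)
            arr.set_annotation("res_id", single.res_seqnums)
            arr.set_annotation("hetero", single.is_hetero)
            arrays.append(arr)
        stack = bst.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(directory / "poses.pdb"))


def run_docking(problem: DockingProblem, start_points: np.ndarray,
                cfg: SwarmConfig | None = None, seed: int = 0) -> list[DockingRun]:
    """Full docking: ``cfg.repeats`` independent swarms from every start
    point; returns one best pose per run. Deterministic for a given seed."""
    cfg = cfg or SwarmConfig()
    runs = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(start_points) * cfg.repeats)
    k = 0
    for start in np.atleast_2d(start_points):
        for _ in range(cfg.repeats):
            child_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            runs.append(_run_single(problem, start, cfg, child_seed))
            k += 1
    return runs
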