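"""Dissipative particle dynamics (DPD) simulator of a sticky block copolymer
near an attractive surface, with block-level structural analysis.

The model represents chromatin as a bead-and-spring copolymer whose blocks
alternate "inactive" beads (non-acetylated nucleosomes, able to form
reversible saturating bonds with each other and with a wall of immobile
surface particles mimicking the nuclear lamina) and "active" beads
(acetylated nucleosomes, inert).  All particles interact through the
standard Groot-Warren DPD triplet: soft conservative repulsion
``a*(1 - r/r_cut)``, pairwise friction ``-gamma*w(r)^2*(v_rel . r_hat)`` and
a matched random force, with ``sigma^2 = 2*gamma*kT`` (fluctuation-
dissipation).  Reversible bonds are re-evaluated every ``check_interval``
steps: existing bonds break with probability ``p_break``; each unbonded
inactive bead picks one random eligible neighbour within ``r_cut`` and bonds
with probability ``p_bond_pp`` (another inactive bead) or ``p_bond_ps``
(surface particle), never exceeding one reversible bond per inactive bead.

Analysis follows the block level: a block is a LAD when at least one of its
beads touches the surface; per block we count surface and intra-block
contacts and derive gyration-tensor shape/volume measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = [
    "SimParams",
    "PolymerSystem",
    "BlockSummary",
    "init_system",
    "dpd_step",
    "bond_update",
    "run_simulation",
    "kinetic_temperature",
    "block_summary",
    "ensemble_distance_map",
    "gyration_eigenvalues",
]

SOLVENT, INACTIVE, ACTIVE, SURFACE = 0, 1, 2, 3
_SQRT3 = math.sqrt(3.0)


@dataclass
class SimParams:
    """DPD simulation parameters (all in reduced DPD units).

    Defaults follow the production-scale chromatin model: a 50x50x50 box at
    number density 3 (375,000 particles), a copolymer of 64 blocks of 500
    inactive + 50 active beads, bond probabilities 0.001 (inactive-inactive)
    / 0.007 (inactive-surface) / 0.01 (break), re-checked every 200 steps,
    10 independent runs.  Force-field constants are the conventional
    Groot-Warren choices.
    """

    box: tuple[float, float, float] = (50.0, 50.0, 50.0)
    density: float = 3.0
    n_blocks: int = 64
    inactive_per_block: int = 500
    active_per_block: int = 50
    p_bond_pp: float = 0.001
    p_bond_ps: float = 0.007
    p_break: float = 0.01
    check_interval: int = 200
    dt: float = 0.04
    a_ij: float = 25.0
    friction_gamma: float = 4.5
    kT: float = 1.0
    r_cut: float = 1.0
    spring_k: float = 4.0
    n_steps: int = 200_000
    snapshot_interval: int = 10_000
    n_runs: int = 10
    seed: int = 0
    with_wall: bool = True
    with_solvent: bool = True
    wall_spacing: float = 0.7
    # upper z bound for the initial chain walk; None = full box. Starting the
    # chain near the surface shortens attachment equilibration.
    chain_init_zmax: float = None  # type: ignore[assignment]

    @property
    def noise_sigma(self) -> float:
        # fluctuation-dissipation: sigma^2 = 2*gamma*kT
        return math.sqrt(2.0 * self.friction_gamma * self.kT)

    @property
    def n_total(self) -> int:
        return int(round(self.density * self.box[0] * self.box[1] * self.box[2]))

    @property
    def chain_length(self) -> int:
        return self.n_blocks * (self.inactive_per_block + self.active_per_block)


@dataclass
class PolymerSystem:
    """Mutable simulation state.

    ``rev_partner[i]`` is the index bonded to inactive bead ``i`` (-1 when
    unbonded); for bead-bead bonds both ends point at each other, for
    bead-surface bonds only the bead side is recorded (a surface particle may
    anchor several beads).
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    block_id: np.ndarray
    backbone: np.ndarray  # (n_bonds, 2) chain connectivity
    rev_partner: np.ndarray
    params: SimParams
    step: int = 0
    forces: np.ndarray = None  # type: ignore[assignment]
    rng_state: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.forces is None:
            self.forces = np.zeros_like(self.positions)
        if self.rng_state is None:
            self.rng_state = np.array([88172645463325252], dtype=np.uint64)

    @property
    def mobile(self) -> np.ndarray:
        return self.types != SURFACE

    @property
    def chain_index(self) -> np.ndarray:
        return np.flatnonzero((self.types == INACTIVE) | (self.types == ACTIVE))

    def rev_bond_pairs(self) -> np.ndarray:
        """Unique reversible bonds as an (m, 2) index array."""
        out = []
        for i in np.flatnonzero(self.rev_partner >= 0):
            j = self.rev_partner[i]
            if self.types[j] == SURFACE or i < j:
                out.append((i, j))
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    def assert_saturation(self) -> None:
        """Every inactive bead holds at most one reversible bond (by design)."""
        holders = self.rev_partner >= 0
        assert not holders[self.types != INACTIVE].any()
        pp = holders & (self.types[np.maximum(self.rev_partner, 0)] == INACTIVE)
        for i in np.flatnonzero(pp):
            assert self.rev_partner[self.rev_partner[i]] == i


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _hex_wall(box, spacing: float) -> np.ndarray:
    """Hexagonal monolayer of surface particles on the z=0 face."""
    lx, ly, _ = box
    nx = max(1, int(round(lx / spacing)))
    dy = spacing * math.sqrt(3.0) / 2.0
    ny = max(1, int(round(ly / dy)))
    dx, dy = lx / nx, ly / ny
    pts = []
    for iy in range(ny):
        xoff = 0.5 * dx if iy % 2 else 0.0
        for ix in range(nx):
            pts.append(((ix * dx + xoff) % lx, iy * dy, 0.0))
    return np.array(pts)


def _place_chain(n: int, box, rng, *, zlo: float, zhi: float | None = None,
                 step: float = 0.7) -> np.ndarray:
    """Random walk with soft self-avoidance (retry if too close to recent beads)."""
    lx, ly, lz = box
    lz = min(zhi, lz) if zhi is not None else lz
    pos = np.empty((n, 3))
    pos[0] = [rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(zlo + 1, lz - 1)]
    for k in range(1, n):
        for _ in range(30):
            d = rng.normal(size=3)
            d *= step / np.linalg.norm(d)
            cand = pos[k - 1] + d
            cand[0] %= lx
            cand[1] %= ly
            if not (zlo + 0.5 < cand[2] < lz - 0.5):
                continue
            recent = pos[max(0, k - 30) : k]
            dr = recent - cand
            dr[:, 0] -= lx * np.round(dr[:, 0] / lx)
            dr[:, 1] -= ly * np.round(dr[:, 1] / ly)
            if (np.einsum("ij,ij->i", dr, dr) > 0.16).all():
                break
        pos[k] = cand
    return pos


def init_system(params: SimParams, rng: np.random.Generator | None = None) -> PolymerSystem:
    """Build wall, copolymer chain and solvent; draw thermal velocities.

    The total particle count equals ``density * box volume`` (chain + wall +
    solvent); the chain is laid down as a self-avoiding random walk of
    alternating inactive/active blocks above the wall.
    """
    rng = rng or np.random.default_rng(params.seed)
    lx, ly, lz = params.box
    wall = _hex_wall(params.box, params.wall_spacing) if params.with_wall else np.empty((0, 3))
    n_chain = params.chain_length
    n_solvent = params.n_total - n_chain - len(wall) if params.with_solvent else 0
    if n_solvent < 0:
        raise ValueError("box too small for chain at the requested density")
    if n_chain > 0 and lz < 4:
        raise ValueError("box too small for chain placement")

    chain = (
        _place_chain(n_chain, params.box, rng, zlo=0.0, zhi=params.chain_init_zmax)
        if n_chain
        else np.empty((0, 3))
    )
    solvent = np.column_stack(
        [
            rng.uniform(0, lx, n_solvent),
            rng.uniform(0, ly, n_solvent),
            rng.uniform(0.05, lz - 0.05, n_solvent),
        ]
    )
    positions = np.concatenate([chain, solvent, wall], axis=0)

    types = np.empty(len(positions), dtype=np.int8)
    block_id = np.full(len(positions), -1, dtype=np.int32)
    per_block = params.inactive_per_block + params.active_per_block
    for b in range(params.n_blocks):
        s = b * per_block
        types[s : s + params.inactive_per_block] = INACTIVE
        types[s + params.inactive_per_block : s + per_block] = ACTIVE
        block_id[s : s + per_block] = b
    types[n_chain : n_chain + n_solvent] = SOLVENT
    types[n_chain + n_solvent :] = SURFACE

    velocities = rng.normal(0.0, math.sqrt(params.kT), size=(len(positions), 3))
    velocities[types == SURFACE] = 0.0
    mob = types != SURFACE
    if mob.any():
        velocities[mob] -= velocities[mob].mean(axis=0)

    backbone = (
        np.column_stack([np.arange(n_chain - 1), np.arange(1, n_chain)])
        if n_chain > 1
        else np.empty((0, 2), dtype=np.int64)
    ).astype(np.int64)
    rev_partner = np.full(len(positions), -1, dtype=np.int64)
    state = np.array([rng.integers(1, 2**63, dtype=np.uint64)], dtype=np.uint64)
    return PolymerSystem(
        positions, velocities, types, block_id, backbone, rev_partner, params,
        rng_state=state,
    )


# ---------------------------------------------------------------------------
# Force kernel and integrator (numba)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_chunk(
    pos, vel, frc, immobile, n_steps,
    lx, ly, lz, pbc_z,
    a_ij, gamma, sigma, rcut, dt, spring_k, bonds, rng_state,
):
    """Integrate ``n_steps`` of DPD velocity-Verlet (lambda = 1/2).

    Periodic in x and y; z is periodic when ``pbc_z`` else a specular
    reflecting slab for every mobile particle.  ``bonds`` holds backbone and
    reversible springs.  Particles are bucket-sorted by cell each step and
    pair forces run over a half stencil of neighbour cells on the sorted
    (cache-contiguous) coordinate arrays.  Returns 1 on instability
    (displacement > r_cut in one step), else 0.
    """
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    rc2 = rcut * rcut
    ncx = max(1, int(lx / rcut))
    ncy = max(1, int(ly / rcut))
    ncz = max(1, int(lz / rcut))
    ncells = ncx * ncy * ncz
    half = 0.5 * dt
    s64 = rng_state[0]

    cell_of = np.empty(n, dtype=np.int64)
    count = np.empty(ncells + 1, dtype=np.int64)
    start = np.empty(ncells + 1, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    sx = np.empty(n)
    sy = np.empty(n)
    sz = np.empty(n)
    svx = np.empty(n)
    svy = np.empty(n)
    svz = np.empty(n)
    sfx = np.empty(n)
    sfy = np.empty(n)
    sfz = np.empty(n)

    # half stencil: self cell handled separately; 13 neighbour offsets
    offs = np.array(
        [
            (1, 0, 0), (-1, 1, 0), (0, 1, 0), (1, 1, 0),
            (-1, -1, 1), (0, -1, 1), (1, -1, 1),
            (-1, 0, 1), (0, 0, 1), (1, 0, 1),
            (-1, 1, 1), (0, 1, 1), (1, 1, 1),
        ],
        dtype=np.int64,
    )

    for _ in range(n_steps):
        # half kick + drift + boundary conditions
        for i in range(n):
            if immobile[i]:
                continue
            vel[i, 0] += half * frc[i, 0]
            vel[i, 1] += half * frc[i, 1]
            vel[i, 2] += half * frc[i, 2]
            dxx = dt * vel[i, 0]
            dyy = dt * vel[i, 1]
            dzz = dt * vel[i, 2]
            if dxx * dxx + dyy * dyy + dzz * dzz > rc2:
                rng_state[0] = s64
                return 1
            pos[i, 0] += dxx
            pos[i, 1] += dyy
            pos[i, 2] += dzz
            if pos[i, 0] < 0.0:
                pos[i, 0] += lx
            elif pos[i, 0] >= lx:
                pos[i, 0] -= lx
            if pos[i, 1] < 0.0:
                pos[i, 1] += ly
            elif pos[i, 1] >= ly:
                pos[i, 1] -= ly
            if pbc_z:
                if pos[i, 2] < 0.0:
                    pos[i, 2] += lz
                elif pos[i, 2] >= lz:
                    pos[i, 2] -= lz
            else:
                if pos[i, 2] < 0.0:
                    pos[i, 2] = -pos[i, 2]
                    vel[i, 2] = -vel[i, 2]
                elif pos[i, 2] > lz:
                    pos[i, 2] = 2.0 * lz - pos[i, 2]
                    vel[i, 2] = -vel[i, 2]

        # counting sort by cell
        for c in range(ncells + 1):
            count[c] = 0
        for i in range(n):
            cx = int(pos[i, 0] * ncx / lx)
            cy = int(pos[i, 1] * ncy / ly)
            cz = int(pos[i, 2] * ncz / lz)
            if cx >= ncx:
                cx = ncx - 1
            elif cx < 0:
                cx = 0
            if cy >= ncy:
                cy = ncy - 1
            elif cy < 0:
                cy = 0
            if cz >= ncz:
                cz = ncz - 1
            elif cz < 0:
                cz = 0
            c = (cz * ncy + cy) * ncx + cx
            cell_of[i] = c
            count[c] += 1
        acc = 0
        for c in range(ncells):
            start[c] = acc
            acc += count[c]
            count[c] = start[c]
        start[ncells] = acc
        for i in range(n):
            k = count[cell_of[i]]
            order[k] = i
            count[cell_of[i]] += 1
        for k in range(n):
            i = order[k]
            sx[k] = pos[i, 0]
            sy[k] = pos[i, 1]
            sz[k] = pos[i, 2]
            svx[k] = vel[i, 0]
            svy[k] = vel[i, 1]
            svz[k] = vel[i, 2]
            sfx[k] = 0.0
            sfy[k] = 0.0
            sfz[k] = 0.0

        # pair forces over sorted arrays
        for cz in range(ncz):
            for cy in range(ncy):
                for cx in range(ncx):
                    c = (cz * ncy + cy) * ncx + cx
                    a0 = start[c]
                    a1 = start[c + 1]
                    # intra-cell pairs
                    for p1 in range(a0, a1):
                        x1 = sx[p1]
                        y1 = sy[p1]
                        z1 = sz[p1]
                        for p2 in range(p1 + 1, a1):
                            rx = x1 - sx[p2]
                            ry = y1 - sy[p2]
                            rz = z1 - sz[p2]
                            r2 = rx * rx + ry * ry + rz * rz
                            if r2 < rc2 and r2 > 1e-12:
                                r = math.sqrt(r2)
                                w = 1.0 - r / rcut
                                inv_r = 1.0 / r
                                ex = rx * inv_r
                                ey = ry * inv_r
                                ez = rz * inv_r
                                rv = (
                                    ex * (svx[p1] - svx[p2])
                                    + ey * (svy[p1] - svy[p2])
                                    + ez * (svz[p1] - svz[p2])
                                )
                                s64 ^= s64 >> np.uint64(12)
                                s64 ^= s64 << np.uint64(25)
                                s64 ^= s64 >> np.uint64(27)
                                u01 = np.float64(s64 * np.uint64(2685821657736338717)) * 5.421010862427522e-20
                                xi = _SQRT3 * (2.0 * u01 - 1.0)
                                fm = (
                                    a_ij * w
                                    - gamma * w * w * rv
                                    + sigma * w * xi * inv_sqrt_dt
                                )
                                sfx[p1] += fm * ex
                                sfy[p1] += fm * ey
                                sfz[p1] += fm * ez
                                sfx[p2] -= fm * ex
                                sfy[p2] -= fm * ey
                                sfz[p2] -= fm * ez
                    # neighbour cells (half stencil)
                    for o in range(13):
                        x2c = cx + offs[o, 0]
                        y2c = cy + offs[o, 1]
                        z2c = cz + offs[o, 2]
                        shx = 0.0
                        shy = 0.0
                        shz = 0.0
                        if x2c < 0:
                            x2c += ncx
                            shx = -lx
                        elif x2c >= ncx:
                            x2c -= ncx
                            shx = lx
                        if y2c < 0:
                            y2c += ncy
                            shy = -ly
                        elif y2c >= ncy:
                            y2c -= ncy
                            shy = ly
                        if z2c < 0 or z2c >= ncz:
                            if not pbc_z:
                                continue
                            if z2c < 0:
                                z2c += ncz
                                shz = -lz
                            else:
                                z2c -= ncz
                                shz = lz
                        c2 = (z2c * ncy + y2c) * ncx + x2c
                        b0 = start[c2]
                        b1 = start[c2 + 1]
                        for p1 in range(a0, a1):
                            x1 = sx[p1]
                            y1 = sy[p1]
                            z1 = sz[p1]
                            for p2 in range(b0, b1):
                                rx = x1 - (sx[p2] + shx)
                                ry = y1 - (sy[p2] + shy)
                                rz = z1 - (sz[p2] + shz)
                                r2 = rx * rx + ry * ry + rz * rz
                                if r2 < rc2 and r2 > 1e-12:
                                    r = math.sqrt(r2)
                                    w = 1.0 - r / rcut
                                    inv_r = 1.0 / r
                                    ex = rx * inv_r
                                    ey = ry * inv_r
                                    ez = rz * inv_r
                                    rv = (
                                        ex * (svx[p1] - svx[p2])
                                        + ey * (svy[p1] - svy[p2])
                                        + ez * (svz[p1] - svz[p2])
                                    )
                                    s64 ^= s64 >> np.uint64(12)
                                    s64 ^= s64 << np.uint64(25)
                                    s64 ^= s64 >> np.uint64(27)
                                    u01 = np.float64(s64 * np.uint64(2685821657736338717)) * 5.421010862427522e-20
                                    xi = _SQRT3 * (2.0 * u01 - 1.0)
                                    fm = (
                                        a_ij * w
                                        - gamma * w * w * rv
                                        + sigma * w * xi * inv_sqrt_dt
                                    )
                                    sfx[p1] += fm * ex
                                    sfy[p1] += fm * ey
                                    sfz[p1] += fm * ez
                                    sfx[p2] -= fm * ex
                                    sfy[p2] -= fm * ey
                                    sfz[p2] -= fm * ez

        # scatter forces back to particle order
        for k in range(n):
            i = order[k]
            frc[i, 0] = sfx[k]
            frc[i, 1] = sfy[k]
            frc[i, 2] = sfz[k]

        # skip immobile-immobile wall self-interaction forces
        # (wall particles never move, their accumulated force is ignored)

        # harmonic springs (zero rest length)
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            if rx > 0.5 * lx:
                rx -= lx
            elif rx < -0.5 * lx:
                rx += lx
            if ry > 0.5 * ly:
                ry -= ly
            elif ry < -0.5 * ly:
                ry += ly
            if pbc_z:
                if rz > 0.5 * lz:
                    rz -= lz
                elif rz < -0.5 * lz:
                    rz += lz
            frc[i, 0] -= spring_k * rx
            frc[i, 1] -= spring_k * ry
            frc[i, 2] -= spring_k * rz
            frc[j, 0] += spring_k * rx
            frc[j, 1] += spring_k * ry
            frc[j, 2] += spring_k * rz

        # second half kick
        for i in range(n):
            if not immobile[i]:
                vel[i, 0] += half * frc[i, 0]
                vel[i, 1] += half * frc[i, 1]
                vel[i, 2] += half * frc[i, 2]
    rng_state[0] = s64
    return 0


def _all_bonds(system: PolymerSystem) -> np.ndarray:
    rev = system.rev_bond_pairs()
    return (
        np.concatenate([system.backbone, rev], axis=0)
        if rev.size
        else system.backbone
    )


def dpd_step(system: PolymerSystem, n_steps: int = 1) -> PolymerSystem:
    """Advance the system ``n_steps`` DPD integration steps in place."""
    p = system.params
    status = _run_chunk(
        system.positions,
        system.velocities,
        system.forces,
        (system.types == SURFACE),
        n_steps,
        p.box[0], p.box[1], p.box[2], not p.with_wall,
        p.a_ij, p.friction_gamma, p.noise_sigma, p.r_cut, p.dt, p.spring_k,
        _all_bonds(system), system.rng_state,
    )
    if status:
        raise RuntimeError(
            "DPD instability: particle moved more than r_cut in one step; reduce dt"
        )
    system.step += n_steps
    return system


def kinetic_temperature(system: PolymerSystem) -> float:
    """Instantaneous kinetic temperature of the mobile particles (m = kB = 1)."""
    v = system.velocities[system.mobile]
    return float((v**2).sum() / (3.0 * len(v)))


# ---------------------------------------------------------------------------
# Reversible bonds
# ---------------------------------------------------------------------------

def bond_update(system: PolymerSystem, rng: np.random.Generator) -> PolymerSystem:
    """One stochastic bond-update sweep (run every ``check_interval`` steps).

    Existing reversible bonds break with probability ``p_break``.  Creation
    attempts then run in randomized order over (i) every eligible
    inactive-inactive pair within ``r_cut`` (both ends unbonded at attempt
    time), each bonding with probability ``p_bond_pp``, and (ii) every
    unbonded inactive bead within ``r_cut`` of the surface plane, which bonds
    to its nearest surface particle with probability ``p_bond_ps``.  Each
    inactive bead holds at most one reversible bond at any time
    (saturation), so earlier successes in a sweep block later attempts.
    """
    p = system.params
    partner = system.rev_partner
    types = system.types

    pairs = system.rev_bond_pairs()
    if len(pairs):
        br = rng.random(len(pairs)) < p.p_break
        for (i, j), b in zip(pairs, br):
            if b:
                partner[i] = -1
                if types[j] == INACTIVE:
                    partner[j] = -1

    inactive = np.flatnonzero(types == INACTIVE)
    if inactive.size == 0:
        return system
    tree = cKDTree(system.positions[inactive])
    pp_pairs = [
        (inactive[a], inactive[b]) for a, b in tree.query_pairs(p.r_cut)
    ]
    surface = np.flatnonzero(types == SURFACE)
    attempts: list[tuple[int, int]] = list(pp_pairs)
    if surface.size and p.with_wall:
        in_zone = inactive[system.positions[inactive, 2] <= p.r_cut]
        attempts.extend((i, -1) for i in in_zone)  # -1 marks a surface attempt
    if not attempts:
        return system
    surf_tree = cKDTree(system.positions[surface]) if surface.size else None
    order = rng.permutation(len(attempts))
    draws = rng.random(len(attempts))
    for k in order:
        i, j = attempts[k]
        if partner[i] >= 0:
            continue
        if j == -1:
            if draws[k] < p.p_bond_ps:
                _, s = surf_tree.query(system.positions[i])
                partner[i] = surface[s]
        elif partner[j] < 0 and draws[k] < p.p_bond_pp:
            partner[i] = j
            partner[j] = i
    return system


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def run_simulation(params: SimParams, *, progress: bool = False) -> list[dict]:
    """Run ``n_runs`` independent trajectories.

    Each run alternates ``check_interval`` DPD steps with one bond-update
    sweep and records a snapshot (positions copy, bond registry, kinetic
    temperature) every ``snapshot_interval`` steps.  Runs use independent
    seeds spawned from ``params.seed`` and are bit-reproducible.
    """
    runs = []
    for r in range(params.n_runs):
        run_seed = int(
            np.random.SeedSequence([params.seed, r]).generate_state(1)[0] % (2**31 - 1)
        )
        rng = np.random.default_rng(run_seed)
        system = init_system(params, rng)
        snapshots = [system.positions.copy()]
        temps = [kinetic_temperature(system)]
        steps_rec = [0]
        n_bonds = [0]
        done = 0
        while done < params.n_steps:
            chunk = min(params.check_interval, params.n_steps - done)
            dpd_step(system, chunk)
            done += chunk
            bond_update(system, rng)
            if done % params.snapshot_interval == 0 or done == params.n_steps:
                snapshots.append(system.positions.copy())
                temps.append(kinetic_temperature(system))
                steps_rec.append(done)
                n_bonds.append(len(system.rev_bond_pairs()))
        runs.append(
            {
                "seed": run_seed,
                "snapshots": snapshots,
                "steps": steps_rec,
                "temperature": temps,
                "n_rev_bonds": n_bonds,
                "system": system,
            }
        )
    return runs


# ---------------------------------------------------------------------------
# Block-level analysis
# ---------------------------------------------------------------------------

def unwrap_chain(positions: np.ndarray, system: PolymerSystem) -> np.ndarray:
    """Unwrap chain coordinates across the periodic x/y images.

    Walks the backbone accumulating minimum-image displacements, so blocks
    straddling a periodic boundary get geometrically contiguous coordinates
    (z is untouched in wall mode, where it is not periodic).
    """
    p = system.params
    chain = system.chain_index
    box = np.array(p.box)
    periodic = np.array([True, True, not p.with_wall])
    xyz = positions[chain].copy()
    d = np.diff(xyz, axis=0)
    for k in range(3):
        if periodic[k]:
            d[:, k] -= box[k] * np.round(d[:, k] / box[k])
    out = np.empty_like(xyz)
    out[0] = xyz[0]
    out[1:] = xyz[0] + np.cumsum(d, axis=0)
    full = positions.copy()
    full[chain] = out
    return full


def gyration_eigenvalues(coords: np.ndarray) -> np.ndarray:
    """Eigenvalues (descending) of the gyration tensor of a particle cloud."""
    c = coords - coords.mean(axis=0)
    g = c.T @ c / len(c)
    return np.sort(np.linalg.eigvalsh(g))[::-1]


@dataclass
class BlockSummary:
    """Structural summary of one inactive block in one snapshot."""

    block: int
    n_surface_contacts: int
    n_intra_contacts: int
    lambda1: float
    lambda2: float
    lambda3: float
    volume_proxy: float
    oblateness: float
    is_lad: bool


def block_summary(
    positions: np.ndarray, system: PolymerSystem
) -> list[BlockSummary]:
    """Per-block surface contacts, intra-block contacts and shape measures.

    Surface contact: an inactive bead within ``r_cut`` of the wall plane.
    Intra-block contacts: unordered bead pairs of the block within ``r_cut``,
    backbone neighbours excluded.  Volume proxy is the equivalent-ellipsoid
    volume ``(4*pi/3) * 3^(3/2) * sqrt(l1*l2*l3)``; oblateness
    ``l3 / sqrt(l1*l2)`` is low for pancake-like clouds.  A block with at
    least one surface contact is a LAD.
    """
    p = system.params
    unwrapped = unwrap_chain(positions, system)
    out = []
    for b in range(p.n_blocks):
        sel = np.flatnonzero((system.block_id == b) & (system.types == INACTIVE))
        xyz = unwrapped[sel]
        n_surf = int((xyz[:, 2] <= p.r_cut).sum()) if p.with_wall else 0
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(p.r_cut)
        # exclude backbone neighbours (consecutive indices within the block)
        n_intra = sum(1 for (u, v) in pairs if abs(sel[u] - sel[v]) != 1)
        lam = gyration_eigenvalues(xyz)
        l1, l2, l3 = lam
        vol = (4.0 * math.pi / 3.0) * (3.0**1.5) * math.sqrt(max(l1 * l2 * l3, 0.0))
        obl = l3 / math.sqrt(l1 * l2) if l1 * l2 > 0 else float("nan")
        out.append(
            BlockSummary(b, n_surf, n_intra, l1, l2, l3, vol, obl, n_surf >= 1)
        )
    return out


def equilibrated_snapshots(run: dict, discard_fraction: float = 0.5) -> list[np.ndarray]:
    """Snapshots after the equilibration phase (first half discarded)."""
    snaps = run["snapshots"]
    k = int(len(snaps) * discard_fraction)
    return snaps[k:] if k < len(snaps) else snaps[-1:]


def ensemble_distance_map(
    runs: list[dict],
    system: PolymerSystem,
    coarse_grain: int = 50,
    discard_fraction: float = 0.5,
) -> np.ndarray:
    """Mean pairwise 3D distance between coarse-grained chain segments.

    The chain is cut into consecutive segments of ``coarse_grain`` beads;
    segment centroids' pairwise distances are averaged over the equilibrated
    snapshots of every run.
    """
    chain = system.chain_index
    n_seg = len(chain) // coarse_grain
    acc = np.zeros((n_seg, n_seg))
    count = 0
    for run in runs:
        for snap in equilibrated_snapshots(run, discard_fraction):
            uw = unwrap_chain(snap, system)
            cent = uw[chain[: n_seg * coarse_grain]].reshape(n_seg, coarse_grain, 3).mean(axis=1)
            d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
            acc += d
            count += 1
    return acc / max(count, 1)


# ---------------------------------------------------------------------------
# Surface-attachment experiment (block compaction vs wall contacts)
# ---------------------------------------------------------------------------

def desk_trend_params(seed: int = 0, *, attractive_surface: bool = True) -> SimParams:
    """Desk-scale configuration for the attachment-compaction experiment.

    A solvent-free melt of six 180+18-bead blocks in an 8x8x12 slab: the
    chain itself provides the crowding of the production-scale system while
    keeping the particle count small enough for workstation runs, and blocks
    of this mass form bond-stabilized globules with tens of surface anchors.
    The chain starts near the wall so attachment states equilibrate within
    the run.  Note that at this scale attached blocks are dominated by
    tethered, partially stretched states rather than fully adsorbed
    pancakes, so the production-scale compaction trends are generally not
    recovered (see the methods note); the function defines the documented
    measurement conditions, not a guaranteed effect.  With
    ``attractive_surface=False`` the surface cannot bind beads (null
    control).
    """
    return SimParams(
        box=(8.0, 8.0, 12.0),
        n_blocks=6,
        inactive_per_block=180,
        active_per_block=18,
        with_solvent=False,
        chain_init_zmax=4.0,
        p_bond_ps=0.007 if attractive_surface else 0.0,
        n_steps=150_000,
        snapshot_interval=5_000,
        n_runs=3,
        seed=seed,
    )


def attachment_trend_stats(runs: list[dict], discard_fraction: float = 0.5) -> dict:
    """Pool block summaries over equilibrated snapshots and score the trends.

    Returns Spearman correlations of surface contacts against intra-block
    contacts and against block volume, the mean oblateness of attached
    (LAD) versus detached blocks, and, for null-control runs, the Spearman
    correlation of block volume against wall distance.
    """
    from scipy import stats as sps

    surf, intra, vol, obl, lad, zmean = [], [], [], [], [], []
    for run in runs:
        system = run["system"]
        inactive_sel = [
            np.flatnonzero((system.block_id == b) & (system.types == INACTIVE))
            for b in range(system.params.n_blocks)
        ]
        for snap in equilibrated_snapshots(run, discard_fraction):
            for b in block_summary(snap, system):
                surf.append(b.n_surface_contacts)
                intra.append(b.n_intra_contacts)
                vol.append(b.volume_proxy)
                obl.append(b.oblateness)
                lad.append(b.is_lad)
                zmean.append(float(snap[inactive_sel[b.block], 2].mean()))
    surf = np.array(surf)
    lad = np.array(lad)
    obl = np.array(obl)
    r_intra = sps.spearmanr(surf, intra)
    r_vol = sps.spearmanr(surf, vol)
    r_z_vol = sps.spearmanr(zmean, vol)
    return {
        "n_block_snapshots": int(len(surf)),
        "attached_fraction": float(lad.mean()),
        "spearman_surface_intra": float(r_intra.statistic),
        "p_surface_intra": float(r_intra.pvalue),
        "spearman_surface_volume": float(r_vol.statistic),
        "p_surface_volume": float(r_vol.pvalue),
        "oblateness_attached": float(obl[lad].mean()) if lad.any() else float("nan"),
        "oblateness_detached": float(obl[~lad].mean()) if (~lad).any() else float("nan"),
        "spearman_zmean_volume": float(r_z_vol.statistic),
        "p_zmean_volume": float(r_z_vol.pvalue),
    }
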