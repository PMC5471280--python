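"""Analytic potentials, an overdamped Langevin sampler, and synthetic structures.

This module is the package's synthetic-data generator.  It stands in for
the atomistic molecular dynamics that produced the free-energy landscapes
being analysed: 2D diffusive dynamics at 298 K on surfaces with two
basins of unequal depth separated by a saddle.  The paired presets
``state_e`` and ``state_plus`` emulate the two protonation states of the
buried histidine that gate which helix-12 conformation is the global
minimum — they differ in which basin is global and in barrier height,
with the landscape scale (barriers of 9 and 7 kcal/mol) matching the
atomistic system these toys replace.

Surfaces are built from C² piecewise-quintic well profiles along the
line joining the minima plus a harmonic transverse term, so minima
depths and the saddle height are *exact by construction* — that is what
makes them usable as oracles for the adaptive-biasing-force estimator
and the landscape integrator.

Dynamics are overdamped (Brownian) Euler–Maruyama: the collective
variables of the real system evolve diffusively on the free-energy
surface, and overdamped dynamics are the simplest faithful model of
that.  The recorded "instantaneous force" is the systematic force
-∇U(x) only (thermal noise excluded), so the bin-conditioned mean force
equals -dA/dξ exactly in expectation — a clean oracle for ABF.

Units: Å, kcal/mol, temperature in K, reduced time with friction γ = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .structio import AtomRecord, Residue, Structure

__all__ = [
    "KB",
    "AnalyticPotential",
    "LangevinParams",
    "Trajectory",
    "harmonic",
    "double_well_1d",
    "two_state_2d",
    "three_state_2d",
    "state_e",
    "state_plus",
    "step",
    "simulate",
    "rotation_about_axis",
    "make_synthetic_helix",
    "make_core_and_helix",
    "transform_structure",
    "drop_residues",
]

KB = 0.0019872041  # Boltzmann constant, kcal/mol/K


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

class AnalyticPotential:
    """A potential with closed-form energy and gradient.

    ``energy(x)`` and ``gradient(x)`` accept a point of shape ``(dim,)``.
    Presets are built by the module-level factory functions.
    """

    def __init__(
        self,
        dim: int,
        energy: Callable[[np.ndarray], float],
        gradient: Callable[[np.ndarray], np.ndarray],
        name: str = "custom",
        meta: dict | None = None,
    ):
        self.dim = dim
        self._energy = energy
        self._gradient = gradient
        self.name = name
        self.meta = meta or {}

    def energy(self, x) -> float:
        return float(self._energy(np.atleast_1d(np.asarray(x, dtype=float))))

    def gradient(self, x) -> np.ndarray:
        return np.asarray(
            self._gradient(np.atleast_1d(np.asarray(x, dtype=float))), dtype=float
        )

    def evaluate(self, x) -> tuple[float, np.ndarray]:
        """Energy and gradient at ``x`` (convenience for samplers)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape != (self.dim,):
            raise ValueError(f"point of dim {x.shape} for a {self.dim}-D potential")
        return self.energy(x), self.gradient(x)


class _QuinticProfile:
    """C² 1-D profile through stationary knots, quadratic beyond the ends.

    Every knot (x_i, E_i) is a stationary point (f' = 0) with prescribed
    curvature f'' = c_i (positive at minima, negative at saddles); each
    inter-knot segment is the unique quintic matching value, slope and
    curvature at both ends.  Outside the knot span the profile continues
    as the parabola E_0 + c_0/2 (x-x_0)^2, so wells at the ends confine.
    """

    def __init__(self, knots: Sequence[tuple[float, float]], curvatures: Sequence[float]):
        if len(knots) < 2:
            raise ValueError("need at least 2 knots")
        self.xs = np.array([k[0] for k in knots], dtype=float)
        self.es = np.array([k[1] for k in knots], dtype=float)
        self.cs = np.array(curvatures, dtype=float)
        if not np.all(np.diff(self.xs) > 0):
            raise ValueError("knot positions must be strictly increasing")
        self.coeffs = []
        for i in range(len(knots) - 1):
            x0, x1 = self.xs[i], self.xs[i + 1]
            h = x1 - x0
            # Quintic in u = (x-x0)/h: 6 conditions on value/slope/curvature.
            A = np.zeros((6, 6))
            b = np.zeros(6)
            for j in range(6):
                A[0, j] = 0.0 ** j if j > 0 else 1.0  # u=0 value
                A[1, j] = 1.0  # u=1 value
                A[2, j] = j * (0.0 ** (j - 1) if j > 1 else (1.0 if j == 1 else 0.0))
                A[3, j] = j  # derivative at u=1 of u^j
                A[4, j] = j * (j - 1) * (1.0 if j == 2 else 0.0)
                A[5, j] = j * (j - 1)
            b[0] = self.es[i]
            b[1] = self.es[i + 1]
            b[2] = 0.0
            b[3] = 0.0
            b[4] = self.cs[i] * h * h
            b[5] = self.cs[i + 1] * h * h
            self.coeffs.append((x0, h, np.linalg.solve(A, b)))

        # Plain-float copies for the scalar fast path used by samplers.
        self._xs = [float(v) for v in self.xs]
        self._es = [float(v) for v in self.es]
        self._cs = [float(v) for v in self.cs]
        self._segs = [
            (float(x0), float(h), tuple(float(v) for v in c))
            for x0, h, c in self.coeffs
        ]

    def __call__(self, s: float) -> float:
        return self.value_slope(s)[0]

    def value_slope(self, s: float) -> tuple[float, float]:
        xs = self._xs
        if s <= xs[0]:
            d = s - xs[0]
            return self._es[0] + 0.5 * self._cs[0] * d * d, self._cs[0] * d
        if s >= xs[-1]:
            d = s - xs[-1]
            return self._es[-1] + 0.5 * self._cs[-1] * d * d, self._cs[-1] * d
        i = len(xs) - 2
        for j in range(1, len(xs)):
            if s < xs[j]:
                i = j - 1
                break
        x0, h, c = self._segs[i]
        u = (s - x0) / h
        v = c[5]
        dv = 5 * c[5]
        v = v * u + c[4]
        dv = dv * u + 4 * c[4]
        v = v * u + c[3]
        dv = dv * u + 3 * c[3]
        v = v * u + c[2]
        dv = dv * u + 2 * c[2]
        v = v * u + c[1]
        dv = dv * u + c[1]
        v = v * u + c[0]
        return v, dv / h


def harmonic(k: float = 1.0, center=0.0, dim: int = 1) -> AnalyticPotential:
    """Isotropic harmonic well U = k/2 |x - c|^2."""
    c = np.broadcast_to(np.atleast_1d(np.asarray(center, dtype=float)), (dim,)).copy()

    def energy(x):
        d = x - c
        return 0.5 * k * float(d @ d)

    def gradient(x):
        return k * (x - c)

    return AnalyticPotential(dim, energy, gradient, name=f"harmonic(k={k})",
                             meta={"k": k, "center": c})


def _default_curvature(e_lo: float, e_hi: float, half_width: float) -> float:
    # Curvature of a parabola climbing (e_hi - e_lo) over half_width.
    return 2.0 * max(e_hi - e_lo, 0.5) / (half_width * half_width)


def _profile_from_knots(knots: Sequence[tuple[float, float]]) -> _QuinticProfile:
    """Alternating min/saddle knots -> profile with auto curvatures."""
    curvatures = []
    xs = [k[0] for k in knots]
    es = [k[1] for k in knots]
    for i in range(len(knots)):
        spans = []
        if i > 0:
            spans.append((abs(es[i] - es[i - 1]), (xs[i] - xs[i - 1]) / 2))
        if i < len(knots) - 1:
            spans.append((abs(es[i + 1] - es[i]), (xs[i + 1] - xs[i]) / 2))
        c = max(_default_curvature(0.0, de, hw) for de, hw in spans)
        curvatures.append(c if i % 2 == 0 else -c)  # even knots = minima
    return _QuinticProfile(knots, curvatures)


def double_well_1d(
    barrier: float = 2.0,
    asymmetry: float = 1.0,
    minima: tuple[float, float] = (3.0, 7.0),
) -> AnalyticPotential:
    """1-D double well: global minimum at ``minima[0]`` (energy 0), second
    minimum at energy ``asymmetry``, saddle of height ``barrier`` midway."""
    x0, x1 = minima
    xm = 0.5 * (x0 + x1)
    profile = _profile_from_knots([(x0, 0.0), (xm, barrier), (x1, asymmetry)])

    def energy(x):
        return profile(float(x[0]))

    def gradient(x):
        return np.array([profile.value_slope(float(x[0]))[1]])

    return AnalyticPotential(
        1, energy, gradient, name="double_well_1d",
        meta={"barrier": barrier, "asymmetry": asymmetry, "minima": minima,
              "saddle_x": xm, "profile": profile},
    )


def _ridge_potential_2d(
    knots_2d: Sequence[tuple[tuple[float, float], float]],
    k_perp: float,
    name: str,
) -> AnalyticPotential:
    """Wells/saddles along the straight line through 2-D knot points.

    ``knots_2d`` alternates minima and saddles as ((x, y), energy); all
    points must be collinear (they are placed on the line through the
    first and last).  Transverse confinement is harmonic with ``k_perp``.
    """
    p_first = np.array(knots_2d[0][0], dtype=float)
    p_last = np.array(knots_2d[-1][0], dtype=float)
    u = p_last - p_first
    length = float(np.linalg.norm(u))
    u /= length
    knots_1d = [(float((np.array(p) - p_first) @ u), e) for p, e in knots_2d]
    profile = _profile_from_knots(knots_1d)

    def energy(x):
        d = x - p_first
        s = float(d @ u)
        t = d - s * u
        return profile(s) + 0.5 * k_perp * float(t @ t)

    def gradient(x):
        d = x - p_first
        s = float(d @ u)
        t = d - s * u
        _, slope = profile.value_slope(s)
        return slope * u + k_perp * t

    # Scalar fast path for tight sampler loops (plain floats, no arrays).
    ox, oy = float(p_first[0]), float(p_first[1])
    ux, uy = float(u[0]), float(u[1])

    def scalar_gradient(x0: float, x1: float) -> tuple[float, float]:
        dx = x0 - ox
        dy = x1 - oy
        s = dx * ux + dy * uy
        tx = dx - s * ux
        ty = dy - s * uy
        slope = profile.value_slope(s)[1]
        return slope * ux + k_perp * tx, slope * uy + k_perp * ty

    meta = {
        "minima": [np.array(p, dtype=float) for p, _ in knots_2d[::2]],
        "minima_energies": [e for _, e in knots_2d[::2]],
        "saddles": [np.array(p, dtype=float) for p, _ in knots_2d[1::2]],
        "saddle_energies": [e for _, e in knots_2d[1::2]],
        "k_perp": k_perp,
        "origin": p_first,
        "axis": u,
        "profile": profile,
    }
    pot = AnalyticPotential(2, energy, gradient, name=name, meta=meta)
    pot.scalar_gradient = scalar_gradient
    return pot


def two_state_2d(
    min_a: tuple[float, float] = (8.75, 4.25),
    min_b: tuple[float, float] = (3.5, 8.0),
    depth_gap: float = 5.0,
    saddle_height: float = 9.0,
    k_perp: float = 2.0,
    name: str = "two_state_2d",
) -> AnalyticPotential:
    """Two-basin 2-D surface: global minimum at ``min_a`` (energy 0), local
    minimum at ``min_b`` (energy ``depth_gap``), saddle of exactly
    ``saddle_height`` midway between them, harmonic transverse walls."""
    pa = np.array(min_a, dtype=float)
    pb = np.array(min_b, dtype=float)
    mid = tuple(0.5 * (pa + pb))
    return _ridge_potential_2d(
        [(tuple(pa), 0.0), (mid, saddle_height), (tuple(pb), depth_gap)],
        k_perp, name,
    )


def three_state_2d(
    min_a: tuple[float, float] = (8.75, 4.25),
    min_i: tuple[float, float] = (6.125, 6.125),
    min_b: tuple[float, float] = (3.5, 8.0),
    energies: tuple[float, float, float] = (0.0, 4.0, 5.0),
    saddles: tuple[float, float] = (6.0, 9.0),
    k_perp: float = 2.0,
) -> AnalyticPotential:
    """Three collinear minima (e.g. two states plus an intermediate)."""
    pa = np.array(min_a, dtype=float)
    pi = np.array(min_i, dtype=float)
    pb = np.array(min_b, dtype=float)
    s1 = tuple(0.5 * (pa + pi))
    s2 = tuple(0.5 * (pi + pb))
    return _ridge_potential_2d(
        [
            (tuple(pa), energies[0]),
            (s1, saddles[0]),
            (tuple(pi), energies[1]),
            (s2, saddles[1]),
            (tuple(pb), energies[2]),
        ],
        k_perp, "three_state_2d",
    )


def state_e(**overrides) -> AnalyticPotential:
    """Neutral-histidine surface: alternative-conformer basin is global.

    Global minimum in the high-RMSD_C / low-RMSD_A corner (alternative
    conformations), local basin at the canonical position 5 kcal/mol up,
    saddle 9 kcal/mol above the global minimum.
    """
    kw = dict(min_a=(8.75, 4.25), min_b=(3.5, 8.0), depth_gap=5.0,
              saddle_height=9.0, name="state_e")
    kw.update(overrides)
    return two_state_2d(**kw)


def state_plus(**overrides) -> AnalyticPotential:
    """Charged-histidine surface: canonical basin global, shallower landscape.

    Global minimum at the canonical position, alternative basin 1 kcal/mol
    up, saddle 7 kcal/mol above the global minimum — the mirror-image
    stability ordering of :func:`state_e` with a lower barrier.
    """
    kw = dict(min_a=(3.5, 8.0), min_b=(9.75, 3.5), depth_gap=1.0,
              saddle_height=7.0, name="state_plus")
    kw.update(overrides)
    return two_state_2d(**kw)


PRESETS: dict[str, Callable[..., AnalyticPotential]] = {
    "harmonic": harmonic,
    "double_well_1d": double_well_1d,
    "two_state_2d": two_state_2d,
    "three_state_2d": three_state_2d,
    "state_e": state_e,
    "state_plus": state_plus,
}


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass
class LangevinParams:
    """Parameters of the overdamped (Brownian) integrator.

    timestep is in reduced time units (friction sets the clock, default
    γ = 1); temperature defaults to 298 K to match the simulations the
    toy replaces.
    """

    timestep: float = 0.02
    friction: float = 1.0
    temperature: float = 298.0
    seed: int = 0
    initial_position: np.ndarray | Sequence[float] = (0.0,)

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        self.initial_position = np.atleast_1d(
            np.asarray(self.initial_position, dtype=float)
        )

    @property
    def kt(self) -> float:
        return KB * self.temperature

    @property
    def noise_sigma(self) -> float:
        return math.sqrt(2.0 * self.kt * self.timestep / self.friction)


@dataclass
class Trajectory:
    """Sampled CV positions with the systematic force recorded at each."""

    positions: np.ndarray  # (n, dim)
    forces: np.ndarray  # (n, dim); -grad U, thermal noise excluded

    def __post_init__(self) -> None:
        if self.positions.shape != self.forces.shape:
            raise ValueError("positions and forces must have equal shapes")

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self, path) -> None:
        dim = self.positions.shape[1]
        header = (
            ["step"]
            + [f"x{i}" for i in range(dim)]
            + [f"f{i}" for i in range(dim)]
        )
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for i, (x, f) in enumerate(zip(self.positions, self.forces)):
                cells = [str(i)] + [f"{v:.6g}" for v in x] + [f"{v:.6g}" for v in f]
                fh.write("\t".join(cells) + "\n")


def step(
    state: np.ndarray,
    p: AnalyticPotential,
    external_force: np.ndarray,
    lp: LangevinParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler–Maruyama update of the overdamped dynamics.

    x += (-∇U + F_ext) dt/γ + sqrt(2 kT dt/γ) ξ, with ξ standard normal
    per dimension.  Deterministic given the generator state.
    """
    x = np.atleast_1d(np.asarray(state, dtype=float))
    force = -p.gradient(x) + np.asarray(external_force, dtype=float)
    new = (
        x
        + force * (lp.timestep / lp.friction)
        + lp.noise_sigma * rng.standard_normal(len(x))
    )
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(
            "non-finite Langevin update; timestep too large for this potential"
        )
    return new


def simulate(
    p: AnalyticPotential,
    lp: LangevinParams,
    n_steps: int,
    force_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    record_every: int = 1,
) -> Trajectory:
    """Run unbiased (or externally forced) dynamics, recording positions
    and the systematic force -∇U at each recorded step."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(lp.seed)
    x = lp.initial_position.astype(float).copy()
    if x.shape != (p.dim,):
        raise ValueError("initial_position dimensionality mismatch")
    dt_over_g = lp.timestep / lp.friction
    sigma = lp.noise_sigma
    positions = []
    forces = []
    chunk = 8192
    noise = rng.standard_normal((chunk, p.dim))
    ni = 0
    for i in range(n_steps):
        sys_force = -p.gradient(x)
        if i % record_every == 0:
            positions.append(x.copy())
            forces.append(sys_force.copy())
        total = sys_force
        if force_fn is not None:
            total = total + force_fn(x)
        if ni == chunk:
            noise = rng.standard_normal((chunk, p.dim))
            ni = 0
        x = x + total * dt_over_g + sigma * noise[ni]
        ni += 1
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite update; timestep too large")
    return Trajectory(np.array(positions), np.array(forces))


# ---------------------------------------------------------------------------
# Synthetic structures
# ---------------------------------------------------------------------------

def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    theta = math.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)


def _atom(serial, name, res_name, chain_id, res_seq, pos, element, hetero=False):
    return AtomRecord(
        serial=serial, name=name, altloc="", res_name=res_name,
        chain_id=chain_id, res_seq=res_seq, i_code="",
        position=np.asarray(pos, dtype=float), occupancy=1.0, b_factor=0.0,
        element=element, is_hetero=hetero,
    )


def make_synthetic_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    chain_id: str = "A",
    start_res: int = 1,
    rotation: np.ndarray | None = None,
    translation=None,
    res_name: str = "ALA",
    pdb_id: str = "SYNH",
) -> Structure:
    """Ideal α-helix with Cα on a regular helix along +z plus dummy
    backbone N/C/O atoms, optionally rigid-transformed.

    Defaults (rise 1.5 Å/residue, 100°/turn, radius 2.3 Å) are the ideal
    α-helix parameters.  The synthetic backbone atoms are small offsets
    from each Cα — geometrically plausible, not stereochemically exact.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    residues: dict[tuple[int, str], Residue] = {}
    serial = 0
    for i in range(n_res):
        ang = math.radians(twist * i)
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), rise * i])
        radial = np.array([math.cos(ang), math.sin(ang), 0.0])
        tangent = np.array([-math.sin(ang), math.cos(ang), 0.0])
        offsets = {
            "N": ca - 0.8 * tangent - 0.5 * np.array([0, 0, 1.0]),
            "CA": ca,
            "C": ca + 0.8 * tangent + 0.5 * np.array([0, 0, 1.0]),
            "O": ca + 0.8 * tangent + 0.5 * np.array([0, 0, 1.0]) + 0.6 * radial,
        }
        res_seq = start_res + i
        res = Residue(res_name, res_seq, "")
        for name in ("N", "CA", "C", "O"):
            serial += 1
            pos = rot @ offsets[name] + trans
            res.atoms[name] = _atom(serial, name, res_name, chain_id, res_seq,
                                    pos, name[0])
        residues[(res_seq, "")] = res
    return Structure(pdb_id=pdb_id, chains={chain_id: residues})


def make_core_and_helix(
    n_core: int = 30,
    helix_start: int = 50,
    n_helix: int = 12,
    helix_rotation: np.ndarray | None = None,
    helix_translation=(12.0, 0.0, 0.0),
    chain_id: str = "A",
    pdb_id: str = "SYNS",
) -> Structure:
    """A rigid 'core' helix (residues 1..n_core) plus a mobile helix placed
    by a rigid transform — the minimal geometry on which region-RMSD and
    displacement-angle metrics are well defined."""
    core = make_synthetic_helix(n_core, chain_id=chain_id, start_res=1,
                                pdb_id=pdb_id)
    mobile = make_synthetic_helix(
        n_helix, chain_id=chain_id, start_res=helix_start,
        rotation=helix_rotation, translation=helix_translation, pdb_id=pdb_id,
    )
    merged = dict(core.chains[chain_id])
    merged.update(mobile.chains[chain_id])
    return Structure(pdb_id=pdb_id, chains={chain_id: merged})


def transform_structure(
    s: Structure,
    rotation: np.ndarray | None = None,
    translation=None,
    res_range: tuple[int, int] | None = None,
) -> Structure:
    """Rigidly transform a structure (or only residues in ``res_range``)."""
    rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    chains: dict[str, dict[tuple[int, str], Residue]] = {}
    for chain_id, residues in s.chains.items():
        new_res: dict[tuple[int, str], Residue] = {}
        for rkey, res in residues.items():
            move = res_range is None or (res_range[0] <= res.res_seq <= res_range[1])
            out = Residue(res.res_name, res.res_seq, res.i_code)
            for name, atom in res.atoms.items():
                pos = rot @ atom.position + trans if move else atom.position
                out.atoms[name] = AtomRecord(
                    serial=atom.serial, name=atom.name, altloc=atom.altloc,
                    res_name=atom.res_name, chain_id=atom.chain_id,
                    res_seq=atom.res_seq, i_code=atom.i_code, position=pos,
                    occupancy=atom.occupancy, b_factor=atom.b_factor,
                    element=atom.element, is_hetero=atom.is_hetero,
                )
            new_res[rkey] = out
        chains[chain_id] = new_res
    return Structure(pdb_id=s.pdb_id, chains=chains, model_index=s.model_index)


def drop_residues(s: Structure, chain_id: str, res_seqs: Sequence[int]) -> Structure:
    """Copy of ``s`` with the given residues removed — emulates a
    crystallographic model with an unresolved loop."""
    drop = set(res_seqs)
    chains = {
        cid: {
            rkey: res
            for rkey, res in residues.items()
            if not (cid == chain_id and res.res_seq in drop)
        }
        for cid, residues in s.chains.items()
    }
    return Structure(pdb_id=s.pdb_id, chains=chains, model_index=s.model_index)
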