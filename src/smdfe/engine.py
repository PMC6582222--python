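"""Desk-scale steered Langevin dynamics on few-atom toy systems.

The engine propagates a handful of point particles interacting through a
pairwise LJ(12-6-1) potential, A/r¹² − B/r⁶ + C·q_i·q_j/r, plus optional
harmonic bonds and angles, with a BAOAB-split Langevin integrator.  A moving
harmonic restraint V(x, t) = ½·k·(ξ(x) − λ(t))² drags a reaction coordinate
ξ — an interatomic distance or a distance difference d(a,b) − d(a,c) — along
a linear schedule λ(t), and the mechanical work W = ∫ (∂V/∂λ)(dλ/dt) dt is
accumulated along the way.  Ensembles of such pulls feed the Jarzynski
estimator.

Units: Å, fs, amu, kcal·mol⁻¹, electron charges.  Nonbonded interactions are
direct sums over all non-bonded pairs — no cutoff, no periodicity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .jarzynski import WorkSample
from .kinetics import R_KCAL, T_DEFAULT

__all__ = [
    "COULOMB_KCAL",
    "ACCEL_CONV",
    "ToySystem",
    "ReactionCoordinate",
    "PullingProtocol",
    "WorkTrajectory",
    "IntegrationError",
    "potential_energy",
    "forces",
    "rc_value_and_gradient",
    "run_pull",
    "run_pull_ensemble",
    "system_from_dict",
    "protocol_from_dict",
]

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻² (AMBER convention).
COULOMB_KCAL = 332.0636
#: (kcal·mol⁻¹·Å⁻¹ per amu) → Å·fs⁻²; converts force/mass to acceleration.
ACCEL_CONV = 4.184e-4

_MIN_R2 = 1e-12


class IntegrationError(RuntimeError):
    """The trajectory blew up; carries the step (and replica) index."""


@dataclass
class ToySystem:
    """A few-atom system: masses/charges, positions, LJ pairs, bonded terms.

    ``lj_pairs`` maps unordered atom-index pairs to (A, B) in
    kcal·Å¹²·mol⁻¹ / kcal·Å⁶·mol⁻¹.  Pairs joined by a bond or an angle
    (1-2 and 1-3 neighbours) are excluded from the nonbonded sum.  Atoms with
    ``fixed`` set never move and feel no net force.
    """

    masses: np.ndarray  # (N,), amu
    charges: np.ndarray  # (N,), e
    positions: np.ndarray  # (N, 3), Å
    lj_pairs: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)  # i, j, k_b, r0
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)  # i, j, k, k_th, th0 (rad)
    fixed: np.ndarray | None = None
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float).ravel()
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.positions = np.array(self.positions, dtype=float).reshape(-1, 3)
        n = self.masses.size
        if self.charges.size != n or self.positions.shape[0] != n:
            raise ValueError("masses, charges and positions disagree on atom count")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be > 0")
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        else:
            self.fixed = np.asarray(self.fixed, dtype=bool).ravel()
            if self.fixed.size != n:
                raise ValueError("fixed mask length mismatch")
        lj: dict[tuple[int, int], tuple[float, float]] = {}
        for (i, j), (A, B) in self.lj_pairs.items():
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid LJ pair ({i}, {j})")
            if A < 0 or B < 0:
                raise ValueError(f"LJ A and B must be >= 0 for pair ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in lj and lj[key] != (A, B):
                raise ValueError(f"conflicting LJ parameters for pair {key}")
            lj[key] = (float(A), float(B))
        self.lj_pairs = lj
        for i, j, *_ in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid bond ({i}, {j})")
        self._build_pair_tables()

    @property
    def n_atoms(self) -> int:
        return int(self.masses.size)

    def _build_pair_tables(self) -> None:
        """Precompute nonbonded pair index/parameter arrays (1-2, 1-3 excluded)."""
        n = self.n_atoms
        excluded = {(min(i, j), max(i, j)) for i, j, *_ in self.bonds}
        for i, j, k, *_ in self.angles:
            excluded.add((min(i, k), max(i, k)))
        pi, pj, A, B, qq = [], [], [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded:
                    continue
                a, b = self.lj_pairs.get((i, j), (0.0, 0.0))
                q = self.charges[i] * self.charges[j]
                if a == 0.0 and b == 0.0 and q == 0.0:
                    continue
                pi.append(i)
                pj.append(j)
                A.append(a)
                B.append(b)
                qq.append(q)
        self._nb_i = np.array(pi, dtype=int)
        self._nb_j = np.array(pj, dtype=int)
        self._nb_A = np.array(A, dtype=float)
        self._nb_B = np.array(B, dtype=float)
        self._nb_qq = np.array(qq, dtype=float)

    # -- energy and forces ---------------------------------------------------

    def energy_forces(self, positions: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        """Potential energy (kcal/mol) and forces −∇U (kcal/mol/Å)."""
        x = self.positions if positions is None else np.asarray(positions, dtype=float)
        U = 0.0
        F = np.zeros_like(x)
        if self._nb_i.size:
            d = x[self._nb_i] - x[self._nb_j]
            r2 = np.einsum("ij,ij->i", d, d)
            if np.any(r2 < _MIN_R2):
                bad = int(np.argmin(r2))
                raise ValueError(
                    f"coincident nonbonded atoms {self._nb_i[bad]} and {self._nb_j[bad]}"
                )
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            r = np.sqrt(r2)
            U += float(
                np.sum(self._nb_A * inv6 * inv6 - self._nb_B * inv6)
                + COULOMB_KCAL * np.sum(self._nb_qq / r)
            )
            # -(dU/dr)/r, so that force on i is coef * (x_i - x_j)
            coef = (12.0 * self._nb_A * inv6 * inv6 - 6.0 * self._nb_B * inv6) * inv2
            coef += COULOMB_KCAL * self._nb_qq * inv2 / r
            fv = coef[:, None] * d
            # few pairs: direct accumulation beats np.add.at
            for k, (i, j) in enumerate(zip(self._nb_i, self._nb_j)):
                F[i] += fv[k]
                F[j] -= fv[k]
        for i, j, kb, r0 in self.bonds:
            d = x[i] - x[j]
            r = math.sqrt(float(d @ d))
            if r < 1e-6:
                raise ValueError(f"coincident bonded atoms {i} and {j}")
            U += kb * (r - r0) ** 2
            fv = (-2.0 * kb * (r - r0) / r) * d
            F[i] += fv
            F[j] -= fv
        for ia, ja, ka, kth, th0 in self.angles:
            U += self._angle_term(x, ia, ja, ka, kth, th0, F)
        return U, F

    @staticmethod
    def _angle_term(x, i, j, k, kth, th0, F) -> float:
        """Harmonic angle k(θ−θ0)² centred on atom j; adds forces into F."""
        a = x[i] - x[j]
        b = x[k] - x[j]
        na = math.sqrt(float(a @ a))
        nb = math.sqrt(float(b @ b))
        cos_t = float(a @ b) / (na * nb)
        cos_t = max(-1.0, min(1.0, cos_t))
        theta = math.acos(cos_t)
        sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
        dU = 2.0 * kth * (theta - th0)
        # dθ/d(x_i) = -(1/sinθ)·(b/(na·nb) - cosθ·a/na²); force = -dU·dθ/dx
        da = (cos_t * a / na - b / nb) / na
        dk = (cos_t * b / nb - a / na) / nb
        Fi = -(dU / sin_t) * da
        Fk = -(dU / sin_t) * dk
        F[i] += Fi
        F[k] += Fk
        F[j] -= Fi + Fk
        return kth * (theta - th0) ** 2


def potential_energy(system: ToySystem, positions: np.ndarray | None = None) -> float:
    """Total potential energy (kcal/mol): LJ(12-6-1) direct sum + bonded terms."""
    return system.energy_forces(positions)[0]


def forces(system: ToySystem, positions: np.ndarray | None = None) -> np.ndarray:
    """Per-atom forces −∇U (kcal/mol/Å); obeys Newton's third law pairwise."""
    return system.energy_forces(positions)[1]


# ---------------------------------------------------------------------------
# Reaction coordinates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionCoordinate:
    """A distance d(a,b) or distance difference d(a,b) − d(a,c), in Å."""

    kind: str  # "distance" | "distance_difference"
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        want = {"distance": 2, "distance_difference": 3}.get(self.kind)
        if want is None:
            raise ValueError(f"unknown reaction-coordinate kind {self.kind!r}")
        if len(self.atoms) != want or len(set(self.atoms)) != want:
            raise ValueError(
                f"{self.kind} coordinate needs {want} distinct atom indices, got {self.atoms}"
            )

    def value(self, positions: np.ndarray) -> float:
        return self.value_and_gradient(positions)[0]

    def value_and_gradient(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(positions, dtype=float)
        grad = np.zeros_like(x)
        if self.kind == "distance":
            a, b = self.atoms
            value = _unit_into(x, a, b, grad, +1.0)
        else:
            a, b, c = self.atoms
            vab = _unit_into(x, a, b, grad, +1.0)
            vac = _unit_into(x, a, c, grad, -1.0)
            value = vab - vac
        return value, grad

    def __call__(self, positions: np.ndarray) -> float:
        return self.value(positions)


def _unit_into(x, a, b, grad, sign) -> float:
    d = x[a] - x[b]
    r = math.sqrt(float(d @ d))
    if r < 1e-9:
        raise ValueError(f"coincident atoms {a} and {b} in reaction coordinate")
    u = d / r
    grad[a] += sign * u
    grad[b] -= sign * u
    return r


def rc_value_and_gradient(
    rc: ReactionCoordinate, positions: np.ndarray
) -> tuple[float, np.ndarray]:
    """Value (Å) and analytic gradient (per-atom 3-vectors) of a coordinate."""
    return rc.value_and_gradient(positions)


# ---------------------------------------------------------------------------
# Pulling
# ---------------------------------------------------------------------------


@dataclass
class PullingProtocol:
    """A linear-schedule harmonic pull along a reaction coordinate.

    ``k_spring`` in kcal·mol⁻¹·Å⁻², ``dt`` in fs, ``gamma`` in ps⁻¹;
    ``n_equil`` restrained equilibration steps precede the schedule.
    """

    rc: ReactionCoordinate
    lambda_start: float
    lambda_end: float
    n_steps: int
    k_spring: float
    dt: float = 0.5
    gamma: float = 1.0
    T: float = T_DEFAULT
    seed: int = 0
    n_equil: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.k_spring < 0 or self.gamma < 0:
            raise ValueError("k_spring and gamma must be >= 0")
        if self.T < 0:
            raise ValueError("temperature must be >= 0")
        if self.n_equil < 0:
            raise ValueError("n_equil must be >= 0")


@dataclass
class WorkTrajectory:
    """Per-step record of a single pull: schedule, coordinate, work."""

    time: np.ndarray  # fs
    lam: np.ndarray  # Å
    xi: np.ndarray  # Å
    restraint_energy: np.ndarray  # kcal/mol
    work: np.ndarray  # kcal/mol, accumulated
    kinetic_energy: np.ndarray | None = None
    potential: np.ndarray | None = None

    @property
    def final_work(self) -> float:
        return float(self.work[-1])

    @property
    def total_energy(self) -> np.ndarray:
        if self.kinetic_energy is None or self.potential is None:
            raise ValueError("trajectory was run without record_energy=True")
        return self.kinetic_energy + self.potential + self.restraint_energy


class _Integrator:
    """BAOAB Langevin stepper bound to one system/protocol pair.

    Fixed atoms are handled through a zero inverse mass: their velocities,
    accelerations and thermal noise all vanish identically, so the update
    never touches array masks on the hot path.
    """

    def __init__(self, system: ToySystem, protocol: PullingProtocol, rng):
        self.system = system
        self.p = protocol
        self.rng = rng
        self.m = system.masses[:, None]
        invm = 1.0 / system.masses
        invm[system.fixed] = 0.0
        self.invm = invm[:, None]
        self.x = system.positions.copy()
        dt = protocol.dt
        g_fs = protocol.gamma * 1e-3  # ps⁻¹ → fs⁻¹
        self.c1 = math.exp(-g_fs * dt)
        self.c2 = math.sqrt(max(0.0, 1.0 - self.c1 * self.c1))
        # thermal velocity scale per component, Å/fs (zero for fixed atoms)
        self.v_std = np.sqrt(R_KCAL * protocol.T * ACCEL_CONV * self.invm)
        self.v = self.rng.standard_normal(self.x.shape) * self.v_std
        self.half = 0.5 * dt
        self.thermostat = self.c2 > 0.0 and protocol.T > 0.0

    def force(self, lam: float) -> tuple[float, float, np.ndarray]:
        """(ξ, restraint energy, total force) at the current positions."""
        U, F = self.system.energy_forces(self.x)
        p = self.p
        xi, grad = p.rc.value_and_gradient(self.x)
        if p.k_spring > 0.0:
            dev = xi - lam
            F -= p.k_spring * dev * grad
            e_rest = 0.5 * p.k_spring * dev * dev
        else:
            e_rest = 0.0
        return xi, e_rest, F

    def step(self, lam: float, a: np.ndarray) -> tuple[np.ndarray, float, float]:
        """One BAOAB step under restraint centre ``lam``.

        Returns the new acceleration plus (ξ, restraint energy) at the new
        positions, so the caller needs no extra force evaluation.
        """
        v, x = self.v, self.x
        hdt = self.half  # dt/2
        v += self.half * a
        x += hdt * v
        if self.thermostat:
            v *= self.c1
            v += self.c2 * self.v_std * self.rng.standard_normal(x.shape)
        else:
            v *= self.c1
        x += hdt * v
        xi, e_rest, F = self.force(lam)
        a = F * (ACCEL_CONV * self.invm)
        v += self.half * a
        return a, xi, e_rest

    def kinetic(self) -> float:
        """Kinetic energy in kcal/mol."""
        return float(0.5 * np.sum(self.m * self.v * self.v) / ACCEL_CONV)


def run_pull(
    system: ToySystem,
    protocol: PullingProtocol,
    record_energy: bool = False,
) -> WorkTrajectory:
    """Drag the restraint from λ_start to λ_end, accumulating work.

    The work increment over each schedule step is the midpoint-rule
    discretization ΔW = −k·(ξ − λ_mid)·Δλ with ξ evaluated at the
    configuration holding when the restraint centre moves.  Deterministic
    given ``protocol.seed``.
    """
    rng = np.random.default_rng(protocol.seed)
    integ = _Integrator(system, protocol, rng)
    p = protocol
    n = p.n_steps
    lam_grid = np.linspace(p.lambda_start, p.lambda_end, n + 1)

    # a diverging trajectory overflows before the periodic check trips;
    # silence the transient and report the failure as IntegrationError
    err_state = np.errstate(over="ignore", invalid="ignore")
    err_state.__enter__()
    try:
        return _run_pull_body(system, integ, p, n, lam_grid, record_energy)
    finally:
        err_state.__exit__(None, None, None)


def _run_pull_body(system, integ, p, n, lam_grid, record_energy) -> "WorkTrajectory":
    xi, e_rest, F = integ.force(p.lambda_start)
    a = F * (ACCEL_CONV * integ.invm)
    for step in range(p.n_equil):
        a, xi, e_rest = integ.step(p.lambda_start, a)
        if step % 64 == 0:
            _check_finite_positions(integ.x, step - p.n_equil)

    time = np.arange(n + 1, dtype=float) * p.dt
    lam_rec = lam_grid.copy()
    xi_rec = np.empty(n + 1)
    rest_rec = np.empty(n + 1)
    work = np.zeros(n + 1)
    ke = np.empty(n + 1) if record_energy else None
    pe = np.empty(n + 1) if record_energy else None

    xi_rec[0], rest_rec[0] = xi, e_rest
    if record_energy:
        ke[0] = integ.kinetic()
        pe[0] = potential_energy(system, integ.x)
    W = 0.0
    check_every = 64
    for step in range(n):
        lam_mid = 0.5 * (lam_grid[step] + lam_grid[step + 1])
        dlam = lam_grid[step + 1] - lam_grid[step]
        # ξ at the moment the restraint centre moves (cached from last eval)
        W += -p.k_spring * (xi - lam_mid) * dlam
        a, xi, e_rest = integ.step(lam_grid[step + 1], a)
        if step % check_every == 0 or step == n - 1:
            _check_finite_positions(integ.x, step)
        xi_rec[step + 1] = xi
        rest_rec[step + 1] = e_rest
        work[step + 1] = W
        if record_energy:
            ke[step + 1] = integ.kinetic()
            pe[step + 1] = potential_energy(system, integ.x)
    return WorkTrajectory(
        time=time,
        lam=lam_rec,
        xi=xi_rec,
        restraint_energy=rest_rec,
        work=work,
        kinetic_energy=ke,
        potential=pe,
    )


def _check_finite_positions(x: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
        raise IntegrationError(f"trajectory blew up at step {step}")


def run_pull_ensemble(
    system: ToySystem,
    protocol: PullingProtocol,
    n_replicas: int,
    seed: int = 0,
) -> WorkSample:
    """Independent pulls with per-replica seeds spawned from a master seed."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicas)
    works = np.empty(n_replicas)
    for r, s in enumerate(child_seeds):
        proto_r = dataclasses.replace(protocol, seed=int(s))
        try:
            works[r] = run_pull(system, proto_r).final_work
        except IntegrationError as exc:
            raise IntegrationError(f"replica {r}: {exc}") from exc
    return WorkSample(
        works=works,
        T=protocol.T,
        protocol_id=f"pull[{protocol.rc.kind}{protocol.rc.atoms}]"
        f"@k={protocol.k_spring},n={protocol.n_steps},seed={seed}",
    )


# ---------------------------------------------------------------------------
# Plain-dict constructors (YAML/CLI surface)
# ---------------------------------------------------------------------------


def system_from_dict(cfg: dict) -> ToySystem:
    """Build a :class:`ToySystem` from the plain-dict file format.

    Expected keys: ``atoms`` (list of {element?, mass, charge, fixed?}),
    ``positions`` (N×3), optional ``lj_pairs`` ({i, j, A, B}), ``bonds``
    ({i, j, k, r0}) and ``angles`` ({i, j, k, k_theta, theta0_deg}).
    """
    atoms = cfg["atoms"]
    return ToySystem(
        masses=[a["mass"] for a in atoms],
        charges=[a.get("charge", 0.0) for a in atoms],
        positions=cfg["positions"],
        lj_pairs={
            (int(p["i"]), int(p["j"])): (float(p["A"]), float(p["B"]))
            for p in cfg.get("lj_pairs", [])
        },
        bonds=[
            (int(b["i"]), int(b["j"]), float(b["k"]), float(b["r0"]))
            for b in cfg.get("bonds", [])
        ],
        angles=[
            (
                int(a["i"]),
                int(a["j"]),
                int(a["k"]),
                float(a["k_theta"]),
                math.radians(float(a["theta0_deg"])),
            )
            for a in cfg.get("angles", [])
        ],
        fixed=[bool(a.get("fixed", False)) for a in atoms],
        elements=[a.get("element", "X") for a in atoms],
    )


def protocol_from_dict(cfg: dict) -> PullingProtocol:
    """Build a :class:`PullingProtocol` from the plain-dict file format.

    The ``rc`` entry is ``{kind: distance, atoms: [i, j]}`` or
    ``{kind: diff, atoms: [a, b, c]}`` meaning d(a,b) − d(a,c).
    """
    rc_cfg = cfg["rc"]
    kind = {"diff": "distance_difference"}.get(rc_cfg["kind"], rc_cfg["kind"])
    rc = ReactionCoordinate(kind=kind, atoms=tuple(int(i) for i in rc_cfg["atoms"]))
    return PullingProtocol(
        rc=rc,
        lambda_start=float(cfg["lambda_start"]),
        lambda_end=float(cfg["lambda_end"]),
        n_steps=int(cfg["n_steps"]),
        k_spring=float(cfg["k_spring"]),
        dt=float(cfg.get("dt", 0.5)),
        gamma=float(cfg.get("gamma", 1.0)),
        T=float(cfg.get("temperature", T_DEFAULT)),
        seed=int(cfg.get("seed", 0)),
        n_equil=int(cfg.get("n_equil", 0)),
    )
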