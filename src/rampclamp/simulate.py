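"""Coarse-grained overdamped-Langevin pulling simulator.

Implements the ramp-clamp steering protocol on a bead-spring model: a dummy
point moves at constant velocity v, coupled to the steered bead by a 1-D
spring of stiffness k acting along the pulling axis (force ramp at nominal
loading rate k·v); once the spring force first reaches the clamp threshold,
the spring is replaced by a constant applied force of that magnitude (force
clamp). Euler-Maruyama integration, x += (F/γ)·dt + sqrt(2·kBT·dt/γ)·η;
fixed beads never move. Interface bonds rupture either deterministically at
an extension threshold or stochastically with a Bell rate
k(F) = k0·exp(±F·x_b/kBT) (slip: +, catch pathway: −), checked per step with
probability 1 − exp(−k·dt); rupture is irreversible.

This is a protocol analogue for exercising the analysis stack, not an
all-atom MD replica.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, UsageError
from .io import ForceLog, Topology, Trajectory
from .units import kbt_pn_a


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdRupture:
    """Deterministic rupture once bond extension exceeds ``extension_A``."""

    extension_A: float


@dataclass(frozen=True)
class BellRupture:
    """Stochastic rupture with rate k0·exp(±F·x_b/kBT).

    ``catch=True`` flips the exponent sign (force suppresses this pathway).
    """

    k0_per_ns: float
    x_b_A: float
    catch: bool = False

    def rate(self, force_pn: np.ndarray, kbt: float) -> np.ndarray:
        if kbt <= 0:
            raise ConfigError(
                "Bell kinetics need kBT > 0; set kinetics_temperature when "
                "running the mechanics at T = 0"
            )
        sign = -1.0 if self.catch else 1.0
        return self.k0_per_ns * np.exp(sign * np.maximum(force_pn, 0.0) * self.x_b_A / kbt)


@dataclass(frozen=True)
class Bond:
    """Harmonic bond; ``rupture`` marks a breakable interface bond."""

    i: int
    j: int
    k: float          # pN/Å
    r0: float         # Å
    label: str = ""
    rupture: ThresholdRupture | BellRupture | None = None


@dataclass
class BeadModel:
    """Beads plus structural and (breakable) interface bonds."""

    positions: np.ndarray            # (n, 3) Å
    gamma: np.ndarray | float = 1.0  # pN·ns/Å
    fixed: np.ndarray | None = None
    bonds: list[Bond] = field(default_factory=list)
    topology: Topology | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.positions)
        self.gamma = np.broadcast_to(np.asarray(self.gamma, float), (n,)).copy()
        if np.any(self.gamma <= 0):
            raise ConfigError("bead friction gamma must be positive")
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        else:
            self.fixed = np.asarray(self.fixed, dtype=bool).copy()
        for b in self.bonds:
            if b.k < 0:
                raise ConfigError("bond stiffness must be >= 0")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def interface_bonds(self) -> list[Bond]:
        return [b for b in self.bonds if b.rupture is not None]


@dataclass
class PullConfig:
    """Ramp-clamp protocol parameters (defaults: 13.90 pN/Å spring,
    5 Å/ns velocity, 25 pN clamp trigger, 310 K)."""

    steered_bead: int
    pull_direction: np.ndarray = (1.0, 0.0, 0.0)
    spring_constant: float = 13.90   # pN/Å
    velocity: float = 5.0            # Å/ns
    clamp_threshold: float = 25.0    # pN
    clamp_duration: float = 5.0      # ns
    ramp_max_duration: float = 20.0  # ns
    temperature: float = 310.0       # K (thermal noise)
    kinetics_temperature: float | None = None  # K for Bell rates; defaults to temperature
    dt: float = 1e-4                 # ns
    seed: int = 0
    log_stride: int = 1

    def __post_init__(self):
        self.pull_direction = np.asarray(self.pull_direction, dtype=float)
        norm = np.linalg.norm(self.pull_direction)
        if norm == 0:
            raise ConfigError("pull_direction must be a non-zero vector")
        self.pull_direction = self.pull_direction / norm
        for name in ("spring_constant", "velocity", "clamp_threshold",
                     "clamp_duration", "ramp_max_duration", "dt"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.temperature < 0:
            raise ConfigError("temperature must be >= 0")


def _validate_stability(model: BeadModel, dt: float, extra_k: float = 0.0,
                        steered: int | None = None) -> None:
    """Refuse configurations where the harmonic update is unstable
    (k·dt/γ must stay < 0.1 for every bond and for the pulling spring)."""
    for b in model.bonds:
        g = min(model.gamma[b.i], model.gamma[b.j])
        if b.k * dt / g >= 0.1:
            raise ConfigError(
                f"unstable dt: bond ({b.i},{b.j}) has k·dt/γ = {b.k * dt / g:.3f} >= 0.1"
            )
    if steered is not None and extra_k * dt / model.gamma[steered] >= 0.1:
        raise ConfigError("unstable dt for the pulling spring (k·dt/γ >= 0.1)")


def generic_topology(n: int, dt_ns: float = 1.0) -> Topology:
    atoms = pd.DataFrame({
        "serial": np.arange(1, n + 1),
        "name": ["CA"] * n,
        "resname": ["BEA"] * n,
        "resid": np.arange(1, n + 1),
        "chain": ["A"] * n,
        "element": ["C"] * n,
        "charge": np.zeros(n),
        "lj_epsilon": np.zeros(n),
        "lj_rmin_half": np.full(n, 2.0),
        "donor": [False] * n,
        "acceptor": [False] * n,
        "fixed": [False] * n,
    })
    return Topology(atoms=atoms, metadata={"dt_ns": dt_ns})


# ---------------------------------------------------------------------------
# Integrator core
# ---------------------------------------------------------------------------

def _bond_arrays(bonds: Sequence[Bond]):
    if not bonds:
        return (np.empty(0, int), np.empty(0, int), np.empty(0), np.empty(0))
    return (
        np.array([b.i for b in bonds]),
        np.array([b.j for b in bonds]),
        np.array([b.k for b in bonds], float),
        np.array([b.r0 for b in bonds], float),
    )


def _bond_forces(x, bi, bj, bk, br0, active):
    """Pairwise harmonic forces and per-bond tension (pN, + = stretched)."""
    forces = np.zeros_like(x)
    if bi.size == 0:
        return forces, np.empty(0)
    rij = x[bj] - x[bi]
    dist = np.linalg.norm(rij, axis=1)
    dist = np.where(dist < 1e-12, 1e-12, dist)
    tension = bk * (dist - br0) * active
    f = (tension / dist)[:, None] * rij
    np.add.at(forces, bi, f)
    np.add.at(forces, bj, -f)
    return forces, tension


def run_ramp_clamp(
    model: BeadModel, config: PullConfig
) -> tuple[Trajectory, ForceLog, list[dict]]:
    """Run the ramp-clamp protocol. Returns (Trajectory, ForceLog, events).

    Events carry ``time_ns``, ``bond_label`` and ``force_pN`` (bond tension
    when it ruptured). Identical model/config/seed give identical outputs.
    """
    if model.fixed[config.steered_bead]:
        raise UsageError("steered bead must not be fixed")
    _validate_stability(model, config.dt, config.spring_constant, config.steered_bead)
    rng = np.random.default_rng(config.seed)
    x = model.positions.copy()
    direction = config.pull_direction
    kbt = kbt_pn_a(config.temperature)
    kin_t = (config.temperature if config.kinetics_temperature is None
             else config.kinetics_temperature)
    kbt_kinetics = kbt_pn_a(kin_t)
    gamma = model.gamma[:, None]
    mobile = ~model.fixed
    noise_scale = np.sqrt(2.0 * kbt * config.dt / model.gamma)[:, None]

    bi, bj, bk, br0 = _bond_arrays(model.bonds)
    active = np.ones(len(model.bonds), dtype=bool)
    rupture_rules = [b.rupture for b in model.bonds]
    labels = [b.label or f"bond_{b.i}_{b.j}" for b in model.bonds]

    dummy0 = float(x[config.steered_bead] @ direction)
    phase = "ramp"
    t = 0.0
    clamp_t0 = None
    events: list[dict] = []
    log_rows = []
    traj_coords = [x.copy()]
    traj_times = [0.0]

    max_steps = int(round((config.ramp_max_duration + config.clamp_duration) / config.dt))
    for step in range(1, max_steps + 1):
        # --- applied pulling force
        steered_proj = float(x[config.steered_bead] @ direction)
        if phase == "ramp":
            dummy = dummy0 + config.velocity * t
            ext = dummy - steered_proj
            applied = config.spring_constant * ext
            if applied >= config.clamp_threshold:
                phase = "clamp"
                clamp_t0 = t
                applied = config.clamp_threshold
        else:
            dummy = dummy0 + config.velocity * clamp_t0
            applied = config.clamp_threshold

        forces, tension = _bond_forces(x, bi, bj, bk, br0, active)
        forces[config.steered_bead] += applied * direction

        # --- rupture checks on interface bonds
        for idx, rule in enumerate(rupture_rules):
            if rule is None or not active[idx]:
                continue
            if isinstance(rule, ThresholdRupture):
                dist = np.linalg.norm(x[bj[idx]] - x[bi[idx]])
                if dist - br0[idx] > rule.extension_A:
                    active[idx] = False
                    events.append({"time_ns": t, "bond_label": labels[idx],
                                   "force_pN": float(tension[idx])})
            else:
                rate = float(rule.rate(np.array(tension[idx]), kbt_kinetics))
                if rng.random() < -np.expm1(-rate * config.dt):
                    active[idx] = False
                    events.append({"time_ns": t, "bond_label": labels[idx],
                                   "force_pN": float(tension[idx])})

        # --- Euler-Maruyama update
        dx = forces / gamma * config.dt
        if config.temperature > 0:
            dx = dx + noise_scale * rng.standard_normal(x.shape)
        x[mobile] += dx[mobile]
        t = step * config.dt

        if step % config.log_stride == 0:
            log_rows.append((t, applied, dummy, float(x[config.steered_bead] @ direction),
                             phase))
            traj_coords.append(x.copy())
            traj_times.append(t)
        if phase == "clamp" and t - clamp_t0 >= config.clamp_duration:
            break
        if phase == "ramp" and t >= config.ramp_max_duration:
            break

    topology = model.topology or generic_topology(model.n_beads)
    traj = Trajectory(topology=topology, coords=np.stack(traj_coords),
                      times=np.array(traj_times))
    log = ForceLog(
        data=pd.DataFrame(log_rows,
                          columns=["time_ns", "force_pN", "dummy_A", "steered_A", "phase"]),
        metadata={
            "spring_constant_pN_A": config.spring_constant,
            "velocity_A_ns": config.velocity,
            "clamp_threshold_pN": config.clamp_threshold,
            "temperature_K": config.temperature,
            "dt_ns": config.dt,
            "seed": config.seed,
        },
    )
    return traj, log, events


def run_free(
    model: BeadModel,
    duration: float,
    dt: float = 1e-4,
    temperature: float = 310.0,
    seed: int = 0,
    log_stride: int = 1,
) -> Trajectory:
    """Free (unforced) thermal dynamics of the bead model."""
    _validate_stability(model, dt)
    rng = np.random.default_rng(seed)
    x = model.positions.copy()
    kbt = kbt_pn_a(temperature)
    gamma = model.gamma[:, None]
    mobile = ~model.fixed
    noise_scale = np.sqrt(2.0 * kbt * dt / model.gamma)[:, None]
    bi, bj, bk, br0 = _bond_arrays(model.bonds)
    active = np.ones(len(model.bonds), dtype=bool)
    n_steps = int(round(duration / dt))
    coords = [x.copy()]
    times = [0.0]
    for step in range(1, n_steps + 1):
        forces, _ = _bond_forces(x, bi, bj, bk, br0, active)
        dx = forces / gamma * dt
        if temperature > 0:
            dx = dx + noise_scale * rng.standard_normal(x.shape)
        x[mobile] += dx[mobile]
        if step % log_stride == 0:
            coords.append(x.copy())
            times.append(step * dt)
    topology = model.topology or generic_topology(model.n_beads)
    return Trajectory(topology=topology, coords=np.stack(coords), times=np.array(times))


# ---------------------------------------------------------------------------
# Constraint patterns
# ---------------------------------------------------------------------------

def constraint_factory(pattern: str, chain: Sequence[int]) -> np.ndarray:
    """Fixed-bead index set for the S0-S3 constraint patterns of a chain.

    S0: none; S1: middle bead; S2: both ends; S3: ends and middle. The chain
    must have odd length >= 3 so a middle bead exists.
    """
    chain = np.asarray(chain, dtype=int)
    if chain.size < 3 or chain.size % 2 == 0:
        raise UsageError("chain must have odd length >= 3 (a designated middle bead)")
    middle = chain[chain.size // 2]
    ends = [chain[0], chain[-1]]
    patterns = {
        "S0": np.array([], dtype=int),
        "S1": np.array([middle]),
        "S2": np.array(ends),
        "S3": np.array(sorted(set(ends) | {middle})),
    }
    key = pattern.upper()
    if key not in patterns:
        raise UsageError(f"unknown constraint pattern {pattern!r}; choose from S0-S3")
    return patterns[key]


def apply_constraint(model: BeadModel, pattern: str, chain: Sequence[int]) -> BeadModel:
    """Copy of the model with the pattern's beads flagged fixed."""
    fixed = model.fixed.copy()
    fixed[:] = False
    fixed[constraint_factory(pattern, chain)] = True
    return BeadModel(positions=model.positions.copy(), gamma=model.gamma.copy(),
                     fixed=fixed, bonds=list(model.bonds), topology=model.topology)


# ---------------------------------------------------------------------------
# Batched clamp-phase lifetime sampling
# ---------------------------------------------------------------------------

def clamp_lifetimes(
    rupture: BellRupture,
    force_pn: float,
    n_replicas: int,
    bond_k: float = 100.0,
    bond_r0: float = 5.0,
    gamma: float = 1.0,
    temperature: float = 310.0,
    thermal_motion: bool = False,
    dt: float = 1e-3,
    max_time: float = 1e4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp-phase bond lifetimes from the simulator, batched over replicas.

    Each replica is a steered bead tethered to a fixed anchor by a breakable
    harmonic bond under a constant applied force (the clamp phase of the
    protocol), integrated with the same Euler-Maruyama update and per-step
    Bell rupture draw as :func:`run_ramp_clamp`. ``temperature`` sets kBT of
    the Bell kinetics; positional thermal noise is added only when
    ``thermal_motion`` is set (off: deterministic mechanics + stochastic
    kinetics). Returns (lifetimes_ns, censored); censored marks replicas
    that never ruptured within ``max_time``.
    """
    if bond_k * dt / gamma >= 0.1:
        raise ConfigError("unstable dt for the clamp tether (k·dt/γ >= 0.1)")
    rng = np.random.default_rng(seed)
    kbt = kbt_pn_a(temperature)
    x = np.full(n_replicas, bond_r0)  # 1-D extension coordinate along the pull axis
    alive = np.ones(n_replicas, dtype=bool)
    lifetimes = np.full(n_replicas, np.nan)
    noise_scale = np.sqrt(2.0 * kbt * dt / gamma) if thermal_motion else 0.0
    n_steps = int(round(max_time / dt))
    for step in range(1, n_steps + 1):
        if not alive.any():
            break
        tension = bond_k * (x - bond_r0)
        rate = rupture.rate(tension, kbt)
        p = -np.expm1(-rate * dt)
        broke = alive & (rng.random(n_replicas) < p)
        lifetimes[broke] = (step - 1) * dt
        alive &= ~broke
        force = force_pn - tension
        dx = force / gamma * dt
        if thermal_motion:
            dx = dx + noise_scale * rng.standard_normal(n_replicas)
        x[alive] += dx[alive]
    return lifetimes, np.isnan(lifetimes)
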