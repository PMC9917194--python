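"""Synthetic inputs with known ground truth.

Every generator returns its dataset together with a :class:`GroundTruth`
record of all planted parameters and the seed, so analysis results can be
checked closed-loop without re-deriving truth from data. All generators are
deterministic under a fixed (parameters, seed) pair.

What is emulated: a toy receptor-ligand complex shaped like the CD44
HABD-HA binding interface (a bag-like receptor with the field's named
binding-site residues and a 7-saccharide GlcNAc/GlcUA chain); two-state
(telegraph) interfacial H-bond dynamics with prescribed occupancies;
ramp force logs with a planted rupture; AFM indentation/retract curves with
a known modulus and planted adhesion events; and exponential bond lifetimes
from the two-pathway catch-slip dissociation model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .events import LifetimeRecord, optimum_force
from .io import AFMCurve, ForceLog, Frame, Topology, Trajectory
from .simulate import BeadModel, BellRupture, Bond
from .units import kbt_pn_a

TELEGRAPH_IN_A = 3.0   # donor-acceptor distance in the bonded state (Å)
TELEGRAPH_OUT_A = 4.5  # unbonded state; both clear of the 3.5 Å cutoff


@dataclass
class GroundTruth:
    """Planted parameters of a generated dataset."""

    generator: str
    parameters: dict
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "parameters": self.parameters,
             "seed": self.seed},
            indent=2, sort_keys=True, default=_jsonify,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(**obj)


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

#: Receptor binding-site beads: (resname, resid, position). Tyr46 is the
#: pocket vertex; Glu52-Tyr166 is the internal latch bond; Ile173 is the
#: steered C-terminal bead.
_RECEPTOR_BEADS = [
    ("ASN", 115, (0.0, 0.0, 0.0)),
    ("ARG", 45, (6.5, 0.0, 0.0)),
    ("TYR", 46, (10.0, 0.0, 1.0)),
    ("ILE", 100, (10.0, 0.0, -1.0)),
    ("CYS", 81, (15.0, 0.0, 1.0)),
    ("ARG", 82, (15.0, 0.0, -1.0)),
    ("ARG", 155, (25.0, 0.0, 0.0)),
    ("GLU", 52, (-3.0, -3.0, 0.0)),
    ("TYR", 166, (-3.0, -6.0, 0.0)),
    ("ILE", 173, (30.0, -6.0, 0.0)),
]

#: Interface bonds as (ligand resid, receptor resid) pairs; the field's
#: high-occupancy interfacial H-bonds.
INTERFACE_PAIRS = [
    (1175, 115), (1176, 45), (1177, 46), (1177, 100),
    (1178, 81), (1178, 82), (1180, 155),
]

LIGAND_SPACING_A = 5.0
LIGAND_Y_A = 3.1


def make_toy_complex(
    n_receptor_beads: int = 10,
    n_ligand_beads: int = 7,
) -> tuple[Topology, Frame, BeadModel]:
    """Coarse-grained receptor-ligand complex with named binding-site beads.

    Ligand beads are C2 pseudo-atoms of saccharides resid 1175.., resnames
    alternating GlcNAc/GlcUA, on chain B; receptor beads are Cα pseudo-atoms
    on chain A. Interface bonds connect the canonical binding pairs (e.g.
    GlcUA1180-Arg155). The ligand chain must have odd length so a middle
    bead exists for the S1/S3 constraint patterns.
    """
    if n_ligand_beads % 2 == 0 or n_ligand_beads < 3:
        raise UsageError("ligand chain length must be odd and >= 3")
    if n_receptor_beads < len(_RECEPTOR_BEADS):
        raise UsageError(f"need at least {len(_RECEPTOR_BEADS)} receptor beads")

    rows = []
    positions = []
    for resname, resid, pos in _RECEPTOR_BEADS:
        rows.append(dict(name="CA", resname=resname, resid=resid, chain="A",
                         element="C", charge=0.3 if resname == "ARG" else 0.0,
                         donor=False, acceptor=True))
        positions.append(pos)
    for k in range(n_receptor_beads - len(_RECEPTOR_BEADS)):
        rows.append(dict(name="CB", resname="GLY", resid=200 + k, chain="A",
                         element="C", charge=0.0, donor=False, acceptor=False))
        positions.append((4.0 * k, -9.0, 0.0))
    for i in range(n_ligand_beads):
        resname = "GlcNAc" if i % 2 == 0 else "GlcUA"
        rows.append(dict(name="C2", resname=resname, resid=1175 + i, chain="B",
                         element="C", charge=-0.3 if resname == "GlcUA" else 0.0,
                         donor=True, acceptor=False))
        positions.append((LIGAND_SPACING_A * i, LIGAND_Y_A, 0.0))

    atoms = pd.DataFrame(rows)
    atoms.insert(0, "serial", np.arange(1, len(rows) + 1))
    atoms["lj_epsilon"] = 0.1
    atoms["lj_rmin_half"] = 2.0
    atoms["fixed"] = False
    topology = Topology(atoms=atoms, metadata={"dt_ns": 0.01})
    coords = np.asarray(positions, dtype=float)
    frame = Frame(time=0.0, coords=coords)

    resid = topology.column("resid")
    chain = topology.column("chain")

    def idx(rid, ch):
        hits = np.flatnonzero((resid == rid) & (chain == ch))
        return int(hits[0])

    bonds: list[Bond] = []
    # structural: ligand backbone springs
    lig_idx = [idx(1175 + i, "B") for i in range(n_ligand_beads)]
    for a, b in zip(lig_idx[:-1], lig_idx[1:]):
        bonds.append(Bond(a, b, k=50.0, r0=LIGAND_SPACING_A))
    # structural: receptor scaffold springs in listed order
    rec_idx = [idx(r, "A") for _, r, _ in _RECEPTOR_BEADS]
    for a, b in zip(rec_idx[:-1], rec_idx[1:]):
        r0 = float(np.linalg.norm(coords[a] - coords[b]))
        bonds.append(Bond(a, b, k=50.0, r0=r0))
    # internal latch bond (Glu52-Tyr166), breakable; stochastic Bell kinetics
    # by default (thermal extension fluctuations of these soft beads dwarf
    # any deterministic threshold that the clamp force could reach)
    latch_rupture = BellRupture(k0_per_ns=0.05, x_b_A=1.0)
    iface_rupture = BellRupture(k0_per_ns=0.2, x_b_A=1.0)
    g, y = idx(52, "A"), idx(166, "A")
    bonds.append(Bond(g, y, k=30.0, r0=float(np.linalg.norm(coords[g] - coords[y])),
                      label="GLU52-TYR166", rupture=latch_rupture))
    # interface bonds
    for lig_rid, rec_rid in INTERFACE_PAIRS:
        if lig_rid - 1175 >= n_ligand_beads:
            continue
        a, b = idx(lig_rid, "B"), idx(rec_rid, "A")
        label = f"{topology.label(a)}-{topology.label(b)}"
        bonds.append(Bond(a, b, k=30.0,
                          r0=float(np.linalg.norm(coords[a] - coords[b])),
                          label=label, rupture=iface_rupture))
    model = BeadModel(positions=coords.copy(), gamma=1.0, bonds=bonds,
                      topology=topology)
    return topology, frame, model


def interface_bond_indices(topology: Topology) -> list[tuple[int, int]]:
    """(donor, acceptor) atom-index pairs of the toy complex's interface bonds.

    Useful for telegraph fixtures: planting states for every pair (occupancy
    0 for pairs meant to stay unbonded) keeps the base geometry's inherent
    contacts from contributing spurious bonds.
    """
    resid = topology.column("resid")
    chain = topology.column("chain")
    pairs = []
    for lig_rid, rec_rid in INTERFACE_PAIRS:
        d = np.flatnonzero((resid == lig_rid) & (chain == "B"))
        a = np.flatnonzero((resid == rec_rid) & (chain == "A"))
        if d.size and a.size:
            pairs.append((int(d[0]), int(a[0])))
    return pairs


def ligand_chain_indices(topology: Topology) -> np.ndarray:
    """Ligand bead indices in chain order (for constraint patterns)."""
    chain = topology.column("chain")
    resid = topology.column("resid")
    lig = np.flatnonzero(chain == "B")
    return lig[np.argsort(resid[lig])]


# ---------------------------------------------------------------------------
# Telegraph trajectories
# ---------------------------------------------------------------------------

def make_telegraph_trajectory(
    topology: Topology,
    base_frame: Frame,
    bonds: Sequence[tuple[int, int]],
    occupancies: Sequence[float],
    correlation_time: float,
    n_frames: int,
    positional_noise: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """Trajectory whose H-bond presence follows independent telegraph processes.

    Each (donor, acceptor) bond's donor-acceptor distance alternates between
    3.0 Å (bonded) and 4.5 Å (unbonded) following a stationary two-state
    Markov chain with stationary presence probability o_i and relaxation
    time ``correlation_time`` (ns, must exceed the frame spacing). Acceptor
    atoms are repositioned along the base donor-acceptor axis; atoms not in
    any bond get isotropic Gaussian jitter of ``positional_noise`` Å.
    """
    dt = topology.dt_ns
    if correlation_time <= dt:
        raise UsageError("correlation_time must exceed the frame spacing")
    occupancies = np.asarray(occupancies, float)
    if len(bonds) != occupancies.size:
        raise UsageError("one occupancy per bond required")
    if np.any((occupancies < 0) | (occupancies > 1)):
        raise UsageError("occupancies must lie in [0, 1]")
    acceptors = [b[1] for b in bonds]
    if len(set(acceptors)) != len(acceptors):
        raise UsageError("telegraph bonds must have distinct acceptor atoms")

    rng = np.random.default_rng(seed)
    base = base_frame.coords
    n_atoms = base.shape[0]
    relax = np.exp(-dt / correlation_time)

    # simulate all bond state paths
    states = np.empty((n_frames, len(bonds)), dtype=bool)
    for j, o in enumerate(occupancies):
        if o in (0.0, 1.0):
            states[:, j] = bool(o)
            continue
        s = rng.random() < o
        for i in range(n_frames):
            states[i, j] = s
            p_on = o + (1.0 - o) * relax if s else o * (1.0 - relax)
            s = rng.random() < p_on
    bonded_atoms = set()
    for d, a in bonds:
        bonded_atoms.add(d)
        bonded_atoms.add(a)
    free_atoms = np.array([i for i in range(n_atoms) if i not in bonded_atoms], int)

    axes = []
    for d, a in bonds:
        v = base[a] - base[d]
        norm = np.linalg.norm(v)
        axes.append(v / norm if norm > 1e-9 else np.array([0.0, 1.0, 0.0]))

    coords = np.repeat(base[None], n_frames, axis=0)
    if positional_noise > 0 and free_atoms.size:
        coords[:, free_atoms, :] += rng.normal(
            0.0, positional_noise, size=(n_frames, free_atoms.size, 3)
        )
    for j, (d, a) in enumerate(bonds):
        dist = np.where(states[:, j], TELEGRAPH_IN_A, TELEGRAPH_OUT_A)
        coords[:, a, :] = base[d] + dist[:, None] * axes[j][None, :]

    times = np.arange(n_frames, dtype=float) * dt
    traj = Trajectory(topology=topology, coords=coords, times=times)
    truth = GroundTruth(
        generator="telegraph_trajectory",
        parameters={
            "bonds": [list(b) for b in bonds],
            "occupancies": occupancies.tolist(),
            "correlation_time_ns": correlation_time,
            "n_frames": n_frames,
            "positional_noise_A": positional_noise,
            "p_dissociation": float(np.prod(1.0 - occupancies)),
            "expected_n_hb": float(np.sum(occupancies)),
        },
        seed=seed,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Force-ramp logs
# ---------------------------------------------------------------------------

def make_force_ramp_log(
    loading_rate: float,
    rupture_force: float,
    noise_sigma: float = 0.0,
    post_rupture_level: float = 0.0,
    seed: int = 0,
    dt_ns: float = 0.01,
    tail_ns: float | None = None,
    spring_constant: float = 13.90,
) -> tuple[ForceLog, GroundTruth]:
    """Force-time log with a linear ramp to a planted rupture, then collapse.

    The noiseless peak sits exactly at t = rupture_force / loading_rate.
    """
    for name, v in (("loading_rate", loading_rate), ("rupture_force", rupture_force)):
        if v <= 0:
            raise UsageError(f"{name} must be positive")
    t_rup = rupture_force / loading_rate
    tail = tail_ns if tail_ns is not None else max(2.0, 0.5 * t_rup)
    t = np.arange(0.0, t_rup + tail, dt_ns)
    force = np.where(t <= t_rup, loading_rate * t, post_rupture_level)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        force = force + rng.normal(0.0, noise_sigma, size=t.shape)
    data = pd.DataFrame({
        "time_ns": t,
        "force_pN": force,
        "dummy_A": loading_rate * t / spring_constant,
        "steered_A": np.zeros_like(t),
        "phase": "ramp",
    })
    log = ForceLog(data=data, metadata={"dt_ns": dt_ns, "seed": seed})
    truth = GroundTruth(
        generator="force_ramp_log",
        parameters={
            "loading_rate_pN_ns": loading_rate,
            "rupture_force_pN": rupture_force,
            "rupture_time_ns": t_rup,
            "noise_sigma_pN": noise_sigma,
            "post_rupture_level_pN": post_rupture_level,
        },
        seed=seed,
    )
    return log, truth


# ---------------------------------------------------------------------------
# AFM curves
# ---------------------------------------------------------------------------

def make_afm_curve(
    E_pa: float,
    alpha_deg: float,
    contact_point_nm: float,
    adhesion_events: Sequence[tuple[float, float]] = (),
    retract_speed_nm_s: float = 100.0,
    dwell_ms: float = 500.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    z_max_nm: float | None = None,
    step_nm: float = 0.5,
    nu: float = 0.5,
    event_width_nm: float = 15.0,
) -> tuple[AFMCurve, GroundTruth]:
    """AFM cycle: Hertzian approach, dwell, retract with planted adhesion.

    ``adhesion_events`` are (rupture force pN, piezo position nm) pairs;
    each appears on the retract trace as a sawtooth that ramps up over
    ``event_width_nm`` and drops discontinuously at its position. Protocol
    defaults mirror the standard single-molecule cycle (100 nm/s retract,
    500 ms dwell).
    """
    if z_max_nm is None:
        z_max_nm = contact_point_nm + 100.0
    for f_ev, p_ev in adhesion_events:
        if not (0.0 < p_ev < z_max_nm - event_width_nm):
            raise UsageError("adhesion event position outside the retract range")
    rng = np.random.default_rng(seed)
    coeff_pn_nm2 = (2.0 / np.pi) * np.tan(np.radians(alpha_deg)) * E_pa / (
        1.0 - nu ** 2
    ) * 1e-6
    z_app = np.arange(0.0, z_max_nm + step_nm / 2, step_nm)
    delta = np.maximum(z_app - contact_point_nm, 0.0)
    f_app = coeff_pn_nm2 * delta ** 2
    n_dwell = max(2, int(round(dwell_ms / 1000.0 * retract_speed_nm_s / step_nm)))
    z_dwell = np.full(n_dwell, z_max_nm)
    f_dwell = np.full(n_dwell, f_app[-1])
    z_ret = z_app[::-1]
    f_ret = np.zeros_like(z_ret)
    for f_ev, p_ev in adhesion_events:
        in_ramp = (z_ret >= p_ev) & (z_ret <= p_ev + event_width_nm)
        f_ret[in_ramp] += f_ev * (p_ev + event_width_nm - z_ret[in_ramp]) / event_width_nm

    phases = (["approach"] * len(z_app) + ["dwell"] * n_dwell + ["retract"] * len(z_ret))
    z = np.concatenate([z_app, z_dwell, z_ret])
    f = np.concatenate([f_app, f_dwell, f_ret])
    if noise_sigma > 0:
        f = f + rng.normal(0.0, noise_sigma, size=f.shape)
    curve = AFMCurve(
        data=pd.DataFrame({"piezo_nm": z, "force_pN": f, "phase": phases}),
        metadata={"retract_speed_nm_s": retract_speed_nm_s, "dwell_ms": dwell_ms,
                  "seed": seed},
    )
    truth = GroundTruth(
        generator="afm_curve",
        parameters={
            "E_Pa": E_pa, "alpha_deg": alpha_deg, "nu": nu,
            "contact_point_nm": contact_point_nm,
            "adhesion_events": [list(e) for e in adhesion_events],
            "noise_sigma_pN": noise_sigma,
            "retract_speed_nm_s": retract_speed_nm_s, "dwell_ms": dwell_ms,
        },
        seed=seed,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Catch-slip lifetimes
# ---------------------------------------------------------------------------

def sample_lifetimes(
    k_c: float,
    x_c: float,
    k_s: float,
    x_s: float,
    forces: Sequence[float],
    n_per_force: int,
    temperature: float = 310.0,
    seed: int = 0,
) -> tuple[list[LifetimeRecord], GroundTruth]:
    """Exponential lifetimes from the two-pathway dissociation model.

    Rates: k(F) = k_c·exp(−F·x_c/kBT) + k_s·exp(+F·x_s/kBT); k in 1/s and
    lifetimes in s, x in Å, F in pN. The ground truth records the analytic
    optimum force F*.
    """
    for name, v in (("k_c", k_c), ("x_c", x_c), ("k_s", k_s), ("x_s", x_s)):
        if v < 0:
            raise UsageError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    kbt = kbt_pn_a(temperature)
    records = []
    for f in forces:
        rate = k_c * np.exp(-f * x_c / kbt) + k_s * np.exp(f * x_s / kbt)
        lifetimes = rng.exponential(1.0 / rate, size=n_per_force)
        records.extend(LifetimeRecord(clamp_force=float(f), lifetime=float(tau))
                       for tau in lifetimes)
    fstar = optimum_force(k_c, x_c, k_s, x_s, kbt)
    truth = GroundTruth(
        generator="catch_slip_lifetimes",
        parameters={
            "k_c": k_c, "x_c": x_c, "k_s": k_s, "x_s": x_s,
            "temperature_K": temperature,
            "forces_pN": list(map(float, forces)),
            "n_per_force": n_per_force,
            "fstar_pN": None if fstar is None else float(fstar),
        },
        seed=seed,
    )
    return records, truth


def catch_slip_params_for_fstar(
    fstar_pn: float,
    x_c: float = 4.0,
    x_s: float = 4.0,
    k_s: float = 1.0,
    temperature: float = 310.0,
) -> dict:
    """Two-pathway parameters whose analytic optimum is exactly ``fstar_pn``.

    Default barrier distances of 4 Å give a clearly biphasic τ(F) over the
    usual 0-40 pN window (peak/edge lifetime ratio > 2), so the optimum is
    identifiable from a few hundred lifetimes per force level.
    """
    kbt = kbt_pn_a(temperature)
    k_c = k_s * x_s / x_c * np.exp(fstar_pn * (x_c + x_s) / kbt)
    return {"k_c": float(k_c), "x_c": x_c, "k_s": k_s, "x_s": x_s}
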