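"""Interfacial chemistry statistics.

Hydrogen-bond and salt-bridge detection between two atom groups, per-bond
occupancies over a trajectory, the dissociation-probability statistic P_D,
the instantaneous interfacial bond count N_HB, and a truncated Coulomb +
Lennard-Jones interaction energy.

Geometric criteria (defaults): donor-heavy to acceptor distance < 3.5 Å and
donor-hydrogen-acceptor deviation angle < 30°, both strict. The deviation
angle is measured at the donor, between the D->H and D->A vectors (the VMD
convention); a donor without an attributable hydrogen (element H, same
residue, within 1.2 Å) falls back to distance-only detection, flagged on the
returned bond.

P_D: with per-bond occupancies o_i treated as independent presence
probabilities, the probability that no interfacial bond is present is
P_D = Π_i (1 - o_i). An empty table gives P_D = 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import UsageError, ValidationError
from .io import Frame, Topology, Trajectory
from .units import COULOMB_KCAL_A_E2

H_COVALENT_CUTOFF = 1.2  # Å, hydrogen-to-donor-heavy attribution

ACIDIC_O_NAMES = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_N_NAMES = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}


@dataclass(frozen=True)
class HBond:
    """A detected hydrogen bond, identified by donor-heavy/acceptor indices."""

    donor_heavy: int
    acceptor: int
    hydrogen: int | None = None
    distance_only: bool = False
    label: str = ""

    def key(self) -> tuple[int, int]:
        return (self.donor_heavy, self.acceptor)


@dataclass
class OccupancyTable:
    """Per-bond occupancies o_i in [0, 1] over n_frames frames."""

    occupancies: dict[str, float]
    n_frames: int
    keys: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValidationError("occupancy table requires n_frames >= 1")
        for label, o in self.occupancies.items():
            if not (0.0 <= o <= 1.0):
                raise ValidationError(f"occupancy of {label} outside [0, 1]: {o}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bond": list(self.occupancies), "occupancy": list(self.occupancies.values())}
        )


@dataclass
class InterfaceSeries:
    """Per-frame interfacial bond statistics.

    ``presence`` is a (n_frames, n_bonds) boolean matrix over ``bond_labels``;
    N_HB is its row sum by construction.
    """

    times: np.ndarray
    n_hb: np.ndarray
    energy: np.ndarray
    presence: np.ndarray
    bond_labels: list[str]

    def summary(self) -> dict:
        def mean_sem(x):
            x = np.asarray(x, float)
            sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
            return {"mean": float(np.mean(x)), "sem": sem}

        return {"n_hb": mean_sem(self.n_hb), "energy": mean_sem(self.energy)}


def _check_groups(group_a, group_b):
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise UsageError("both atom groups must be non-empty")
    if np.intersect1d(ga, gb).size:
        raise UsageError("atom groups overlap; they must be disjoint")
    return ga, gb


def _bond_label(topology: Topology, donor: int, acceptor: int) -> str:
    return f"{topology.label(donor)}-{topology.label(acceptor)}"


def _hydrogens_for_donor(topology: Topology, coords: np.ndarray, donor: int) -> np.ndarray:
    elements = topology.column("element").astype(str)
    resid = topology.column("resid")
    chain = topology.column("chain")
    mask = (
        (elements == "H")
        & (resid == resid[donor])
        & (chain == chain[donor])
    )
    h_idx = np.flatnonzero(mask)
    if h_idx.size == 0:
        return h_idx
    d = np.linalg.norm(coords[h_idx] - coords[donor], axis=1)
    return h_idx[d < H_COVALENT_CUTOFF]


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    group_a: Sequence[int],
    group_b: Sequence[int],
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
) -> set[HBond]:
    """Cross-group hydrogen bonds in one frame (both donor directions)."""
    ga, gb = _check_groups(group_a, group_b)
    coords = frame.coords
    donors = topology.column("donor").astype(bool)
    acceptors = topology.column("acceptor").astype(bool)
    bonds: set[HBond] = set()
    for d_group, a_group in ((ga, gb), (gb, ga)):
        d_idx = d_group[donors[d_group]]
        a_idx = a_group[acceptors[a_group]]
        if d_idx.size == 0 or a_idx.size == 0:
            continue
        dist = cdist(coords[d_idx], coords[a_idx])
        for i, j in zip(*np.nonzero(dist < d_cut)):
            donor, acceptor = int(d_idx[i]), int(a_idx[j])
            hydrogens = _hydrogens_for_donor(topology, coords, donor)
            if hydrogens.size == 0:
                bonds.add(HBond(donor, acceptor, None, True,
                                _bond_label(topology, donor, acceptor)))
                continue
            da = coords[acceptor] - coords[donor]
            dh = coords[hydrogens] - coords[donor]
            cosang = (dh @ da) / (
                np.linalg.norm(dh, axis=1) * np.linalg.norm(da) + 1e-300
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            best = int(np.argmin(ang))
            if ang[best] < angle_cut:
                bonds.add(HBond(donor, acceptor, int(hydrogens[best]), False,
                                _bond_label(topology, donor, acceptor)))
    return bonds


def detect_salt_bridges(
    frame: Frame,
    topology: Topology,
    group_a: Sequence[int],
    group_b: Sequence[int],
    d_cut: float = 4.0,
) -> set[tuple[str, str]]:
    """Cross-group salt bridges: any acidic side-chain O within d_cut (strict)
    of a basic side-chain N. Reported per residue pair as label tuples."""
    ga, gb = _check_groups(group_a, group_b)
    names = topology.column("name").astype(str)
    resnames = topology.column("resname").astype(str)

    def classify(idx):
        acidic, basic = [], []
        for i in idx:
            rn = resnames[i]
            if rn in ACIDIC_O_NAMES and names[i] in ACIDIC_O_NAMES[rn]:
                acidic.append(int(i))
            if rn in BASIC_N_NAMES and names[i] in BASIC_N_NAMES[rn]:
                basic.append(int(i))
        return acidic, basic

    coords = frame.coords
    resid = topology.column("resid")
    bridges: set[tuple[str, str]] = set()
    acid_a, base_a = classify(ga)
    acid_b, base_b = classify(gb)
    for o_side, n_side in ((acid_a, base_b), (acid_b, base_a)):
        for o in o_side:
            for n in n_side:
                if np.linalg.norm(coords[o] - coords[n]) < d_cut:
                    bridges.add(
                        (f"{resnames[o]}{resid[o]}", f"{resnames[n]}{resid[n]}")
                    )
    return bridges


def occupancy(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
) -> OccupancyTable:
    """Fraction of frames in which each observed cross-group H-bond is present.

    Bond identity is the donor-heavy/acceptor atom pair, so one residue pair
    may contribute several tracked bonds.
    """
    if traj.n_frames < 1:
        raise UsageError("occupancy requires at least one frame")
    counts: dict[tuple[int, int], int] = {}
    labels: dict[tuple[int, int], str] = {}
    for frame in traj.frames():
        for bond in detect_hbonds(frame, traj.topology, group_a, group_b, d_cut, angle_cut):
            counts[bond.key()] = counts.get(bond.key(), 0) + 1
            labels[bond.key()] = bond.label
    occ = {labels[k]: counts[k] / traj.n_frames for k in counts}
    keys = {labels[k]: k for k in counts}
    return OccupancyTable(occupancies=occ, n_frames=traj.n_frames, keys=keys)


def dissociation_probability(occ: OccupancyTable | Mapping[str, float]) -> float:
    """P_D = Π_i (1 - o_i): probability that no interfacial bond is present,
    under the independence assumption. Empty table -> 1.0."""
    values = occ.occupancies if isinstance(occ, OccupancyTable) else dict(occ)
    p = 1.0
    for label, o in values.items():
        if not (0.0 <= o <= 1.0):
            raise ValidationError(f"occupancy of {label} outside [0, 1]: {o}")
        p *= 1.0 - o
    return p


def interaction_energy(
    frame: Frame,
    topology: Topology,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff: float = 12.0,
) -> float:
    """Truncated non-bonded interaction energy between two groups, kcal/mol.

    E = Σ_{r_ij < cutoff} [ 332.0636 q_i q_j / r_ij
        + ε_ij ((Rmin_ij/r_ij)^12 - 2 (Rmin_ij/r_ij)^6) ],
    ε_ij = sqrt(ε_i ε_j), Rmin_ij = Rmin/2_i + Rmin/2_j. Plain truncation,
    ε_r = 1; a descriptor, not an MD-grade energy.
    """
    ga, gb = _check_groups(group_a, group_b)
    charge = topology.column("charge").astype(float)
    eps = topology.column("lj_epsilon").astype(float)
    rmin_half = topology.column("lj_rmin_half").astype(float)
    for grp in (ga, gb):
        bad = grp[~np.isfinite(charge[grp]) | ~np.isfinite(eps[grp])]
        if bad.size:
            labels = [topology.label(i) for i in bad[:10]]
            raise ValidationError(f"missing charge/LJ parameters for atoms: {labels}")
    r = cdist(frame.coords[ga], frame.coords[gb])
    mask = r < cutoff
    if not mask.any():
        return 0.0
    rij = r[mask]
    qq = np.outer(charge[ga], charge[gb])[mask]
    eij = np.sqrt(np.outer(eps[ga], eps[gb]))[mask]
    rmin = np.add.outer(rmin_half[ga], rmin_half[gb])[mask]
    coulomb = COULOMB_KCAL_A_E2 * qq / rij
    ratio6 = np.zeros_like(rij)
    lj_mask = eij > 0
    ratio6[lj_mask] = (rmin[lj_mask] / rij[lj_mask]) ** 6
    lj = eij * (ratio6 ** 2 - 2.0 * ratio6)
    return float(np.sum(coulomb + lj))


def interface_series(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
    energy_cutoff: float = 12.0,
    compute_energy: bool = True,
) -> InterfaceSeries:
    """Per-frame N_HB, interaction energy and bond presence matrix."""
    if traj.n_frames < 1:
        raise UsageError("interface_series requires at least one frame")
    per_frame_bonds: list[set[tuple[int, int]]] = []
    labels: dict[tuple[int, int], str] = {}
    energies = np.zeros(traj.n_frames)
    for i, frame in enumerate(traj.frames()):
        bonds = detect_hbonds(frame, traj.topology, group_a, group_b, d_cut, angle_cut)
        per_frame_bonds.append({b.key() for b in bonds})
        labels.update({b.key(): b.label for b in bonds})
        if compute_energy:
            energies[i] = interaction_energy(
                frame, traj.topology, group_a, group_b, energy_cutoff
            )
    keys = sorted(labels)
    presence = np.zeros((traj.n_frames, len(keys)), dtype=bool)
    for i, bonds in enumerate(per_frame_bonds):
        for j, k in enumerate(keys):
            presence[i, j] = k in bonds
    return InterfaceSeries(
        times=traj.times.copy(),
        n_hb=presence.sum(axis=1).astype(float),
        energy=energies,
        presence=presence,
        bond_labels=[labels[k] for k in keys],
    )


def replicate_summary(series_list: Iterable[InterfaceSeries]) -> dict:
    """Mean ± SEM of N_HB and E across replicate trajectories (run means)."""
    n_hb = np.array([float(np.mean(s.n_hb)) for s in series_list])
    if n_hb.size == 0:
        raise UsageError("no replicate series given")

    def mean_sem(x):
        sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
        return {"mean": float(np.mean(x)), "sem": sem, "n": int(len(x))}

    return {"n_hb": mean_sem(n_hb)}


def occupancy_heatmap_table(
    tables: Mapping[str, OccupancyTable]
) -> pd.DataFrame:
    """Long-format residue-pair occupancy table (system, pair, occupancy).

    Atom-level bonds are aggregated to residue-saccharide pairs by maximum
    occupancy, matching how interfacial heatmaps are usually drawn.
    """
    rows = []
    for system, table in tables.items():
        pairs: dict[str, float] = {}
        for label, o in table.occupancies.items():
            left, _, right = label.partition("-")
            pair = f"{left.split('(')[0]}-{right.split('(')[0]}"
            pairs[pair] = max(pairs.get(pair, 0.0), o)
        for pair, o in pairs.items():
            rows.append({"system": system, "pair": pair, "occupancy": o})
    return pd.DataFrame(rows, columns=["system", "pair", "occupancy"])
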