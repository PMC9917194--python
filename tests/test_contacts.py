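"""Hydrogen bonds, salt bridges, occupancy, P_D and interaction energy.

Detectors are checked against independent all-pairs brute-force oracles that
re-apply the geometric criteria with plain Python loops.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rampclamp.contacts import (
    H_COVALENT_CUTOFF,
    detect_hbonds,
    detect_salt_bridges,
    dissociation_probability,
    interaction_energy,
    interface_series,
    occupancy,
    occupancy_heatmap_table,
)
from rampclamp.errors import UsageError, ValidationError
from rampclamp.io import Frame, Topology, Trajectory
from rampclamp.synth import interface_bond_indices, make_telegraph_trajectory
from rampclamp.units import COULOMB_KCAL_A_E2

from conftest import frame_of, minimal_topology


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def hbond_oracle(frame, top, ga, gb, d_cut=3.5, angle_cut=30.0):
    """All-pairs re-derivation of the H-bond criteria (donor-heavy to
    acceptor distance, deviation angle at the donor over attributed Hs)."""
    coords = frame.coords
    donor = top.column("donor")
    acceptor = top.column("acceptor")
    element = top.column("element").astype(str)
    resid = top.column("resid")
    chain = top.column("chain")
    found = set()
    for dg, ag in ((ga, gb), (gb, ga)):
        for d in dg:
            if not donor[d]:
                continue
            for a in ag:
                if not acceptor[a]:
                    continue
                if np.linalg.norm(coords[d] - coords[a]) >= d_cut:
                    continue
                hs = [h for h in range(top.n_atoms)
                      if element[h] == "H" and resid[h] == resid[d]
                      and chain[h] == chain[d]
                      and np.linalg.norm(coords[h] - coords[d]) < H_COVALENT_CUTOFF]
                if not hs:
                    found.add((d, a))
                    continue
                for h in hs:
                    u = coords[h] - coords[d]
                    v = coords[a] - coords[d]
                    cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < angle_cut:
                        found.add((d, a))
                        break
    return found


def salt_bridge_oracle(frame, top, ga, gb, d_cut=4.0):
    coords = frame.coords
    names = top.column("name").astype(str)
    resnames = top.column("resname").astype(str)
    resid = top.column("resid")
    acid = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
    base = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
    found = set()
    for og, ng in ((ga, gb), (gb, ga)):
        for o in og:
            if names[o] not in acid.get(resnames[o], ()):
                continue
            for n in ng:
                if names[n] not in base.get(resnames[n], ()):
                    continue
                if np.linalg.norm(coords[o] - coords[n]) < d_cut:
                    found.add((f"{resnames[o]}{resid[o]}", f"{resnames[n]}{resid[n]}"))
    return found


def _hbond_topology(n, rng):
    """Random topology mixing donors, acceptors and hydrogens."""
    element = rng.choice(["C", "H", "O", "N"], size=n, p=[0.3, 0.3, 0.2, 0.2])
    donor = (element != "H") & (rng.random(n) < 0.5)
    acceptor = (element != "H") & (rng.random(n) < 0.5)
    return minimal_topology(
        n,
        element=list(element),
        donor=list(donor),
        acceptor=list(acceptor),
        resid=list(rng.integers(1, 8, size=n)),
    )


# ---------------------------------------------------------------------------
# H-bonds
# ---------------------------------------------------------------------------

def test_hbond_inside_both_cutoffs():
    top = minimal_topology(3, element=["O", "H", "N"],
                           donor=[True, False, False],
                           acceptor=[False, False, True],
                           resid=[1, 1, 2])
    # D at origin, A at 3.4 along x; H placed so the D-H/D-A angle is 20 deg
    h = 1.0 * np.array([np.cos(np.radians(20)), np.sin(np.radians(20)), 0.0])
    frame = frame_of([[0, 0, 0], h, [3.4, 0, 0]])
    bonds = detect_hbonds(frame, top, [0, 1], [2])
    assert len(bonds) == 1
    bond = next(iter(bonds))
    assert (bond.donor_heavy, bond.acceptor) == (0, 2)
    assert not bond.distance_only


def test_hbond_distance_exceeds_cutoff():
    top = minimal_topology(2, element=["O", "N"], donor=[True, False],
                           acceptor=[False, True], resid=[1, 2])
    frame = frame_of([[0, 0, 0], [3.6, 0, 0]])
    assert detect_hbonds(frame, top, [0], [1]) == set()


def test_hbond_angle_exceeds_cutoff():
    top = minimal_topology(3, element=["O", "H", "N"],
                           donor=[True, False, False],
                           acceptor=[False, False, True],
                           resid=[1, 1, 2])
    h = 1.0 * np.array([np.cos(np.radians(45)), np.sin(np.radians(45)), 0.0])
    frame = frame_of([[0, 0, 0], h, [3.4, 0, 0]])
    assert detect_hbonds(frame, top, [0, 1], [2]) == set()


def test_hbond_overlapping_groups_rejected(toy):
    top, frame, _ = toy
    with pytest.raises(UsageError):
        detect_hbonds(frame, top, [0, 1], [1, 2])


@pytest.mark.parametrize("seed", range(5))
def test_hbond_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    top = _hbond_topology(60, rng)
    split = 30
    ga, gb = np.arange(split), np.arange(split, 60)
    for _ in range(20):
        frame = frame_of(rng.uniform(0, 12, size=(60, 3)))
        got = {b.key() for b in detect_hbonds(frame, top, ga, gb)}
        assert got == hbond_oracle(frame, top, ga, gb)


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

def test_salt_bridge_inside_cutoff():
    top = minimal_topology(2, element=["O", "N"], name=["OE1", "NH1"],
                           resname=["GLU", "ARG"], resid=[52, 82])
    frame = frame_of([[0, 0, 0], [3.9, 0, 0]])
    assert detect_salt_bridges(frame, top, [0], [1]) == {("GLU52", "ARG82")}


def test_salt_bridge_boundary_is_strict():
    top = minimal_topology(2, element=["O", "N"], name=["OD1", "NZ"],
                           resname=["ASP", "LYS"], resid=[3, 7])
    frame = frame_of([[0, 0, 0], [4.0, 0, 0]])
    assert detect_salt_bridges(frame, top, [0], [1]) == set()


@pytest.mark.parametrize("seed", range(3))
def test_salt_bridge_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    n = 40
    resnames = list(rng.choice(["ASP", "GLU", "LYS", "ARG", "ALA"], size=n))
    names = []
    for r in resnames:
        pool = {"ASP": ["OD1", "OD2", "CB"], "GLU": ["OE1", "OE2", "CB"],
                "LYS": ["NZ", "CB"], "ARG": ["NE", "NH1", "NH2", "CB"],
                "ALA": ["CB"]}[r]
        names.append(str(rng.choice(pool)))
    top = minimal_topology(n, resname=resnames, name=names,
                           resid=list(rng.integers(1, 15, size=n)))
    ga, gb = np.arange(20), np.arange(20, n)
    for _ in range(20):
        frame = frame_of(rng.uniform(0, 10, size=(n, 3)))
        assert (detect_salt_bridges(frame, top, ga, gb)
                == salt_bridge_oracle(frame, top, ga, gb))


# ---------------------------------------------------------------------------
# occupancy and P_D
# ---------------------------------------------------------------------------

def _two_atom_bond_traj(presence):
    """Trajectory whose single bond is present exactly where ``presence``."""
    top = minimal_topology(2, element=["O", "N"], donor=[True, False],
                           acceptor=[False, True], resid=[1, 2],
                           chain=["A", "B"])
    coords = np.zeros((len(presence), 2, 3))
    coords[:, 1, 0] = np.where(presence, 3.0, 4.5)
    return top, Trajectory(top, coords, np.arange(len(presence), dtype=float))


def test_occupancy_exact_counting():
    presence = np.zeros(100, dtype=bool)
    presence[:40] = True
    top, traj = _two_atom_bond_traj(presence)
    table = occupancy(traj, [0], [1])
    assert list(table.occupancies.values()) == [0.40]
    assert table.n_frames == 100


def test_occupancy_always_present():
    top, traj = _two_atom_bond_traj(np.ones(100, dtype=bool))
    assert list(occupancy(traj, [0], [1]).occupancies.values()) == [1.0]


def test_occupancy_unbiased_on_telegraph(toy):
    """Stationary presence probability 0.7 recovered within 3 SE
    (SE inflated for telegraph autocorrelation)."""
    top, frame, _ = toy
    pairs = interface_bond_indices(top)
    o, tau_c, n = 0.7, 0.05, 10_000
    occs = [o] + [0.0] * (len(pairs) - 1)
    traj, _ = make_telegraph_trajectory(top, frame, pairs, occs, tau_c, n, seed=7)
    ga = np.flatnonzero(top.column("chain") == "B")
    gb = np.flatnonzero(top.column("chain") == "A")
    table = occupancy(traj, ga, gb)
    assert len(table.occupancies) == 1
    est = next(iter(table.occupancies.values()))
    rho = np.exp(-top.dt_ns / tau_c)
    se = np.sqrt(o * (1 - o) / n * (1 + rho) / (1 - rho))
    assert abs(est - o) < 3 * se


def test_occupancy_empty_trajectory_rejected(toy):
    top, frame, _ = toy
    with pytest.raises((UsageError, ValidationError)):
        occupancy(Trajectory(top, np.empty((0, top.n_atoms, 3)), np.empty(0)),
                  [0], [1])


def test_pd_examples():
    assert dissociation_probability({"a": 1.0, "b": 0.3}) == 0.0
    assert dissociation_probability({"a": 0.9, "b": 0.8, "c": 0.5}) == pytest.approx(0.01)
    assert dissociation_probability({}) == 1.0


def test_pd_invalid_occupancy_rejected():
    with pytest.raises(ValidationError):
        dissociation_probability({"a": 1.2})


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=0, max_size=8),
       st.floats(0, 1), st.floats(0, 0.5))
def test_pd_monotone_and_zero_bond_neutral(occs, o, delta):
    """P_D never increases when any occupancy grows; o=0 bonds are neutral."""
    base = {f"b{i}": v for i, v in enumerate(occs)}
    p = dissociation_probability(base)
    assert dissociation_probability({**base, "new": 0.0}) == pytest.approx(p)
    bumped = dict(base)
    bumped["extra"] = min(1.0, o + delta)
    assert dissociation_probability(bumped) <= dissociation_probability(
        {**base, "extra": o}) + 1e-12


def test_pd_matches_monte_carlo_zero_bond_frequency(toy):
    """Product rule equals the zero-bond frame frequency of the independence
    model (5 telegraph bonds, moderate n here; the full-scale check runs in
    the acceptance suite)."""
    top, frame, _ = toy
    pairs = interface_bond_indices(top)
    occs = [0.9, 0.8, 0.5, 0.6, 0.7, 0.0, 0.0]
    traj, truth = make_telegraph_trajectory(top, frame, pairs, occs, 0.05,
                                            20_000, seed=11)
    ga = np.flatnonzero(top.column("chain") == "B")
    gb = np.flatnonzero(top.column("chain") == "A")
    series = interface_series(traj, ga, gb, compute_energy=False)
    mc = float(np.mean(series.n_hb == 0))
    p = truth.parameters["p_dissociation"]
    rho = np.exp(-top.dt_ns / 0.05)
    se = np.sqrt(p * (1 - p) / traj.n_frames * (1 + rho) / (1 - rho))
    assert abs(mc - p) < 3 * se


# ---------------------------------------------------------------------------
# interaction energy
# ---------------------------------------------------------------------------

def energy_oracle(frame, top, ga, gb, cutoff=12.0):
    coords = frame.coords
    q = top.column("charge")
    eps = top.column("lj_epsilon")
    rmin = top.column("lj_rmin_half")
    total = 0.0
    for i in ga:
        for j in gb:
            r = np.linalg.norm(coords[i] - coords[j])
            if r >= cutoff:
                continue
            total += COULOMB_KCAL_A_E2 * q[i] * q[j] / r
            e = np.sqrt(eps[i] * eps[j])
            if e > 0:
                ratio = (rmin[i] + rmin[j]) / r
                total += e * (ratio ** 12 - 2 * ratio ** 6)
    return total


def test_energy_coulomb_reference_value():
    top = minimal_topology(2, charge=[1.0, -1.0])
    frame = frame_of([[0, 0, 0], [3.320636, 0, 0]])
    assert interaction_energy(frame, top, [0], [1]) == pytest.approx(-100.0, rel=1e-6)


def test_energy_zero_beyond_cutoff():
    top = minimal_topology(2, charge=[1.0, -1.0])
    frame = frame_of([[0, 0, 0], [12.5, 0, 0]])
    assert interaction_energy(frame, top, [0], [1]) == 0.0


@pytest.mark.parametrize("seed", range(3))
def test_energy_matches_oracle_symmetry_additivity(seed):
    rng = np.random.default_rng(200 + seed)
    n = 30
    top = minimal_topology(
        n, charge=list(rng.normal(0, 0.4, n)),
        lj_epsilon=list(rng.uniform(0.01, 0.3, n)),
        lj_rmin_half=list(rng.uniform(1.5, 2.5, n)),
    )
    frame = frame_of(rng.uniform(0, 14, size=(n, 3)))
    ga, gb = np.arange(12), np.arange(12, n)
    e = interaction_energy(frame, top, ga, gb)
    assert e == pytest.approx(energy_oracle(frame, top, ga, gb), rel=1e-9)
    assert e == pytest.approx(interaction_energy(frame, top, gb, ga), rel=1e-9)
    gb1, gb2 = gb[:9], gb[9:]
    assert e == pytest.approx(
        interaction_energy(frame, top, ga, gb1)
        + interaction_energy(frame, top, ga, gb2), rel=1e-9)


def test_energy_missing_parameters_listed():
    top = minimal_topology(2, charge=[np.nan, 0.1])
    frame = frame_of([[0, 0, 0], [3, 0, 0]])
    with pytest.raises(ValidationError, match="RES1"):
        interaction_energy(frame, top, [0], [1])


# ---------------------------------------------------------------------------
# interface series
# ---------------------------------------------------------------------------

def test_nhb_equals_presence_row_sums(toy):
    top, frame, _ = toy
    pairs = interface_bond_indices(top)
    traj, _ = make_telegraph_trajectory(top, frame, pairs,
                                        [0.5] * len(pairs), 0.05, 300, seed=2)
    ga = np.flatnonzero(top.column("chain") == "B")
    gb = np.flatnonzero(top.column("chain") == "A")
    series = interface_series(traj, ga, gb, compute_energy=False)
    assert (series.n_hb == series.presence.sum(axis=1)).all()


def test_mean_nhb_matches_planted_occupancy_sum(toy):
    """Planted mean bond count 5.8 recovered within 3 SE."""
    top, frame, _ = toy
    occs = [0.9, 0.9, 0.9, 0.8, 0.8, 0.8, 0.7]  # sums to 5.8
    pairs = interface_bond_indices(top)
    tau_c, n = 0.05, 8000
    traj, _ = make_telegraph_trajectory(top, frame, pairs, occs, tau_c, n, seed=5)
    ga = np.flatnonzero(top.column("chain") == "B")
    gb = np.flatnonzero(top.column("chain") == "A")
    series = interface_series(traj, ga, gb, compute_energy=False)
    rho = np.exp(-top.dt_ns / tau_c)
    var = np.sum([o * (1 - o) for o in occs]) / n * (1 + rho) / (1 - rho)
    assert abs(np.mean(series.n_hb) - 5.8) < 3 * np.sqrt(var)


def test_heatmap_table_aggregates_by_max(toy):
    top, frame, _ = toy
    pairs = interface_bond_indices(top)
    traj, _ = make_telegraph_trajectory(top, frame, pairs,
                                        [0.6] * len(pairs), 0.05, 200, seed=3)
    ga = np.flatnonzero(top.column("chain") == "B")
    gb = np.flatnonzero(top.column("chain") == "A")
    table = occupancy(traj, ga, gb)
    long = occupancy_heatmap_table({"S2": table})
    assert set(long.columns) == {"system", "pair", "occupancy"}
    assert (long["occupancy"] <= 1).all() and (long["occupancy"] >= 0).all()
    assert long["pair"].str.contains("-").all()
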