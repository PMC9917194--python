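"""Conformational descriptors.

Least-squares superposition (Kabsch), RMSD time courses, per-residue RMSF,
Shrake-Rupley solvent-accessible surface area (SASA), buried interface SASA,
and the binding-pocket geometry descriptors: cross angle φ at the pocket
vertex, ligand bend angle θ with a reflex (0, 360)° convention, and the
pocket-mouth distance l.

Bend-angle convention: let a ∈ [0, 180] be the planar angle at the middle
atom of the three chain markers. θ = a when the middle atom bows toward the
supplied reference point (chain convex toward the receptor), else
θ = 360 - a. A collinear chain gives exactly 180°. This makes concave vs
convex chain shapes distinguishable in a single scalar.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError
from .io import Frame, Topology, Trajectory
from .select import select_atoms

#: van der Waals radii (Å) used for SASA; LJ Rmin/2 is the fallback.
VDW_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "F": 1.47, "CL": 1.75,
}


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------

def superpose(
    mobile: Frame | np.ndarray,
    reference: Frame | np.ndarray,
    fit_selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition (Kabsch).

    Returns (rotation R, translation t, rmsd) such that mobile @ R.T + t best
    matches reference over ``fit_selection``; R is a proper rotation
    (det = +1) and rmsd is evaluated over the fit selection after transform.
    """
    x = mobile.coords if isinstance(mobile, Frame) else np.asarray(mobile, float)
    y = reference.coords if isinstance(reference, Frame) else np.asarray(reference, float)
    idx = np.arange(len(x)) if fit_selection is None else np.asarray(fit_selection, int)
    if idx.size < 3:
        raise UsageError("superposition requires at least 3 fit atoms")
    xs, ys = x[idx], y[idx]
    xc, yc = xs.mean(axis=0), ys.mean(axis=0)
    x0, y0 = xs - xc, ys - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise UsageError("fit atoms are collinear; superposition is degenerate")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = yc - rot @ xc
    moved = x0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y0) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def rmsd_timecourse(
    traj: Trajectory,
    fit_selection: Sequence[int] | str,
    measure_selection: Sequence[int] | str | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) vs the first frame, after superposing each frame on
    the reference over ``fit_selection``; measured over ``measure_selection``
    (defaults to the fit selection)."""
    fit = _resolve(traj.topology, fit_selection)
    measure = fit if measure_selection is None else _resolve(traj.topology, measure_selection)
    if fit.size == 0 or measure.size == 0:
        raise UsageError("selections must be non-empty")
    ref = traj.coords[0]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rot, trans, _ = superpose(traj.coords[i], ref, fit)
        moved = apply_transform(traj.coords[i][measure], rot, trans)
        out[i] = np.sqrt(np.mean(np.sum((moved - ref[measure]) ** 2, axis=1)))
    return out


def rmsf_per_residue(
    traj: Trajectory,
    selection: Sequence[int] | str,
    fit_selection: Sequence[int] | str | None = None,
) -> pd.Series:
    """Per-residue RMSF (Å): per-atom sqrt(<|x - <x>|²>) over frames, averaged
    over each residue's selected atoms. If ``fit_selection`` is given, every
    frame is first superposed on the first frame over that selection."""
    sel = _resolve(traj.topology, selection)
    if sel.size == 0:
        raise UsageError("RMSF selection is empty")
    if traj.n_frames < 2:
        raise UsageError("RMSF requires at least 2 frames")
    coords = traj.coords
    if fit_selection is not None:
        fit = _resolve(traj.topology, fit_selection)
        ref = coords[0]
        aligned = np.empty_like(coords)
        for i in range(traj.n_frames):
            rot, trans, _ = superpose(coords[i], ref, fit)
            aligned[i] = apply_transform(coords[i], rot, trans)
        coords = aligned
    x = coords[:, sel, :]
    mean = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    resid = traj.topology.column("resid")[sel]
    return pd.Series(per_atom).groupby(pd.Series(resid)).mean().rename("rmsf_A")


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def atom_radii(topology: Topology, indices: np.ndarray) -> np.ndarray:
    elements = topology.column("element").astype(str)
    rmin_half = topology.column("lj_rmin_half").astype(float)
    eps = topology.column("lj_epsilon").astype(float)
    radii = np.empty(indices.size)
    for k, i in enumerate(indices):
        el = elements[i].upper()
        if el in VDW_RADII:
            radii[k] = VDW_RADII[el]
        elif eps[i] > 0 and rmin_half[i] > 0:
            radii[k] = rmin_half[i]
        else:
            raise ValidationError(
                f"no van der Waals radius for atom {topology.label(int(i))} "
                f"(element {elements[i]!r}, no LJ fallback)"
            )
    return radii


def sasa(
    frame: Frame,
    topology: Topology,
    selection: Sequence[int] | str | None = None,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    environment: Sequence[int] | str | None = None,
) -> float:
    """Shrake-Rupley SASA (Å²) of the selected atoms.

    Only the selected atoms (plus optional occluding ``environment`` atoms,
    which contribute no area) are considered present; deterministic for a
    fixed point count.
    """
    sel = (
        np.arange(topology.n_atoms)
        if selection is None
        else _resolve(topology, selection)
    )
    if sel.size == 0:
        raise UsageError("SASA selection is empty")
    env = np.array([], dtype=int) if environment is None else _resolve(topology, environment)
    present = np.concatenate([sel, env])
    coords = frame.coords[present]
    radii = atom_radii(topology, present) + probe
    points = _sphere_points(n_sphere_points)
    total = 0.0
    n_sel = sel.size
    for k in range(n_sel):
        shell = coords[k] + radii[k] * points
        accessible = np.ones(n_sphere_points, dtype=bool)
        d2 = np.sum((coords - coords[k]) ** 2, axis=1)
        near = np.flatnonzero((d2 < (radii + radii[k]) ** 2) & (d2 > 0))
        for j in near:
            accessible &= np.sum((shell - coords[j]) ** 2, axis=1) >= radii[j] ** 2
            if not accessible.any():
                break
        total += 4.0 * np.pi * radii[k] ** 2 * accessible.sum() / n_sphere_points
    return float(total)


def buried_sasa(
    frame: Frame,
    topology: Topology,
    group_a: Sequence[int] | str,
    group_b: Sequence[int] | str,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Interface area: SASA(A) + SASA(B) - SASA(A ∪ B), not halved (total
    buried area over both partners). Non-negative up to sampling error."""
    ga = _resolve(topology, group_a)
    gb = _resolve(topology, group_b)
    if np.intersect1d(ga, gb).size:
        raise UsageError("groups overlap; buried SASA requires disjoint groups")
    args = dict(probe=probe, n_sphere_points=n_sphere_points)
    sa = sasa(frame, topology, ga, **args)
    sb = sasa(frame, topology, gb, **args)
    sab = sasa(frame, topology, np.concatenate([ga, gb]), **args)
    return sa + sb - sab


# ---------------------------------------------------------------------------
# Pocket geometry
# ---------------------------------------------------------------------------

DEFAULT_VERTEX = "resid 46 and name CA"     # Tyr46 Cα (pocket vertex)
DEFAULT_ARM_A = "resid 155 and name CA"     # Arg155 Cα
DEFAULT_ARM_B = "resid 100 and name CA"     # Ile100 Cα
DEFAULT_BEND_MIDDLE = "resid 1178 and name C2"
DEFAULT_BEND_END_A = "resid 1175 and name C2"
DEFAULT_BEND_END_B = "resid 1181 and name C2"


def _single_atom(topology: Topology, query) -> int:
    idx = _resolve(topology, query)
    if idx.size != 1:
        raise UsageError(f"selection {query!r} resolves to {idx.size} atoms, expected 1")
    return int(idx[0])


def _planar_angle(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise UsageError("degenerate geometry: coincident points")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def cross_angle(
    frame: Frame,
    topology: Topology,
    vertex: Sequence[int] | str = DEFAULT_VERTEX,
    arm_a: Sequence[int] | str = DEFAULT_ARM_A,
    arm_b: Sequence[int] | str = DEFAULT_ARM_B,
) -> float:
    """Planar cross angle φ ∈ [0, 180]° at the pocket vertex."""
    v = _single_atom(topology, vertex)
    a = _single_atom(topology, arm_a)
    b = _single_atom(topology, arm_b)
    return _planar_angle(frame.coords[v], frame.coords[a], frame.coords[b])


def bend_angle(
    frame: Frame,
    topology: Topology,
    reference_point: np.ndarray,
    middle: Sequence[int] | str = DEFAULT_BEND_MIDDLE,
    end_a: Sequence[int] | str = DEFAULT_BEND_END_A,
    end_b: Sequence[int] | str = DEFAULT_BEND_END_B,
) -> float:
    """Chain bend angle θ ∈ (0, 360)° with the reflex convention above."""
    m = frame.coords[_single_atom(topology, middle)]
    a = frame.coords[_single_atom(topology, end_a)]
    b = frame.coords[_single_atom(topology, end_b)]
    ref = np.asarray(reference_point, float)
    angle = _planar_angle(m, a, b)
    axis = b - a
    norm2 = axis @ axis
    if norm2 < 1e-18:
        raise UsageError("degenerate geometry: chain ends coincide")
    # components of middle/reference perpendicular to the end-to-end axis
    def perp(p):
        w = p - a
        return w - (w @ axis) / norm2 * axis

    pm, pr = perp(m), perp(ref)
    if np.linalg.norm(pm) < 1e-9:
        return 180.0  # collinear chain
    same_side = (pm @ pr) > 0.0
    return angle if same_side else 360.0 - angle


def pocket_distance(
    frame: Frame,
    topology: Topology,
    atom_a: Sequence[int] | str = DEFAULT_ARM_A,
    atom_b: Sequence[int] | str = DEFAULT_ARM_B,
) -> float:
    """Euclidean pocket-mouth distance l (Å)."""
    a = _single_atom(topology, atom_a)
    b = _single_atom(topology, atom_b)
    return float(np.linalg.norm(frame.coords[a] - frame.coords[b]))


def geometry_report(
    traj: Trajectory,
    binding_site: Sequence[int] | str,
    ligand: Sequence[int] | str,
    reference_point: np.ndarray | None = None,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    **angle_selections,
) -> pd.DataFrame:
    """Per-frame φ, θ, l, binding-site SASA and buried SASA."""
    top = traj.topology
    site = _resolve(top, binding_site)
    lig = _resolve(top, ligand)
    if reference_point is None:
        reference_point = traj.coords[0][site].mean(axis=0)
    rows = []
    for frame in traj.frames():
        rows.append({
            "time_ns": frame.time,
            "phi_deg": cross_angle(frame, top,
                                   **{k: v for k, v in angle_selections.items()
                                      if k in ("vertex", "arm_a", "arm_b")}),
            "theta_deg": bend_angle(frame, top, reference_point,
                                    **{k: v for k, v in angle_selections.items()
                                       if k in ("middle", "end_a", "end_b")}),
            "l_A": pocket_distance(frame, top),
            "site_sasa_A2": sasa(frame, top, site, probe, n_sphere_points),
            "buried_sasa_A2": buried_sasa(frame, top, site, lig, probe, n_sphere_points),
        })
    return pd.DataFrame(rows)


def _resolve(topology: Topology, selection) -> np.ndarray:
    if isinstance(selection, str):
        return select_atoms(topology, selection)
    return np.asarray(selection, dtype=int)
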