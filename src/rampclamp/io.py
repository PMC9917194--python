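"""On-disk representations and in-memory containers.

Trajectories travel as multi-model PDB (text) with a tab-separated topology
sidecar keyed by atom order; force logs and AFM curves are tab-separated
tables with ``# key\tvalue`` metadata header lines. All value columns are
plain decimal text so round-trips are exact at the declared precision
(PDB coordinates: 3 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, StructuralError, UsageError, ValidationError

TOPOLOGY_COLUMNS = [
    "serial", "name", "resname", "resid", "chain", "element",
    "charge", "lj_epsilon", "lj_rmin_half", "donor", "acceptor", "fixed",
]

FORCELOG_COLUMNS = ["time_ns", "force_pN", "dummy_A", "steered_A", "phase"]
AFM_COLUMNS = ["piezo_nm", "force_pN", "phase"]
AFM_PHASES = ("approach", "dwell", "retract")


# ---------------------------------------------------------------------------
# Topology / Frame / Trajectory
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom identity plus force-field-style parameters and role flags.

    ``atoms`` is a DataFrame with :data:`TOPOLOGY_COLUMNS`; row order defines
    atom order and must match the coordinate order of any associated frames.
    ``metadata`` holds sidecar key/values, notably ``dt_ns`` (frame spacing
    used when a trajectory file carries no explicit times).
    """

    atoms: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValidationError(f"topology missing columns: {missing}")
        extras = [c for c in self.atoms.columns if c not in TOPOLOGY_COLUMNS]
        self.atoms = self.atoms[TOPOLOGY_COLUMNS + extras].reset_index(drop=True)
        serials = self.atoms["serial"].to_numpy()
        if len(np.unique(serials)) != len(serials):
            raise ValidationError("atom serials are not unique")
        eps = self.atoms["lj_epsilon"].to_numpy(float)
        rmin = self.atoms["lj_rmin_half"].to_numpy(float)
        if np.any(eps < 0):
            raise ValidationError("lj_epsilon must be >= 0")
        if np.any((eps > 0) & ~(rmin > 0)):
            raise ValidationError("lj_rmin_half must be > 0 where lj_epsilon > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def dt_ns(self) -> float:
        return float(self.metadata.get("dt_ns", 1.0))

    def column(self, name: str) -> np.ndarray:
        # cached: analysis loops hit these arrays once per frame
        cache = self.__dict__.setdefault("_column_cache", {})
        if name not in cache:
            cache[name] = self.atoms[name].to_numpy()
        return cache[name]

    def label(self, index: int) -> str:
        """Human-readable atom label, e.g. ``GlcUA1178(C2)``."""
        row = self.atoms.iloc[index]
        return f"{row['resname']}{row['resid']}({row['name']})"


@dataclass
class Frame:
    """One trajectory frame: a time stamp (ns) and (n_atoms, 3) coordinates in Å."""

    time: float
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology.

    Coordinates are stored as one (n_frames, n_atoms, 3) array for vectorised
    analysis; :meth:`frames` iterates Frame views.
    """

    topology: Topology
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("trajectory coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructuralError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValidationError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coords=self.coords[i])

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_frames(cls, topology: Topology, frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise UsageError("cannot build a trajectory from zero frames")
        coords = np.stack([f.coords for f in frames])
        times = np.array([f.time for f in frames])
        return cls(topology, coords, times)


# ---------------------------------------------------------------------------
# Topology sidecar TSV
# ---------------------------------------------------------------------------

def _read_metadata_lines(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "\t" in body:
                key, value = body.split("\t", 1)
            elif "=" in body:
                key, value = body.split("=", 1)
            else:
                continue
            key, value = key.strip(), value.strip()
            try:
                meta[key] = float(value)
            except ValueError:
                meta[key] = value
    return meta


def write_topology(topology: Topology, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in topology.metadata.items():
            fh.write(f"# {key}\t{value}\n")
        topology.atoms.to_csv(fh, sep="\t", index=False, columns=TOPOLOGY_COLUMNS)


def read_topology(path) -> Topology:
    path = Path(path)
    meta = _read_metadata_lines(path)
    try:
        atoms = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse topology table {path}: {exc}") from exc
    missing = [c for c in TOPOLOGY_COLUMNS if c not in atoms.columns]
    if missing:
        raise FormatError(f"topology {path} missing required columns {missing}")
    for flag in ("donor", "acceptor", "fixed"):
        atoms[flag] = atoms[flag].astype(bool)
    return Topology(atoms=atoms, metadata=meta)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> list[int]:
    """Validate ATOM/HETATM records and return per-model atom counts.

    Supplies the line-numbered format errors and model-numbered structural
    errors that the downstream parser does not report.
    """
    counts: list[int] = []
    current = 0
    saw_model_records = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model_records = True
                current = 0
            elif record == "ENDMDL":
                counts.append(current)
                current = 0
            elif record in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(
                        f"truncated {record} record at line {lineno}", line=lineno
                    )
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise FormatError(
                        f"unparsable {record} record at line {lineno}: {exc}",
                        line=lineno,
                    ) from exc
                current += 1
    if not saw_model_records:
        counts = [current]
    elif current > 0:  # trailing MODEL without ENDMDL
        counts.append(current)
    if not counts or counts[0] == 0:
        raise FormatError(f"{path} contains no ATOM/HETATM records")
    first = counts[0]
    for model_index, n in enumerate(counts, start=1):
        if n != first:
            raise StructuralError(
                f"model {model_index} has {n} atoms, expected {first}"
            )
    return counts


def read_trajectory(pdb_path, topology_path) -> Trajectory:
    """Read a multi-model PDB plus its topology sidecar.

    Atom order is the file order; frame times are ``index × dt_ns`` from the
    sidecar metadata (``dt_ns`` defaults to 1.0).
    """
    pdb_path = Path(pdb_path)
    topology = read_topology(topology_path)
    counts = _prescan_pdb(pdb_path)
    if counts[0] != topology.n_atoms:
        raise StructuralError(
            f"PDB atom count {counts[0]} does not match topology atom count "
            f"{topology.n_atoms}"
        )
    pdb = PDBFile.read(str(pdb_path))
    structure = pdb.get_structure()  # AtomArrayStack, shape (models, atoms)
    coords = np.asarray(structure.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    times = np.arange(coords.shape[0], dtype=float) * topology.dt_ns
    return Trajectory(topology=topology, coords=coords, times=times)


#: sugar names mapped to standard 3-character PDB ligand codes on write;
#: atom identity always comes from the sidecar, so reading needs no inverse.
PDB_RESNAME_CODES = {"GlcNAc": "NAG", "GlcUA": "BDP"}


def write_trajectory(traj: Trajectory, pdb_path, topology_path=None) -> None:
    """Write a multi-model PDB (and optionally the topology sidecar)."""
    top = traj.topology
    n_atoms = top.n_atoms
    resnames = np.asarray(
        [PDB_RESNAME_CODES.get(r, str(r)[:3]) for r in top.column("resname")],
        dtype="U3",
    )
    template = AtomArray(n_atoms)
    template.coord = np.zeros((n_atoms, 3))
    template.chain_id = np.asarray(top.column("chain"), dtype="U4")
    template.res_id = np.asarray(top.column("resid"), dtype=int)
    template.res_name = resnames
    template.atom_name = np.asarray(top.column("name"), dtype="U6")
    template.element = np.asarray(top.column("element"), dtype="U2")
    template.hetero = np.zeros(n_atoms, dtype=bool)
    stack = AtomArrayStack(traj.n_frames, n_atoms)
    for category in template.get_annotation_categories():
        stack.set_annotation(category, template.get_annotation(category))
    stack.coord = np.asarray(traj.coords, dtype=float)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    if topology_path is not None:
        write_topology(top, topology_path)


# ---------------------------------------------------------------------------
# Force logs
# ---------------------------------------------------------------------------

@dataclass
class ForceLog:
    """Time series of applied tensile force during a ramp-clamp run.

    Columns: time_ns, force_pN, dummy_A, steered_A, phase ('ramp'|'clamp').
    The dummy/steered columns are positions projected on the pulling axis and
    are physically meaningful only during the ramp phase.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in FORCELOG_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"force log missing required columns {missing}")
        self.data = self.data.reset_index(drop=True)
        t = self.data["time_ns"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("force-log times must be strictly increasing")
        phases = self.data["phase"].to_numpy()
        bad = set(phases) - {"ramp", "clamp"}
        if bad:
            raise ValidationError(f"unknown force-log phases: {sorted(bad)}")
        switches = np.sum(phases[1:] != phases[:-1]) if len(phases) > 1 else 0
        if switches > 1 or (switches == 1 and phases[0] != "ramp"):
            raise ValidationError("phase may transition at most once, from ramp to clamp")

    @property
    def times(self) -> np.ndarray:
        return self.data["time_ns"].to_numpy(float)

    @property
    def forces(self) -> np.ndarray:
        return self.data["force_pN"].to_numpy(float)


def write_force_log(log: ForceLog, path) -> None:
    with open(path, "w") as fh:
        for key, value in log.metadata.items():
            fh.write(f"# {key}\t{value}\n")
        log.data.to_csv(fh, sep="\t", index=False)


def read_force_log(path) -> ForceLog:
    path = Path(path)
    meta = _read_metadata_lines(path)
    data = pd.read_csv(path, sep="\t", comment="#")
    return ForceLog(data=data, metadata=meta)


# ---------------------------------------------------------------------------
# AFM curves
# ---------------------------------------------------------------------------

@dataclass
class AFMCurve:
    """Piezo displacement vs force with approach/dwell/retract phases.

    Units are nm and pN (the AFM layer's native units). Retract-phase
    adhesion tension is stored as a positive excursion above baseline.
    Metadata keys commonly present: retract_speed_nm_s, dwell_ms,
    clamp_setpoint_pN.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in AFM_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"AFM curve missing required columns {missing}")
        self.data = self.data.reset_index(drop=True)
        phases = self.data["phase"].to_numpy()
        bad = set(phases) - set(AFM_PHASES)
        if bad:
            raise ValidationError(f"unknown AFM phases: {sorted(bad)}")
        # phases must form contiguous blocks in approach -> dwell -> retract order
        order = []
        for p in phases:
            if not order or order[-1] != p:
                order.append(p)
        expected = [p for p in AFM_PHASES if p in order]
        if order != expected:
            raise ValidationError(
                f"AFM phases out of order: saw {order}, expected subsequence of "
                f"{list(AFM_PHASES)}"
            )
        z = self.data["piezo_nm"].to_numpy(float)
        for name, sign in (("approach", 1.0), ("retract", -1.0)):
            mask = phases == name
            if np.sum(mask) > 1:
                dz = np.diff(z[mask]) * sign
                if np.any(dz < 0):
                    raise ValidationError(
                        f"piezo displacement not monotone within {name} phase"
                    )

    def phase(self, name: str) -> pd.DataFrame:
        return self.data[self.data["phase"] == name]


def write_afm_curve(curve: AFMCurve, path) -> None:
    with open(path, "w") as fh:
        for key, value in curve.metadata.items():
            fh.write(f"# {key}\t{value}\n")
        curve.data.to_csv(fh, sep="\t", index=False)


def read_afm_curve(path) -> AFMCurve:
    path = Path(path)
    meta = _read_metadata_lines(path)
    data = pd.read_csv(path, sep="\t", comment="#")
    return AFMCurve(data=data, metadata=meta)
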