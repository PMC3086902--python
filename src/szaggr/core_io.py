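"""Data model, multi-model PDB trajectory I/O, and unit conventions.

Internal units are nm / ps / kJ/mol throughout the package (GROMACS
convention); PDB coordinates in Angstrom are converted on read and write.
Chains are identified by their PDB chain ID, frames are indexed 0-based
internally.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import kabsch_superpose

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "ReferenceDimer",
    "TopologyReport",
    "TrajectoryError",
    "TopologyError",
    "read_trajectory",
    "write_trajectory",
    "validate_topology",
    "build_reference_dimer",
    "molar_concentration_mM",
    "total_sampling_us",
    "AA3_TO_1",
    "ELEMENT_MASSES",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

BACKBONE_NAMES = ("N", "CA", "C", "O")


class TrajectoryError(ValueError):
    pass


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position in nm."""
    chain_id: str
    residue_index: int  # 1-based within its chain
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be non-empty")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


class Topology:
    """Array-backed per-atom identity shared by all frames of a trajectory."""

    def __init__(self, chain_ids, atom_chain, atom_resid, atom_resname,
                 atom_name, element):
        self.chain_ids: tuple[str, ...] = tuple(chain_ids)
        self.atom_chain = np.asarray(atom_chain, dtype=int)
        self.atom_resid = np.asarray(atom_resid, dtype=int)
        self.atom_resname = np.asarray(atom_resname, dtype="U4")
        self.atom_name = np.asarray(atom_name, dtype="U5")
        self.element = np.asarray(element, dtype="U2")
        self._index = {
            (int(c), int(r), str(n)): i
            for i, (c, r, n) in enumerate(
                zip(self.atom_chain, self.atom_resid, self.atom_name))
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atom_chain)

    @property
    def n_chains(self) -> int:
        return len(self.chain_ids)

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def chain_index(self, chain_id: str) -> int:
        return self.chain_ids.index(chain_id)

    def chain_atoms(self, ci: int) -> np.ndarray:
        return np.flatnonzero(self.atom_chain == ci)

    def chain_length(self, ci: int) -> int:
        sel = self.atom_chain == ci
        return int(self.atom_resid[sel].max())

    def sequence(self, ci: int) -> str:
        """1-letter sequence of one chain."""
        sel = self.atom_chain == ci
        resids = self.atom_resid[sel]
        resnames = self.atom_resname[sel]
        seq = {}
        for r, rn in zip(resids, resnames):
            if rn not in AA3_TO_1:
                raise TopologyError(f"unknown residue {rn!r} in chain "
                                    f"{self.chain_ids[ci]!r} residue {r}")
            seq[int(r)] = AA3_TO_1[rn]
        return "".join(seq[r] for r in sorted(seq))

    def index_of(self, ci: int, resid: int, atom_name: str) -> int:
        """Atom index or -1 if absent."""
        return self._index.get((int(ci), int(resid), atom_name), -1)

    def backbone_indices(self, atom_names=("N", "CA", "C", "O", "H")) -> np.ndarray:
        """(n_chains, L, len(atom_names)) atom indices; -1 where absent.

        Requires equal chain lengths (validated trajectories).
        """
        L = self.chain_length(0)
        out = np.full((self.n_chains, L, len(atom_names)), -1, dtype=int)
        for ci in range(self.n_chains):
            for r in range(1, L + 1):
                for k, nm in enumerate(atom_names):
                    out[ci, r - 1, k] = self.index_of(ci, r, nm)
        return out


@dataclass
class Frame:
    """One time sample: coordinates (nm), time (ps) and cubic box edges (nm)."""
    time: float
    box: np.ndarray | None
    coords: np.ndarray
    topology: Topology

    def atoms(self):
        t = self.topology
        for i in range(t.n_atoms):
            yield AtomRecord(t.chain_ids[t.atom_chain[i]], int(t.atom_resid[i]),
                             str(t.atom_resname[i]), str(t.atom_name[i]),
                             str(t.element[i]), self.coords[i])


@dataclass
class Trajectory:
    topology: Topology
    coords: np.ndarray          # (n_frames, n_atoms, 3) nm
    times: np.ndarray           # (n_frames,) ps
    box: np.ndarray | None      # (n_frames, 3) nm edge lengths, or None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise TrajectoryError("times and coords disagree on frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def dt(self) -> float:
        if "dt" in self.metadata:
            return float(self.metadata["dt"])
        if self.n_frames > 1:
            return float(np.median(np.diff(self.times)))
        return 0.0

    def frame(self, i: int) -> Frame:
        box = None if self.box is None else self.box[i]
        return Frame(float(self.times[i]), box, self.coords[i], self.topology)


@dataclass
class TopologyReport:
    ok: bool
    messages: list[str]
    h_reconstructable: list[tuple[str, int]]  # (chain_id, resid) lacking amide H


@dataclass
class ReferenceDimer:
    """Ideal two-stranded beta-sheet dimer used as superposition reference.

    Built from ideal strand geometry; stands in for the crystal-packing
    dimer when experimental coordinates are not supplied.
    """
    label: str                      # parallel_in_register | antiparallel_in_register
    trajectory: Trajectory          # single frame, two chains, full atom set

    def mainchain_coords(self) -> np.ndarray:
        """(2, 4L, 3) N/CA/C/O coordinates of both chains, residue-major."""
        top = self.trajectory.topology
        bb = top.backbone_indices(BACKBONE_NAMES)
        xyz = self.trajectory.coords[0]
        return np.stack([xyz[bb[ci].reshape(-1)] for ci in range(2)])

    def chain_coords(self, ci: int) -> np.ndarray:
        top = self.trajectory.topology
        return self.trajectory.coords[0][top.chain_atoms(ci)]


# ---------------------------------------------------------------------------
# unit bookkeeping

AVOGADRO = 6.02214076e23


def molar_concentration_mM(n_molecules: int, volume_nm3: float) -> float:
    """Molar concentration in mM of n molecules in a volume given in nm^3."""
    litres = volume_nm3 * 1e-24
    return n_molecules / (AVOGADRO * litres) * 1e3


def total_sampling_us(n_systems: int, runs_per_system: int, ns_per_run: float) -> float:
    """Aggregate simulated time in microseconds across systems and replicas."""
    return n_systems * runs_per_system * ns_per_run * 1e-3


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)

def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    return name[0].upper()


def read_trajectory(path, dt: float = 2.5, dialect: str = "pdb") -> Trajectory:
    """Read a multi-model PDB trajectory; coordinates converted A -> nm.

    ``dt`` (ps) spaces the frames since the PDB format carries no time axis.
    """
    if dialect != "pdb":
        raise NotImplementedError(f"dialect {dialect!r} not supported; use 'pdb'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise TrajectoryError(f"{path}: no MODEL records")
    try:
        stack = pdb.get_structure(model=None)
    except Exception:
        # diagnose which frame has a deviating atom count
        first = pdb.get_structure(model=1)
        for m in range(2, n_models + 1):
            arr = pdb.get_structure(model=m)
            if arr.array_length() != first.array_length():
                raise TrajectoryError(
                    f"{path}: frame {m} has {arr.array_length()} atoms, "
                    f"expected {first.array_length()}") from None
        raise

    chain_col = np.asarray(stack.chain_id, dtype="U4")
    if np.any(chain_col == "") or np.any(chain_col == " "):
        raise TrajectoryError(f"{path}: missing chain IDs")

    elements = np.asarray(stack.element, dtype="U2")
    names = np.asarray(stack.atom_name, dtype="U5")
    for i, el in enumerate(elements):
        if not el:
            elements[i] = _infer_element(str(names[i]))

    resnames = np.asarray(stack.res_name, dtype="U4")
    bad = [rn for rn in np.unique(resnames) if rn not in AA3_TO_1]
    if bad:
        idx = int(np.flatnonzero(np.isin(resnames, bad))[0])
        raise TrajectoryError(
            f"{path}: unknown residue(s) {sorted(bad)}; first at atom record "
            f"{idx + 1} (chain {chain_col[idx]!r}, residue {int(stack.res_id[idx])})")

    chain_ids = list(dict.fromkeys(chain_col))
    cmap = {c: i for i, c in enumerate(chain_ids)}
    atom_chain = np.array([cmap[c] for c in chain_col])
    # residue index 1-based within each chain
    atom_resid = np.empty(len(chain_col), dtype=int)
    for ci in range(len(chain_ids)):
        sel = atom_chain == ci
        rid = np.asarray(stack.res_id)[sel]
        atom_resid[sel] = rid - rid.min() + 1

    top = Topology(chain_ids, atom_chain, atom_resid, resnames, names, elements)
    coords = np.asarray(stack.coord, dtype=float) / 10.0  # A -> nm
    box = None
    if stack.box is not None:
        box = np.stack([np.diag(b) for b in np.asarray(stack.box, float)]) / 10.0
        if np.allclose(box, 0):
            box = None
    times = np.arange(len(coords)) * float(dt)
    return Trajectory(top, coords, times, box,
                      metadata={"source": str(path), "dt": float(dt)})


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (nm -> A, CRYST1 from the cubic box)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = traj.topology
    n = top.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = np.array([top.chain_ids[c] for c in top.atom_chain])
    template.res_id = top.atom_resid.copy()
    template.res_name = top.atom_resname.copy()
    template.atom_name = top.atom_name.copy()
    template.element = top.element.copy()
    template.hetero = np.zeros(n, dtype=bool)

    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coords * 10.0
    if traj.box is not None:
        stack.box = np.stack([np.diag(b) for b in traj.box]) * 10.0
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def validate_topology(traj: Trajectory) -> TopologyReport:
    """Assert chain/frame invariants; flag residues whose amide H is absent.

    Hard violations (unequal chain lengths, incomplete backbone, unknown
    residues) raise :class:`TopologyError`; recoverable findings (missing
    amide hydrogens, reconstructable by the DSSP convention) are reported.
    """
    top = traj.topology
    messages: list[str] = []
    lengths = [top.chain_length(ci) for ci in range(top.n_chains)]
    if len(set(lengths)) != 1:
        raise TopologyError(f"chains have unequal residue counts: "
                            f"{dict(zip(top.chain_ids, lengths))}")
    L = lengths[0]
    for ci in range(top.n_chains):
        top.sequence(ci)  # raises on unknown residues
        for r in range(1, L + 1):
            for nm in BACKBONE_NAMES:
                if top.index_of(ci, r, nm) < 0:
                    raise TopologyError(
                        f"chain {top.chain_ids[ci]!r} residue {r} lacks "
                        f"backbone atom {nm}")
    h_missing = []
    for ci in range(top.n_chains):
        for r in range(2, L + 1):  # residue 1 has no DSSP-reconstructable H
            if top.index_of(ci, r, "H") < 0:
                h_missing.append((top.chain_ids[ci], r))
    if h_missing:
        messages.append(f"{len(h_missing)} residues lack amide H "
                        "(reconstructable from preceding C=O)")
    messages.append(f"{top.n_chains} chains x {L} residues, "
                    f"{traj.n_frames} frames, dt={traj.dt} ps")
    return TopologyReport(ok=True, messages=messages,
                          h_reconstructable=h_missing)


def build_reference_dimer(label: str, sequence: str = "VQIVYK") -> ReferenceDimer:
    """Ideal in-register two-strand beta-sheet dimer with stated polarity.

    Strands are built from ideal extended geometry (builder parameters live
    in :mod:`szaggr.synthetic_data`) and paired at ~0.48 nm inter-strand
    spacing so that the DSSP hydrogen-bond pattern of the requested polarity
    is actually realized.
    """
    if label not in ("parallel_in_register", "antiparallel_in_register"):
        raise ValueError(f"unknown reference dimer label {label!r}")
    from .synthetic_data import build_ideal_dimer_trajectory

    traj = build_ideal_dimer_trajectory(
        polarity="parallel" if label.startswith("parallel") else "antiparallel",
        sequence=sequence)
    ref = ReferenceDimer(label=label, trajectory=traj)
    mc = ref.mainchain_coords()
    a, b = mc[0], mc[1]
    # both chains originate from the same ideal strand
    _, _, r = kabsch_superpose(a, b)
    if r > 0.05:
        raise RuntimeError(f"reference dimer chains deviate: RMSD {r:.3f} nm")
    return ref
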