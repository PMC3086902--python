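"""Conformational order metrics: nematic P2, chain extension, hydrophobic
SASA, strand polarity/registry, contact maps and Rg-RMSD landscapes.

Chain orientation vectors are the unit vectors linking the CA atoms of the
second and fifth residue of each hexapeptide. The nematic order parameter
P2 is the largest eigenvalue of the molecular ordering tensor
Q = (1/N) sum_i (3/2 z_i z_i^T - 1/2 I); P2 = 1 for perfectly aligned
strand axes (parallel or anti-parallel alike), 0 for an isotropic set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import kabsch_superpose, min_image_displacement
from .core_io import ELEMENT_MASSES, Frame
from .ss_hbond import SSAssignment

__all__ = [
    "OrderResult",
    "ExtensionResult",
    "Landscape2D",
    "BONDI_RADII_NM",
    "chain_z_vectors",
    "nematic_p2",
    "chain_extension",
    "hydrophobic_sasa",
    "strand_polarity",
    "cluster_contact_map",
    "radius_of_gyration",
    "rg_rmsd_landscape",
    "stratify_by_order",
]

BONDI_RADII_NM = {"H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180}
SASA_PROBE_NM = 0.14
SASA_POINTS = 960
HYDROPHOBIC_ELEMENTS = {"C", "S"}


@dataclass
class OrderResult:
    P2: float
    director: np.ndarray
    z_vectors: np.ndarray


@dataclass
class ExtensionResult:
    r_e2e: np.ndarray     # per chain, nm
    r_norm: np.ndarray    # r_e2e / reference end-to-end


@dataclass
class Landscape2D:
    rg_edges: np.ndarray
    rmsd_edges: np.ndarray
    frequency: np.ndarray      # normalized so the maximal bin equals 1
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rg_mid = 0.5 * (self.rg_edges[:-1] + self.rg_edges[1:])
        rmsd_mid = 0.5 * (self.rmsd_edges[:-1] + self.rmsd_edges[1:])
        rows = []
        for a, rg in enumerate(rg_mid):
            for b, rm in enumerate(rmsd_mid):
                rows.append({"rg_nm": rg, "rmsd_nm": rm,
                             "frequency": self.frequency[a, b],
                             "count": self.counts[a, b]})
        return pd.DataFrame(rows)


def chain_z_vectors(frame: Frame, first_res: int = 2, last_res: int = 5
                    ) -> np.ndarray:
    """Unit vectors CA(second residue) -> CA(fifth residue), per chain."""
    top = frame.topology
    out = np.empty((top.n_chains, 3))
    for ci in range(top.n_chains):
        a = top.index_of(ci, first_res, "CA")
        b = top.index_of(ci, last_res, "CA")
        v = frame.coords[b] - frame.coords[a]
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError(f"degenerate orientation vector for chain "
                             f"{top.chain_ids[ci]!r}")
        out[ci] = v / norm
    return out


def nematic_p2(z_vectors: np.ndarray) -> OrderResult:
    """Largest eigenvalue of the ordering tensor and its director."""
    z = np.asarray(z_vectors, float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need at least two chain vectors")
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms < 1e-10):
        raise ValueError(f"zero-length chain vector at index "
                         f"{int(np.argmin(norms))}")
    z = z / norms[:, None]
    Q = 1.5 * np.einsum("ni,nj->ij", z, z) / len(z) - 0.5 * np.eye(3)
    w, v = np.linalg.eigh(Q)
    return OrderResult(P2=float(w[-1]), director=v[:, -1], z_vectors=z)


def chain_extension(frame: Frame, r_reference: float) -> ExtensionResult:
    """Per-chain CA(1)-CA(L) distance, normalized to a reference distance."""
    if r_reference <= 0:
        raise ValueError("reference extension must be positive")
    top = frame.topology
    L = top.chain_length(0)
    r = np.empty(top.n_chains)
    for ci in range(top.n_chains):
        a = top.index_of(ci, 1, "CA")
        b = top.index_of(ci, L, "CA")
        r[ci] = np.linalg.norm(frame.coords[b] - frame.coords[a])
    return ExtensionResult(r_e2e=r, r_norm=r / r_reference)


def hydrophobic_sasa(frame: Frame, chains=None, probe: float = SASA_PROBE_NM,
                     n_points: int = SASA_POINTS) -> dict:
    """Shrake-Rupley solvent-accessible surface (nm^2) of a chain complex.

    Returns total and hydrophobic SASA; hydrophobic atoms are carbons and
    sulfurs together with their bonded hydrogens (hydrogens named after
    the backbone amide are polar and excluded). Bondi radii.
    """
    import biotite.structure as struc

    top = frame.topology
    if chains is None:
        sel = np.arange(top.n_atoms)
    else:
        cidx = {top.chain_index(c) if isinstance(c, str) else int(c)
                for c in chains}
        sel = np.flatnonzero(np.isin(top.atom_chain, list(cidx)))
    arr = struc.AtomArray(len(sel))
    arr.coord = frame.coords[sel] * 10.0
    arr.chain_id = np.array([top.chain_ids[c] for c in top.atom_chain[sel]])
    arr.res_id = top.atom_resid[sel]
    arr.res_name = top.atom_resname[sel]
    arr.atom_name = top.atom_name[sel]
    arr.element = top.element[sel]
    radii = np.empty(len(sel))
    for i, el in enumerate(top.element[sel]):
        if el not in BONDI_RADII_NM:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii[i] = BONDI_RADII_NM[el] * 10.0
    per_atom = struc.sasa(arr, probe_radius=probe * 10.0, vdw_radii=radii,
                          ignore_ions=False,
                          point_number=n_points) / 100.0  # A^2 -> nm^2
    hydrophobic = np.isin(top.element[sel], list(HYDROPHOBIC_ELEMENTS))
    return {
        "total": float(np.nansum(per_atom)),
        "hydrophobic": float(np.nansum(per_atom[hydrophobic])),
        "per_atom": per_atom,
    }


def strand_polarity(frame: Frame, ss: SSAssignment, chain_a, chain_b
                    ) -> tuple[str, int]:
    """Majority bridge polarity and registry offset of a ladder-paired pair.

    Registry offset is the median of (j - i) over bridges for parallel
    pairs and of (i + j - (L + 1)) for antiparallel pairs; 0 = in register.
    Ties in polarity are broken by the sign of z_a . z_b.
    """
    top = frame.topology
    ca = top.chain_index(chain_a) if isinstance(chain_a, str) else int(chain_a)
    cb = top.chain_index(chain_b) if isinstance(chain_b, str) else int(chain_b)
    L = top.chain_length(0)
    pairs = []
    for b in ss.bridges:
        if {b.chain_i, b.chain_j} == {ca, cb}:
            i, j = ((b.res_i, b.res_j) if b.chain_i == ca
                    else (b.res_j, b.res_i))
            pairs.append((i, j, b.polarity))
    if not pairs:
        raise ValueError("chains share no beta bridge")
    n_par = sum(1 for p in pairs if p[2] == "parallel")
    n_anti = len(pairs) - n_par
    if n_par > n_anti:
        polarity = "parallel"
    elif n_anti > n_par:
        polarity = "antiparallel"
    else:
        z = chain_z_vectors(frame)
        polarity = "parallel" if z[ca] @ z[cb] > 0 else "antiparallel"
    sel = [p for p in pairs if p[2] == polarity]
    if polarity == "parallel":
        offset = np.median([j - i for i, j, _ in sel])
    else:
        offset = np.median([i + j - (L + 1) for i, j, _ in sel])
    return polarity, int(round(offset))


def cluster_contact_map(dimer_frames: list[tuple[Frame, str, str]],
                        cutoff: float = 0.45) -> np.ndarray:
    """L x L inter-chain residue contact probabilities over a dimer set.

    Cell (p, q) is the fraction of dimers in which residue p of the first
    chain and residue q of the second share at least one heavy-atom contact.
    """
    if not dimer_frames:
        raise ValueError("empty dimer set")
    frame0 = dimer_frames[0][0]
    L = frame0.topology.chain_length(0)
    acc = np.zeros((L, L))
    for frame, chain_a, chain_b in dimer_frames:
        top = frame.topology
        ca = top.chain_index(chain_a) if isinstance(chain_a, str) else int(chain_a)
        cb = top.chain_index(chain_b) if isinstance(chain_b, str) else int(chain_b)
        heavy = top.heavy_mask
        for p in range(1, L + 1):
            ia = np.flatnonzero((top.atom_chain == ca) & (top.atom_resid == p)
                                & heavy)
            xa = frame.coords[ia]
            for q in range(1, L + 1):
                ib = np.flatnonzero((top.atom_chain == cb)
                                    & (top.atom_resid == q) & heavy)
                d = min_image_displacement(
                    xa[:, None] - frame.coords[ib][None, :], frame.box)
                if (np.linalg.norm(d, axis=-1) <= cutoff).any():
                    acc[p - 1, q - 1] += 1
    return acc / len(dimer_frames)


def radius_of_gyration(coords: np.ndarray, elements: np.ndarray) -> float:
    """Mass-weighted radius of gyration over heavy atoms (nm)."""
    heavy = np.asarray(elements) != "H"
    xyz = np.asarray(coords, float)[heavy]
    m = np.array([ELEMENT_MASSES[e] for e in np.asarray(elements)[heavy]])
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((xyz - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_rmsd_landscape(rg_values: np.ndarray, rmsd_values: np.ndarray,
                      bins: int | tuple = 40,
                      ranges=None) -> Landscape2D:
    """2D histogram over (Rg, RMSD-to-reference), max-normalized to 1."""
    counts, rg_edges, rmsd_edges = np.histogram2d(
        np.asarray(rg_values, float), np.asarray(rmsd_values, float),
        bins=bins, range=ranges)
    peak = counts.max()
    freq = counts / peak if peak > 0 else counts
    return Landscape2D(rg_edges=rg_edges, rmsd_edges=rmsd_edges,
                       frequency=freq, counts=counts)


def landscape_from_ensemble(coords: np.ndarray, elements: np.ndarray,
                            reference: np.ndarray, bins: int | tuple = 40
                            ) -> Landscape2D:
    """Convenience: superpose each structure to the reference, then bin
    (heavy-atom mass-weighted Rg, fitted RMSD)."""
    rgs, rmsds = [], []
    for c in coords:
        rgs.append(radius_of_gyration(c, elements))
        _, _, r = kabsch_superpose(c, reference)
        rmsds.append(r)
    return rg_rmsd_landscape(np.array(rgs), np.array(rmsds), bins=bins)


def stratify_by_order(values: np.ndarray, sizes: np.ndarray, dt: float,
                      min_cumulative_ps: float = 50000.0) -> pd.DataFrame:
    """Mean and standard error of a per-aggregate metric, grouped by size.

    Each sample contributes dt of cumulative occurrence to its size class;
    classes below ``min_cumulative_ps`` are flagged excluded (default 50 ns).
    """
    df = pd.DataFrame({"size": np.asarray(sizes, int),
                       "value": np.asarray(values, float)})
    rows = []
    for s, grp in df.groupby("size"):
        n = len(grp)
        rows.append({
            "size": int(s),
            "mean": grp["value"].mean(),
            "sem": grp["value"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
            "cumulative_ps": n * dt,
            "excluded": n * dt < min_cumulative_ps,
        })
    return pd.DataFrame(rows)
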