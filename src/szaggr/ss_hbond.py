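"""Backbone hydrogen bonds (Kabsch–Sander), beta-bridge/sheet/bend/coil
assignment, and Espinosa hydrogen-bond energy decomposition.

The secondary-structure states covered are the ones that hexapeptide
aggregates populate: extended beta-sheet (E), isolated beta-bridge (B),
bend (S) and coil (C). Helix and turn states are deliberately out of scope;
a residue matching a helix pattern would be reported as coil.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from ._geometry import min_image_displacement
from .core_io import Frame, Topology, Trajectory

__all__ = [
    "HydrogenBond",
    "SSAssignment",
    "Bridge",
    "KS_CUTOFF_KCAL",
    "reconstruct_amide_H",
    "kabsch_sander_energy",
    "backbone_hbond_matrix",
    "assign_beta_structure",
    "espinosa_energy",
    "espinosa_decomposition",
    "load_roster",
]

# Kabsch-Sander electrostatic H-bond model: E = q1*q2*332*(...) kcal/mol
KS_PREFACTOR = 0.084 * 332.0          # kcal/mol * A
KS_CUTOFF_KCAL = -0.5                 # accepted iff E < cutoff
KS_CLASH_NM = 0.05                    # any pairwise distance below -> reject

# Espinosa et al. H-bond energy from the H...O distance (d in Angstrom)
ESPINOSA_A = 25300.0                  # kJ/mol
ESPINOSA_B = 3.6                      # 1/Angstrom
ESPINOSA_DIST_SCREEN_NM = 0.35        # donor-acceptor heavy-atom screen
ESPINOSA_ANGLE_SCREEN_DEG = 120.0     # donor-H-acceptor angle screen
BEND_ANGLE_DEG = 70.0


@dataclass(frozen=True)
class HydrogenBond:
    donor: tuple[str, int, str]       # (chain_id, resid, atom_name)
    acceptor: tuple[str, int, str]
    d_HO: float                       # Angstrom
    espinosa_energy: float            # kJ/mol, negative = stabilizing
    category: str                     # bb | sc_sc | mc_sc
    ks_energy: float | None = None    # kcal/mol, backbone bonds only


@dataclass(frozen=True)
class Bridge:
    chain_i: int
    res_i: int          # 1-based
    chain_j: int
    res_j: int
    polarity: str       # parallel | antiparallel


@dataclass
class SSAssignment:
    """Per-residue labels (n_chains, L) in {E, B, S, C} plus bridge list."""
    labels: np.ndarray
    bridges: list[Bridge]

    def bridge_partners(self) -> dict[tuple[int, int], set[tuple[int, int, str]]]:
        """(chain, resid) -> set of (partner_chain, partner_resid, polarity)."""
        out: dict[tuple[int, int], set] = {}
        for b in self.bridges:
            out.setdefault((b.chain_i, b.res_i), set()).add(
                (b.chain_j, b.res_j, b.polarity))
            out.setdefault((b.chain_j, b.res_j), set()).add(
                (b.chain_i, b.res_i, b.polarity))
        return out


def load_roster(path=None) -> dict:
    """Load the donor/acceptor roster (package default or user file)."""
    if path is None:
        text = resources.files("szaggr").joinpath(
            "data/hbond_roster.yaml").read_text()
    else:
        text = open(path).read()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# amide hydrogen reconstruction (DSSP convention)

def reconstruct_amide_H(traj: Trajectory) -> Trajectory:
    """Return a trajectory with amide hydrogens added where absent.

    H is placed 0.1 nm from N along the unit vector (C_{i-1} - O_{i-1}),
    for residues i >= 2 (the N-terminal residue gets none). Existing
    hydrogens are untouched.
    """
    top = traj.topology
    L = top.chain_length(0)
    missing = []  # (chain, resid, insert_after_atom_index)
    for ci in range(top.n_chains):
        for r in range(2, L + 1):
            if top.index_of(ci, r, "H") < 0:
                missing.append((ci, r, top.index_of(ci, r, "N")))
    if not missing:
        return traj

    order = np.argsort([m[2] for m in missing])
    missing = [missing[i] for i in order]
    n_old = top.n_atoms
    insert_at = np.array([m[2] + 1 for m in missing])

    def _insert(arr, values):
        return np.insert(np.asarray(arr), insert_at, values)

    new_top = Topology(
        top.chain_ids,
        _insert(top.atom_chain, [m[0] for m in missing]),
        _insert(top.atom_resid, [m[1] for m in missing]),
        _insert(top.atom_resname,
                [top.atom_resname[m[2]] for m in missing]),
        _insert(top.atom_name, ["H"] * len(missing)),
        _insert(top.element, ["H"] * len(missing)),
    )
    new_coords = np.empty((traj.n_frames, n_old + len(missing), 3))
    h_pos = np.empty((traj.n_frames, len(missing), 3))
    for k, (ci, r, _) in enumerate(missing):
        n_i = top.index_of(ci, r, "N")
        c_prev = top.index_of(ci, r - 1, "C")
        o_prev = top.index_of(ci, r - 1, "O")
        v = traj.coords[:, c_prev] - traj.coords[:, o_prev]
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        h_pos[:, k] = traj.coords[:, n_i] + 0.1 * v
    for f in range(traj.n_frames):
        new_coords[f] = np.insert(traj.coords[f], insert_at, h_pos[f], axis=0)
    return Trajectory(new_top, new_coords, traj.times.copy(),
                      None if traj.box is None else traj.box.copy(),
                      dict(traj.metadata))


# ---------------------------------------------------------------------------
# Kabsch-Sander energy

def kabsch_sander_energy(n_pos, h_pos, c_pos, o_pos):
    """Kabsch-Sander H-bond energy (kcal/mol) for N-H...O=C geometry in nm.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) with r in
    Angstrom. Any pairwise distance below the clash guard yields +inf
    (bond rejected with a clash, DSSP convention). Broadcasts over leading
    dimensions.
    """
    n_pos, h_pos = np.asarray(n_pos, float), np.asarray(h_pos, float)
    c_pos, o_pos = np.asarray(c_pos, float), np.asarray(o_pos, float)

    def dist(a, b):
        return np.linalg.norm(a - b, axis=-1)

    r_on = dist(o_pos, n_pos)
    r_ch = dist(c_pos, h_pos)
    r_oh = dist(o_pos, h_pos)
    r_cn = dist(c_pos, n_pos)
    r = np.stack([r_on, r_ch, r_oh, r_cn])
    with np.errstate(divide="ignore"):
        e = KS_PREFACTOR * (1 / (10 * r_on) + 1 / (10 * r_ch)
                            - 1 / (10 * r_oh) - 1 / (10 * r_cn))
    e = np.where((r < KS_CLASH_NM).any(axis=0), np.inf, e)
    return e if e.ndim else float(e)


def _backbone_positions(frame: Frame):
    """(n_chains, L, 3) arrays for N, H, CA, C, O; NaN where absent."""
    top = frame.topology
    bb = top.backbone_indices(("N", "H", "CA", "C", "O"))
    out = {}
    for k, nm in enumerate(("N", "H", "CA", "C", "O")):
        idx = bb[:, :, k]
        pos = np.where(idx[..., None] >= 0,
                       frame.coords[np.clip(idx, 0, None)], np.nan)
        out[nm] = pos
    return out


def backbone_hbond_matrix(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs backbone N-H(i) -> C=O(j) bonds over global residues.

    Returns ``(accepted, energy)`` with shape (R, R), R = n_chains * L;
    row = donor residue, column = acceptor residue. Minimum-image applied
    using the frame's box. Donors without an amide H never bond.
    """
    top = frame.topology
    L = top.chain_length(0)
    pos = _backbone_positions(frame)
    R = top.n_chains * L
    N = pos["N"].reshape(R, 3)
    H = pos["H"].reshape(R, 3)
    C = pos["C"].reshape(R, 3)
    O = pos["O"].reshape(R, 3)

    # place every donor group minimum-image relative to its acceptor O
    box = frame.box
    dN = N[:, None, :] - O[None, :, :]
    shift = min_image_displacement(dN, box) - dN
    n_d = N[:, None, :] + shift
    h_d = H[:, None, :] + shift
    c_a = np.broadcast_to(C[None, :, :], n_d.shape)
    o_a = np.broadcast_to(O[None, :, :], n_d.shape)
    with np.errstate(invalid="ignore"):
        e = kabsch_sander_energy(n_d, h_d, c_a, o_a)
    e = np.where(np.isnan(e), np.inf, e)

    res_chain = np.repeat(np.arange(top.n_chains), L)
    res_idx = np.tile(np.arange(1, L + 1), top.n_chains)
    same_chain = res_chain[:, None] == res_chain[None, :]
    gap = np.abs(res_idx[:, None] - res_idx[None, :])
    excluded = same_chain & (gap < 2)
    accepted = (e < KS_CUTOFF_KCAL) & ~excluded
    return accepted, e


# ---------------------------------------------------------------------------
# beta structure assignment

def assign_beta_structure(frame: Frame, hbonds: np.ndarray | None = None
                          ) -> SSAssignment:
    """Kabsch-Sander bridge rules -> E/B plus bend (S) and coil (C).

    With Hb(a, b) denoting an accepted bond from C=O of residue a to N-H of
    residue b (the Kabsch-Sander convention), residues (i, j) form a
    parallel bridge iff [Hb(i-1,j) and Hb(j,i+1)] or [Hb(j-1,i) and
    Hb(i,j+1)], and an antiparallel bridge iff [Hb(i,j) and Hb(j,i)] or
    [Hb(i-1,j+1) and Hb(j-1,i+1)]. Ladders are maximal runs of consecutive
    bridges; E = ladder of >= 2 bridges, B = isolated bridge. S = CA kink
    angle above 70 deg (residues 3..L-2). Precedence E > B > S > C.
    """
    top = frame.topology
    L = top.chain_length(0)
    nc = top.n_chains
    R = nc * L
    if hbonds is None:
        hbonds, _ = backbone_hbond_matrix(frame)
    # backbone_hbond_matrix is donor-indexed; bridge rules are acceptor-first
    hb_acc = hbonds.T

    def hb(p, q):
        if p < 0 or q < 0 or p >= R or q >= R:
            return False
        return bool(hb_acc[p, q])

    res_chain = np.repeat(np.arange(nc), L)
    res_idx = np.tile(np.arange(1, L + 1), nc)

    def same_chain_step(p, k):
        """p+k if it stays within p's chain, else -1."""
        q = p + k
        if 0 <= q < R and res_chain[q] == res_chain[p]:
            return q
        return -1

    bridges: dict[tuple[int, int], str] = {}
    for p in range(R):
        for q in range(p + 1, R):
            if res_chain[p] == res_chain[q] and res_idx[q] - res_idx[p] < 3:
                continue
            pm, pp = same_chain_step(p, -1), same_chain_step(p, +1)
            qm, qp = same_chain_step(q, -1), same_chain_step(q, +1)
            parallel = ((hb(pm, q) and hb(q, pp)) or
                        (hb(qm, p) and hb(p, qp)))
            antiparallel = ((hb(p, q) and hb(q, p)) or
                            (hb(pm, qp) and hb(qm, pp)))
            if parallel:
                bridges[(p, q)] = "parallel"
            elif antiparallel:
                bridges[(p, q)] = "antiparallel"

    # ladders: union of consecutive bridges of equal polarity
    parent = {b: b for b in bridges}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for (p, q), pol in bridges.items():
        p2 = p + 1
        q2 = q + 1 if pol == "parallel" else q - 1
        if not (0 <= p2 < R and 0 <= q2 < R):
            continue
        if res_chain[p2] != res_chain[p] or res_chain[q2] != res_chain[q]:
            continue
        nxt = (min(p2, q2), max(p2, q2))
        if bridges.get(nxt) == pol:
            union((p, q), nxt)

    ladder_size: dict[tuple[int, int], int] = {}
    for b in bridges:
        ladder_size[find(b)] = ladder_size.get(find(b), 0) + 1

    labels = np.full((nc, L), "C", dtype="U1")
    bridge_list = []
    for (p, q), pol in bridges.items():
        size = ladder_size[find((p, q))]
        lab = "E" if size >= 2 else "B"
        for r in (p, q):
            ci, ri = res_chain[r], res_idx[r]
            if labels[ci, ri - 1] != "E":
                labels[ci, ri - 1] = lab
        bridge_list.append(Bridge(int(res_chain[p]), int(res_idx[p]),
                                  int(res_chain[q]), int(res_idx[q]), pol))

    # bend: angle between CA(i)-CA(i-2) and CA(i+2)-CA(i), residues 3..L-2
    ca = _backbone_positions(frame)["CA"]
    for ci in range(nc):
        for i in range(3, L - 1):  # 1-based residues 3..L-2
            if labels[ci, i - 1] in ("E", "B"):
                continue
            u = ca[ci, i - 1] - ca[ci, i - 3]
            v = ca[ci, i + 1] - ca[ci, i - 1]
            denom = np.linalg.norm(u) * np.linalg.norm(v)
            if denom == 0 or np.any(np.isnan(denom)):
                continue
            ang = np.degrees(np.arccos(np.clip(u @ v / denom, -1, 1)))
            if ang > BEND_ANGLE_DEG:
                labels[ci, i - 1] = "S"
    return SSAssignment(labels=labels, bridges=bridge_list)


# ---------------------------------------------------------------------------
# Espinosa decomposition

def espinosa_energy(d_ho_angstrom):
    """Espinosa H-bond energy: E = -25300 * exp(-3.6 * d_HO[A]) kJ/mol."""
    return -ESPINOSA_A * np.exp(-ESPINOSA_B * np.asarray(d_ho_angstrom, float))


def _roster_sites(top: Topology, roster: dict):
    """Per-chain donor and acceptor atom lists from the roster.

    Donors are (atom_index, h_index_or_-1, is_backbone); acceptors are
    (atom_index, is_backbone). Raises KeyError naming a residue type absent
    from the roster.
    """
    L = top.chain_length(0)
    acidic = float(roster.get("ph", 7.0)) < 4.0
    donors, acceptors = [], []
    for ci in range(top.n_chains):
        for r in range(1, L + 1):
            sel = np.flatnonzero((top.atom_chain == ci) & (top.atom_resid == r))
            if not len(sel):
                continue
            resname = str(top.atom_resname[sel[0]])
            if resname not in roster["residues"]:
                raise KeyError(
                    f"no donor/acceptor roster entry for residue {resname} "
                    f"(chain {top.chain_ids[ci]!r}, residue {r})")
            entry = roster["residues"][resname]
            n_i = top.index_of(ci, r, "N")
            h_i = top.index_of(ci, r, "H")
            # backbone amide; at the N-terminus the ammonium group donates
            if n_i >= 0:
                donors.append((n_i, h_i, True))
            o_i = top.index_of(ci, r, "O")
            if o_i >= 0:
                acceptors.append((o_i, True))
            if r == L:
                oxt = top.index_of(ci, r, "OXT")
                if oxt >= 0:
                    acceptors.append((oxt, True))
            sc_d = list(entry.get("donors", []))
            if acidic:
                sc_d += list(entry.get("acidic_donors", []))
            for nm in sc_d:
                i = top.index_of(ci, r, nm)
                if i >= 0:
                    donors.append((i, -1, False))
            for nm in entry.get("acceptors", []):
                i = top.index_of(ci, r, nm)
                if i >= 0:
                    acceptors.append((i, False))
    return donors, acceptors


def espinosa_decomposition(frame: Frame, chains, roster: dict | None = None
                           ) -> tuple[dict, list[HydrogenBond]]:
    """Espinosa H-bond energy terms (kJ/mol) for a complex of chains.

    ``hbE_bb``, ``hbE_scsc`` and ``hbE_mcsc`` sum inter-chain bonds of the
    respective category; ``hbE_tot`` sums every hydrogen bond within the
    complex, intra-chain bonds included, so its magnitude can exceed the sum
    of the three inter-chain terms.

    Geometric screen: d(donor, acceptor) < 0.35 nm, and donor-H-acceptor
    angle > 120 deg where an H is present. For donors lacking an explicit
    hydrogen (united-atom side chains, N-terminal ammonium) d_HO is taken as
    d(donor, acceptor) - 0.1 nm along the donor->acceptor line.
    """
    if roster is None:
        roster = load_roster()
    top = frame.topology
    chain_set = {top.chain_index(c) if isinstance(c, str) else int(c)
                 for c in chains}
    donors, acceptors = _roster_sites(top, roster)
    donors = [d for d in donors if top.atom_chain[d[0]] in chain_set]
    acceptors = [a for a in acceptors if top.atom_chain[a[0]] in chain_set]
    box = frame.box
    xyz = frame.coords

    sums = {"hbE_tot": 0.0, "hbE_bb": 0.0, "hbE_scsc": 0.0, "hbE_mcsc": 0.0}
    bonds: list[HydrogenBond] = []
    for d_i, h_i, d_bb in donors:
        for a_i, a_bb in acceptors:
            if a_i == d_i:
                continue
            ci_d, ci_a = top.atom_chain[d_i], top.atom_chain[a_i]
            ri_d, ri_a = top.atom_resid[d_i], top.atom_resid[a_i]
            if ci_d == ci_a and ri_d == ri_a:
                continue
            # covalent neighbors: backbone N(i) vs O(i-1) of the same chain
            if d_bb and a_bb and ci_d == ci_a and ri_a == ri_d - 1:
                continue
            dvec = min_image_displacement(xyz[a_i] - xyz[d_i], box)
            d_da = float(np.linalg.norm(dvec))
            if d_da >= ESPINOSA_DIST_SCREEN_NM:
                continue
            if h_i >= 0:
                hvec = min_image_displacement(xyz[h_i] - xyz[d_i], box)
                u = -hvec
                v = min_image_displacement(xyz[a_i] - (xyz[d_i] + hvec), box)
                denom = np.linalg.norm(u) * np.linalg.norm(v)
                ang = np.degrees(np.arccos(np.clip(u @ v / denom, -1, 1)))
                if ang <= ESPINOSA_ANGLE_SCREEN_DEG:
                    continue
                d_ho = float(np.linalg.norm(v)) * 10.0
            else:
                d_ho = (d_da - 0.1) * 10.0
            e = float(espinosa_energy(d_ho))
            if d_bb and a_bb:
                cat = "bb"
            elif not d_bb and not a_bb:
                cat = "sc_sc"
            else:
                cat = "mc_sc"
            sums["hbE_tot"] += e
            if ci_d != ci_a:
                sums["hbE_" + ("bb" if cat == "bb" else
                               "scsc" if cat == "sc_sc" else "mcsc")] += e
            bonds.append(HydrogenBond(
                donor=(top.chain_ids[ci_d], int(ri_d), str(top.atom_name[d_i])),
                acceptor=(top.chain_ids[ci_a], int(ri_a), str(top.atom_name[a_i])),
                d_HO=d_ho, espinosa_energy=e, category=cat))
    return sums, bonds
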