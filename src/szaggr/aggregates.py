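"""Contact graphs and hierarchical aggregate classification.

Two chains belong to the same *general* aggregate when any heavy atom of
one lies within 0.45 nm of any heavy atom of the other (minimum image);
a *beta-sheet* aggregate additionally requires two consecutive inter-chain
beta-bridge contacts (a ladder), and always refines the general partition.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import Frame
from .ss_hbond import SSAssignment, assign_beta_structure

__all__ = [
    "ContactGraph",
    "Partition",
    "CONTACT_CUTOFF_NM",
    "heavy_atom_contacts",
    "general_aggregates",
    "beta_sheet_edges",
    "beta_sheet_aggregates",
    "size_population",
    "size_distribution",
    "sheet_size_stats",
]

CONTACT_CUTOFF_NM = 0.45

Partition = list[frozenset]


@dataclass
class ContactGraph:
    """Undirected chain-pair contacts of one frame with minimal distances."""
    chain_ids: tuple[str, ...]
    edges: dict[tuple[str, str], float]  # (a, b) sorted -> min heavy dist, nm

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.chain_ids)
        for (a, b), d in self.edges.items():
            g.add_edge(a, b, distance=d)
        return g


def heavy_atom_contacts(frame: Frame, cutoff: float = CONTACT_CUTOFF_NM
                        ) -> ContactGraph:
    """Chain-pair contact graph from heavy-atom distances (cell list).

    An edge (a, b) exists iff the minimal heavy-atom distance between the
    chains is <= cutoff, under the minimum-image convention of the frame's
    cubic box.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = frame.topology
    heavy = np.flatnonzero(top.heavy_mask)
    xyz = frame.coords[heavy]
    chains = top.atom_chain[heavy]
    box = frame.box
    if box is not None:
        b = float(box[0])
        pos = np.mod(xyz, b)
        # guard against coordinates landing exactly on the upper edge
        pos[pos >= b] -= b
        tree = cKDTree(pos, boxsize=b)
    else:
        pos = xyz
        tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    edges: dict[tuple[str, str], float] = {}
    if len(pairs):
        ci = chains[pairs[:, 0]]
        cj = chains[pairs[:, 1]]
        mask = ci != cj
        if mask.any():
            d = np.linalg.norm(
                _min_image(pos[pairs[mask, 0]] - pos[pairs[mask, 1]], box),
                axis=-1)
            for a, b_, dist in zip(ci[mask], cj[mask], d):
                key = tuple(sorted((top.chain_ids[a], top.chain_ids[b_])))
                if key not in edges or dist < edges[key]:
                    edges[key] = float(dist)
    return ContactGraph(chain_ids=top.chain_ids, edges=edges)


def _min_image(dx, box):
    if box is None:
        return dx
    b = float(box[0])
    return dx - b * np.round(dx / b)


def general_aggregates(graph: ContactGraph) -> Partition:
    """Connected components of the contact graph, sorted by member IDs."""
    comps = nx.connected_components(graph.graph())
    return sorted((frozenset(c) for c in comps), key=lambda s: sorted(s))


def beta_sheet_edges(frame: Frame, ss: SSAssignment) -> set[tuple[str, str]]:
    """Chain pairs sharing two consecutive inter-chain beta-bridge contacts."""
    top = frame.topology
    by_pair: dict[tuple[int, int], set[int]] = {}
    for b in ss.bridges:
        if b.chain_i == b.chain_j:
            continue
        by_pair.setdefault((b.chain_i, b.chain_j), set()).add(b.res_i)
        by_pair.setdefault((b.chain_j, b.chain_i), set()).add(b.res_j)
    edges = set()
    for (ca, cb), residues in by_pair.items():
        if any(r + 1 in residues for r in residues):
            edges.add(tuple(sorted((top.chain_ids[ca], top.chain_ids[cb]))))
    return edges


def beta_sheet_aggregates(frame: Frame, ss: SSAssignment | None = None,
                          general: Partition | None = None) -> Partition:
    """Components of the beta-ladder graph; refines the general partition."""
    if ss is None:
        ss = assign_beta_structure(frame)
    top = frame.topology
    g = nx.Graph()
    g.add_nodes_from(top.chain_ids)
    g.add_edges_from(beta_sheet_edges(frame, ss))
    part = sorted((frozenset(c) for c in nx.connected_components(g)),
                  key=lambda s: sorted(s))
    if general is not None:
        for sheet in part:
            if len(sheet) > 1 and not any(sheet <= agg for agg in general):
                raise RuntimeError(
                    f"beta-sheet aggregate {sorted(sheet)} is not contained "
                    "in a single general aggregate")
    return part


def size_population(partition_streams: list[list[Partition]],
                    times: np.ndarray, n_chains: int) -> pd.DataFrame:
    """Averaged count of size-s aggregates at each time, M(s, t).

    ``partition_streams`` holds one per-frame partition list per replica;
    replicas are averaged arithmetically at matched times.
    """
    n_frames = len(times)
    counts = np.zeros((len(partition_streams), n_frames, n_chains))
    for r, stream in enumerate(partition_streams):
        if len(stream) != n_frames:
            raise ValueError("replica frame count does not match times")
        for f, part in enumerate(stream):
            for agg in part:
                counts[r, f, len(agg) - 1] += 1
    mean = counts.mean(axis=0)
    df = pd.DataFrame(mean, columns=np.arange(1, n_chains + 1))
    df.insert(0, "time_ps", np.asarray(times, float))
    return df


def size_distribution(partition_streams: list[list[Partition]],
                      times: np.ndarray, n_chains: int,
                      window: tuple[float, float]) -> pd.DataFrame:
    """Normalized aggregate-size probability within a time window [t0, t1]."""
    t0, t1 = window
    times = np.asarray(times, float)
    if t0 < times[0] or t1 > times[-1] or t1 <= t0:
        raise ValueError(f"window {window} outside trajectory span "
                         f"[{times[0]}, {times[-1]}]")
    sel = (times >= t0) & (times <= t1)
    counts = np.zeros(n_chains)
    for stream in partition_streams:
        for f in np.flatnonzero(sel):
            for agg in stream[f]:
                counts[len(agg) - 1] += 1
    total = counts.sum()
    prob = counts / total if total > 0 else counts
    return pd.DataFrame({"size": np.arange(1, n_chains + 1),
                         "probability": prob})


def sheet_size_stats(beta_partitions: list[Partition]) -> pd.DataFrame:
    """Distribution of strands per beta-sheet over frames.

    A sheet is a ladder-connected set of strands (component of the
    beta-edge graph); isolated chains count as size-1 "sheets" but are
    excluded from the multi-strand fractions column.
    """
    max_size = max((len(s) for part in beta_partitions for s in part),
                   default=1)
    counts = np.zeros(max_size)
    for part in beta_partitions:
        for sheet in part:
            counts[len(sheet) - 1] += 1
    multi = counts[1:].sum()
    frac_multi = np.zeros_like(counts)
    if multi > 0:
        frac_multi[1:] = counts[1:] / multi
    return pd.DataFrame({
        "size": np.arange(1, max_size + 1),
        "count": counts,
        "fraction": counts / counts.sum() if counts.sum() else counts,
        "fraction_of_sheets": frac_multi,
    })
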