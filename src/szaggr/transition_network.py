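"""Dimer tracking through time and conformational transition networks.

A track is a maximal run of consecutive frames in which the same unordered
chain pair is a contact-neighbor pair inside an aggregate of the stratum's
order; leaving the stratum (the aggregate grows, shrinks or dissolves)
terminates the track. Cluster-to-cluster transitions are counted between
consecutive frames of a track; track starts and ends contribute entry and
exit boundary flows, so per node entries + inbound = exits + outbound.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dimer_mapping import DimerRecord

__all__ = [
    "DimerTrack",
    "TransitionCounts",
    "TransitionNetwork",
    "track_dimers",
    "count_transitions",
    "build_network",
    "export_graphml",
    "read_graphml",
]


@dataclass
class DimerTrack:
    pair: tuple[str, str]
    frames: list[int]          # consecutive frame indices
    labels: list[int]          # cluster label per frame
    orders: list[int]          # source aggregate order per frame


@dataclass
class TransitionCounts:
    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    entries: dict[int, int] = field(default_factory=dict)
    exits: dict[int, int] = field(default_factory=dict)
    occupancy: dict[int, int] = field(default_factory=dict)
    n_tracks: int = 0


@dataclass
class TransitionNetwork:
    graph: nx.DiGraph
    stratum: str = ""

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame([{"cluster": n, **d}
                              for n, d in self.graph.nodes(data=True)])
        edges = pd.DataFrame([{"source": a, "target": b, **d}
                              for a, b, d in self.graph.edges(data=True)])
        return nodes, edges


def track_dimers(records: list[DimerRecord], labels: np.ndarray,
                 stratum_order: int) -> list[DimerTrack]:
    """Group labeled dimer records into per-pair tracks of one stratum.

    Only records whose source aggregate has the stratum's order belong to
    the track; a one-frame gap (or a frame spent at another order) breaks
    the track.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for rec, lab in zip(records, labels):
        if rec.source_order != stratum_order:
            continue
        by_pair.setdefault(rec.pair, []).append(
            (rec.frame_index, int(lab), rec.source_order))
    tracks = []
    for pair, items in sorted(by_pair.items()):
        items.sort()
        run: list[tuple[int, int, int]] = []
        for item in items:
            if run and item[0] != run[-1][0] + 1:
                tracks.append(DimerTrack(pair, [f for f, _, _ in run],
                                         [l for _, l, _ in run],
                                         [o for _, _, o in run]))
                run = []
            run.append(item)
        if run:
            tracks.append(DimerTrack(pair, [f for f, _, _ in run],
                                     [l for _, l, _ in run],
                                     [o for _, _, o in run]))
    return tracks


def count_transitions(tracks: list[DimerTrack]) -> TransitionCounts:
    """Raw transition counts plus entry/exit boundary flows.

    For consecutive frames with labels a != b, c(a->b) is incremented;
    each track start adds an entry at its first label, each track end an
    exit at its last label. Every frame of every track adds occupancy.
    """
    tc = TransitionCounts(n_tracks=len(tracks))
    for tr in tracks:
        if not tr.labels:
            continue
        tc.entries[tr.labels[0]] = tc.entries.get(tr.labels[0], 0) + 1
        tc.exits[tr.labels[-1]] = tc.exits.get(tr.labels[-1], 0) + 1
        for lab in tr.labels:
            tc.occupancy[lab] = tc.occupancy.get(lab, 0) + 1
        for a, b in zip(tr.labels[:-1], tr.labels[1:]):
            if a != b:
                tc.counts[(a, b)] = tc.counts.get((a, b), 0) + 1
    return tc


def build_network(tc: TransitionCounts, names: list[str] | None = None,
                  stratum: str = "") -> TransitionNetwork:
    """Directed net-transition network with normalized node/edge sizes.

    One edge per unordered cluster pair, pointing in the surplus direction
    with net = |c(a->b) - c(b->a)|; the raw total is kept as an attribute.
    Node and edge sizes are normalized by the network's own maxima.
    """
    g = nx.DiGraph()
    nodes = sorted(set(tc.occupancy) | set(tc.entries) | set(tc.exits)
                   | {a for a, _ in tc.counts} | {b for _, b in tc.counts})

    def label(n):
        return names[n] if names else n

    max_occ = max(tc.occupancy.values(), default=0)
    for n in nodes:
        occ = tc.occupancy.get(n, 0)
        g.add_node(label(n),
                   occupancy=occ,
                   entry=tc.entries.get(n, 0),
                   exit=tc.exits.get(n, 0),
                   normalized_size=occ / max_occ if max_occ else 0.0)
    pairs = {tuple(sorted(k)) for k in tc.counts}
    net_values = {}
    for a, b in pairs:
        ab = tc.counts.get((a, b), 0)
        ba = tc.counts.get((b, a), 0)
        src, dst = (a, b) if ab >= ba else (b, a)
        net_values[(src, dst)] = (abs(ab - ba), ab + ba)
    max_net = max((v[0] for v in net_values.values()), default=0)
    for (src, dst), (net, total) in sorted(net_values.items()):
        g.add_edge(label(src), label(dst), net=net, total=total,
                   normalized_width=net / max_net if max_net else 0.0)
    return TransitionNetwork(graph=g, stratum=stratum)


def export_graphml(network: TransitionNetwork, path) -> None:
    g = network.graph.copy()
    g.graph["stratum"] = network.stratum
    nx.write_graphml(g, str(path))


def read_graphml(path) -> TransitionNetwork:
    g = nx.read_graphml(str(path))
    return TransitionNetwork(graph=g, stratum=g.graph.get("stratum", ""))
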