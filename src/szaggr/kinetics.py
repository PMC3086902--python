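"""Association/dissociation event tracing and bimolecular reaction accounting.

Aggregates are identified across frames by their chain-ID set. Brief,
unreactive collisions are excluded by a stability filter: an aggregate must
persist for at least 10 ps (default) of consecutive frames before its
formation or decay counts as an event. All growth steps are bookkept as
bimolecular reactions A_i + A_j -> A_{i+j}; simultaneous k-way merges are
decomposed largest-first and flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "EventLog",
    "ReactionMatrix",
    "RateEstimate",
    "BOLTZMANN_KJ_PER_MOL_K",
    "stable_partition_stream",
    "detect_events",
    "classify_reactions",
    "estimate_rate_and_barrier",
    "replay_events",
]

BOLTZMANN_KJ_PER_MOL_K = 0.0083145


@dataclass(frozen=True)
class Event:
    time: float                 # ps
    type: str                   # assoc | dissoc
    size_i: int
    size_j: int
    members_i: frozenset
    members_j: frozenset
    simultaneous: bool = False  # part of a decomposed k-way change

    @property
    def product_size(self) -> int:
        return self.size_i + self.size_j


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "time_ps": e.time, "type": e.type, "i": e.size_i, "j": e.size_j,
            "product": e.product_size,
            "members_i": "+".join(sorted(e.members_i)),
            "members_j": "+".join(sorted(e.members_j)),
            "simultaneous": e.simultaneous,
        } for e in self.events])


def stable_partition_stream(partitions: list[list[frozenset]], dt: float,
                            min_lifetime: float = 10.0) -> list[list[frozenset]]:
    """Suppress aggregates that live shorter than the stability window.

    An aggregate (identified by its chain set) is recognized only if the
    identical set persists for >= ceil(min_lifetime / dt) consecutive
    frames; recognition applies from the first frame of the qualifying run.
    Chains of unrecognized aggregates keep their last recognized state.
    The initial partition is taken as recognized.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if min_lifetime < dt:
        raise ValueError("min_lifetime must be >= dt")
    n_min = int(np.ceil(min_lifetime / dt))
    n = len(partitions)
    if n == 0:
        return []

    # total consecutive run length covering each aggregate occurrence
    fwd: list[dict[frozenset, int]] = [dict() for _ in range(n)]
    for f in range(n - 1, -1, -1):
        nxt = fwd[f + 1] if f + 1 < n else {}
        for agg in partitions[f]:
            fwd[f][agg] = 1 + nxt.get(agg, 0)
    back: list[dict[frozenset, int]] = [dict() for _ in range(n)]
    for f in range(n):
        prev = back[f - 1] if f > 0 else {}
        for agg in partitions[f]:
            back[f][agg] = 1 + prev.get(agg, 0)
    best = [{agg: back[f][agg] + fwd[f][agg] - 1 for agg in partitions[f]}
            for f in range(n)]

    out: list[list[frozenset]] = []
    current: list[frozenset] = list(partitions[0])
    out.append(sorted(current, key=lambda s: sorted(s)))
    for f in range(1, n):
        recognized = [agg for agg in partitions[f]
                      if best[f][agg] >= n_min or agg in current]
        rec_chains = set().union(*recognized) if recognized else set()
        remnants = []
        for old in current:
            rest = old - rec_chains
            if rest:
                remnants.append(frozenset(rest))
        current = recognized + remnants
        out.append(sorted(current, key=lambda s: sorted(s)))
    return out


def _merge_sequence(pieces: list[frozenset]) -> list[tuple[frozenset, frozenset]]:
    """Largest-first pairwise merge order assembling the given pieces."""
    work = sorted(pieces, key=lambda s: (-len(s), sorted(s)))
    steps = []
    while len(work) > 1:
        a = work.pop(0)
        b = work.pop(0)
        steps.append((a, b))
        work.append(a | b)
        work.sort(key=lambda s: (-len(s), sorted(s)))
    return steps


def detect_events(filtered: list[list[frozenset]], times: np.ndarray
                  ) -> EventLog:
    """Compare consecutive partitions and emit bimolecular events.

    A merge of exactly two aggregates is one association; a two-way split
    one dissociation. k-way changes are decomposed into k-1 sequential
    bimolecular events (largest partners first) with the simultaneous flag
    set. Chain exchanges decompose into dissociations followed by
    associations at the same timestamp.
    """
    log = EventLog()
    times = np.asarray(times, float)
    for f in range(1, len(filtered)):
        old, new = filtered[f - 1], filtered[f]
        if set().union(*old) != set().union(*new):
            raise ValueError(f"chain set changed between frames {f-1} and {f}")
        old_set, new_set = set(old), set(new)
        if old_set == new_set:
            continue
        gone = [g for g in old if g not in new_set]
        born = [g for g in new if g not in old_set]
        # refinement pieces mediate between disappearing and appearing groups
        t = times[f]
        for g in sorted(gone, key=lambda s: sorted(s)):
            pieces = [g & h for h in born if g & h]
            if len(pieces) < 2:
                continue
            flag = len(pieces) > 2
            for a, b in reversed(_merge_sequence(pieces)):
                log.events.append(Event(t, "dissoc", len(a), len(b),
                                        frozenset(a), frozenset(b), flag))
        for h in sorted(born, key=lambda s: sorted(s)):
            pieces = [h & g for g in old if h & g]
            if len(pieces) < 2:
                continue
            flag = len(pieces) > 2
            for a, b in _merge_sequence(pieces):
                log.events.append(Event(t, "assoc", len(a), len(b),
                                        frozenset(a), frozenset(b), flag))
    return log


def replay_events(initial: list[frozenset], log: EventLog) -> list[frozenset]:
    """Apply the event log to an initial partition (consistency check)."""
    current = set(initial)
    for e in log:
        if e.type == "assoc":
            current.discard(e.members_i)
            current.discard(e.members_j)
            current.add(e.members_i | e.members_j)
        else:
            current.discard(e.members_i | e.members_j)
            current.add(e.members_i)
            current.add(e.members_j)
    return sorted(current, key=lambda s: sorted(s))


@dataclass
class ReactionMatrix:
    """Per (i, j), i <= j: association/dissociation totals and net counts."""
    n_max: int
    total_assoc: np.ndarray
    total_dissoc: np.ndarray

    @property
    def net(self) -> np.ndarray:
        return self.total_assoc - self.total_dissoc

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(1, self.n_max + 1):
            for j in range(i, self.n_max + 1):
                ta = int(self.total_assoc[i - 1, j - 1])
                td = int(self.total_dissoc[i - 1, j - 1])
                if ta or td:
                    rows.append({"i": i, "j": j, "total_assoc": ta,
                                 "total_dissoc": td, "net": ta - td})
        return pd.DataFrame(rows, columns=["i", "j", "total_assoc",
                                           "total_dissoc", "net"])


def classify_reactions(log: EventLog, n_max: int | None = None) -> dict:
    """Polymerization (min(i,j)=1) vs condensation (min(i,j)>=2) counts
    plus the bimolecular reaction matrix."""
    if n_max is None:
        n_max = max((e.product_size for e in log), default=1)
    ta = np.zeros((n_max, n_max))
    td = np.zeros((n_max, n_max))
    poly = cond = 0
    for e in log:
        i, j = sorted((e.size_i, e.size_j))
        if e.type == "assoc":
            ta[i - 1, j - 1] += 1
            if i == 1:
                poly += 1
            else:
                cond += 1
        else:
            td[i - 1, j - 1] += 1
    return {
        "polymerization": poly,
        "condensation": cond,
        "matrix": ReactionMatrix(n_max, ta, td),
    }


@dataclass
class RateEstimate:
    k: float | None              # per s; None -> only a lower bound exists
    n_transitions: int
    T_obs: float                 # s
    barrier_kJ_mol: float | None
    nu: float                    # attempt frequency, per s
    T: float                     # K
    lower_bound_only: bool = False


def estimate_rate_and_barrier(n_transitions: int, T_obs_s: float,
                              nu: float = 1e12, T: float = 310.0
                              ) -> RateEstimate:
    """First-order rate k = n/T_obs and barrier dG = kB*T*ln(nu/k).

    With zero observed transitions the rate is undefined and only the
    lower bound dG > kB*T*ln(nu*T_obs) can be stated; the estimate is then
    flagged instead of reporting a number.
    """
    if T_obs_s <= 0:
        raise ValueError("observation time must be positive")
    if n_transitions < 0:
        raise ValueError("transition count must be >= 0")
    if n_transitions == 0:
        return RateEstimate(None, 0, T_obs_s, None, nu, T,
                            lower_bound_only=True)
    k = n_transitions / T_obs_s
    dG = BOLTZMANN_KJ_PER_MOL_K * T * np.log(nu / k)
    return RateEstimate(float(k), int(n_transitions), float(T_obs_s),
                        float(dG), nu, T)
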