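"""Dimer-decomposition conformational mapping.

Oligomers of a chosen order are decomposed into their unique contact-
neighbor chain pairs; each dimeric substructure is iteratively relabeled
(slot assignment chosen by lower RMSD against a converging average
reference), superposed, mapped by coordinate PCA, and clustered by k-means
(Hartigan-Wong refinement over global-k-means seeds, cluster number chosen
by the Krzanowski-Lai criterion). Dimers extracted from higher oligomers
are assigned to the dimer-derived cluster model without re-fitting.

Clustering operates on superposed coordinate vectors, where Euclidean
distance is proportional to RMSD in the common frame — an approximation to
pairwise-optimal RMSD that keeps the problem in a vector space.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import apply_superposition, kabsch_superpose
from .core_io import Frame, Trajectory
from .aggregates import ContactGraph

__all__ = [
    "DimerRecord",
    "PCAModel",
    "ClusterModel",
    "MAINCHAIN_NAMES",
    "decompose",
    "kabsch_superpose",
    "relabel",
    "pca",
    "cluster",
    "assign",
    "name_clusters",
]

MAINCHAIN_NAMES = ("N", "CA", "C", "O")


@dataclass
class DimerRecord:
    """One dimeric substructure cut out of an aggregate."""
    frame_index: int
    source_order: int                  # size of the parent aggregate
    pair: tuple[str, str]              # unordered (sorted) chain IDs
    coords: np.ndarray                 # (2, 4L, 3) main-chain+CA, slot order
    heavy_coords: np.ndarray           # (n_heavy, 3) both chains, for Rg etc.
    heavy_elements: np.ndarray
    z_vectors: np.ndarray              # (2, 3) CA2->CA5 unit vectors
    swapped: bool = False              # slot order != sorted pair order
    aligned: np.ndarray | None = None  # coords after relabel+superposition

    def flat(self, swapped: bool | None = None) -> np.ndarray:
        c = self.coords
        if swapped if swapped is not None else self.swapped:
            c = c[::-1]
        return c.reshape(-1, 3)


def _mainchain_coords(frame: Frame, ci: int) -> np.ndarray:
    top = frame.topology
    L = top.chain_length(0)
    idx = [top.index_of(ci, r, nm) for r in range(1, L + 1)
           for nm in MAINCHAIN_NAMES]
    return frame.coords[idx]


def decompose(frame: Frame, frame_index: int, partition, contacts: ContactGraph,
              order_filter) -> list[DimerRecord]:
    """Unique contact-neighbor dimers from aggregates of selected orders.

    One record per unordered chain pair in contact (0.45 nm heavy-atom
    neighbor list); [ij] and [ji] are the same record.
    """
    from .conf_metrics import chain_z_vectors

    top = frame.topology
    order_filter = set(order_filter)
    z = chain_z_vectors(frame)
    heavy = top.heavy_mask
    records = []
    for agg in partition:
        if len(agg) not in order_filter:
            continue
        members = sorted(agg)
        for a_pos in range(len(members)):
            for b_pos in range(a_pos + 1, len(members)):
                a, b = members[a_pos], members[b_pos]
                if (a, b) not in contacts.edges:
                    continue
                ca, cb = top.chain_index(a), top.chain_index(b)
                mc = np.stack([_mainchain_coords(frame, ca),
                               _mainchain_coords(frame, cb)])
                hsel = np.flatnonzero(
                    np.isin(top.atom_chain, [ca, cb]) & heavy)
                records.append(DimerRecord(
                    frame_index=frame_index, source_order=len(agg),
                    pair=(a, b), coords=mc,
                    heavy_coords=frame.coords[hsel],
                    heavy_elements=top.element[hsel],
                    z_vectors=np.stack([z[ca], z[cb]])))
    return records


def relabel(records: list[DimerRecord], reference: np.ndarray,
            max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterative consistent chain labeling against a converging reference.

    For every record both slot assignments are superposed to the reference
    and the lower-RMSD one kept; the average of the superposed ensemble
    becomes the next reference, until labels repeat in two consecutive
    iterations. Returns (aligned coords (n, 4L*2, 3), swap flags, n_iter).
    Raises RuntimeError when not converged within ``max_iter``.
    """
    if not records:
        raise ValueError("empty dimer ensemble")
    ref = np.asarray(reference, float).reshape(-1, 3)
    n = len(records)
    prev_flags = None
    for it in range(1, max_iter + 1):
        aligned = np.empty((n, ref.shape[0], 3))
        flags = np.empty(n, dtype=bool)
        for k, rec in enumerate(records):
            best = None
            for swapped in (False, True):
                c = rec.flat(swapped=swapped)
                R, t, r = kabsch_superpose(c, ref)
                if best is None or r < best[0]:
                    best = (r, swapped, apply_superposition(c, R, t))
            flags[k] = best[1]
            aligned[k] = best[2]
        if prev_flags is not None and np.array_equal(flags, prev_flags):
            for rec, fl, al in zip(records, flags, aligned):
                rec.swapped = bool(fl)
                rec.aligned = al
            return aligned, flags, it
        prev_flags = flags
        ref = aligned.mean(axis=0)
    raise RuntimeError(
        f"relabeling did not converge in {max_iter} iterations "
        f"({n} records; last flip count "
        f"{int(np.sum(flags != prev_flags)) if prev_flags is not None else n})")


@dataclass
class PCAModel:
    mean: np.ndarray              # (n_atoms, 3)
    eigenvectors: np.ndarray      # (p, p) columns, descending eigenvalue
    eigenvalues: np.ndarray       # (p,) descending, >= 0
    projections: np.ndarray       # (n, p)
    fitted: np.ndarray            # (n, n_atoms, 3) superposed onto the mean

    @property
    def ev123(self) -> np.ndarray:
        return self.projections[:, :3]


def pca(aligned: np.ndarray) -> PCAModel:
    """Coordinate PCA of a superposed dimer ensemble.

    Structures are re-superposed onto their ensemble average, the
    covariance matrix of the stacked main-chain+CA coordinates is
    diagonalized, and every record is projected on all eigenvectors.
    """
    X = np.asarray(aligned, float)
    if X.ndim != 3 or len(X) < 2:
        raise ValueError("need an (n >= 2, n_atoms, 3) aligned ensemble")
    mean = X.mean(axis=0)
    fitted = np.empty_like(X)
    for k, c in enumerate(X):
        R, t, _ = kabsch_superpose(c, mean)
        fitted[k] = apply_superposition(c, R, t)
    mean = fitted.mean(axis=0)
    flat = (fitted - mean).reshape(len(X), -1)
    cov = flat.T @ flat / len(X)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    return PCAModel(mean=mean, eigenvectors=v, eigenvalues=w,
                    projections=flat @ v, fitted=fitted)


# ---------------------------------------------------------------------------
# k-means: global seeding, Hartigan-Wong refinement, Krzanowski-Lai selection

def _wss(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    w = 0.0
    for c in range(k):
        pts = X[labels == c]
        if len(pts):
            w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(w)


def _assign_nearest(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


def _hartigan_wong(X: np.ndarray, centers: np.ndarray,
                   max_passes: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Hartigan-Wong point-transfer refinement from given initial centers."""
    n, k = len(X), len(centers)
    labels = _assign_nearest(X, centers)
    # recompute centers as member means
    means = np.stack([X[labels == c].mean(axis=0) if (labels == c).any()
                      else centers[c] for c in range(k)])
    counts = np.bincount(labels, minlength=k).astype(float)
    for _ in range(max_passes):
        moved = 0
        for i in range(n):
            a = labels[i]
            if counts[a] <= 1:
                continue
            da = ((X[i] - means[a]) ** 2).sum()
            removal = counts[a] / (counts[a] - 1) * da
            d = ((X[i] - means) ** 2).sum(axis=1)
            gain = counts / (counts + 1) * d
            gain[a] = np.inf
            b = int(np.argmin(gain))
            if gain[b] < removal:
                # incremental center update
                means[a] = (means[a] * counts[a] - X[i]) / (counts[a] - 1)
                means[b] = (means[b] * counts[b] + X[i]) / (counts[b] + 1)
                counts[a] -= 1
                counts[b] += 1
                labels[i] = b
                moved += 1
        if moved == 0:
            break
    return labels, means


def _global_kmeans_path(X: np.ndarray, k_max: int) -> dict[int, np.ndarray]:
    """Incremental (fast) global k-means seeding: the solution for k is the
    solution for k-1 plus the candidate point with the largest guaranteed
    error reduction, each followed by Hartigan-Wong refinement."""
    n = len(X)
    centers_by_k = {1: X.mean(axis=0)[None, :]}
    d2 = ((X - centers_by_k[1][0]) ** 2).sum(axis=1)
    pair_d2 = None
    for k in range(2, k_max + 1):
        if pair_d2 is None:
            pair_d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        reduction = np.maximum(d2[None, :] - pair_d2, 0.0).sum(axis=1)
        cand = int(np.argmax(reduction))
        centers = np.vstack([centers_by_k[k - 1], X[cand]])
        labels, means = _hartigan_wong(X, centers)
        centers_by_k[k] = means
        d2 = ((X - means[labels]) ** 2).sum(axis=1)
    return centers_by_k


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray                 # (k, p) centroid vectors
    labels: np.ndarray                  # (n,)
    representatives: np.ndarray         # (k,) index of closest member
    wss_by_k: dict[int, float]
    kl_by_k: dict[int, float]
    names: list[str] = field(default_factory=list)
    atom_shape: tuple = ()


def cluster(aligned: np.ndarray, k_range=range(2, 11)) -> ClusterModel:
    """k-means over the superposed ensemble with Krzanowski-Lai selection.

    KL(k) = |DIFF(k)| / |DIFF(k+1)| with
    DIFF(k) = (k-1)^{2/p} W_{k-1} - k^{2/p} W_k, p = coordinate dimension;
    the chosen k maximizes KL over ``k_range``. Centers are seeded by
    global k-means and refined by Hartigan-Wong passes.
    """
    X = np.asarray(aligned, float)
    atom_shape = X.shape[1:]
    X = X.reshape(len(X), -1)
    ks = sorted(k_range)
    if ks[0] < 2 or ks[-1] > len(X) - 1:
        raise ValueError(f"k_range {ks[0]}..{ks[-1]} outside [2, n-1]")
    p = X.shape[1]
    k_top = ks[-1] + 1  # KL at the top of the range needs one extra W
    path = _global_kmeans_path(X, k_top)
    labels_by_k, wss_by_k = {}, {1: _wss(X, np.zeros(len(X), int), 1)}
    for k in range(2, k_top + 1):
        lab = _assign_nearest(X, path[k])
        labels_by_k[k] = lab
        wss_by_k[k] = _wss(X, lab, k)

    def diff(k):
        return ((k - 1) ** (2.0 / p) * wss_by_k[k - 1]
                - k ** (2.0 / p) * wss_by_k[k])

    kl_by_k = {}
    for k in ks:
        denom = abs(diff(k + 1))
        kl_by_k[k] = abs(diff(k)) / denom if denom > 0 else np.inf
    best_k = max(ks, key=lambda k: (kl_by_k[k], -k))
    labels = labels_by_k[best_k]
    centers = np.stack([X[labels == c].mean(axis=0) for c in range(best_k)])
    reps = np.empty(best_k, dtype=int)
    for c in range(best_k):
        members = np.flatnonzero(labels == c)
        d = ((X[members] - centers[c]) ** 2).sum(axis=1)
        reps[c] = members[np.argmin(d)]
    return ClusterModel(k=best_k, centers=centers, labels=labels,
                        representatives=reps, wss_by_k=wss_by_k,
                        kl_by_k=kl_by_k, atom_shape=atom_shape)


def assign(aligned: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Nearest-center labels for records relabeled against the converged
    dimer reference; centers are not updated. Ties go to the lower index."""
    X = np.asarray(aligned, float).reshape(len(aligned), -1)
    return _assign_nearest(X, model.centers)


def name_clusters(model: ClusterModel, records: list[DimerRecord],
                  labels: np.ndarray | None = None) -> list[str]:
    """A/P/I/E nomenclature from the mean dimer arrangement per cluster.

    mean(z1 . z2) < -0.5 -> A (anti-parallel); > 0.5 -> P (parallel);
    minimal inter-chain distance > 0.6 nm -> E (encounter complex);
    otherwise I (intermediate/irregular). Numbered by descending occupancy.
    """
    if labels is None:
        labels = model.labels
    letters = []
    occupancy = []
    for c in range(model.k):
        members = [r for r, l in zip(records, labels) if l == c]
        occupancy.append(len(members))
        if not members:
            letters.append("I")
            continue
        zdot = np.mean([r.z_vectors[0] @ r.z_vectors[1] for r in members])
        mind = np.mean([
            np.min(np.linalg.norm(
                r.coords[0][:, None] - r.coords[1][None, :], axis=-1))
            for r in members])
        if mind > 0.6:
            letters.append("E")
        elif zdot < -0.5:
            letters.append("A")
        elif zdot > 0.5:
            letters.append("P")
        else:
            letters.append("I")
    # number by descending occupancy within each letter class
    order = np.argsort([-o for o in occupancy], kind="stable")
    counter: dict[str, int] = {}
    names = [""] * model.k
    for c in order:
        letter = letters[c]
        counter[letter] = counter.get(letter, 0) + 1
        names[c] = f"{letter}{counter[letter]}"
    model.names = names
    return names
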