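"""Dimer decomposition, superposition, relabeling, PCA and clustering."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from szaggr import synthetic_data
from szaggr.aggregates import ContactGraph, general_aggregates, heavy_atom_contacts
from szaggr.dimer_mapping import (DimerRecord, assign, cluster,
                                  decompose, kabsch_superpose, name_clusters,
                                  pca, relabel)
from szaggr._geometry import apply_superposition, rmsd


def _complete_graph(chains):
    return ContactGraph(tuple(chains),
                        {tuple(sorted((a, b))): 0.3
                         for i, a in enumerate(chains)
                         for b in chains[i + 1:]})


@pytest.fixture(scope="module")
def stacked_frame():
    """One frame with a 10-chain stack (single decamer, path contacts)."""
    cfg = synthetic_data.SimConfig(n_frames=30, seed=2, p_assoc=1.0,
                                   p_dissoc=0.0)
    traj, _ = synthetic_data.simulate_aggregation(cfg)
    return traj.frame(traj.n_frames - 1)


class TestDecompose:
    def test_fully_connected_trimer(self, stacked_frame):
        chains = list(stacked_frame.topology.chain_ids[:3])
        recs = decompose(stacked_frame, 0, [frozenset(chains)],
                         _complete_graph(chains), {3})
        assert len(recs) == 3

    def test_fully_connected_decamer(self, stacked_frame):
        chains = list(stacked_frame.topology.chain_ids)
        recs = decompose(stacked_frame, 0, [frozenset(chains)],
                         _complete_graph(chains), {10})
        assert len(recs) == 10 * 9 // 2

    def test_path_topology_tetramer(self, stacked_frame):
        chains = list(stacked_frame.topology.chain_ids[:4])
        graph = ContactGraph(tuple(chains),
                             {(chains[0], chains[1]): 0.3,
                              (chains[1], chains[2]): 0.3,
                              (chains[2], chains[3]): 0.3})
        recs = decompose(stacked_frame, 0, [frozenset(chains)], graph, {4})
        assert len(recs) == 3
        assert all(r.source_order == 4 for r in recs)

    def test_counts_match_bruteforce_on_random_graphs(self, stacked_frame):
        rng = np.random.default_rng(5)
        chains = list(stacked_frame.topology.chain_ids)
        for _ in range(200):
            edges = {}
            for i, a in enumerate(chains):
                for b in chains[i + 1:]:
                    if rng.random() < 0.3:
                        edges[(a, b)] = 0.3
            graph = ContactGraph(tuple(chains), edges)
            recs = decompose(stacked_frame, 0, [frozenset(chains)], graph,
                             {10})
            assert len(recs) == len(edges)
            assert len({r.pair for r in recs}) == len(recs)

    def test_real_contact_graph_of_stack(self, stacked_frame):
        graph = heavy_atom_contacts(stacked_frame)
        part = general_aggregates(graph)
        assert len(part) == 1 and len(part[0]) == 10
        recs = decompose(stacked_frame, 0, part, graph, {10})
        assert len(recs) == 9  # stack: only adjacent chains touch


class TestKabsch:
    def test_identical_structures(self):
        x = np.random.default_rng(0).normal(size=(24, 3))
        _, _, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rotated_translated_copy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(24, 3))
        rot = Rotation.random(random_state=rng).as_matrix()
        y = x @ rot.T + [1.0, -0.5, 2.0]
        _, _, r = kabsch_superpose(y, x)
        assert r < 1e-10

    def test_optimality_against_sampled_rotations(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        _, _, best = kabsch_superpose(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        for rot in Rotation.random(1000, random_state=rng):
            assert rmsd(xc @ rot.as_matrix().T, yc) >= best - 1e-12

    def test_proper_rotation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 3))
        # reflected copy must still be fitted with det(R) = +1
        y = x * np.array([-1.0, 1.0, 1.0])
        R, _, _ = kabsch_superpose(y, x)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_collinear_input_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 0.1)


def _records_from_coords(coords):
    recs = []
    for k, c in enumerate(coords):
        recs.append(DimerRecord(
            frame_index=k, source_order=2, pair=("A", "B"),
            coords=c.reshape(2, -1, 3), heavy_coords=c.reshape(-1, 3),
            heavy_elements=np.array(["C"] * c.reshape(-1, 3).shape[0]),
            z_vectors=np.stack([c.reshape(2, -1, 3)[0][17] - c.reshape(2, -1, 3)[0][5],
                                c.reshape(2, -1, 3)[1][17] - c.reshape(2, -1, 3)[1][5]])))
    return recs


@pytest.fixture(scope="module")
def relabeled_ensemble(labeled_ensemble, reference_dimers):
    coords, labels, names = labeled_ensemble
    recs = _records_from_coords(coords)
    ref = reference_dimers["antiparallel"].mainchain_coords().reshape(-1, 3)
    aligned, flags, n_iter = relabel(recs, ref)
    return recs, aligned, flags, n_iter, labels, names


class TestRelabel:
    def test_symmetric_ensemble_converges_fast(self, reference_dimers):
        mc = reference_dimers["antiparallel"].mainchain_coords()
        coords = np.tile(mc.reshape(1, -1, 3), (10, 1, 1))
        recs = _records_from_coords(coords)
        _, flags, n_iter = relabel(recs, mc.reshape(-1, 3))
        assert n_iter <= 2
        assert len(set(flags.tolist())) == 1

    def test_permutation_invariance(self, labeled_ensemble, reference_dimers):
        coords, _, _ = labeled_ensemble
        ref = reference_dimers["antiparallel"].mainchain_coords().reshape(-1, 3)
        aligned1, _, _ = relabel(_records_from_coords(coords), ref)
        rng = np.random.default_rng(8)
        swapped = coords.copy().reshape(len(coords), 2, -1, 3)
        do_swap = rng.random(len(coords)) < 0.5
        swapped[do_swap] = swapped[do_swap][:, ::-1]
        aligned2, _, _ = relabel(
            _records_from_coords(swapped.reshape(len(coords), -1, 3)), ref)
        assert np.allclose(aligned1, aligned2, atol=1e-9)

    def test_forced_assignment(self, reference_dimers):
        ref = reference_dimers["antiparallel"].mainchain_coords()
        rec = _records_from_coords(ref.reshape(1, -1, 3))[0]
        flat = ref.reshape(-1, 3)
        _, _, r_keep = kabsch_superpose(rec.flat(swapped=False), flat)
        _, _, r_swap = kabsch_superpose(rec.flat(swapped=True), flat)
        # the swapped labeling is clearly worse by construction
        assert r_keep < 1e-9
        assert r_swap > 0.05
        aligned, flags, _ = relabel([rec] * 4, flat)
        assert not flags.any()

    def test_idempotent_on_own_output(self, relabeled_ensemble):
        recs, aligned, flags, _, _, _ = relabeled_ensemble
        ref = aligned.mean(axis=0)
        re_recs = _records_from_coords(aligned)
        _, flags2, n_iter = relabel(re_recs, ref)
        assert n_iter <= 2
        assert not flags2.any()  # no record flips labeling again


class TestPCA:
    def test_identical_structures_zero_variance(self, reference_dimers):
        mc = reference_dimers["antiparallel"].mainchain_coords()
        ens = np.tile(mc.reshape(1, -1, 3), (5, 1, 1))
        model = pca(ens)
        assert np.all(model.eigenvalues < 1e-12)

    def test_single_mode_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(12, 3))
        # superposition-neutral breathing mode: zero net translation/torque
        mode = np.zeros((12, 3))
        mode[0] = base[0] - base.mean(axis=0)
        mode[1] = -(base[0] - base.mean(axis=0))
        base[1] = 2 * base.mean(axis=0) - base[0]  # opposite position
        amps = rng.normal(0.0, 0.1, 50)
        ens = base[None] + amps[:, None, None] * mode[None]
        model = pca(ens)
        assert model.eigenvalues[0] > 1e-6
        assert model.eigenvalues[1] < 1e-9 * model.eigenvalues[0] + 1e-12
        total = model.eigenvalues.sum()
        assert model.eigenvalues[0] == pytest.approx(total)

    def test_eigenvector_orthonormality(self, relabeled_ensemble):
        _, aligned, _, _, _, _ = relabeled_ensemble
        model = pca(aligned)
        v = model.eigenvectors
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_projection_covariance_diagonal(self, relabeled_ensemble):
        _, aligned, _, _, _, _ = relabeled_ensemble
        model = pca(aligned)
        proj = model.projections
        cov = proj.T @ proj / len(proj)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction(self, relabeled_ensemble):
        _, aligned, _, _, _, _ = relabeled_ensemble
        model = pca(aligned)
        back = model.projections @ model.eigenvectors.T
        # back-transform must reproduce the centered fitted coordinates
        flat = (model.fitted - model.mean).reshape(len(aligned), -1)
        assert np.allclose(back, flat, atol=1e-8)

    def test_eigenvalues_nonnegative_descending(self, relabeled_ensemble):
        _, aligned, _, _, _, _ = relabeled_ensemble
        model = pca(aligned)
        assert np.all(model.eigenvalues >= 0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            pca(np.zeros((1, 10, 3)))


class TestCluster:
    def test_three_separated_blobs(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
        X = np.concatenate([c + rng.normal(0, 1.0, (60, 2))
                            for c in centers])
        model = cluster(X[:, :, None], k_range=range(2, 7))
        assert model.k == 3
        got = sorted(model.centers.reshape(3, 2).tolist())
        for g, c in zip(got, sorted(centers.tolist())):
            assert np.linalg.norm(np.array(g) - c) < 1.0

    def test_two_duplicate_groups_zero_wss(self):
        X = np.array([[0.0, 0.0]] * 10 + [[5.0, 5.0]] * 10)
        model = cluster(X[:, :, None], k_range=range(2, 4))
        assert model.wss_by_k[2] == pytest.approx(0.0, abs=1e-12)

    def test_refinement_never_worsens_seeding(self):
        from szaggr.dimer_mapping import _hartigan_wong, _wss, _assign_nearest
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 5))
        seeds = X[:4].copy()
        w0 = _wss(X, _assign_nearest(X, seeds), 4)
        labels, means = _hartigan_wong(X, seeds)
        assert _wss(X, labels, 4) <= w0 + 1e-9

    def test_record_order_permutation_invariance(self, relabeled_ensemble):
        _, aligned, _, _, _, _ = relabeled_ensemble
        model1 = cluster(aligned, k_range=range(2, 7))
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(aligned))
        model2 = cluster(aligned[perm], k_range=range(2, 7))
        assert model2.k == model1.k
        # partitions agree up to cluster renaming
        relabeling = {}
        for a, b in zip(model1.labels[perm], model2.labels):
            relabeling.setdefault(a, b)
            assert relabeling[a] == b

    def test_invalid_k_range(self):
        with pytest.raises(ValueError):
            cluster(np.zeros((5, 2, 3)), k_range=range(2, 10))


class TestAssignAndNaming:
    def test_recovers_template_labels(self, relabeled_ensemble):
        recs, aligned, _, _, truth, names = relabeled_ensemble
        model = cluster(aligned, k_range=range(2, 11))
        assert model.k == 4
        # >= 99% purity against the generating template
        agree = 0
        mapping = {}
        for c in range(model.k):
            members = truth[model.labels == c]
            counts = np.bincount(members, minlength=4)
            mapping[c] = int(np.argmax(counts))
            agree += counts.max()
        assert agree / len(truth) >= 0.99

    def test_assign_center_structure(self, relabeled_ensemble):
        _, aligned, _, _, _, _ = relabeled_ensemble
        model = cluster(aligned, k_range=range(2, 11))
        center_like = model.centers[2].reshape(1, -1, 3)
        assert assign(center_like, model)[0] == 2

    def test_assign_tie_goes_to_lower_index(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        model = cluster(X[:, :, None], k_range=range(2, 3))
        mid = 0.5 * (model.centers[0] + model.centers[1])
        assert assign(mid.reshape(1, 1, -1), model)[0] == 0

    def test_synthetic_records_high_assignment_agreement(self):
        rng = np.random.default_rng(11)
        centers = rng.normal(size=(4, 8)) * 3.0
        X = np.concatenate([c + rng.normal(0, 0.05, (125, 8))
                            for c in centers])
        model = cluster(X.reshape(500, 8, 1), k_range=range(2, 8))
        labels = assign(X.reshape(500, 8, 1), model)
        truth = np.repeat(np.arange(4), 125)
        agree = 0
        for c in range(model.k):
            counts = np.bincount(truth[labels == c], minlength=4)
            agree += counts.max()
        assert model.k == 4
        assert agree / 500 >= 0.99

    def test_cluster_names_match_templates(self, relabeled_ensemble):
        recs, aligned, _, _, truth, template_names = relabeled_ensemble
        model = cluster(aligned, k_range=range(2, 11))
        names = name_clusters(model, recs)
        assert len(names) == model.k
        # every cluster's letter equals its dominant template's letter
        for c in range(model.k):
            dominant = template_names[int(np.bincount(
                truth[model.labels == c], minlength=4).argmax())]
            assert names[c][0] == dominant
        assert len(set(names)) == model.k
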