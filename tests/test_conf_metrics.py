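"""Nematic order, extension, SASA, polarity, contact maps and landscapes."""
import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import single_atom_chains
from szaggr import core_io, synthetic_data
from szaggr.conf_metrics import (chain_extension, chain_z_vectors,
                                 cluster_contact_map, hydrophobic_sasa,
                                 landscape_from_ensemble, nematic_p2,
                                 radius_of_gyration, rg_rmsd_landscape,
                                 strand_polarity, stratify_by_order)
from szaggr.ss_hbond import assign_beta_structure


class TestNematicOrder:
    def test_perfect_alignment(self):
        assert nematic_p2(np.tile([0.0, 0.0, 1.0], (6, 1))).P2 \
            == pytest.approx(1.0)

    def test_sign_invariance(self):
        z = np.array([[0, 0, 1.0]] * 3 + [[0, 0, -1.0]] * 3)
        assert nematic_p2(z).P2 == pytest.approx(1.0)

    def test_orthogonal_triad_is_isotropic(self):
        assert nematic_p2(np.eye(3)).P2 == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            z = rng.normal(size=(8, 3))
            p2 = nematic_p2(z).P2
            assert 0.0 <= p2 <= 1.0 + 1e-12
            rot = Rotation.random(random_state=rng).as_matrix()
            assert nematic_p2(z @ rot.T).P2 == pytest.approx(p2, abs=1e-9)
            flip = z.copy()
            flip[0] = -flip[0]
            assert nematic_p2(flip).P2 == pytest.approx(p2, abs=1e-9)

    def test_degenerate_vector_rejected(self):
        with pytest.raises(ValueError):
            nematic_p2(np.array([[0, 0, 1.0], [0, 0, 0.0]]))

    @given(st.lists(st.lists(st.floats(-1, 1), min_size=3, max_size=3),
                    min_size=2, max_size=12))
    @settings(deadline=None, derandomize=True)
    def test_order_parameter_bounds_property(self, vecs):
        z = np.asarray(vecs, float)
        assume(np.all(np.linalg.norm(z, axis=1) > 1e-3))
        p2 = nematic_p2(z).P2
        assert -1e-9 <= p2 <= 1.0 + 1e-9
        assert nematic_p2(-z).P2 == pytest.approx(p2, abs=1e-9)


class TestChainExtension:
    def test_reference_normalizes_to_one(self, antiparallel_dimer):
        frame = antiparallel_dimer.frame(0)
        r = chain_extension(frame, 1.0).r_e2e[0]
        out = chain_extension(frame, r)
        assert out.r_norm[0] == pytest.approx(1.0)

    def test_ideal_strand_extension(self):
        strand = synthetic_data.build_ideal_hexapeptide()
        traj = synthetic_data.chains_to_trajectory({"A": strand.coords}, strand)
        r = chain_extension(traj.frame(0), 1.0).r_e2e[0]
        assert r == pytest.approx(1.735, abs=0.02)

    def test_collapsed_chain(self):
        strand = synthetic_data.build_ideal_hexapeptide()
        coords = strand.coords.copy()
        ca1 = strand.atom_index(1, "CA")
        ca6 = strand.atom_index(6, "CA")
        coords[ca6] = coords[ca1] + [0.0, 0.0, 0.35]
        traj = synthetic_data.chains_to_trajectory({"A": coords}, strand)
        out = chain_extension(traj.frame(0), r_reference=1.735)
        assert out.r_norm[0] < 0.25


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        frame = single_atom_chains([0.0])
        out = hydrophobic_sasa(frame)
        expected = 4 * np.pi * (0.17 + 0.14) ** 2
        assert out["total"] == pytest.approx(expected, rel=0.01)
        assert out["hydrophobic"] == pytest.approx(out["total"])

    def test_distant_atoms_additive(self):
        frame = single_atom_chains([0.0, 5.0])
        out = hydrophobic_sasa(frame)
        single = 4 * np.pi * (0.31) ** 2
        assert out["total"] == pytest.approx(2 * single, rel=0.01)

    def test_fully_buried_atom(self):
        # central N enclosed by 12 overlapping carbon spheres (icosahedron)
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi],
                          [0, -1, -phi], [1, phi, 0], [-1, phi, 0],
                          [1, -phi, 0], [-1, -phi, 0], [phi, 0, 1],
                          [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]])
        verts = 0.12 * verts / np.linalg.norm(verts[0])
        n = len(verts) + 1
        top = core_io.Topology(
            [chr(65 + i) for i in range(n)], np.arange(n), np.ones(n, int),
            np.array(["ALA"] * n), np.array(["N"] + ["CB"] * 12),
            np.array(["N"] + ["C"] * 12))
        coords = np.vstack([[0.0, 0.0, 0.0], verts])
        out = hydrophobic_sasa(core_io.Frame(0.0, None, coords, top))
        assert out["per_atom"][0] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_element_rejected(self):
        top = core_io.Topology(["A"], [0], [1], ["ALA"], ["FE"], ["X"])
        with pytest.raises(KeyError):
            hydrophobic_sasa(core_io.Frame(0.0, None, np.zeros((1, 3)), top))

    def test_burial_monotonic_on_approach(self):
        strand = synthetic_data.build_ideal_hexapeptide()
        values = []
        for gap in np.linspace(2.0, 0.45, 10):
            other = strand.coords + [0.0, gap, 0.0]
            traj = synthetic_data.chains_to_trajectory(
                {"A": strand.coords, "B": other}, strand)
            values.append(hydrophobic_sasa(traj.frame(0))["total"])
        assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))


class TestStrandPolarity:
    def test_antiparallel_in_register(self, antiparallel_dimer):
        frame = antiparallel_dimer.frame(0)
        ss = assign_beta_structure(frame)
        assert strand_polarity(frame, ss, "A", "B") == ("antiparallel", 0)

    def test_parallel_shifted_by_one(self):
        traj = synthetic_data.build_ideal_dimer_trajectory(
            "parallel", registry_shift=-1)
        frame = traj.frame(0)
        ss = assign_beta_structure(frame)
        assert strand_polarity(frame, ss, "A", "B") == ("parallel", 1)

    def test_orientation_agrees_with_bridges(self, antiparallel_dimer,
                                             parallel_dimer):
        for traj, expected in ((antiparallel_dimer, -1), (parallel_dimer, 1)):
            frame = traj.frame(0)
            z = chain_z_vectors(frame)
            pol, _ = strand_polarity(frame, assign_beta_structure(frame),
                                     "A", "B")
            assert np.sign(z[0] @ z[1]) == expected
            assert (pol == "parallel") == (expected == 1)

    def test_no_bridges_rejected(self):
        strand = synthetic_data.build_ideal_hexapeptide()
        traj = synthetic_data.chains_to_trajectory(
            {"A": strand.coords, "B": strand.coords + [0, 3.0, 0]}, strand)
        frame = traj.frame(0)
        with pytest.raises(ValueError):
            strand_polarity(frame, assign_beta_structure(frame), "A", "B")


class TestContactMap:
    def test_in_register_antiparallel_antidiagonal(self, antiparallel_dimer):
        frame = antiparallel_dimer.frame(0)
        m = cluster_contact_map([(frame, "A", "B")] * 5)
        for p in range(2, 6):
            assert m[p - 1, 6 - p] == 1.0

    def test_single_dimer_binary(self, parallel_dimer):
        m = cluster_contact_map([(parallel_dimer.frame(0), "A", "B")])
        assert set(np.unique(m)) <= {0.0, 1.0}

    def test_recount_matches_bruteforce(self, antiparallel_dimer,
                                        parallel_dimer):
        frames = [(antiparallel_dimer.frame(0), "A", "B"),
                  (parallel_dimer.frame(0), "A", "B")]
        m = cluster_contact_map(frames)
        expected = np.zeros((6, 6))
        for frame, _, _ in frames:
            top = frame.topology
            heavy = top.heavy_mask
            for p in range(1, 7):
                for q in range(1, 7):
                    xa = frame.coords[(top.atom_chain == 0)
                                      & (top.atom_resid == p) & heavy]
                    xb = frame.coords[(top.atom_chain == 1)
                                      & (top.atom_resid == q) & heavy]
                    d = np.linalg.norm(xa[:, None] - xb[None, :], axis=-1)
                    if (d <= 0.45).any():
                        expected[p - 1, q - 1] += 1
        assert np.array_equal(m, expected / 2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cluster_contact_map([])


class TestLandscape:
    def test_copies_of_reference_single_peak(self, reference_dimers):
        ref = reference_dimers["antiparallel"]
        mc = ref.mainchain_coords().reshape(-1, 3)
        elements = np.array(["C"] * len(mc))
        ens = np.tile(mc, (20, 1, 1))
        ls = landscape_from_ensemble(ens, elements, mc, bins=10)
        assert ls.counts.max() == 20
        assert ls.frequency.max() == 1.0
        assert (ls.counts > 0).sum() == 1
        rg = radius_of_gyration(mc, elements)
        a = np.searchsorted(ls.rg_edges, rg) - 1
        assert ls.counts[a].sum() == 20

    def test_histogram_matches_bruteforce_binning(self):
        rng = np.random.default_rng(1)
        rgs = rng.uniform(0.4, 1.0, 500)
        rmsds = rng.uniform(0.0, 0.6, 500)
        ls = rg_rmsd_landscape(rgs, rmsds, bins=8)
        expected, _, _ = np.histogram2d(rgs, rmsds, bins=8)
        assert np.array_equal(ls.counts, expected)
        assert ls.counts.sum() == 500
        assert ls.frequency.max() == 1.0

    def test_unequal_modes_normalization(self):
        rgs = np.array([0.5] * 30 + [1.5] * 10)
        rmsds = np.zeros(40)
        ls = rg_rmsd_landscape(rgs, rmsds, bins=2)
        vals = sorted(ls.frequency.ravel(), reverse=True)[:2]
        assert vals[0] == 1.0
        assert vals[1] == pytest.approx(10 / 30)


class TestStratify:
    def test_scripted_means(self):
        sizes = np.array([2, 2, 3, 3, 3])
        values = np.array([0.8, 0.8, 0.5, 0.6, 0.7])
        df = stratify_by_order(values, sizes, dt=2.5, min_cumulative_ps=0.0)
        assert df.loc[df["size"] == 2, "mean"].item() == pytest.approx(0.8)
        assert df.loc[df["size"] == 3, "mean"].item() == pytest.approx(0.6)

    def test_cumulative_occurrence_exclusion(self):
        # size 2 occurs 40 ns, size 3 occurs 60 ns; threshold 50 ns
        sizes = np.array([2] * 16000 + [3] * 24000)
        values = np.ones(40000)
        df = stratify_by_order(values, sizes, dt=2.5,
                               min_cumulative_ps=50000.0)
        assert df.loc[df["size"] == 2, "excluded"].item()
        assert not df.loc[df["size"] == 3, "excluded"].item()

    def test_recount_matches_groupby_oracle(self):
        rng = np.random.default_rng(9)
        sizes = rng.integers(2, 6, 300)
        values = rng.normal(size=300)
        df = stratify_by_order(values, sizes, dt=2.5, min_cumulative_ps=0.0)
        for s in np.unique(sizes):
            sel = values[sizes == s]
            row = df[df["size"] == s]
            assert row["mean"].item() == pytest.approx(sel.mean())
            assert row["n"].item() == len(sel)
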