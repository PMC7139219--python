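"""Contact fingerprints, reproducibility, binding modes, deformation maps."""

import numpy as np
import pytest

from lolkit import contacts as ct
from lolkit import fixtures as fx


def brute_force_counts(universe, classes, cutoff=6.0):
    """Oracle: all-pairs minimum-image distances, binary per frame/residue/class."""
    import re

    prot = universe.select_atoms("protein")
    lip = universe.select_atoms("not protein")
    resids = prot.residues.resids
    counts = {rid: {c: 0 for c in classes} for rid in resids}
    for _ in universe.trajectory:
        box = universe.dimensions[:3]
        for rid in resids:
            ratoms = prot.select_atoms(f"resid {rid}")
            for label, pattern in classes.items():
                rx = re.compile(pattern)
                hit = False
                for rp in ratoms.positions:
                    for name, lp in zip(lip.names, lip.positions):
                        if not rx.match(name):
                            continue
                        d = rp - lp
                        d -= box * np.round(d / box)
                        if np.linalg.norm(d) <= cutoff:
                            hit = True
                            break
                    if hit:
                        break
                counts[rid][label] += int(hit)
    return counts


def make_profile(counts, label=""):
    n = len(counts)
    return ct.ContactProfile(
        resids=np.arange(1, n + 1), resnames=np.array(["ALA"] * n, object),
        classes=("PO4",), counts=np.asarray(counts).reshape(n, 1),
        n_frames=int(max(np.max(counts), 1)), label=label)


class TestContactProfile:
    def test_matches_generator_ground_truth(self):
        truth = {1: {"PO4": 3}, 2: {"Tail": 5}, 3: {"GL0": 2, "NH3": 1},
                 4: {"GL1:2": 7}}
        fix = fx.make_membrane_trajectory(truth, n_frames=8, n_residues=5, seed=3)
        prof = ct.contact_profile(fix.universe)
        for i, rid in enumerate(prof.resids):
            got = {c: int(v) for c, v in zip(prof.classes, prof.counts[i]) if v}
            assert got == fix.ground_truth.get(int(rid), {})

    def test_matches_brute_force_oracle(self):
        truth = {1: {"PO4": 2, "Tail": 1}, 2: {"NH3": 3}}
        fix = fx.make_membrane_trajectory(truth, n_frames=3, n_residues=2, seed=9)
        prof = ct.contact_profile(fix.universe)
        oracle = brute_force_counts(fix.universe, ct.DEFAULT_BEAD_CLASSES)
        for i, rid in enumerate(prof.resids):
            assert dict(zip(prof.classes, prof.counts[i].tolist())) == oracle[int(rid)]

    def test_periodic_wrapping_counts_across_boundary(self):
        """A bead 3 A outside the box edge is 3+eps A from one at the edge."""
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        u = mda.Universe.empty(2, n_residues=2, n_segments=2,
                               atom_resindex=[0, 1], residue_segindex=[0, 1],
                               trajectory=True)
        u.add_TopologyAttr("names", ["BB", "PO4"])
        u.add_TopologyAttr("resnames", ["ALA", "LIP"])
        u.add_TopologyAttr("resids", [1, 2])
        u.add_TopologyAttr("segids", ["PROT", "MEMB"])
        # protein at x=1, lipid at x=48 in a 50 A box: direct 47, wrapped 3
        u.load_new(np.array([[[1.0, 10, 10], [48.0, 10, 10]]]),
                   format=MemoryReader,
                   dimensions=np.array([[50.0, 50, 50, 90, 90, 90]]))
        prof = ct.contact_profile(u)
        assert prof.counts[0][list(prof.classes).index("PO4")] == 1

    def test_cutoff_boundaries(self):
        fix = fx.make_membrane_trajectory({}, n_frames=1, n_residues=1, seed=0)
        prof = ct.contact_profile(fix.universe, cutoff=6.0)
        assert prof.totals().sum() == 0

    def test_empty_selection_errors(self):
        fix = fx.make_membrane_trajectory({1: {"PO4": 1}}, 2, 1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            ct.contact_profile(fix.universe, protein_sel="name NOPE")

    def test_tsv_round_trip(self, tmp_path):
        fix = fx.make_membrane_trajectory({1: {"PO4": 2}}, 4, 2, seed=5)
        prof = ct.contact_profile(fix.universe)
        path = tmp_path / "prof.tsv"
        prof.to_tsv(path)
        back = ct.ContactProfile.from_tsv(path)
        assert np.array_equal(back.counts, prof.counts)
        assert back.n_frames == prof.n_frames
        assert back.classes == prof.classes


class TestReplicateCorrelation:
    def test_identical_profiles_give_unit_correlation(self):
        p = make_profile([3, 0, 5, 2])
        mat = ct.replicate_correlation([p, make_profile([3, 0, 5, 2])])
        assert mat.r[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_profiles_give_minus_one(self):
        a = np.array([4, 0, 6, 2])
        b = (2 * a.mean() - a).astype(int)   # reflection about the mean
        mat = ct.replicate_correlation([make_profile(a), make_profile(b)])
        assert mat.r[0, 1] == pytest.approx(-1.0)

    def test_matrix_is_symmetric_with_unit_diagonal(self, rng):
        profs = [make_profile(rng.integers(0, 10, 6)) for _ in range(4)]
        mat = ct.replicate_correlation(profs)
        assert np.allclose(mat.r, mat.r.T, equal_nan=True)
        assert np.allclose(np.diag(mat.r), 1.0)
        valid = np.isfinite(mat.r)
        assert np.all(mat.r[valid] >= -1.0) and np.all(mat.r[valid] <= 1.0)

    def test_zero_variance_reported_missing_not_zero(self):
        flat = make_profile([2, 2, 2, 2])
        mat = ct.replicate_correlation([flat, make_profile([1, 2, 3, 4])])
        assert np.isnan(mat.r[0, 1])

    def test_uncorrelated_profiles_average_near_zero(self, rng):
        rs = []
        for _ in range(200):
            a = make_profile(rng.integers(0, 20, 40))
            b = make_profile(rng.integers(0, 20, 40))
            rs.append(ct.replicate_correlation([a, b]).r[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_replicates_from_same_ground_truth_correlate_exactly(self):
        truth = {1: {"PO4": 3}, 2: {"Tail": 6}, 3: {"NH3": 1}}
        profs = [ct.contact_profile(
            fx.make_membrane_trajectory(truth, 8, 3, seed=s).universe)
            for s in (1, 2)]
        assert ct.replicate_correlation(profs).r[0, 1] == pytest.approx(1.0)


class TestBindingModes:
    @staticmethod
    def matrix(r):
        r = np.asarray(r, float)
        return ct.ReproducibilityMatrix(r=r, labels=tuple(
            f"rep{i+1}" for i in range(len(r))))

    def test_all_high_is_one_mode(self):
        r = np.full((5, 5), 0.9)
        np.fill_diagonal(r, 1.0)
        out = ct.classify_binding_modes(self.matrix(r))
        assert out.modes == ((0, 1, 2, 3, 4),)
        assert set(out.mode_of) == {1}

    def test_block_structure_primary_and_secondary(self):
        r = np.full((5, 5), -0.5)
        r[:4, :4] = 0.8
        np.fill_diagonal(r, 1.0)
        out = ct.classify_binding_modes(self.matrix(r))
        assert out.modes == ((0, 1, 2, 3), (4,))
        assert out.primary == (0, 1, 2, 3)
        assert out.mode_of == (1, 1, 1, 1, 2)

    def test_single_linkage_chains_through_intermediates(self):
        """Oracle: single linkage joins a-b and b-c even when r(a,c) is low."""
        r = np.eye(3)
        r[0, 1] = r[1, 0] = 0.9
        r[1, 2] = r[2, 1] = 0.9
        r[0, 2] = r[2, 0] = -0.9
        out = ct.classify_binding_modes(self.matrix(r))
        assert out.modes == ((0, 1, 2),)

    def test_impossible_threshold_gives_singletons(self, rng):
        r = rng.uniform(-1, 0.99, (4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        out = ct.classify_binding_modes(self.matrix(r), threshold=1.0)
        assert len(out.modes) == 4

    def test_invariant_under_relabeling(self, rng):
        r = rng.uniform(-1, 1, (5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        perm = rng.permutation(5)
        out = ct.classify_binding_modes(self.matrix(r))
        out_p = ct.classify_binding_modes(self.matrix(r[np.ix_(perm, perm)]))
        sizes = sorted(len(m) for m in out.modes)
        assert sizes == sorted(len(m) for m in out_p.modes)


class TestDeformation:
    def test_flat_membrane_recovers_bulk_thickness(self):
        fix = fx.make_deformed_membrane(n_frames=3, noise=0.0, seed=2)
        surf = ct.deformation_surface(fix.universe, bin_size=10.0)
        assert surf.bulk_thickness == pytest.approx(22.0, abs=0.1)
        assert surf.max_thickness == pytest.approx(surf.bulk_thickness, abs=0.1)

    def test_funnel_field_recovered_within_half_bin(self):
        bin_size = 5.0
        funnel = lambda x, y: 11.0 + 10.0 * np.exp(
            -(((np.asarray(x) - 60.0) ** 2 + (np.asarray(y) - 60.0) ** 2) / 800.0))
        fix = fx.make_deformed_membrane(funnel, n_frames=6,
                                        n_beads_per_leaflet=4000,
                                        noise=0.0, seed=4)
        surf = ct.deformation_surface(fix.universe, bin_size=bin_size)
        xc = 0.5 * (surf.x_edges[:-1] + surf.x_edges[1:])
        yc = 0.5 * (surf.y_edges[:-1] + surf.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        expected = funnel(xx, yy)
        ok = ~surf.empty
        assert np.nanmax(np.abs(surf.upper[ok] - expected[ok])) < bin_size / 2

    def test_empty_bins_flagged_not_zero(self):
        fix = fx.make_deformed_membrane(n_frames=1, n_beads_per_leaflet=30,
                                        seed=6)
        surf = ct.deformation_surface(fix.universe, bin_size=4.0)
        assert surf.empty.any()
        assert np.isnan(surf.thickness[surf.empty]).all()

    def test_tsv_and_heatmap_outputs(self, tmp_path):
        fix = fx.make_deformed_membrane(n_frames=2, seed=1)
        surf = ct.deformation_surface(fix.universe, bin_size=10.0)
        surf.to_tsv(tmp_path / "surf.tsv")
        surf.plot(tmp_path / "surf.png")
        assert (tmp_path / "surf.tsv").stat().st_size > 0
        assert (tmp_path / "surf.png").stat().st_size > 0


class TestEnrichment:
    @staticmethod
    def profile(resnames, counts, classes=("PO4", "Tail")):
        counts = np.asarray(counts)
        return ct.ContactProfile(
            resids=np.arange(1, len(resnames) + 1),
            resnames=np.array(resnames, object), classes=classes,
            counts=counts, n_frames=int(counts.max(initial=1)))

    def test_single_protein_single_residue_type(self):
        p = self.profile(["PHE", "ALA"], [[0, 10], [0, 0]])
        table = ct.residue_class_enrichment([p])
        assert table.loc["PHE", "Tail"] == 10.0
        assert table.loc["ALA", "Tail"] == 0.0

    def test_aggregate_equals_concat_then_group_oracle(self):
        import pandas as pd

        p1 = self.profile(["PHE", "LYS", "PHE"], [[1, 4], [5, 0], [3, 8]])
        p2 = self.profile(["LYS"], [[7, 2]])
        table = ct.residue_class_enrichment([p1, p2])
        rows = pd.DataFrame(
            [("PHE", 1, 4), ("LYS", 5, 0), ("PHE", 3, 8), ("LYS", 7, 2)],
            columns=["resname", "PO4", "Tail"])
        oracle = rows.groupby("resname").mean().sort_index()
        assert np.allclose(table.to_numpy(), oracle.to_numpy())

    def test_order_invariant(self):
        p1 = self.profile(["PHE"], [[1, 4]])
        p2 = self.profile(["LYS"], [[5, 0]])
        a = ct.residue_class_enrichment([p1, p2])
        b = ct.residue_class_enrichment([p2, p1])
        assert a.equals(b)
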