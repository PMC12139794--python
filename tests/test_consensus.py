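import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrosite.consensus import (
    aggregate_waters,
    classify_consensus,
    cluster_waters,
    filter_first_shell,
    superpose,
)
from hydrosite.model import (
    DegenerateGeometryError,
    SoluteStructure,
    ValidationError,
)
from hydrosite.structure_io import StructureRecord
from hydrosite.synth import benchmark_solute

from oracles import clusters_union_find


def _protein(coords, chain="A"):
    n = len(coords)
    return SoluteStructure(
        coords=np.asarray(coords, dtype=float),
        atom_names=["CA"] * n,
        residue_names=["GLY"] * n,
        residue_ids=list(range(1, n + 1)),
        chain_ids=[chain] * n,
    )


@pytest.fixture()
def reference_protein(rng):
    return _protein(rng.uniform(0, 20, size=(12, 3)))


class TestSuperpose:
    def test_identity(self, reference_protein):
        tr, rmsd = superpose(reference_protein, reference_protein)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-8)

    def test_translation_recovered(self, reference_protein):
        shifted = _protein(reference_protein.coords + [1.0, 2.0, 3.0])
        tr, rmsd = superpose(shifted, reference_protein)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(tr.translation, [-1, -2, -3], atol=1e-8)

    def test_random_rotation_recovered(self, reference_protein):
        rot = Rotation.random(random_state=42)
        moved = _protein(rot.apply(reference_protein.coords) + [5.0, -3.0, 2.0])
        tr, rmsd = superpose(moved, reference_protein)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        # recovered rotation is the inverse of the applied one
        residual = Rotation.from_matrix(tr.rotation) * rot
        assert residual.magnitude() == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(
            tr.apply(moved.coords), reference_protein.coords, atol=1e-6
        )

    def test_rmsd_invariant_under_rigid_motion_of_mobile(self, reference_protein, rng):
        noisy = _protein(reference_protein.coords + rng.normal(0, 0.3, (12, 3)))
        _, rmsd0 = superpose(noisy, reference_protein)
        rot = Rotation.random(random_state=7)
        moved = _protein(rot.apply(noisy.coords) + [4.0, 4.0, 4.0])
        _, rmsd1 = superpose(moved, reference_protein)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)

    def test_too_few_pairs(self):
        a = _protein([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValidationError):
            superpose(a, a)

    def test_collinear_selection_is_degenerate(self):
        line = _protein([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)


class TestAggregate:
    def _records(self, solute, water_sets):
        return [
            StructureRecord(id=f"S{i}", solute=solute, waters=np.asarray(w))
            for i, w in enumerate(water_sets, start=1)
        ]

    def test_shell_boundary(self, reference_protein):
        atom = reference_protein.coords[0]
        near = atom + [3.9, 0, 0]
        far = atom + [4.1, 0, 0]
        # place far water away from all other atoms too
        dists = np.linalg.norm(reference_protein.coords - far, axis=1)
        if dists.min() <= 4.0:  # re-aim along a clear direction
            far = reference_protein.coords.max(axis=0) + [4.1, 4.1, 4.1]
        ref = StructureRecord(id="REF", solute=reference_protein,
                              waters=np.empty((0, 3)))
        recs = self._records(reference_protein, [[near], [far]])
        pooled = aggregate_waters(recs, ref, shell=4.0)
        ids = [sid for sid, _ in pooled]
        assert "S1" in ids and "S2" not in ids

    def test_record_without_waters_contributes_nothing(self, reference_protein):
        ref = StructureRecord(id="REF", solute=reference_protein,
                              waters=np.empty((0, 3)))
        recs = self._records(reference_protein, [np.empty((0, 3))])
        assert aggregate_waters(recs, ref) == []

    def test_waters_mapped_back_through_superposition(self, reference_protein):
        rot = Rotation.random(random_state=3)
        water = reference_protein.coords[0] + [2.0, 0.0, 0.0]
        moved_solute = _protein(rot.apply(reference_protein.coords))
        moved_water = rot.apply(water[None])
        rec = StructureRecord(id="MOB", solute=moved_solute, waters=moved_water)
        ref = StructureRecord(id="REF", solute=reference_protein,
                              waters=np.empty((0, 3)))
        pooled = aggregate_waters([rec], ref, shell=4.0)
        assert len(pooled) == 1
        np.testing.assert_allclose(pooled[0][1], water, atol=1e-6)


class TestClustering:
    def test_chain_of_three_across_structures(self):
        waters = [
            ("A", np.array([0.0, 0.0, 0.0])),
            ("B", np.array([0.8, 0.0, 0.0])),
            ("C", np.array([1.6, 0.0, 0.0])),
        ]
        clusters = cluster_waters(waters, link_cutoff=1.0)
        assert len(clusters) == 1
        assert clusters[0].n_structures == 3
        np.testing.assert_allclose(clusters[0].mean_position, [0.8, 0, 0])

    @pytest.mark.parametrize("gap,expected", [(1.2, 2), (1.0, 2), (0.999, 1)])
    def test_link_cutoff_is_strict(self, gap, expected):
        waters = [
            ("A", np.array([0.0, 0.0, 0.0])),
            ("B", np.array([gap, 0.0, 0.0])),
        ]
        assert len(cluster_waters(waters, link_cutoff=1.0)) == expected

    def test_same_structure_counted_once(self):
        waters = [
            ("A", np.array([0.0, 0.0, 0.0])),
            ("A", np.array([0.5, 0.0, 0.0])),
        ]
        clusters = cluster_waters(waters)
        assert len(clusters) == 1
        assert clusters[0].n_structures == 1
        assert len(clusters[0].members) == 2

    def test_partition_matches_union_find_oracle(self, rng):
        coords = rng.uniform(0, 8, size=(200, 3))
        waters = [(f"S{i % 9}", c) for i, c in enumerate(coords)]
        clusters = cluster_waters(waters, link_cutoff=1.0)
        oracle = clusters_union_find(coords, 1.0)
        # same partition: compare as sets of frozensets of point indices
        def key(points):
            return frozenset(
                tuple(np.round(p, 9)) for p in points
            )
        got = {key([p for _, p in c.members]) for c in clusters}
        want = {key([coords[i] for i in grp]) for grp in oracle}
        assert got == want
        assert sum(len(c.members) for c in clusters) == 200

    def test_mean_invariant_to_input_order(self, rng):
        coords = rng.uniform(0, 5, size=(50, 3))
        waters = [(f"S{i}", c) for i, c in enumerate(coords)]
        a = cluster_waters(waters)
        b = cluster_waters(waters[::-1])
        means_a = sorted(tuple(np.round(c.mean_position, 9)) for c in a)
        means_b = sorted(tuple(np.round(c.mean_position, 9)) for c in b)
        assert means_a == means_b


class TestShellFilterAndClassification:
    def test_first_shell_boundary(self):
        solute = _protein([[0.0, 0.0, 0.0], [0.0, 1.5, 0.0], [0.0, 0.0, 1.5]])
        near = cluster_waters([("A", np.array([3.20, 0.0, 0.0]))])
        at = cluster_waters([("A", np.array([3.25, 0.0, 0.0]))])
        far = cluster_waters([("A", np.array([3.30, 0.0, 0.0]))])
        assert len(filter_first_shell(near, solute)) == 1
        assert len(filter_first_shell(at, solute)) == 1  # inclusive <=
        assert len(filter_first_shell(far, solute)) == 0

    def test_empty_inputs(self):
        solute = benchmark_solute()
        assert filter_first_shell([], solute) == []
        empty = SoluteStructure(
            coords=np.empty((0, 3)), atom_names=[], residue_names=[],
            residue_ids=[], chain_ids=[],
        )
        clusters = cluster_waters([("A", np.zeros(3))])
        with pytest.raises(ValidationError):
            filter_first_shell(clusters, empty)

    @pytest.mark.parametrize(
        "n_structures,expected",
        [(9, "high"), (5, "high"), (4, "lower"), (1, "lower")],
    )
    def test_high_consensus_threshold(self, n_structures, expected):
        waters = [(f"S{i}", np.zeros(3)) for i in range(n_structures)]
        clusters = classify_consensus(cluster_waters(waters))
        assert len(clusters) == 1
        assert clusters[0].consensus_class == expected

    def test_class_counts_partition_total(self, rng):
        waters = [
            (f"S{rng.integers(0, 9)}", rng.uniform(0, 30, 3)) for _ in range(120)
        ]
        clusters = classify_consensus(cluster_waters(waters))
        n_high = sum(c.consensus_class == "high" for c in clusters)
        n_lower = sum(c.consensus_class == "lower" for c in clusters)
        assert n_high + n_lower == len(clusters)
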