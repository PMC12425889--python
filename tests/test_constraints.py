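"""Constraint assembly, extra-node TPS prediction, candidate selection."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from hbmpose.constraints import (
    ConstraintSet,
    ExtraNodeConfig,
    assemble_surface_constraints,
    predict_extra_nodes,
    select_interface_candidates,
)
from hbmpose.mesh_io import extract_surface
from hbmpose.tps import fit_tps


def limb_surfaces(fixture):
    mesh = fixture.mesh
    return (
        extract_surface(mesh, {fixture.parts["skin"]}, name="skin"),
        extract_surface(mesh, {fixture.parts["bone"]}, name="bone"),
    )


class TestAssemble:
    def test_identity_pose_reproduces_originals(self, small_limb):
        mesh = small_limb.mesh
        skin, bone = limb_surfaces(small_limb)
        cs = assemble_surface_constraints(
            mesh,
            [(skin, skin.coords(mesh)), (bone, bone.coords(mesh))],
        )
        assert len(cs) == skin.n_nodes + bone.n_nodes  # disjoint node sets
        np.testing.assert_allclose(
            cs.targets(skin.node_ids), skin.coords(mesh)
        )
        assert set(cs.tags.values()) == {"surface"}

    def test_posed_counts_and_no_conflicts(self, small_limb):
        mesh = small_limb.mesh
        posed = small_limb.posed_coords(45.0)
        skin, bone = limb_surfaces(small_limb)
        cs = assemble_surface_constraints(
            mesh,
            [
                (skin, posed[mesh.index_of(skin.node_ids)]),
                (bone, posed[mesh.index_of(bone.node_ids)]),
            ],
        )
        assert len(cs) == skin.n_nodes + bone.n_nodes

    def test_conflicting_duplicate_targets_rejected(self, small_limb):
        mesh = small_limb.mesh
        skin, _ = limb_surfaces(small_limb)
        shifted = skin.coords(mesh) + 1.0
        with pytest.raises(ValueError, match="conflict"):
            assemble_surface_constraints(
                mesh, [(skin, skin.coords(mesh)), (skin, shifted)]
            )

    def test_non_finite_target_rejected(self):
        cs = ConstraintSet()
        with pytest.raises(ValueError, match="non-finite"):
            cs.add(1, [np.nan, 0, 0])

    def test_json_round_trip(self, tmp_path, small_limb):
        mesh = small_limb.mesh
        skin, bone = limb_surfaces(small_limb)
        cs = assemble_surface_constraints(
            mesh, [(skin, skin.coords(mesh)), (bone, bone.coords(mesh))]
        )
        p = tmp_path / "c.json"
        cs.to_json(p)
        back = ConstraintSet.from_json(p)
        assert set(back.entries) == set(cs.entries)
        np.testing.assert_allclose(
            back.targets(cs.node_ids), cs.targets(cs.node_ids)
        )
        assert back.tags == cs.tags


class TestPredictExtraNodes:
    def rigid_constraints(self, fixture, seed=0):
        """All surface nodes carry one rigid motion."""
        mesh = fixture.mesh
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.uniform(-10, 10, 3)
        skin, bone = limb_surfaces(fixture)
        cs = ConstraintSet()
        for surf in (skin, bone):
            for nid, x in zip(surf.node_ids, surf.coords(mesh)):
                cs.add(int(nid), R @ x + t, tag="surface")
        return cs, R, t

    def test_rigid_motion_reproduced(self, small_limb):
        mesh = small_limb.mesh
        cs, R, t = self.rigid_constraints(small_limb)
        cand = small_limb.interface_ids["joint"][:40]
        out = predict_extra_nodes(
            mesh, cs, ExtraNodeConfig(k=30, candidate_ids=cand)
        )
        pred = out.targets(cand)
        expect = mesh.coords[mesh.index_of(cand)] @ R.T + t
        assert np.abs(pred - expect).max() <= 1e-6

    def test_coincident_candidate_inherits_constraint_target(self, small_limb):
        """A candidate sitting exactly on a constrained node must receive
        that node's target (exact interpolation at a control point)."""
        mesh = small_limb.mesh
        rng = np.random.default_rng(1)
        skin, _ = limb_surfaces(small_limb)
        cs = ConstraintSet()
        pool = skin.node_ids[:60]
        for nid in pool:
            i = mesh.index_of([nid])[0]
            cs.add(int(nid), mesh.coords[i] + rng.normal(0, 0.3, 3))
        donor = int(pool[10])
        cand = int(small_limb.interface_ids["joint"][0])
        # place the candidate on top of the donor in the original mesh
        coords = np.array(mesh.coords)
        coords[mesh.index_of([cand])[0]] = coords[mesh.index_of([donor])[0]]
        mesh2 = mesh.with_coords(coords)
        out = predict_extra_nodes(
            mesh2, cs, ExtraNodeConfig(k=30, candidate_ids=[cand])
        )
        np.testing.assert_allclose(
            out.entries[cand], cs.entries[donor], atol=1e-6
        )

    def test_tags_and_idempotence(self, small_limb):
        mesh = small_limb.mesh
        cs, *_ = self.rigid_constraints(small_limb, seed=2)
        cand = small_limb.interface_ids["joint"][:20]
        cfg = ExtraNodeConfig(k=30, candidate_ids=cand)
        once = predict_extra_nodes(mesh, cs, cfg)
        assert set(once.ids_with_tag("extra")) == set(map(int, cand))
        twice = predict_extra_nodes(mesh, once, cfg)
        assert len(twice) == len(once)
        np.testing.assert_allclose(
            twice.targets(once.node_ids), once.targets(once.node_ids)
        )

    def test_local_matches_global_tps_away_from_joint(self, small_limb):
        """On a smoothly posed limb, local k-NN predictions agree with a
        global TPS built from all constraints, away from the joint."""
        mesh = small_limb.mesh
        posed = small_limb.posed_coords(45.0)
        skin, bone = limb_surfaces(small_limb)
        cs = assemble_surface_constraints(
            mesh,
            [
                (skin, posed[mesh.index_of(skin.node_ids)]),
                (bone, posed[mesh.index_of(bone.node_ids)]),
            ],
        )
        cand = small_limb.interface_ids["flesh_inner"]
        zc = mesh.coords[mesh.index_of(cand), 2]
        L = small_limb.spec.seg_length
        far = cand[np.abs(zc - L) > 1.2 * small_limb.spec.band]
        out = predict_extra_nodes(
            mesh, cs, ExtraNodeConfig(k=30, candidate_ids=far)
        )
        glob = fit_tps(
            mesh.coords[mesh.index_of(cs.node_ids)], cs.targets()
        )
        pred = out.targets(far)
        ref = glob(mesh.coords[mesh.index_of(far)])
        edge = 2 * L / (2 * small_limb.spec.flesh_n_axial_per_seg)
        assert np.isfinite(pred).all()
        assert np.abs(pred - ref).max() <= 0.05 * edge

    def test_knn_matches_brute_force(self, small_limb):
        mesh = small_limb.mesh
        cs, *_ = self.rigid_constraints(small_limb, seed=3)
        ids = cs.node_ids
        pts = mesh.coords[mesh.index_of(ids)]
        tree = cKDTree(pts)
        q = mesh.coords[mesh.index_of(small_limb.interface_ids["joint"][:10])]
        d_tree, i_tree = tree.query(q, k=12)
        for row, x in enumerate(q):
            d = np.linalg.norm(pts - x, axis=1)
            brute = np.sort(d)[:12]
            np.testing.assert_allclose(np.sort(d_tree[row]), brute, rtol=1e-12)

    def test_k_below_minimum_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 5"):
            ExtraNodeConfig(k=4)

    def test_fewer_constraints_than_k_uses_all(self, small_limb):
        mesh = small_limb.mesh
        rng = np.random.default_rng(4)
        cs = ConstraintSet()
        skin, _ = limb_surfaces(small_limb)
        for nid in skin.node_ids[:8]:
            i = mesh.index_of([nid])[0]
            cs.add(int(nid), mesh.coords[i] + rng.normal(0, 0.1, 3))
        cand = small_limb.interface_ids["joint"][:3]
        out = predict_extra_nodes(
            mesh, cs, ExtraNodeConfig(k=30, candidate_ids=cand)
        )
        assert len(out) == 8 + 3


class TestInterfaceCandidates:
    def test_zero_threshold_empty(self, small_limb):
        got = select_interface_candidates(
            small_limb.mesh,
            small_limb.parts["organ"],
            small_limb.parts["bone"],
            threshold=0.0,
        )
        assert got.size == 0

    def test_organ_near_bone_ground_truth(self, small_limb):
        got = select_interface_candidates(
            small_limb.mesh,
            small_limb.parts["organ"],
            small_limb.parts["bone"],
            threshold=1.0,
        )
        expected = small_limb.interface_ids["organ"]
        np.testing.assert_array_equal(np.sort(got), np.sort(expected))

    def test_infinite_threshold_all_part_nodes(self, small_limb):
        got = select_interface_candidates(
            small_limb.mesh,
            small_limb.parts["organ"],
            small_limb.parts["bone"],
            threshold=np.inf,
        )
        organ_nodes = {
            n
            for el in small_limb.mesh.solids
            if el.pid == small_limb.parts["organ"]
            for n in el.nodes
        }
        assert set(map(int, got)) == organ_nodes
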