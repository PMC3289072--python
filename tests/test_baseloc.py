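import numpy as np
import pytest

from dnagroove import baseloc as bl
from dnagroove import dbu as dbum
from dnagroove import fixtures as fx
from dnagroove import knowledgebase as kbm
from dnagroove.geometry import random_rotation

from _oracles import brute_density

DBU_TYPES = ["ARG", "LYS", "ASN", "SER", "ARG"]


def _discovered(planted, trained_kb):
    model, truth = planted
    conserved = dbum.ConservedSet.all_residues(model)
    dbus = dbum.find_dbus(model, conserved, trained_kb.propensities)
    return model, truth, dbus[0]


def _mini_kb(n_instances=3):
    """Hand-built kb: one ARG model for base G with n translated instances."""
    frames = kbm.ReferenceFrameSpec(frames={"ARG": ("NH1", "NH2", "CZ")})
    model = kbm.GeometricModel("ARG", "G")
    base = np.array([[3.0, 1.0, 0.5], [4.0, 1.5, 0.5], [3.5, 2.5, 0.0]])
    for i in range(n_instances):
        model.instances.append(
            kbm.BaseInstance("train", ("X", i + 1, ""), "G",
                             ["N9", "C8", "N7"], base + i * 8.0)
        )
    model.pairwise_rmsd = kbm.pairwise_instance_rmsd(model)
    table = kbm.PropensityTable({"ARG": (1, 1)})
    return kbm.Knowledgebase(propensities=table, frames=frames,
                             models={("ARG", "G"): model})


def _arg_structure(make_struct):
    return make_struct([
        ("A", 1, "ARG", [("NH1", "N", (0, 0, 0)), ("NH2", "N", (1.3, 0.2, 0)),
                         ("CZ", "C", (0.6, 1.2, 0.1)), ("CA", "C", (2, 2, 2)),
                         ("C", "C", (3, 2, 2))]),
    ])


def _dbu_of(keys):
    return type("D", (), {"residues": frozenset(keys)})()


class TestPlaceModels:
    def test_instance_count(self, make_struct):
        kb = _mini_kb(3)
        s = _arg_structure(make_struct)
        placements = bl.place_models(_dbu_of({("A", 1, "")}), s, kb, "G")
        assert len(placements) == 3

    def test_empty_model_no_error(self, make_struct):
        kb = _mini_kb(3)
        s = _arg_structure(make_struct)
        with pytest.warns(UserWarning, match="no model instances"):
            assert bl.place_models(_dbu_of({("A", 1, "")}), s, kb, "T") == []

    def test_rigid_motion_equivariance(self, make_struct):
        kb = _mini_kb(2)
        s = _arg_structure(make_struct)
        rng = np.random.default_rng(3)
        rot, t = random_rotation(rng), rng.uniform(-15, 15, 3)
        moved = s.transformed(rot, t)
        d = _dbu_of({("A", 1, "")})
        p1 = bl.place_models(d, s, kb, "G")
        p2 = bl.place_models(d, moved, kb, "G")
        for a, b in zip(p1, p2):
            np.testing.assert_allclose((rot @ a.coords.T).T + t, b.coords, atol=1e-6)

    def test_roundtrip_recovers_training_geometry(self, planted, trained_kb):
        # every training (residue, base) contact is reproduced exactly by at
        # least one placement when models are placed back onto the training
        # structure itself
        model, truth, d = _discovered(planted, trained_kb)
        for b in "ACGT":
            placements = bl.place_models(d, model, trained_kb, b)
            for inst in (
                inst
                for key, m in trained_kb.models.items()
                if key[1] == b
                for inst in m.instances
            ):
                src = model.residue(inst.base_key)
                src_coords = np.array([src.atom(n).coord for n in inst.atom_names])
                err = min(
                    float(np.max(np.abs(p.coords - src_coords)))
                    for p in placements
                    if p.atom_names == inst.atom_names
                )
                assert err < 1e-9


class TestDensityScore:
    def test_unit_peak_single_atom(self, make_struct):
        kb = _mini_kb(1)
        s = _arg_structure(make_struct)
        d = _dbu_of({("A", 1, "")})
        (p,) = bl.place_models(d, s, kb, "G")
        single = bl.BasePlacement(
            base_type="G", model_key=("ARG", "G"), instance_index=0,
            residue_key=("A", 1, ""), atom_names=["N9"],
            coords=p.coords[:1],
        )
        params = bl.DensityParams()
        val = bl.density_score(single.coords[0], [single], d, s, params)
        assert val == pytest.approx(1.0)

    def test_decay_to_zero(self, make_struct):
        kb = _mini_kb(1)
        s = _arg_structure(make_struct)
        d = _dbu_of({("A", 1, "")})
        placements = bl.place_models(d, s, kb, "G")
        far = np.array([100.0, 100.0, 100.0])
        assert bl.density_score(far, placements, d, s, bl.DensityParams()) < 1e-10

    def test_matches_brute_force(self, planted, trained_kb):
        model, truth, d = _discovered(planted, trained_kb)
        params = bl.DensityParams()
        placements = bl.place_models(d, model, trained_kb, "G")
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.uniform(-10, 10, 3)
            got = bl.density_score(x, placements, d, model, params)
            want = brute_density(x, placements, d, model, params.kernel_sigma)
            assert got == pytest.approx(want, rel=1e-9)

    def test_duplicate_type_normalization(self, make_struct):
        kb = _mini_kb(2)
        s1 = _arg_structure(make_struct)
        # duplicate the ARG at the same coordinates under a new key
        atoms = [(a.name, a.element, tuple(a.coord)) for a in s1.residues[0].atoms]
        s2 = make_struct([("A", 1, "ARG", atoms), ("A", 2, "ARG", atoms)])
        d1 = _dbu_of({("A", 1, "")})
        d2 = _dbu_of({("A", 1, ""), ("A", 2, "")})
        p1 = bl.place_models(d1, s1, kb, "G")
        p2 = bl.place_models(d2, s2, kb, "G")
        params = bl.DensityParams()
        x = p1[0].centroid
        assert bl.density_score(x, p2, d2, s2, params) == pytest.approx(
            bl.density_score(x, p1, d1, s1, params)
        )


class TestCoreFilter:
    def _globule(self, make_struct, n=60, radius=8.0, seed=0):
        rng = np.random.default_rng(seed)
        specs = []
        for i in range(n):
            v = rng.normal(size=3)
            v = v / np.linalg.norm(v) * rng.uniform(0, radius)
            specs.append(("A", i + 1, "ALA",
                          [("CA", "C", tuple(v)), ("CB", "C", tuple(v + 0.8))]))
        return make_struct(specs)

    def _placement(self, center, pid=0):
        coords = np.asarray(center, float) + np.array(
            [[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]
        )
        return bl.BasePlacement(
            base_type="G", model_key=("ARG", "G"), instance_index=0,
            residue_key=("A", 1, ""), atom_names=["N9", "C8", "N7"],
            coords=coords, placement_id=pid,
        )

    def test_buried_scores_higher_than_exposed(self, make_struct):
        s = self._globule(make_struct)
        params = bl.DensityParams()
        inside = bl.core_scores(np.zeros((1, 3)), s, params)[0]
        outside = bl.core_scores(np.array([[28.0, 0, 0]]), s, params)[0]
        assert inside > outside

    def test_clash_terminates_keep_loop(self, make_struct):
        s = self._globule(make_struct)
        far = self._placement((40, 0, 0), 0)       # exposed, low core
        clashing = self._placement((9.0, 0, 0), 1)  # near surface atoms
        buried = self._placement((0.5, 0, 0), 2)    # center, highest core
        clashing.coords[0] = s.residues[0].atoms[0].coord + 0.5  # force clash
        kept = bl.core_filter([far, clashing, buried], s, params=bl.DensityParams())
        assert [p.placement_id for p in kept] == [0]

    def test_no_clash_keeps_all(self, make_struct):
        s = self._globule(make_struct)
        ps = [self._placement((30 + 5 * i, 0, 0), i) for i in range(3)]
        kept = bl.core_filter(ps, s, params=bl.DensityParams())
        assert len(kept) == 3

    def test_prefix_property(self, make_struct):
        s = self._globule(make_struct)
        ps = [self._placement((12 + 3 * i, 0, 0), i) for i in range(5)]
        ps[3].coords[0] = s.residues[0].atoms[0].coord + 0.3
        kept = bl.core_filter(ps, s, params=bl.DensityParams())
        scores = sorted(p.core_score for p in ps)
        kept_scores = [p.core_score for p in kept]
        # kept placements form a prefix of the core-score ordering
        assert kept_scores == scores[: len(kept_scores)]

    def test_clash_boundary(self, make_struct):
        s = make_struct([("A", 1, "ALA", [("CA", "C", (0, 0, 0))])])
        params = bl.DensityParams()
        for d, expected in ((1.9, 0), (2.1, 1)):
            p = self._placement((d, 0, 0))
            p.coords = np.array([[d, 0.0, 0.0], [d + 1, 0, 0], [d, 1, 0]])
            assert len(bl.core_filter([p], s, params)) == expected

    def test_no_ca_atoms_error(self, make_struct):
        s = make_struct([("A", 1, "ALA", [("CB", "C", (0, 0, 0))])])
        with pytest.raises(ValueError, match="CA"):
            bl.core_scores(np.zeros((1, 3)), s, bl.DensityParams())


class TestDiverseSelect:
    def _p(self, offset, density, pid):
        coords = np.array([[0, 0, 0], [1.0, 0, 0], [0, 1.0, 0]]) + offset
        p = bl.BasePlacement(
            base_type="G", model_key=("ARG", "G"), instance_index=pid,
            residue_key=("A", 1, ""), atom_names=["N9", "C8", "N7"],
            coords=coords, placement_id=pid,
        )
        p.density = density
        return p

    def test_identical_placements_keep_first(self):
        a, b = self._p(0.0, 1.0, 0), self._p(0.0, 1.0, 1)
        kept = bl.diverse_select([a, b], bl.DensityParams())
        assert [p.placement_id for p in kept] == [0]

    def test_distant_placements_both_kept(self):
        a, b = self._p(0.0, 2.0, 0), self._p(10.0, 1.0, 1)
        kept = bl.diverse_select([a, b], bl.DensityParams())
        assert [p.placement_id for p in kept] == [0, 1]

    @pytest.mark.parametrize("offset,expected", [(4.9, 1), (5.1, 2)])
    def test_diversity_boundary(self, offset, expected):
        # pure translation: RMSD equals |offset|
        a = self._p(0.0, 2.0, 0)
        b = self._p(np.array([offset, 0.0, 0.0]), 1.0, 1)
        kept = bl.diverse_select([a, b], bl.DensityParams())
        assert len(kept) == expected

    def test_greedy_matches_brute_force(self):
        rng = np.random.default_rng(17)
        placements = [
            self._p(rng.uniform(0, 12, 3), float(rng.uniform(0, 5)), pid)
            for pid in range(12)
        ]
        params = bl.DensityParams()
        kept = bl.diverse_select(list(reversed(placements)), params)
        # brute force: sort by (-density, id), greedy scan
        order = sorted(placements, key=lambda p: (-p.density, p.placement_id))
        want = []
        for p in order:
            if all(bl.placement_rmsd(p, q) > params.diversity_rmsd for q in want):
                want.append(p)
        assert [p.placement_id for p in kept] == [p.placement_id for p in want]


class TestPredictBaseLocation:
    def test_self_consistency_top_placement_on_true_base(self, planted, trained_kb):
        model, truth, d = _discovered(planted, trained_kb)
        for b in "ACGT":
            res = bl.predict_base_location(d, model, trained_kb, b)
            assert res.status == "ok" and res.best is not None
            src_key = trained_kb.models[res.best.model_key].instances[
                res.best.instance_index].base_key
            true_centroid = model.residue(src_key).base_centroid()
            assert np.linalg.norm(res.best.centroid - true_centroid) < 1.0

    def test_parameter_recovery_on_rotated_copy(self, duplex16, trained_kb):
        rng = np.random.default_rng(23)
        spec = fx.PlantedDBUSpec(residue_types=DBU_TYPES, center_bp=8,
                                 jitter_sd=0.25, seed=23)
        query, truth = fx.plant_dbu(duplex16, spec)
        rot, t = random_rotation(rng), rng.uniform(-20, 20, 3)
        query = query.transformed(rot, t)
        conserved = dbum.ConservedSet.all_residues(query)
        d = dbum.find_dbus(query, conserved, trained_kb.propensities)[0]
        from dnagroove.evaluation import location_error

        best = None
        for b in "ACGT":
            res = bl.predict_base_location(d, query, trained_kb, b)
            if res.best is not None and (best is None or res.best.density > best.density):
                best = res.best
        assert location_error(best, query) < 2.0

    def test_empty_models_status(self, make_struct):
        kb = _mini_kb(0)
        kb.models.clear()
        s = _arg_structure(make_struct)
        with pytest.warns(UserWarning):
            res = bl.predict_base_location(_dbu_of({("A", 1, "")}), s, kb, "G")
        assert res.status == "no-models"
        assert res.placements == [] and res.best is None

    def test_end_to_end_rigid_equivariance(self, planted, trained_kb):
        model, truth, d = _discovered(planted, trained_kb)
        rng = np.random.default_rng(31)
        rot, t = random_rotation(rng), rng.uniform(-25, 25, 3)
        moved = model.transformed(rot, t)
        conserved = dbum.ConservedSet.all_residues(moved)
        d2 = dbum.find_dbus(moved, conserved, trained_kb.propensities)[0]
        assert d2.residues == d.residues
        r1 = bl.predict_base_location(d, model, trained_kb, "G")
        r2 = bl.predict_base_location(d2, moved, trained_kb, "G")
        assert len(r1.placements) == len(r2.placements)
        for a, b in zip(r1.placements, r2.placements):
            np.testing.assert_allclose(rot @ a.centroid + t, b.centroid, atol=1e-6)


class TestDensityParams:
    @pytest.mark.parametrize("field", [
        "kernel_sigma", "core_sigma", "clash_distance", "diversity_rmsd",
    ])
    def test_positive_required(self, field):
        with pytest.raises(ValueError):
            bl.DensityParams(**{field: 0.0})
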