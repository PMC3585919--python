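"""Per-atom fields, distance-window confirmation (vs brute force), merging."""

import numpy as np
import pytest

from locsurf import prediction as P
from locsurf.training import DistanceBounds


def _field(values, ids=None, role="P_A"):
    return P.ProbabilityField(
        surface_id="s", values=np.asarray(values, float), role=role,
        resolution="representatives" if ids is not None else "vertices",
        sample_ids=None if ids is None else np.asarray(ids, int),
    )


def brute_force_confirm(fields, positions, bounds, radii, cutoff, combine="arithmetic"):
    """Independent triple-loop reimplementation of the confirmation rule."""
    out = {}
    names = sorted(fields)
    for a in names:
        fa = fields[a]
        pc = np.empty(len(fa.values))
        for si, s in enumerate(fa.sample_ids):
            confs = []
            for b in names:
                if b == a:
                    continue
                lo, hi = bounds.get(a, b)
                if lo > cutoff:
                    continue
                fb = fields[b]
                window = []
                for sj, sp in enumerate(fb.sample_ids):
                    d = float(np.linalg.norm(positions[s] - positions[sp]))
                    r = float(radii[b][sj])
                    if lo - r <= d <= hi + r:
                        window.append(fb.values[sj])
                confs.append(sum(window) / len(window) if window else 0.0)
            if confs:
                if combine == "arithmetic":
                    agg = sum(confs) / len(confs)
                else:
                    agg = float(np.exp(np.mean(np.log(np.maximum(confs, 1e-300)))))
                    if any(c == 0 for c in confs):
                        agg = 0.0
                pc[si] = fa.values[si] * agg
            else:
                pc[si] = fa.values[si]
        out[a] = pc
    return out


class TestConfirmFields:
    def _random_setup(self, seed, n=30, n_atoms=3):
        rng = np.random.default_rng(seed)
        positions = rng.uniform(-8, 8, size=(n, 3))
        names = [f"A{k}" for k in range(n_atoms)]
        fields, radii = {}, {}
        for k, a in enumerate(names):
            ids = np.sort(rng.choice(n, size=rng.integers(5, n), replace=False))
            fields[a] = _field(rng.uniform(0, 1, size=len(ids)), ids)
            radii[a] = rng.choice([0.0, 0.5, 1.0, 2.0], size=len(ids))
        b = {}
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                lo = float(rng.uniform(0.5, 6.0))
                b[frozenset((names[i], names[j]))] = (lo, lo + float(rng.uniform(0, 6)))
        return fields, positions, DistanceBounds(b), radii

    @pytest.mark.parametrize("combine", ["arithmetic", "geometric"])
    def test_matches_brute_force_100_seeds(self, combine):
        for seed in range(100):
            fields, pos, bounds, radii = self._random_setup(seed)
            got = P.confirm_fields(fields, pos, bounds, radii, combine=combine)
            want = brute_force_confirm(fields, pos, bounds, radii,
                                       P.PAIR_CUTOFF, combine)
            for a in fields:
                np.testing.assert_allclose(got[a].values, want[a], rtol=0, atol=1e-12)

    def test_full_confirmation_identity(self):
        # P_B ≡ 1 everywhere -> PC_A = P_A
        pos = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [5, 5, 0.0]])
        fa = _field([0.2, 0.9], [0, 1])
        fb = _field([1.0, 1.0], [2, 3])
        bounds = DistanceBounds({frozenset(("A", "B")): (1.0, 10.0)})
        radii = {"A": np.zeros(2), "B": np.zeros(2)}
        out = P.confirm_fields({"A": fa, "B": fb}, pos, bounds, radii)
        np.testing.assert_allclose(out["A"].values, fa.values)

    def test_zero_partner_disconfirms(self):
        pos = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        fa = _field([0.8, 0.5], [0, 1])
        fb = _field([0.0], [2])
        bounds = DistanceBounds({frozenset(("A", "B")): (1.0, 10.0)})
        radii = {"A": np.zeros(2), "B": np.zeros(1)}
        out = P.confirm_fields({"A": fa, "B": fb}, pos, bounds, radii)
        np.testing.assert_allclose(out["A"].values, 0.0)

    def test_empty_window_disconfirms(self):
        pos = np.array([[0, 0, 0], [100, 0, 0.0]])
        fa = _field([0.9], [0])
        fb = _field([0.9], [1])
        bounds = DistanceBounds({frozenset(("A", "B")): (1.0, 5.0)})
        radii = {"A": np.zeros(1), "B": np.zeros(1)}
        out = P.confirm_fields({"A": fa, "B": fb}, pos, bounds, radii)
        assert out["A"].values[0] == 0.0

    def test_pair_beyond_cutoff_excluded(self):
        pos = np.array([[0, 0, 0], [20, 0, 0.0]])
        fa = _field([0.9], [0])
        fb = _field([0.0], [1])
        bounds = DistanceBounds({frozenset(("A", "B")): (18.0, 25.0)})
        radii = {"A": np.zeros(1), "B": np.zeros(1)}
        out = P.confirm_fields({"A": fa, "B": fb}, pos, bounds, radii)
        # min bound 18 > 15 Å cutoff: B contributes nothing, PC_A = P_A
        assert out["A"].values[0] == pytest.approx(0.9)

    def test_confirmed_never_exceeds_raw(self):
        for seed in (0, 1, 2):
            fields, pos, bounds, radii = self._random_setup(seed, n=40)
            out = P.confirm_fields(fields, pos, bounds, radii)
            for a in fields:
                assert np.all(out[a].values <= fields[a].values + 1e-12)

    def test_missing_bounds_rejected(self):
        pos = np.zeros((2, 3))
        fields = {"A": _field([0.5], [0]), "B": _field([0.5], [1])}
        radii = {"A": np.zeros(1), "B": np.zeros(1)}
        with pytest.raises(KeyError):
            P.confirm_fields(fields, pos, DistanceBounds({}), radii)


class TestExpandAndMerge:
    def _groups(self, member_of, radii):
        from locsurf.grouping import SampleGroups
        reps = sorted(set(member_of.values()))
        return SampleGroups(
            representatives=np.asarray(reps),
            member_of=member_of,
            patch_radius={r: radii.get(r, 0.0) for r in reps},
            unassigned=np.array([], int),
        )

    def test_singleton_groups_identity(self):
        groups = self._groups({0: 0, 1: 1, 2: 2}, {})
        f = _field([0.1, 0.5, 0.9], [0, 1, 2])
        out = P.expand_field(f, groups)
        np.testing.assert_allclose(out.values, f.values)

    def test_copy_semantics_and_max_preserved(self):
        member_of = {v: 0 for v in range(10)}
        member_of.update({10: 10})
        groups = self._groups(member_of, {0: 4.0})
        f = _field([0.7, 0.2], [0, 10])
        out = P.expand_field(f, groups)
        assert np.all(out.values[:10] == 0.7)
        assert out.values[10] == 0.2
        assert out.values.max() == f.values.max()

    def test_merge_moiety_max_semantics(self):
        a = _field([0.2, 0.4])
        b = _field([0.9, 0.1])
        c = _field([0.4, 0.4])
        m = P.merge_moiety([a, b, c])
        np.testing.assert_allclose(m.values, [0.9, 0.4])
        assert m.role == "P_M"
        # single field -> identity; zero field is the max identity element
        np.testing.assert_allclose(P.merge_moiety([a]).values, a.values)
        np.testing.assert_allclose(
            P.merge_moiety([a, _field([0.0, 0.0])]).values, a.values)
        # P_M dominates every input pointwise
        for f in (a, b, c):
            assert np.all(m.values >= f.values)

    def test_merge_ligand_commutative_associative(self):
        rng = np.random.default_rng(0)
        fs = [_field(rng.uniform(0, 1, 8)) for _ in range(3)]
        m1 = P.merge_ligand(fs).values
        m2 = P.merge_ligand(fs[::-1]).values
        m3 = P.merge_ligand([P.merge_ligand(fs[:2]), fs[2]]).values
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(m1, m3)

    def test_surface_mismatch_rejected(self):
        a = _field([0.1])
        b = P.ProbabilityField(surface_id="other", values=np.array([0.1]), role="P_M")
        with pytest.raises(ValueError, match="mismatch"):
            P.merge_ligand([a, b])

    def test_empty_merge_rejected(self):
        with pytest.raises(ValueError):
            P.merge_moiety([])


class TestPredictLigand:
    def test_planted_sites_rank_above_decoys(self, corpus_split, toy_model,
                                             normalized_test_surfaces):
        """Confirmation suppresses a single-atom decoy signature."""
        from locsurf.descriptor import apply_normalization
        from locsurf.fixtures import DEFAULT_SIGNATURE_A
        _, test = corpus_split
        cx = test[0]
        raw = cx.surface
        # plant atom A's signature alone at a far-away decoy patch
        far = np.argsort(
            np.linalg.norm(raw.mesh.vertices - raw.mesh.vertices[cx.planted_vertices[0]],
                           axis=1))[-30:]
        decoy = np.asarray(far)
        feats = raw.features.copy()
        sd = feats.std(axis=0)
        feats[np.ix_(decoy, np.asarray(DEFAULT_SIGNATURE_A))] += 2.0 * sd[list(DEFAULT_SIGNATURE_A)]
        from locsurf.descriptor import DescriptorSurface
        doctored = DescriptorSurface(mesh=raw.mesh, features=feats,
                                     surface_id="decoy-case")
        surf = apply_normalization(doctored, toy_model.stats)
        res = P.predict_ligand(surf, toy_model)
        planted_mean = res.field.values[cx.planted_vertices].mean()
        decoy_mean = res.field.values[decoy].mean()
        assert planted_mean > decoy_mean

    def test_probabilities_in_range_and_determinism(self, toy_model,
                                                    normalized_test_surfaces):
        surf = normalized_test_surfaces[1]
        r1 = P.predict_ligand(surf, toy_model)
        r2 = P.predict_ligand(surf, toy_model)
        assert r1.field.values.min() >= 0 and r1.field.values.max() <= 1
        np.testing.assert_array_equal(r1.field.values, r2.field.values)

    def test_stats_provenance_enforced(self, toy_model, corpus_split):
        _, test = corpus_split
        raw = test[0].surface
        with pytest.raises(P.ProvenanceError):
            P.predict_ligand(raw, toy_model)

    def test_single_atom_moiety_degenerates_to_pa(self, normalized_test_surfaces,
                                                  toy_model):
        """With one atom and no partners, P = expanded P_A."""
        from locsurf.grouping import group_samples
        from locsurf.training import LigandModel, MoietyModel, MoietySpec
        mm = toy_model.moieties[0]
        solo = MoietyModel(
            spec=MoietySpec("solo", ["L1"], ["LIG"]),
            classifiers={"L1": mm.classifiers["L1"]},
            bounds=mm.bounds, stats_id=mm.stats_id,
        )
        model1 = LigandModel("LIG", [solo], stats=toy_model.stats)
        surf = normalized_test_surfaces[0]
        res = P.predict_ligand(surf, model1)
        clf = mm.classifiers["L1"]
        groups = group_samples(surf, clf.important_mask)
        pa = P.predict_atom_field(surf, groups, clf)
        expanded = P.expand_field(pa, groups)
        np.testing.assert_allclose(res.field.values, expanded.values)
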