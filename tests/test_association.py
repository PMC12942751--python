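"""Negative sampling, pair features, and the boosted classifier."""

import numpy as np
import pytest

import hypermet as hm
from hypermet.association import LabeledPairSet


def _catalog(n_dis, n_met):
    cat = hm.EntityCatalog()
    cat.add_all([f"m{i}" for i in range(1, n_met + 1)], "metabolite")
    cat.add_all([f"d{i}" for i in range(1, n_dis + 1)], "disease")
    return cat


class TestIndirectPairs:
    def test_single_two_hop_path(self):
        assert hm.indirect_pairs([("m2", "p")], [("p", "d1")]) == {("m2", "d1")}

    def test_no_protein_disease_links(self):
        assert hm.indirect_pairs([("m1", "p1")], []) == set()

    def test_no_shared_protein(self):
        assert hm.indirect_pairs([("m1", "p1")], [("p2", "d1")]) == set()

    def test_fixture_world(self):
        """The hand-built toy yields exactly {(m2, d1)}."""
        world = hm.toy_fixture("indirect_toy")
        h = hm.build_hypergraph(world.tables, world.catalog, protein_via_go=True)
        from hypermet.pipeline import derive_protein_disease

        pd = derive_protein_disease(h)
        assert hm.indirect_pairs(world.tables.metabolite_protein, pd) == {("m2", "d1")}


class TestSampleNegatives:
    def test_empty_pool_error(self):
        # 1 disease x 2 metabolites; one positive, the other indirect-excluded
        cat = _catalog(1, 2)
        with pytest.raises(ValueError, match="pool too small"):
            hm.sample_negatives([("d1", "m1")], cat, ratio=1,
                                indirect={("m2", "d1")})

    def test_exhaustive_two_candidate_pool(self):
        # pool is exactly {(d1,m3),(d1,m4)}; every draw must come from it
        cat = _catalog(1, 4)
        pool = {("d1", "m3"), ("d1", "m4")}
        for seed in range(10):
            out = hm.sample_negatives([("d1", "m1")], cat, ratio=1,
                                      indirect={("m2", "d1")}, seed=seed)
            assert out.negatives() <= pool
            assert len(out.negatives()) == 1

    def test_seed_reproducibility(self):
        cat = _catalog(5, 30)
        pos = [("d1", "m1"), ("d2", "m5"), ("d3", "m9")]
        a = hm.sample_negatives(pos, cat, ratio=3, seed=7)
        b = hm.sample_negatives(pos, cat, ratio=3, seed=7)
        assert a.pairs == b.pairs and np.array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("ratio", [1, 2, 5, 10])
    def test_ratio_bookkeeping_and_disjointness(self, ratio):
        cat = _catalog(8, 40)
        pos = [(f"d{i}", f"m{i}") for i in range(1, 9)]
        indirect = {(f"m{i + 10}", f"d{i}") for i in range(1, 9)}
        out = hm.sample_negatives(pos, cat, ratio=ratio, indirect=indirect, seed=1)
        assert len(out.negatives()) == ratio * len(pos)
        assert out.negatives() & set(pos) == set()
        assert out.negatives() & {(d, m) for m, d in indirect} == set()

    def test_duplicate_rows_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LabeledPairSet(["d1", "d1"], ["m1", "m1"], np.array([1, 0]))


class TestPairFeatures:
    def _embs(self, d=1):
        demb = hm.EmbeddingSet(["d1"], np.full((1, d), 0.2), role="hyperedge")
        memb = hm.EmbeddingSet(["m1"], np.full((1, d), 0.7), role="vertex")
        return demb, memb

    def test_concatenation_order_disease_first(self):
        demb, memb = self._embs()
        pairs = LabeledPairSet(["d1"], ["m1"], np.array([1]))
        feats = hm.build_pair_features(pairs, demb, memb)
        assert feats.values.tolist() == [[0.2, 0.7]]

    @pytest.mark.parametrize("d", [1, 4, 32])
    def test_width_contract(self, d):
        demb, memb = self._embs(d)
        pairs = LabeledPairSet(["d1"], ["m1"], np.array([0]))
        assert hm.build_pair_features(pairs, demb, memb).values.shape == (1, 2 * d)

    def test_unknown_metabolite_rejected(self):
        demb, memb = self._embs()
        pairs = LabeledPairSet(["d1"], ["mX"], np.array([0]))
        with pytest.raises(KeyError, match="mX"):
            hm.build_pair_features(pairs, demb, memb)

    def test_mismatched_dims_rejected(self):
        demb = hm.EmbeddingSet(["d1"], np.ones((1, 3)), role="hyperedge")
        memb = hm.EmbeddingSet(["m1"], np.ones((1, 4)), role="vertex")
        pairs = LabeledPairSet(["d1"], ["m1"], np.array([0]))
        with pytest.raises(ValueError, match="dims differ"):
            hm.build_pair_features(pairs, demb, memb)


def _separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = np.column_stack([rng.normal(y * 4.0, 0.3), rng.normal(size=n)])
    return x, y


class TestClassifier:
    def test_separable_toy_perfect_training_accuracy(self):
        x, y = _separable_toy()
        model = hm.train_classifier(x, y, params={"min_child_samples": 2})
        scores, labels = hm.predict_pairs(model, x)
        assert (labels == y).all()
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_single_class_rejected(self):
        x, _ = _separable_toy()
        with pytest.raises(ValueError, match="single class"):
            hm.train_classifier(x, np.ones(len(x), int))

    def test_seeded_determinism(self):
        x, y = _separable_toy()
        a = hm.train_classifier(x, y, seed=5).predict_proba(x)
        b = hm.train_classifier(x, y, seed=5).predict_proba(x)
        assert np.array_equal(a, b)

    def test_threshold_boundary_maps_to_positive(self):
        x, y = _separable_toy()
        model = hm.train_classifier(x, y, params={"min_child_samples": 2})
        scores = np.array([0.73, 0.5, 0.49])
        _, labels = hm.predict_pairs(model, x[:3])
        # direct rule check on the documented threshold semantics
        assert ((scores >= 0.5).astype(int) == [1, 1, 0]).all()
        assert set(labels.tolist()) <= {0, 1}

    def test_width_mismatch_rejected(self):
        x, y = _separable_toy()
        model = hm.train_classifier(x, y)
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(x[:, :1])

    def test_empty_features_empty_outputs(self):
        x, y = _separable_toy()
        model = hm.train_classifier(x, y)
        scores, labels = hm.predict_pairs(model, np.empty((0, 2)))
        assert scores.size == 0 and labels.size == 0

    def test_feature_importances_exposed(self):
        x, y = _separable_toy()
        model = hm.train_classifier(x, y, params={"min_child_samples": 2})
        imp = model.feature_importances
        assert imp.shape == (2,)
        assert imp[0] > imp[1]  # the informative feature dominates

    def test_save_load_round_trip(self, tmp_path):
        from hypermet.association import load_model, save_model

        x, y = _separable_toy()
        model = hm.train_classifier(x, y, params={"min_child_samples": 2})
        save_model(model, tmp_path / "model.txt")
        loaded = load_model(tmp_path / "model.txt")
        assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))


class TestRankMetabolites:
    def _setup(self):
        rng = np.random.default_rng(2)
        mets = [f"m{i}" for i in range(6)]
        demb = hm.EmbeddingSet(["d1"], rng.normal(size=(1, 4)), role="hyperedge")
        memb = hm.EmbeddingSet(mets, rng.normal(size=(6, 4)), role="vertex")
        pairs = LabeledPairSet(["d1"] * 6, mets, np.array([1, 1, 1, 0, 0, 0]))
        feats = hm.build_pair_features(pairs, demb, memb)
        model = hm.train_classifier(feats.values, pairs.labels,
                                    params={"min_child_samples": 2})
        return model, demb, memb, mets

    def test_descending_order_and_length(self):
        model, demb, memb, mets = self._setup()
        ranked = hm.rank_metabolites(model, "d1", mets, demb, memb)
        assert len(ranked) == len(mets)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        assert ranked[0][1] == max(scores)

    def test_tied_scores_id_ordered(self):
        model, demb, memb, _ = self._setup()
        # duplicate embedding rows => identical features => identical scores
        memb2 = hm.EmbeddingSet(["mz", "ma"],
                                np.vstack([memb.vectors[0], memb.vectors[0]]),
                                role="vertex")
        ranked = hm.rank_metabolites(model, "d1", ["mz", "ma"], demb, memb2)
        assert ranked[0][1] == ranked[1][1]
        assert [m for m, _ in ranked] == ["ma", "mz"]

    def test_unknown_disease_rejected(self):
        model, demb, memb, mets = self._setup()
        with pytest.raises(KeyError, match="dX"):
            hm.rank_metabolites(model, "dX", mets, demb, memb)
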