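"""Fold-change and VIP filtering, and biomarker-library assembly."""

import numpy as np
import pytest

from foodreadout import (
    BiomarkerLibrary,
    FeatureTable,
    FoodOntology,
    LibraryConfig,
    Spectrum,
    SynthConfig,
    fold_change,
    learn_library,
    select_biomarkers,
    simulate_reference,
)


def uniform_table(rng, n_features=30, cats=("A", "B", "C"), per_cat=4):
    sample_ids = [f"{c}_{i}" for c in cats for i in range(per_cat)]
    intensities = rng.uniform(50, 100, size=(n_features, len(sample_ids)))
    return (
        FeatureTable(
            feature_ids=[f"F{i}" for i in range(n_features)],
            mz=rng.uniform(100, 900, n_features),
            rt=rng.uniform(10, 600, n_features),
            sample_ids=sample_ids,
            intensities=intensities,
        ),
        FoodOntology.from_edges(
            [("root", None, "root")] + [(c, "root", c) for c in cats],
            {s: s.split("_")[0] for s in sample_ids},
        ),
    )


class TestFoldChange:
    def build(self, pos_vals, neg_vals):
        pos_vals, neg_vals = np.atleast_2d(pos_vals), np.atleast_2d(neg_vals)
        n_pos, n_neg = pos_vals.shape[1], neg_vals.shape[1]
        return FeatureTable(
            feature_ids=[f"F{i}" for i in range(pos_vals.shape[0])],
            mz=np.arange(pos_vals.shape[0]) + 100.0,
            rt=np.arange(pos_vals.shape[0]) + 1.0,
            sample_ids=[f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)],
            intensities=np.hstack([pos_vals, neg_vals]),
        )

    def test_six_fold_arithmetic(self):
        table = self.build([[12.0, 12.0]], [[2.0, 2.0]])
        fc = fold_change(table, ["p0", "p1"], ["n0", "n1"], epsilon=1e-9, tic_normalize=False)
        assert fc[0] == pytest.approx(6.0, rel=1e-6)

    def test_equal_means_give_unity(self):
        table = self.build([[5.0, 5.0]], [[5.0, 5.0]])
        fc = fold_change(table, ["p0", "p1"], ["n0", "n1"], tic_normalize=False)
        assert fc[0] == pytest.approx(1.0)

    def test_absent_in_rest_is_finite(self):
        eps = 0.01
        table = self.build([[8.0, 8.0]], [[0.0, 0.0]])
        fc = fold_change(table, ["p0", "p1"], ["n0", "n1"], epsilon=eps, tic_normalize=False)
        assert np.isfinite(fc[0])
        assert fc[0] == pytest.approx((8.0 + eps) / eps)

    def test_overlapping_sets_rejected(self):
        table = self.build([[1.0, 2.0]], [[3.0, 4.0]])
        with pytest.raises(ValueError, match="overlap"):
            fold_change(table, ["p0"], ["p0", "n0"])

    def test_unknown_sample_rejected(self):
        table = self.build([[1.0, 2.0]], [[3.0, 4.0]])
        with pytest.raises(KeyError):
            fold_change(table, ["p0", "zzz"], ["n0"])


class TestSelect:
    def test_threshold_logic(self):
        vip = np.array([5.0, 5.0, 3.9, 4.5, 5.0])
        fc = np.array([10.0, 2.0, 10.0, 6.0, 0.1])
        mask = select_biomarkers(vip, fc, vip_threshold=4.0, fold_threshold=6.0)
        # pass; FC too low; VIP too low; boundary FC=6 inclusive; depleted not enriched
        assert mask.tolist() == [True, False, False, True, False]

    def test_vip_threshold_is_strict(self):
        assert not select_biomarkers(np.array([4.0]), np.array([10.0]))[0]

    def test_matches_brute_force_on_planted_data(self):
        table, ontology, _, truth = simulate_reference(
            SynthConfig(n_categories=3, samples_per_category=6,
                        planted_biomarkers_per_category=10, background_features=50, seed=2)
        )
        from foodreadout.discriminant import PreprocessSpec, fit_opls, preprocess, vip_scores

        cat = "food01"
        pos = sorted(ontology.subtree_samples(cat))
        neg = sorted(set(table.sample_ids) - set(pos))
        prep = preprocess(table, PreprocessSpec())
        y = np.array([1.0 if s in set(pos) else -1.0 for s in prep.sample_ids])
        model = fit_opls(prep.matrix, y, n_ortho=1)
        vip = vip_scores(model)
        fc = fold_change(table, pos, neg)
        mask = select_biomarkers(vip, fc, vip_threshold=1.5, fold_threshold=6.0)
        brute = [(v > 1.5) and (f >= 6.0) and (f > 1.0) for v, f in zip(vip, fc)]
        assert mask.tolist() == brute

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            select_biomarkers(np.ones(3), np.ones(4))

    def test_selection_monotone_in_thresholds(self, rng):
        vip = rng.uniform(0, 8, 200)
        fc = rng.uniform(0, 20, 200)
        base = select_biomarkers(vip, fc, 2.0, 4.0).sum()
        assert select_biomarkers(vip, fc, 3.0, 4.0).sum() <= base
        assert select_biomarkers(vip, fc, 2.0, 8.0).sum() <= base


class TestLearnLibrary:
    def test_planted_markers_recovered(self, reference_dataset, learned_library):
        _, _, _, truth = reference_dataset
        selected = {(e.category_id, e.feature_id) for e in learned_library.entries}
        planted = {(c, f) for c, fs in truth.planted.items() for f in fs}
        tp = len(selected & planted)
        assert tp / len(planted) >= 0.9  # recall
        assert tp / len(selected) >= 0.9  # precision

    def test_no_enrichment_gives_empty_library(self, rng):
        table, ontology = uniform_table(rng)
        library = learn_library(table, ontology, [], LibraryConfig())
        assert len(library) == 0
        assert library.run_log["n_contrasts"] == 3

    def test_branch_and_leaf_levels_both_carry_markers(self, rng):
        # two branches of two leaves; one marker family per leaf and one per branch
        edges = [
            ("root", None, "r"),
            ("b1", "root", "b1"), ("b2", "root", "b2"),
            ("l1", "b1", "l1"), ("l2", "b1", "l2"),
            ("l3", "b2", "l3"), ("l4", "b2", "l4"),
        ]
        leaves = ["l1", "l2", "l3", "l4"]
        per = 4
        samples = {f"{l}_{i}": l for l in leaves for i in range(per)}
        ontology = FoodOntology.from_edges(edges, samples)
        sample_ids = sorted(samples)
        n_features = 6 + 40
        intens = rng.uniform(90, 110, size=(n_features, len(sample_ids)))
        leaf_of = {s: samples[s] for s in sample_ids}
        for j, s in enumerate(sample_ids):
            leaf = leaf_of[s]
            branch = "b1" if leaf in ("l1", "l2") else "b2"
            intens[leaves.index(leaf), j] *= 20.0  # features 0-3: leaf markers
            intens[4 + (branch == "b2"), j] *= 20.0  # features 4-5: branch markers
        table = FeatureTable(
            feature_ids=[f"F{i}" for i in range(n_features)],
            mz=rng.uniform(100, 900, n_features),
            rt=rng.uniform(10, 600, n_features),
            sample_ids=sample_ids,
            intensities=intens,
        )
        library = learn_library(table, ontology, [], LibraryConfig(vip_threshold=1.5))
        levels = {e.level for e in library.entries}
        assert {1, 2} <= levels
        b1_features = {e.feature_id for e in library.by_category("b1")}
        assert "F4" in b1_features and "F5" not in b1_features
        assert {e.feature_id for e in library.by_category("l1")} >= {"F0"}

    def test_sample_column_permutation_invariance(self, rng):
        table, ontology, spectra, _ = simulate_reference(
            SynthConfig(n_categories=3, samples_per_category=6,
                        planted_biomarkers_per_category=10, background_features=40, seed=5)
        )
        lib1 = learn_library(table, ontology, spectra, LibraryConfig(vip_threshold=1.5))
        perm = rng.permutation(table.n_samples)
        shuffled = FeatureTable(
            feature_ids=list(table.feature_ids),
            mz=table.mz, rt=table.rt,
            sample_ids=[table.sample_ids[i] for i in perm],
            intensities=table.intensities[:, perm],
        )
        lib2 = learn_library(shuffled, ontology, spectra, LibraryConfig(vip_threshold=1.5))
        key = lambda lib: sorted((e.category_id, e.feature_id) for e in lib.entries)
        assert key(lib1) == key(lib2)

    def test_entries_record_spectrum_links(self, reference_dataset, learned_library):
        table, _, spectra, _ = reference_dataset
        by_feature = {s.feature_id: s.spectrum_id for s in spectra}
        for entry in learned_library.entries:
            assert entry.reference_spectrum_id == by_feature[entry.feature_id]

    def test_save_load_round_trip_and_audit(self, tmp_path, learned_library):
        json_path = tmp_path / "library.json"
        learned_library.save(json_path)
        back = BiomarkerLibrary.load(json_path)
        assert len(back) == len(learned_library)
        assert back.parameters.vip_threshold == learned_library.parameters.vip_threshold
        assert set(back.spectra) == set(learned_library.spectra)
        back.audit()  # self-consistency on load

    def test_audit_catches_threshold_violation(self, learned_library):
        import dataclasses

        bad = dataclasses.replace(learned_library.entries[0], vip=0.1)
        broken = BiomarkerLibrary(
            entries=[bad],
            spectra=dict(learned_library.spectra),
            parameters=learned_library.parameters,
        )
        with pytest.raises(ValueError, match="VIP"):
            broken.audit()
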