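"""Match→feature linking, dietary scoring and proportion normalization."""

import numpy as np
import pandas as pd
import pytest

from foodreadout import (
    BiomarkerEntry,
    BiomarkerLibrary,
    FeatureTable,
    LibraryConfig,
    Spectrum,
    SpectralMatch,
    dietary_scores,
    link_matches_to_features,
    normalize_scores,
)
from foodreadout.readout import DietaryScoreMatrix


def query_table(n_features=4, n_samples=2, rng=None):
    if rng is None:
        intens = np.arange(n_features * n_samples, dtype=float).reshape(n_features, n_samples) + 1
        mz = 100.0 + 50.0 * np.arange(n_features)
        rt = 60.0 * (np.arange(n_features) + 1)
    else:
        intens = rng.uniform(1, 100, size=(n_features, n_samples))
        mz = np.sort(rng.uniform(100, 900, n_features))
        rt = rng.uniform(30, 600, n_features)
    return FeatureTable(
        feature_ids=[f"F{i + 1}" for i in range(n_features)],
        mz=mz,
        rt=rt,
        sample_ids=[f"s{j + 1}" for j in range(n_samples)],
        intensities=intens,
    )


def match(qid, lid, score=0.9):
    return SpectralMatch(qid, lid, score, 4, 0.0, "cosine")


def library_with(entries, spectra):
    return BiomarkerLibrary(
        entries=entries,
        spectra={s.spectrum_id: s for s in spectra},
        parameters=LibraryConfig(vip_threshold=0.0, fold_threshold=0.0),
    )


def entry(fid, cat, level=1, sid=None):
    return BiomarkerEntry(
        feature_id=fid, category_id=cat, level=level, vip=5.0, fold_change=10.0,
        mean_intensity_target=1.0, mean_intensity_rest=0.1,
        reference_spectrum_id=sid,
    )


class TestLinking:
    def test_explicit_feature_id_wins_over_mz(self):
        table = query_table()
        spectrum = Spectrum("q1", 999.0, [[100.0, 1.0]], feature_id="F3")
        links, dropped = link_matches_to_features([match("q1", "lib1")], table, [spectrum])
        assert links == {"q1": "F3"}
        assert dropped == 0

    def test_tolerance_linking_prefers_rt_consistent_feature(self):
        table = FeatureTable(
            feature_ids=["Fa", "Fb"],
            mz=[250.101, 250.100],
            rt=[118.0, 400.0],
            sample_ids=["s1"],
            intensities=[[1.0], [1.0]],
        )
        spectrum = Spectrum("q1", 250.100, [[100.0, 1.0]], retention_time=120.0)
        links, _ = link_matches_to_features(
            [match("q1", "lib1")], table, [spectrum], mz_tol=0.01, rt_tol=30.0
        )
        assert links == {"q1": "Fa"}

    def test_unlinkable_matches_dropped_and_counted(self):
        table = query_table()
        spectrum = Spectrum("q1", 5000.0, [[100.0, 1.0]])  # nothing near in m/z
        links, dropped = link_matches_to_features([match("q1", "lib1")], table, [spectrum])
        assert links == {}
        assert dropped == 1

    def test_matches_brute_force_nearest_within_tolerance(self, rng):
        table = query_table(n_features=30, n_samples=3, rng=rng)
        spectra, matches = [], []
        for i in range(40):
            spectra.append(
                Spectrum(
                    f"q{i}", float(rng.uniform(100, 900)), [[100.0, 1.0]],
                    retention_time=float(rng.uniform(30, 600)),
                )
            )
            matches.append(match(f"q{i}", "lib1"))
        mz_tol, rt_tol = 5.0, 100.0
        links, _ = link_matches_to_features(matches, table, spectra, mz_tol, rt_tol)
        for s in spectra:
            candidates = [
                (abs(table.mz[j] - s.precursor_mz), table.feature_ids[j])
                for j in range(table.n_features)
                if abs(table.mz[j] - s.precursor_mz) <= mz_tol
                and abs(table.rt[j] - s.retention_time) <= rt_tol
            ]
            if candidates:
                assert links[s.spectrum_id] == min(candidates)[1]
            else:
                assert s.spectrum_id not in links


class TestDietaryScores:
    def build_case(self):
        """Category with 3 biomarkers; intensities 2, 4 detected, third absent."""
        table = FeatureTable(
            feature_ids=["F1", "F2", "F3"],
            mz=[100.0, 200.0, 300.0],
            rt=[10.0, 20.0, 30.0],
            sample_ids=["s1"],
            intensities=[[2.0], [4.0], [7.0]],
        )
        spectra = [
            Spectrum(f"ref{i}", 100.0 * (i + 1), [[50.0, 1.0], [60.0, 1.0]], feature_id=f"F{i + 1}")
            for i in range(3)
        ]
        entries = [entry(f"F{i + 1}", "fruit", sid=f"ref{i}") for i in range(3)]
        library = library_with(entries, spectra)
        matches = [match("q1", "ref0"), match("q2", "ref1")]  # third biomarker undetected
        links = {"q1": "F1", "q2": "F2"}
        return table, library, matches, links

    def test_fill_modes_arithmetic(self):
        table, library, matches, links = self.build_case()
        zeros = dietary_scores(table, library, matches, links, fill="zeros", tic_normalize=False)
        detected = dietary_scores(
            table, library, matches, links, fill="detected_only", tic_normalize=False
        )
        assert zeros.values[0, 0] == pytest.approx(2.0)  # (2+4+0)/3
        assert detected.values[0, 0] == pytest.approx(3.0)  # (2+4)/2

    def test_no_matches_gives_zero_row(self):
        table, library, _, _ = self.build_case()
        scores = dietary_scores(table, library, [], {}, tic_normalize=False)
        assert np.all(scores.values == 0)

    def test_matrix_covers_all_library_categories(self):
        table, library, matches, links = self.build_case()
        library.category_levels["veg"] = 1  # category with no entries
        scores = dietary_scores(table, library, matches, links, tic_normalize=False)
        assert set(scores.category_ids) == {"fruit", "veg"}
        assert np.all(scores.values[:, scores.category_ids.index("veg")] == 0)

    def test_linearity_in_sample_intensities(self):
        table, library, matches, links = self.build_case()
        doubled = FeatureTable(
            feature_ids=list(table.feature_ids), mz=table.mz, rt=table.rt,
            sample_ids=list(table.sample_ids), intensities=table.intensities * 2,
        )
        s1 = dietary_scores(table, library, matches, links, tic_normalize=False)
        s2 = dietary_scores(doubled, library, matches, links, tic_normalize=False)
        assert np.allclose(s2.values, 2 * s1.values)
        # proportion-mode readout is unchanged by the doubling
        assert np.allclose(
            normalize_scores(s1, 1).values, normalize_scores(s2, 1).values
        )

    def test_zeros_fill_never_exceeds_detected_only(self, rng):
        table, library, matches, links = self.build_case()
        zeros = dietary_scores(table, library, matches, links, fill="zeros", tic_normalize=False)
        detected = dietary_scores(
            table, library, matches, links, fill="detected_only", tic_normalize=False
        )
        assert np.all(zeros.values <= detected.values + 1e-12)

    def test_adding_unmatched_biomarker_dilutes_zeros_score(self):
        table, library, matches, links = self.build_case()
        before = dietary_scores(table, library, matches, links, tic_normalize=False)
        extra = entry("F9", "fruit", sid=None)
        bigger = BiomarkerLibrary(
            entries=library.entries + [extra],
            spectra=dict(library.spectra),
            parameters=library.parameters,
        )
        after = dietary_scores(table, bigger, matches, links, tic_normalize=False)
        assert np.all(after.values <= before.values + 1e-12)

    def test_score_export_round_trip(self, tmp_path):
        table, library, matches, links = self.build_case()
        scores = dietary_scores(table, library, matches, links, tic_normalize=False)
        path = tmp_path / "scores.tsv"
        scores.save(path, sidecar={"library_hash": "abc"})
        back = DietaryScoreMatrix.load(path)
        assert np.allclose(back.values, scores.values)
        assert back.category_ids == scores.category_ids
        assert back.fill == scores.fill


class TestNormalize:
    def make(self, values, levels=None):
        cats = [f"c{i}" for i in range(np.shape(values)[1])]
        return DietaryScoreMatrix(
            values=np.asarray(values, float),
            sample_ids=[f"s{i}" for i in range(np.shape(values)[0])],
            category_ids=cats,
            category_levels={c: (levels or {}).get(c, 1) for c in cats},
        )

    def test_row_proportion_arithmetic(self):
        scores = self.make([[2.0, 6.0]])
        out = normalize_scores(scores, 1)
        assert np.allclose(out.values, [[0.25, 0.75]])
        assert out.proportion == 1

    def test_all_zero_row_unchanged(self):
        out = normalize_scores(self.make([[0.0, 0.0], [1.0, 3.0]]), 1)
        assert np.allclose(out.values[0], 0.0)
        assert np.allclose(out.values[1], [0.25, 0.75])

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            normalize_scores(self.make([[1.0, 2.0]]), 7)

    def test_rows_sum_to_one_or_zero_randomized(self, rng):
        for _ in range(100):
            values = rng.uniform(0, 10, size=(5, 4))
            values[rng.random(5) < 0.3] = 0.0
            out = normalize_scores(self.make(values), 1)
            sums = out.values.sum(axis=1)
            assert np.all(np.isclose(sums, 1.0) | np.isclose(sums, 0.0))

    def test_only_requested_level_retained(self):
        scores = self.make([[1.0, 2.0, 3.0]], levels={"c0": 1, "c1": 1, "c2": 2})
        out = normalize_scores(scores, 1)
        assert out.category_ids == ["c0", "c1"]
        assert np.allclose(out.values, [[1 / 3, 2 / 3]])
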