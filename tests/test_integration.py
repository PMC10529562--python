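import numpy as np
import pytest

import ecgfuse as ef
from ecgfuse.errors import ConfigurationError, IntegrationError
from ecgfuse.integration import ClassMap, load_dataset, per_class_counts, save_dataset


class TestClassMap:
    def test_default_scheme_has_16_classes(self, class_map):
        assert class_map.n_classes == 16
        assert sorted(class_map.code_to_id.values()) == list(range(16))

    def test_known_code_assignments(self, class_map):
        assert class_map.label_for("N") == 0
        assert class_map.label_for("V") == 12
        assert class_map.label_for("L") == 6
        assert class_map.label_for("/") == 3
        assert class_map.abbr(12) == "PVC"

    def test_superclass_and_nonbeat_codes_excluded(self, class_map):
        for code in ("B", "+", "~", "|"):
            assert class_map.label_for(code) is None
            assert code in class_map.excluded_codes

    def test_duplicate_class_id_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassMap(code_to_id={"N": 0, "V": 0}, id_to_abbr={}, id_to_name={})

    def test_overlapping_excluded_codes_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassMap(code_to_id={"N": 0}, id_to_abbr={}, id_to_name={},
                     excluded_codes=frozenset("N"))

    def test_toy_map_labels_symbols(self):
        toy = ClassMap(code_to_id={"N": 0, "V": 12}, id_to_abbr={}, id_to_name={})
        assert [toy.label_for(s) for s in ("N", "V", "N")] == [0, 12, 0]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigurationError):
            ef.build_class_map("no-such-scheme")


class TestIntegrate:
    def test_single_database_no_boundary_beats(self, class_map):
        from ecgfuse.synthetic_data import zero_noise
        p = zero_noise(ef.default_profiles()[0])
        rec, ann, _ = ef.generate_record(p, 10, seed=1)
        src = ef.DatabaseSource(name="one", records=[(rec, ann)],
                                lead_priority=["MLII"])
        res = ef.integrate([src], preprocessor="none")
        assert len(res.dataset) == 10
        assert not res.drop_log

    def test_three_rates_unify_to_fixed_length(self, noisy_sources):
        res = ef.integrate(noisy_sources, preprocessor="self")
        assert res.dataset.A.shape[1] == 260
        dbs = set(res.dataset.provenance["source_db"])
        assert dbs == {"db360", "db128", "db257"}

    def test_counts_table_sums_match(self, noisy_sources, class_map):
        res = ef.integrate(noisy_sources, preprocessor="none")
        counts = res.counts
        assert (counts[["db360", "db128", "db257"]].sum(axis=1)
                == counts["merged"]).all()
        assert counts["merged"].sum() == len(res.dataset)

    def test_class_only_in_one_database_survives_merge(self, class_map):
        from ecgfuse.synthetic_data import zero_noise
        profs = [zero_noise(p) for p in ef.default_profiles()[:2]]
        profs[0].mixture = {0: 1.0}
        profs[1].mixture = {0: 0.5, 8: 0.5}  # SP only in database 2
        sources = []
        for i, p in enumerate(profs):
            rec, ann, _ = ef.generate_record(p, 40, seed=10 + i)
            sources.append(ef.DatabaseSource(name=p.name, records=[(rec, ann)],
                                             lead_priority=[p.lead]))
        res = ef.integrate(sources, preprocessor="none")
        row = res.counts.set_index("class_id").loc[8]
        assert row["merged"] > 0 and row["db360"] == 0 and row["db128"] > 0

    def test_merge_order_insensitive_up_to_permutation(self, clean_sources):
        a = ef.integrate(clean_sources, preprocessor="none").dataset
        b = ef.integrate(clean_sources[::-1], preprocessor="none").dataset
        assert sorted(map(tuple, a.A.round(9))) == sorted(map(tuple, b.A.round(9)))

    def test_empty_result_raises(self, class_map):
        rec = ef.EcgRecord("x", np.random.default_rng(0).normal(size=(2000, 1)),
                           360.0, ["MLII"])
        ann = ef.BeatAnnotationSet(np.array([900]), ["+"])  # non-beat only
        src = ef.DatabaseSource(name="d", records=[(rec, ann)],
                                lead_priority=["MLII"])
        with pytest.raises(IntegrationError):
            ef.integrate([src])

    def test_paths_based_source(self, tmp_path, class_map):
        from ecgfuse.synthetic_data import zero_noise
        profs = [zero_noise(ef.default_profiles()[0])]
        ef.generate_corpus(profs, n_records=2, seed=0, out_dir=tmp_path,
                           n_beats_per_record=12, dialect="wfdb")
        src = ef.DatabaseSource(
            name="db360",
            record_paths=[tmp_path / "db360" / f"rec{i:03d}" for i in range(2)],
            lead_priority=["MLII"],
        )
        res = ef.integrate([src], preprocessor="self")
        assert len(res.dataset) == 24


class TestStratifiedSplit:
    @pytest.mark.parametrize("m_c,frac,expected_test",
                             [(16, 0.2, 3), (10, 0.2, 2), (982, 0.2, 196),
                              (7028, 0.2, 1405), (2, 0.2, 1), (1, 0.2, 0),
                              (3, 0.5, 1)])
    def test_per_class_test_counts(self, m_c, frac, expected_test):
        ds = ef.BeatDataset(
            np.random.default_rng(0).normal(size=(m_c, 4)), np.zeros(m_c, int)
        )
        res = ef.stratified_split(ds, frac, seed=1)
        assert len(res.test) == expected_test
        assert len(res.train) + len(res.test) == m_c

    def test_counts_conserved_and_disjoint(self, clean_dataset):
        res = ef.stratified_split(clean_dataset, 0.2, seed=3)
        t = res.per_class_counts
        assert (t["train"] + t["test"] == t["total"]).all()
        assert len(res.train) + len(res.test) == len(clean_dataset)
        # disjointness: every original row lands in exactly one side
        merged = np.vstack([res.train.A, res.test.A])
        assert sorted(map(tuple, merged.round(9))) == sorted(
            map(tuple, clean_dataset.A.round(9))
        )

    def test_seed_reproducible(self, clean_dataset):
        a = ef.stratified_split(clean_dataset, 0.2, seed=7)
        b = ef.stratified_split(clean_dataset, 0.2, seed=7)
        np.testing.assert_array_equal(a.test.A, b.test.A)
        c = ef.stratified_split(clean_dataset, 0.2, seed=8)
        assert not np.array_equal(a.test.A, c.test.A)

    def test_exhaustive_small_classes(self):
        # every class size 2..12 at fraction 0.2: conservation + floor rule
        sizes = list(range(2, 13))
        labels = np.concatenate([[i] * s for i, s in enumerate(sizes)])
        ds = ef.BeatDataset(
            np.random.default_rng(1).normal(size=(len(labels), 3)), labels
        )
        res = ef.stratified_split(ds, 0.2, seed=0)
        for i, s in enumerate(sizes):
            row = res.per_class_counts.set_index("class_id").loc[i]
            assert row["test"] == max(1, int(np.floor(0.2 * s)))

    def test_bad_fraction_rejected(self, clean_dataset):
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                ef.stratified_split(clean_dataset, frac, seed=0)


def test_dataset_csv_round_trip(tmp_path, clean_dataset):
    path = tmp_path / "beats.csv"
    save_dataset(clean_dataset, path, meta={"L": 260})
    back = load_dataset(path)
    np.testing.assert_allclose(back.A, clean_dataset.A, atol=1e-9)
    np.testing.assert_array_equal(back.labels, clean_dataset.labels)
    assert (path.with_suffix(".meta.json")).exists()


def test_count_annotations_tallies_planted_beats(tmp_path):
    from ecgfuse.synthetic_data import zero_noise
    profs = [zero_noise(ef.default_profiles()[0])]
    profs[0].mixture = {0: 0.7, 12: 0.3}
    ef.generate_corpus(profs, n_records=3, seed=5, out_dir=tmp_path,
                       n_beats_per_record=50, dialect="wfdb")
    paths = [tmp_path / "db360" / f"rec{i:03d}" for i in range(3)]
    tally = ef.count_annotations(paths)
    assert tally["total_beats"] == 150
    assert tally["per_class"][0] + tally["per_class"][12] == 150
    assert tally["per_class"][0] > tally["per_class"][12]
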