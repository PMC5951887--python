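"""Data model, reverse coding, listwise deletion and category collapsing."""

import numpy as np
import pytest

from likertdif import (
    DataError,
    GroupAssignment,
    GroupSpec,
    ScaleDefinition,
    StudySpec,
    apply_reverse_coding,
    bundled_scale,
    collapse_sparse_categories,
    generate_study,
    listwise_subset,
    load_responses,
    write_study,
)

from conftest import make_matrix


class TestScaleDefinition:
    def test_bundled_hiv_stigma_scale(self):
        scale = bundled_scale()
        sizes = [len(v) for v in scale.subscales.values()]
        assert sizes == [11, 8, 6, 7]
        assert len(scale.all_items) == 32
        assert scale.reverse_items == {"item08", "item21"}

    def test_overlapping_subscales_rejected(self):
        with pytest.raises(DataError, match="more than one subscale"):
            ScaleDefinition({"a": ["i1", "i2"], "b": ["i2", "i3"]})

    def test_yaml_round_trip(self, tmp_path):
        scale = bundled_scale()
        scale.to_yaml(tmp_path / "s.yaml")
        back = ScaleDefinition.from_yaml(tmp_path / "s.yaml")
        assert back.subscales == scale.subscales
        assert back.reverse_items == scale.reverse_items


class TestLoadResponses:
    def _write(self, tmp_path, rows, header="a,b,grp"):
        path = tmp_path / "r.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_identity_read_back(self, tmp_path):
        scale = ScaleDefinition({"s": ["a", "b"]})
        path = self._write(tmp_path, ["1,4,G1", "2,3,G1", "3,2,G2"])
        m, g = load_responses(path, scale, "grp")
        assert m.n_persons == 3
        assert not np.isnan(m.responses).any()
        np.testing.assert_array_equal(m.responses, [[1, 4], [2, 3], [3, 2]])
        assert g.levels == ["G1", "G2"]

    def test_out_of_range_code_names_cell(self, tmp_path):
        scale = ScaleDefinition({"s": ["a", "b"]})
        path = self._write(tmp_path, ["1,5,G1"])
        with pytest.raises(DataError, match=r"code 5.*row 0.*'b'"):
            load_responses(path, scale, "grp")

    def test_non_integer_cell_named(self, tmp_path):
        scale = ScaleDefinition({"s": ["a", "b"]})
        path = self._write(tmp_path, ["1,x,G1"])
        with pytest.raises(DataError, match=r"non-integer.*'x'.*row 0"):
            load_responses(path, scale, "grp")

    def test_missing_item_column(self, tmp_path):
        scale = ScaleDefinition({"s": ["a", "zz"]})
        path = self._write(tmp_path, ["1,2,G1"])
        with pytest.raises(DataError, match="zz"):
            load_responses(path, scale, "grp")

    def test_blank_cells_become_missing(self, tmp_path):
        scale = ScaleDefinition({"s": ["a", "b"]})
        path = self._write(tmp_path, ["1,,G1", "2,3,"])
        m, g = load_responses(path, scale, "grp")
        assert np.isnan(m.responses[0, 1])
        assert g.labels[1] is None

    def test_generator_round_trip(self, tmp_path):
        spec = StudySpec(
            groups=[GroupSpec("A", 25), GroupSpec("B", 25)],
            scale=ScaleDefinition({"s": [f"i{j}" for j in range(5)]}),
            missing_rate=0.05,
            seed=1,
        )
        study = generate_study(spec)
        paths = write_study(study, tmp_path)
        m, g = load_responses(paths["responses"], study.scale, "group")
        np.testing.assert_array_equal(
            np.isnan(m.responses), np.isnan(study.responses.responses)
        )
        obs = ~np.isnan(m.responses)
        np.testing.assert_array_equal(m.responses[obs], study.responses.responses[obs])
        np.testing.assert_array_equal(g.labels, study.groups.labels)


class TestReverseCoding:
    def test_formula(self):
        scale = ScaleDefinition({"s": ["i0", "i1"]}, reverse_items={"i1"})
        m = make_matrix([[2, 1], [3, 4]])
        out = apply_reverse_coding(m, scale)
        np.testing.assert_array_equal(out.responses, [[2, 4], [3, 1]])

    def test_involution_preserves_missingness(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(1, 5, size=(40, 6)).astype(float)
        codes[rng.random(codes.shape) < 0.2] = np.nan
        scale = ScaleDefinition({"s": [f"i{k}" for k in range(6)]}, reverse_items={"i1", "i4"})
        m = make_matrix(codes)
        twice = apply_reverse_coding(apply_reverse_coding(m, scale), scale)
        np.testing.assert_array_equal(np.isnan(twice.responses), np.isnan(codes))
        obs = ~np.isnan(codes)
        np.testing.assert_array_equal(twice.responses[obs], codes[obs])

    def test_empty_reverse_set_is_identity(self):
        scale = ScaleDefinition({"s": ["i0", "i1"]})
        m = make_matrix([[2, 1], [3, 4]])
        out = apply_reverse_coding(m, scale)
        np.testing.assert_array_equal(out.responses, m.responses)


class TestListwiseSubset:
    def test_missing_item_drops_person(self):
        m = make_matrix([[1, 2], [3, np.nan], [2, 2], [4, 4]])
        g = GroupAssignment(np.array(["A", "A", "B", "B"], dtype=object))
        sub, gsub = listwise_subset(m, g, ["i0", "i1"])
        assert sub.n_persons == 3
        assert sub.person_ids == ["p0", "p2", "p3"]

    def test_missing_group_drops_person(self):
        m = make_matrix([[1, 2], [3, 2], [2, 2]])
        g = GroupAssignment(np.array(["A", None, "B"], dtype=object))
        sub, gsub = listwise_subset(m, g, ["i0", "i1"])
        assert sub.n_persons == 2
        assert list(gsub.labels) == ["A", "B"]

    def test_no_missing_is_identity(self):
        m = make_matrix([[1, 2], [3, 2]])
        g = GroupAssignment(np.array(["A", "B"], dtype=object))
        sub, _ = listwise_subset(m, g, ["i0", "i1"])
        np.testing.assert_array_equal(sub.responses, m.responses)
        assert not np.isnan(sub.responses).any()

    def test_all_dropped_fails(self):
        m = make_matrix([[np.nan, 2]])
        g = GroupAssignment(np.array(["A"], dtype=object))
        with pytest.raises(DataError, match="no persons remain"):
            listwise_subset(m, g, ["i0", "i1"])

    def test_items_subset_only_considered(self):
        m = make_matrix([[1, np.nan], [3, 2]])
        g = GroupAssignment(np.array(["A", "B"], dtype=object))
        sub, _ = listwise_subset(m, g, ["i0"])
        assert sub.n_persons == 2
        assert sub.item_ids == ["i0"]


def _matrix_with_counts(counts_by_group):
    """Build a 1-item matrix realizing exact per-group category counts."""
    codes, labels = [], []
    for grp, counts in counts_by_group.items():
        for cat, c in enumerate(counts, start=1):
            codes.extend([cat] * c)
            labels.extend([grp] * c)
    m = make_matrix(np.array(codes, dtype=float)[:, None], item_ids=["i0"])
    return m, GroupAssignment(np.array(labels, dtype=object))


class TestCollapseSparseCategories:
    def test_minimum_count_above_threshold_unchanged(self):
        m, g = _matrix_with_counts({"A": [6, 10, 9, 7], "B": [8, 6, 11, 6]})
        out, report = collapse_sparse_categories(m, g, min_cell=5)
        assert not report.any_collapsed
        np.testing.assert_array_equal(out.responses, m.responses)
        assert out.item_categories[0] == 4

    def test_sparse_bottom_category_merges_up(self):
        m, g = _matrix_with_counts({"A": [3, 10, 12, 9]})
        # single group suffices for the merge rule; add a healthy second group
        m2, g2 = _matrix_with_counts({"A": [3, 10, 12, 9], "B": [9, 9, 9, 9]})
        out, report = collapse_sparse_categories(m2, g2, min_cell=5)
        assert out.item_categories[0] == 3
        assert report.merges[0].merged_code == 1
        assert report.merges[0].into_code == 2
        assert set(np.unique(out.responses)) == {1.0, 2.0, 3.0}

    def test_recount_after_collapse_meets_min_cell(self):
        rng = np.random.default_rng(5)
        # skewed item: top category rare
        codes = rng.choice([1, 2, 3, 4], size=200, p=[0.5, 0.3, 0.18, 0.02]).astype(float)
        codes[:4] = 4  # ensure the category occurs
        m = make_matrix(codes[:, None], item_ids=["i0"])
        g = GroupAssignment(np.array(["A"] * 100 + ["B"] * 100, dtype=object))
        out, report = collapse_sparse_categories(m, g, min_cell=5)
        k = int(out.item_categories[0])
        for lvl, idx in g.indices_by_level().items():
            counts = [int((out.responses[idx, 0] == c).sum()) for c in range(1, k + 1)]
            assert min(counts) >= 5, counts

    def test_deterministic_report(self):
        m, g = _matrix_with_counts({"A": [2, 10, 12, 3], "B": [9, 9, 9, 9]})
        out1, r1 = collapse_sparse_categories(m, g)
        out2, r2 = collapse_sparse_categories(m, g)
        np.testing.assert_array_equal(out1.responses, out2.responses)
        assert [(x.merged_code, x.into_code) for x in r1.merges] == [
            (x.merged_code, x.into_code) for x in r2.merges
        ]

    def test_collapse_to_single_category_fails(self):
        m, g = _matrix_with_counts({"A": [1, 1, 1, 1], "B": [1, 1, 1, 1]})
        with pytest.raises(DataError, match="single usable category"):
            collapse_sparse_categories(m, g, min_cell=5)
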