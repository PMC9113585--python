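"""Loading, validation and filtering of incidence studies."""

import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paleoems.incidence import (
    IncidenceError,
    drop_degenerate,
    drop_singletons,
    load_incidence,
    study_from_arrays,
    subset_study,
)


def write_pair(tmp_path, matrix_text, meta_text):
    m = tmp_path / "matrix.csv"
    meta = tmp_path / "meta.csv"
    m.write_text(textwrap.dedent(matrix_text))
    meta.write_text(textwrap.dedent(meta_text))
    return m, meta


META_TWO = """\
    site,assemblage,palaeoenvironment,depth_index,lithology,time_index,region
    a,Avalon,outer shelf,3,mudstone,1,Canada
    b,Nama,middle shelf,8,sandstone,3,Namibia
"""


class TestLoad:
    def test_identity_matrix_loads(self, tmp_path):
        m, meta = write_pair(
            tmp_path,
            """\
            site,tax1,tax2
            a,1,0
            b,0,1
            """,
            META_TWO,
        )
        study = load_incidence(m, meta)
        assert study.n_sites == 2
        assert study.n_taxa == 2
        assert study.n_occurrences == 2
        assert study.sites.loc["a", "assemblage"] == "Avalon"

    def test_non_binary_cell_names_location(self, tmp_path):
        m, meta = write_pair(
            tmp_path,
            """\
            site,tax1,tax2
            a,1,2
            b,0,1
            """,
            META_TWO,
        )
        with pytest.raises(IncidenceError, match="'a'.*'tax2'"):
            load_incidence(m, meta)

    def test_orphan_site_listed(self, tmp_path):
        m, meta = write_pair(
            tmp_path,
            """\
            site,tax1,tax2
            a,1,0
            b,0,1
            zz,1,1
            """,
            META_TWO,
        )
        with pytest.raises(IncidenceError, match="zz"):
            load_incidence(m, meta)

    def test_duplicate_site_label_rejected(self, tmp_path):
        m, meta = write_pair(
            tmp_path,
            """\
            site,tax1,tax2
            a,1,0
            a,0,1
            """,
            META_TWO,
        )
        with pytest.raises(IncidenceError, match="duplicate"):
            load_incidence(m, meta)

    def test_unknown_assemblage_becomes_indeterminate_with_warning(self, tmp_path):
        m, meta = write_pair(
            tmp_path,
            """\
            site,tax1,tax2
            a,1,0
            b,0,1
            """,
            """\
            site,assemblage,palaeoenvironment,depth_index,lithology,time_index,region
            a, avalon ,outer shelf,3,mudstone,1,Canada
            b,Ediacara?,middle shelf,8,sandstone,3,Namibia
            """,
        )
        with pytest.warns(UserWarning, match="Ediacara"):
            study = load_incidence(m, meta)
        # case/whitespace-insensitive match succeeds, unknown maps down
        assert study.sites.loc["a", "assemblage"] == "Avalon"
        assert study.sites.loc["b", "assemblage"] == "indeterminate"

    def test_depth_index_out_of_range_rejected(self, tmp_path):
        m, meta = write_pair(
            tmp_path,
            """\
            site,tax1,tax2
            a,1,0
            b,0,1
            """,
            """\
            site,assemblage,palaeoenvironment,depth_index,lithology,time_index,region
            a,Avalon,outer shelf,12,mudstone,1,Canada
            b,Nama,middle shelf,8,sandstone,3,Namibia
            """,
        )
        with pytest.raises(IncidenceError, match="depth_index"):
            load_incidence(m, meta)

    def test_csv_roundtrip(self, tmp_path, toy_study):
        toy_study.to_csv(tmp_path / "m.csv", tmp_path / "meta.csv")
        again = load_incidence(tmp_path / "m.csv", tmp_path / "meta.csv")
        assert again.matrix.astype(int).equals(toy_study.matrix.astype(int))


class TestSubset:
    @pytest.fixture
    def labelled_study(self):
        values = np.array(
            [[1, 0, 1], [1, 1, 0], [0, 1, 0], [0, 1, 1], [1, 0, 0]]
        )
        study = study_from_arrays(values)
        meta = study.sites.copy()
        meta["assemblage"] = ["Avalon", "Avalon", "Nama", "Nama", "White Sea"]
        return study_from_arrays(values, metadata=meta)

    def test_subset_by_assemblage(self, labelled_study):
        sub = subset_study(labelled_study, assemblage="Nama")
        assert sub.n_sites == 2
        assert set(sub.sites["assemblage"]) == {"Nama"}

    def test_subset_by_collection(self, labelled_study):
        sub = subset_study(labelled_study, assemblage={"Avalon", "White Sea"})
        assert sub.n_sites == 3

    def test_absent_taxa_dropped(self, labelled_study):
        # taxon 3 only occurs at Avalon/Nama sites
        sub = subset_study(labelled_study, assemblage="White Sea")
        assert sub.n_taxa == 1

    def test_empty_subset_rejected(self, labelled_study):
        with pytest.raises(IncidenceError, match="no sites"):
            subset_study(labelled_study, assemblage="Doushantuo")

    def test_unknown_field_rejected(self, labelled_study):
        with pytest.raises(IncidenceError, match="unknown metadata field"):
            subset_study(labelled_study, epoch="late")

    def test_callable_predicate(self, labelled_study):
        sub = subset_study(labelled_study, lambda row: row["depth_index"] <= 5)
        assert sub.n_sites >= 1
        assert (sub.sites["depth_index"] <= 5).all()


class TestSingletonsAndDegenerate:
    def test_singleton_column_removed_others_intact(self):
        values = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 1, 1]])
        # taxon 0 occurs twice, taxon 1 three times, taxon 2 twice -> keep all
        study = study_from_arrays(values)
        assert drop_singletons(study).n_taxa == 3
        values[:, 0] = [1, 0, 0, 0]  # now a singleton
        study = study_from_arrays(values)
        filtered = drop_singletons(study)
        assert filtered.n_taxa == 2
        assert list(filtered.matrix.columns) == ["t02", "t03"]

    def test_no_singletons_is_identity(self, toy_study):
        assert drop_singletons(toy_study) is toy_study

    def test_emptied_sites_retained_and_flagged(self):
        values = np.array([[1, 0], [0, 1], [0, 1]])
        study = study_from_arrays(values)
        filtered = drop_singletons(study)  # taxon 0 is a singleton
        assert filtered.n_sites == 3
        assert filtered.empty_sites == ["s01"]
        assert "retained" in filtered.provenance

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        values = (rng.random((10, 8)) < 0.3).astype(int)
        study = study_from_arrays(values)
        once = drop_singletons(study)
        twice = drop_singletons(once)
        assert once.matrix.equals(twice.matrix)

    def test_drop_degenerate_removes_zero_row(self):
        values = np.array([[1, 1], [0, 0], [1, 0]])
        out = drop_degenerate(study_from_arrays(values))
        assert out.n_sites == 2

    def test_drop_degenerate_iterates_to_fixed_point(self):
        # removing the empty column leaves a row empty too
        values = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]])
        out = drop_degenerate(study_from_arrays(values))
        assert (out.values().sum(axis=0) > 0).all()
        assert (out.values().sum(axis=1) > 0).all()

    def test_dense_matrix_unchanged(self, toy_study):
        assert drop_degenerate(toy_study) is toy_study

    def test_too_small_after_removal(self):
        values = np.array([[1, 1, 1], [0, 0, 0]])
        with pytest.raises(IncidenceError, match="too small"):
            drop_degenerate(study_from_arrays(values))


@settings(max_examples=50, deadline=None)
@given(
    values=arrays(
        np.int8,
        st.tuples(st.integers(3, 8), st.integers(3, 8)),
        elements=st.integers(0, 1),
    )
)
def test_filters_never_invent_occurrences(values):
    """Every filter's output matrix is a submatrix of its input."""
    study = study_from_arrays(values)
    for op in (drop_singletons,):
        out = op(study)
        sub = study.matrix.loc[out.matrix.index, out.matrix.columns]
        assert out.matrix.equals(sub)
    try:
        out = drop_degenerate(study)
    except IncidenceError:
        return
    assert out.matrix.equals(study.matrix.loc[out.matrix.index, out.matrix.columns])
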