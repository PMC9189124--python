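"""Readers, writers, containers and gene-universe harmonization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cssig.data_model import (
    DatasetCollection,
    ExpressionDataset,
    FormatError,
    GeneModule,
    MetaboliteTable,
    collapse_duplicate_genes,
    gene_universe,
    load_collection,
    read_expression_table,
    read_gmt,
    read_metabolite_table,
    samples_in_class,
    write_collection,
    write_expression_table,
    write_gmt,
)


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestExpressionIO:
    def test_minimal_tsv(self, tmp_path):
        p = _write(tmp_path / "e.tsv", "gene\tS1\tS2\nG1\t1.0\t2.0\nG2\t3.0\t4.0\n")
        ds = read_expression_table(p)
        assert ds.genes == ["G1", "G2"]
        assert ds.samples == ["S1", "S2"]
        assert ds.values.loc["G2", "S2"] == 4.0

    def test_csv_dialect(self, tmp_path):
        p = _write(tmp_path / "e.csv", "gene,S1,S2\nG1,1,2\nG2,3,4\n")
        ds = read_expression_table(p)
        assert ds.values.shape == (2, 2)

    def test_gct_roundtrip_and_fixture(self, tmp_path):
        text = ("#1.2\n3\t2\nName\tDescription\tS1\tS2\n"
                "G1\tna\t1.5\t2.5\nG2\tna\t0.0\t1.0\nG3\tna\t-1.0\t4.0\n")
        p = _write(tmp_path / "e.gct", text)
        ds = read_expression_table(p)
        assert ds.values.shape == (3, 2)
        assert ds.values.loc["G3", "S1"] == -1.0
        out = tmp_path / "w.gct"
        write_expression_table(ds, out, dialect="gct")
        again = read_expression_table(out)
        pd.testing.assert_frame_equal(ds.values, again.values)

    def test_gct_dims_mismatch(self, tmp_path):
        text = "#1.2\n5\t2\nName\tDescription\tS1\tS2\nG1\tna\t1\t2\n"
        with pytest.raises(FormatError, match="declares"):
            read_expression_table(_write(tmp_path / "bad.gct", text))

    def test_duplicate_gene_rejected(self, tmp_path):
        p = _write(tmp_path / "d.tsv", "gene\tS1\tS2\nG1\t1\t2\nG1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate gene"):
            read_expression_table(p)

    def test_duplicate_sample_rejected(self, tmp_path):
        p = _write(tmp_path / "d.tsv", "gene\tS1\tS1\nG1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            read_expression_table(p)

    def test_non_numeric_cell(self, tmp_path):
        p = _write(tmp_path / "n.tsv", "gene\tS1\tS2\nG1\t1\toops\n")
        with pytest.raises(FormatError, match="non-numeric"):
            read_expression_table(p)

    def test_missing_cell_rejected(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "gene\tS1\tS2\nG1\t1\t\n")
        with pytest.raises(FormatError):
            read_expression_table(p)

    def test_tsv_roundtrip_full_precision(self, tmp_path, rng):
        values = pd.DataFrame(rng.normal(size=(7, 5)),
                              index=[f"G{i}" for i in range(7)],
                              columns=[f"S{j}" for j in range(5)])
        ds = ExpressionDataset("d", values)
        path = tmp_path / "rt.tsv"
        write_expression_table(ds, path)
        back = read_expression_table(path)
        np.testing.assert_array_equal(ds.values.to_numpy(),
                                      back.values.to_numpy())


class TestCollapse:
    def test_no_duplicates_unchanged(self):
        frame = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["S1", "S2"])
        pd.testing.assert_frame_equal(collapse_duplicate_genes(frame), frame)

    def test_highest_mean_kept(self):
        frame = pd.DataFrame([[1.0, 1.0], [2.0, 2.0], [0.0, 5.0]],
                             index=["G1", "G1", "G2"], columns=["S1", "S2"])
        out = collapse_duplicate_genes(frame, policy="highest_mean")
        assert list(out.index) == ["G1", "G2"]
        assert out.loc["G1", "S1"] == 2.0  # mean-2.0 row retained

    def test_error_policy(self):
        frame = pd.DataFrame([[1.0], [2.0]], index=["G1", "G1"], columns=["S1"])
        with pytest.raises(ValueError, match="duplicate"):
            collapse_duplicate_genes(frame, policy="error")

    def test_reader_applies_policy(self, tmp_path):
        p = _write(tmp_path / "d.tsv", "gene\tS1\tS2\nG1\t1\t1\nG1\t3\t3\n")
        ds = read_expression_table(p, duplicates="highest_mean")
        assert ds.values.loc["G1", "S1"] == 3.0


class TestGeneUniverse:
    def _mk(self, dataset_id, genes):
        values = pd.DataFrame(np.arange(len(genes) * 3, dtype=float
                                        ).reshape(len(genes), 3),
                              index=genes, columns=["S1", "S2", "S3"])
        return ExpressionDataset(dataset_id, values)

    def test_single_dataset_both_modes(self):
        coll = DatasetCollection([self._mk("A", ["G2", "G1"])], anchor_id="A")
        assert gene_universe(coll, "union") == ["G2", "G1"]
        assert gene_universe(coll, "shared") == ["G2", "G1"]

    def test_union_and_shared_enumeration(self):
        coll = DatasetCollection(
            [self._mk("X", ["A", "B", "C"]), self._mk("Y", ["B", "C", "D"])],
            anchor_id="X")
        assert gene_universe(coll, "union") == ["A", "B", "C", "D"]
        assert gene_universe(coll, "shared") == ["B", "C"]

    def test_union_first_seen_order(self):
        coll = DatasetCollection(
            [self._mk("X", ["Z", "A"]), self._mk("Y", ["A", "M", "Z"])],
            anchor_id="X")
        assert gene_universe(coll, "union") == ["Z", "A", "M"]

    def test_size_bounds_and_subset(self, small_study):
        collection, _, _ = small_study
        union = gene_universe(collection, "union")
        shared = gene_universe(collection, "shared")
        per = [ds.n_genes for ds in collection]
        assert max(per) <= len(union) <= sum(per)
        for ds in collection:
            assert set(shared) <= set(ds.genes)


class TestGmt:
    def test_parse_line(self, tmp_path):
        p = _write(tmp_path / "m.gmt", "SIG\tdesc\tG1\tG2\n")
        mods = read_gmt(p)
        assert mods[0].name == "SIG"
        assert mods[0].members == ["G1", "G2"]

    def test_short_line_rejected(self, tmp_path):
        p = _write(tmp_path / "m.gmt", "SIG\tdesc\n")
        with pytest.raises(FormatError, match=">= 3"):
            read_gmt(p)

    def test_duplicate_member_rejected(self, tmp_path):
        p = _write(tmp_path / "m.gmt", "SIG\tdesc\tG1\tG1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_field_count_for_150_members(self, tmp_path):
        module = GeneModule("big", [f"G{i:03d}" for i in range(150)])
        path = tmp_path / "big.gmt"
        write_gmt([module], path)
        line = path.read_text().splitlines()[0]
        assert len(line.split("\t")) == 152

    @given(member_lists=st.lists(
        st.lists(st.from_regex(r"[A-Z][A-Z0-9]{0,8}", fullmatch=True),
                 min_size=1, max_size=60, unique=True),
        min_size=1, max_size=4))
    def test_roundtrip_random_modules(self, member_lists, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("gmt")
        modules = [GeneModule(f"M{i}", members)
                   for i, members in enumerate(member_lists)]
        path = tmp / "rt.gmt"
        write_gmt(modules, path)
        back = read_gmt(path)
        assert [(m.name, m.members) for m in back] == \
            [(m.name, m.members) for m in modules]

    def test_roundtrip_large_module(self, tmp_path):
        module = GeneModule("L", [f"G{i:04d}" for i in range(500)])
        path = tmp_path / "l.gmt"
        write_gmt([module], path)
        assert read_gmt(path)[0].members == module.members


class TestMetabolites:
    def test_read_dims(self, tmp_path):
        p = _write(tmp_path / "m.tsv",
                   "metabolite\tS1\tS2\tS3\ncitrate\t1\t2\t3\nspermine\t4\t5\t6\n")
        table = read_metabolite_table(p)
        assert table.metabolites == ["citrate", "spermine"]
        assert len(table.samples) == 3

    def test_negative_rejected(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "metabolite\tS1\ncitrate\t-1.0\n")
        with pytest.raises(ValueError, match="non-negative"):
            read_metabolite_table(p)

    def test_join_requires_shared_samples(self, tiny_dataset, tiny_metabolites):
        shared = [s for s in tiny_dataset.samples
                  if s in set(tiny_metabolites.samples)]
        assert shared == ["S1", "S2", "S3", "S4"]
        other = MetaboliteTable(pd.DataFrame([[1.0]], index=["citrate"],
                                             columns=["Z9"]))
        assert not set(tiny_dataset.samples) & set(other.samples)


class TestContainers:
    def test_module_score_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            GeneModule("m", ["A", "B"], scores=[0.1, 0.9])

    def test_gene_id_validation(self):
        with pytest.raises(ValueError, match="tab/newline"):
            GeneModule("m", ["A\tB"])

    def test_collection_requires_anchor_member(self, tiny_dataset):
        with pytest.raises(ValueError, match="anchor"):
            DatasetCollection([tiny_dataset], anchor_id="missing")

    def test_class_filter(self, tiny_dataset):
        assert samples_in_class(tiny_dataset, "cancer") == ["S3", "S4"]
        assert samples_in_class(tiny_dataset, "normal") == ["S1", "S2"]
        assert samples_in_class(tiny_dataset, None) == tiny_dataset.samples
        with pytest.raises(ValueError, match="unknown tissue class"):
            samples_in_class(tiny_dataset, "bogus")


class TestManifest:
    def test_collection_roundtrip(self, tmp_path, small_study):
        collection, metabolites, truth = small_study
        manifest = write_collection(collection, tmp_path / "sim",
                                    metabolites=metabolites,
                                    truth=truth.to_json_dict())
        back, met = load_collection(manifest)
        assert back.ids == collection.ids
        assert back.anchor_id == collection.anchor_id
        np.testing.assert_array_equal(back.anchor.values.to_numpy(),
                                      collection.anchor.values.to_numpy())
        assert met is not None
        np.testing.assert_array_equal(met.values.to_numpy(),
                                      metabolites.values.to_numpy())
        ann = back.anchor.annotations
        assert list(ann["tissue_class"]) == \
            list(collection.anchor.annotations["tissue_class"])
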