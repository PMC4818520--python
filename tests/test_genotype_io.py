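import numpy as np
import pytest

import multitrans as mt
from multitrans.errors import (
    EmptyPanelError,
    InputError,
    ParseError,
    ValidationError,
)
from multitrans.genotype_io import GenotypeMatrix


class TestReadMatrix:
    def test_shape_metadata_and_missing(self, toy_matrix_file):
        g = mt.read_genotypes(toy_matrix_file)
        assert g.dosages.shape == (2, 3)
        assert not g.standardized
        assert g.missing_mask.sum() == 1
        # snp3 (pos 200) sorts before snp2 (pos 300)
        assert list(g.marker_ids) == ["snp1", "snp3", "snp2"]
        assert list(g.positions) == [100, 200, 300]

    def test_positions_sorted_per_chromosome(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text(
            "2 a 500 A 0 1 2\n1 b 900 A 1 1 0\n1 c 100 A 2 0 1\n"
        )
        g = mt.read_genotypes(path)
        # chromosome order of first appearance is kept; positions ascend within
        assert list(g.chromosomes) == ["2", "1", "1"]
        assert list(g.positions) == [500, 100, 900]

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1 a 100 A 0 1\n1 b 200 A 0 oops\n")
        with pytest.raises(ParseError, match="line 2"):
            mt.read_genotypes(path)

    def test_duplicate_marker_id_rejected(self, tmp_path):
        path = tmp_path / "dup.txt"
        path.write_text("1 a 100 A 0 1\n1 a 200 A 1 1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            mt.read_genotypes(path)

    def test_single_individual_rejected(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("1 a 100 A 0\n")
        with pytest.raises(ValidationError):
            mt.read_genotypes(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError):
            mt.read_genotypes(tmp_path / "nope.txt")

    def test_round_trip_exact(self, small_panel, tmp_path):
        path = tmp_path / "rt.txt"
        mt.write_genotypes(small_panel, path)
        back = mt.read_genotypes(path)
        np.testing.assert_array_equal(back.dosages, small_panel.dosages)
        assert list(back.marker_ids) == list(small_panel.marker_ids)
        assert list(back.positions) == list(small_panel.positions)
        assert list(back.chromosomes) == list(small_panel.chromosomes)


class TestPlink:
    def test_round_trip(self, small_panel, tmp_path):
        prefix = str(tmp_path / "panel")
        mt.write_plink(small_panel, prefix)
        back = mt.read_plink(prefix)
        np.testing.assert_array_equal(back.dosages, small_panel.dosages)
        assert list(back.marker_ids) == list(small_panel.marker_ids)

    def test_round_trip_with_missing_and_odd_n(self, tmp_path):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(5, 4)).astype(float)
        dos[2, 1] = np.nan
        g = GenotypeMatrix(
            dos, [f"s{i}" for i in range(4)], ["1"] * 4,
            [10, 20, 30, 40], [f"i{i}" for i in range(5)],
        )
        prefix = str(tmp_path / "odd")
        mt.write_plink(g, prefix)
        back = mt.read_plink(prefix + ".bed")
        np.testing.assert_array_equal(back.missing_mask, g.missing_mask)
        np.testing.assert_array_equal(
            back.dosages[~back.missing_mask], g.dosages[~g.missing_mask]
        )

    def test_bad_magic(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x01")
        (tmp_path / "x.bim").write_text("1 a 0 100 A C\n")
        (tmp_path / "x.fam").write_text("f1 i1 0 0 0 -9\nf2 i2 0 0 0 -9\n")
        with pytest.raises(ParseError, match="magic"):
            mt.read_plink(tmp_path / "x.bed")


class TestPhenotype:
    def test_one_column(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("1.5\n-0.25\n3\n")
        y = mt.read_phenotype(path)
        np.testing.assert_allclose(y.values, [1.5, -0.25, 3.0])

    def test_two_column_aligned(self, tmp_path):
        path = tmp_path / "p2.txt"
        path.write_text("b\t2.0\na\t1.0\n")
        y = mt.read_phenotype(path, individual_ids=["a", "b"])
        np.testing.assert_allclose(y.values, [1.0, 2.0])

    def test_round_trip(self, tmp_path):
        y = mt.PhenotypeVector([0.1, -2.5, 3.25], ["a", "b", "c"])
        mt.write_phenotype(y, tmp_path / "y.txt")
        back = mt.read_phenotype(tmp_path / "y.txt", individual_ids=["a", "b", "c"])
        np.testing.assert_array_equal(back.values, y.values)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            mt.PhenotypeVector([1.0, np.inf])


class TestFilterMarkers:
    def test_monomorphic_removed_and_maf_boundary(self):
        dos = np.array([[0, 2, 1], [0, 1, 0], [0, 1, 1], [0, 0, 2]], dtype=float)
        g = GenotypeMatrix(dos, ["a", "b", "c"], ["1"] * 3, [1, 2, 3],
                           [f"i{k}" for k in range(4)])
        kept = mt.filter_markers(g, maf_min=0.05)
        assert list(kept.marker_ids) == ["b", "c"]

    def test_missingness_filter(self):
        dos = np.ones((10, 2))
        dos[:5, 0] = 0.0  # MAF 0.25 both after edits
        dos[:5, 1] = 0.0
        dos[:3, 1] = np.nan  # 30 % missing
        g = GenotypeMatrix(dos, ["a", "b"], ["1"] * 2, [1, 2],
                           [f"i{k}" for k in range(10)])
        kept = mt.filter_markers(g, maf_min=0.05, missing_max=0.10)
        assert list(kept.marker_ids) == ["a"]

    def test_all_retained_at_half_maf(self):
        # every column half 0s half 2s -> MAF exactly 0.5
        col = np.concatenate([np.zeros(25), np.full(25, 2.0)])
        dos = np.tile(col[:, None], (1, 100))
        g = GenotypeMatrix(dos, [f"s{j}" for j in range(100)], ["1"] * 100,
                           np.arange(1, 101), [f"i{k}" for k in range(50)])
        assert mt.filter_markers(g).m == 100

    def test_empty_panel_error(self):
        dos = np.zeros((4, 2))
        g = GenotypeMatrix(dos + [[0, 0]], ["a", "b"], ["1"] * 2, [1, 2],
                           [f"i{k}" for k in range(4)])
        with pytest.raises(EmptyPanelError):
            mt.filter_markers(g)


class TestStandardize:
    def test_closed_form_column(self):
        g = GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]), ["a"], ["1"], [1],
                           ["x", "y", "z"])
        s = mt.standardize(g)
        root = np.sqrt(3.0 / 2.0)
        np.testing.assert_allclose(s.dosages[:, 0], [-root, 0.0, root], atol=1e-12)

    def test_missing_mean_imputed(self):
        g = GenotypeMatrix(np.array([[0.0], [2.0], [np.nan]]), ["a"], ["1"], [1],
                           ["x", "y", "z"])
        s = mt.standardize(g)
        assert s.dosages[2, 0] == pytest.approx(0.0, abs=1e-12)
        assert abs(s.dosages.mean()) < 1e-12

    def test_idempotent(self, small_panel):
        s1 = mt.standardize(mt.filter_markers(small_panel))
        s2 = mt.standardize(s1)
        np.testing.assert_allclose(s2.dosages, s1.dosages, atol=1e-8)

    def test_zero_variance_names_marker(self):
        dos = np.column_stack([np.ones(4), [0, 1, 2, 1.0]])
        g = GenotypeMatrix(dos, ["mono", "ok"], ["1"] * 2, [1, 2],
                           [f"i{k}" for k in range(4)])
        with pytest.raises(ValidationError, match="mono"):
            mt.standardize(g)

    def test_filter_then_standardize_never_degenerate(self, small_panel):
        # with maf_min > 0 every surviving marker is polymorphic
        s = mt.standardize(mt.filter_markers(small_panel, maf_min=0.05))
        assert np.all(s.dosages.std(axis=0) > 0.1)
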