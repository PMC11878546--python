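"""Allele count tensor invariants, dialect readers/writers and the HDF5 store."""

import gzip

import numpy as np
import pytest

from mitocall import (
    AlleleCountTensor,
    CloneSimSpec,
    MitoMutationModel,
    read_cellsnp,
    read_mgatk,
    simulate_dataset,
    write_fixture,
)
from mitocall.io import MitoStore, export_results


def _cellsnp_paths(d):
    return (
        d / "cellSNP.tag.AD.mtx",
        d / "cellSNP.tag.DP.mtx",
        d / "cellSNP.base.vcf",
        d / "cellSNP.samples.tsv",
    )


class TestTensor:
    def test_depth_is_base_sum(self, small_tensor):
        depth = small_tensor.depth()
        expected = np.zeros((3, 5), dtype=int)
        for x in range(4):
            for i in range(3):
                for j in range(5):
                    expected[i, j] += small_tensor.counts[x, i, j]
        assert np.array_equal(depth, expected)

    def test_zero_count_loci_flagged_not_dropped(self, small_tensor):
        assert small_tensor.n_loci == 5
        assert small_tensor.zero_loci[4] and not small_tensor.zero_loci[:4].any()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            AlleleCountTensor(["a"], [("chrM", 1)], -np.ones((4, 1, 1), dtype=int))

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            AlleleCountTensor(
                ["a", "a"], [("chrM", 1)], np.ones((4, 2, 1), dtype=int)
            )

    def test_loci_sorted_on_construction(self):
        t = AlleleCountTensor(
            ["a"],
            [("chrM", 30), ("chrM", 10)],
            np.arange(8).reshape(4, 1, 2),
        )
        assert t.loci == [("chrM", 10), ("chrM", 30)]
        # column for position 10 was originally index 1
        assert np.array_equal(t.counts[:, 0, 0], [1, 3, 5, 7])


class TestMgatkDialect:
    def test_round_trip(self, tmp_path):
        tensor, _ = simulate_dataset(CloneSimSpec(n_cells=6, n_loci=5, seed=2))
        write_fixture(tensor, "mgatk", tmp_path)
        assert read_mgatk(tmp_path) == tensor

    def test_strand_counts_are_summed(self, tmp_path):
        for b in "ACGT":
            with gzip.open(tmp_path / f"{b}.txt.gz", "wt") as fh:
                if b == "A":
                    fh.write("100,BC1,2,3\n")
                else:
                    fh.write("100,BC1,0,0\n")
        t = read_mgatk(tmp_path)
        assert t.base_counts("A")[0, 0] == 5

    def test_missing_base_file_names_it(self, tmp_path):
        for b in "ACG":
            with gzip.open(tmp_path / f"{b}.txt.gz", "wt") as fh:
                fh.write("1,BC1,1,0\n")
        with pytest.raises(FileNotFoundError, match="T"):
            read_mgatk(tmp_path)

    def test_empty_base_file_errors(self, tmp_path):
        for b in "ACGT":
            with gzip.open(tmp_path / f"{b}.txt.gz", "wt") as fh:
                if b != "A":
                    fh.write("1,BC1,1,0\n")
        with pytest.raises(ValueError, match="no records"):
            read_mgatk(tmp_path)

    def test_malformed_row_reports_line(self, tmp_path):
        for b in "ACGT":
            with gzip.open(tmp_path / f"{b}.txt.gz", "wt") as fh:
                fh.write("1,BC1,1,0\n")
                if b == "C":
                    fh.write("2,BC1,x,0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_mgatk(tmp_path)

    def test_whitelist_drops_unlisted_barcodes(self, tmp_path):
        # >= 4 loci so every base carries reads and all four files have rows
        tensor, _ = simulate_dataset(CloneSimSpec(n_cells=4, n_loci=4, seed=5))
        write_fixture(tensor, "mgatk", tmp_path)
        sub = read_mgatk(tmp_path, whitelist=tensor.cells[:2])
        assert sub.cells == tensor.cells[:2]
        assert np.array_equal(sub.counts, tensor.counts[:, :2, :])

    def test_custom_column_order(self, tmp_path):
        for b in "ACGT":
            with gzip.open(tmp_path / f"{b}.txt.gz", "wt") as fh:
                # barcode first, then position, rev, fwd
                fh.write("BC1,100,3,2\n" if b == "A" else "BC1,100,0,0\n")
        t = read_mgatk(tmp_path, columns=("barcode", "position", "rev", "fwd"))
        assert t.base_counts("A")[0, 0] == 5


class TestCellsnpDialect:
    def test_round_trip(self, tmp_path):
        tensor, _ = simulate_dataset(CloneSimSpec(n_cells=6, n_loci=5, seed=2))
        write_fixture(tensor, "cellsnp", tmp_path)
        assert read_cellsnp(*_cellsnp_paths(tmp_path)) == tensor

    def test_dialects_agree_on_biallelic_fixture(self, tmp_path):
        tensor, _ = simulate_dataset(CloneSimSpec(n_cells=8, n_loci=4, seed=9))
        write_fixture(tensor, "mgatk", tmp_path / "m")
        write_fixture(tensor, "cellsnp", tmp_path / "c")
        assert read_mgatk(tmp_path / "m") == read_cellsnp(*_cellsnp_paths(tmp_path / "c"))

    def test_ref_alt_count_mapping(self, tmp_path):
        from scipy import io as spio
        from scipy import sparse

        spio.mmwrite(str(tmp_path / "AD.mtx"), sparse.coo_matrix([[3]]))
        spio.mmwrite(str(tmp_path / "DP.mtx"), sparse.coo_matrix([[10]]))
        (tmp_path / "vars.vcf").write_text("#CHROM\tPOS\tID\tREF\tALT\nchrM\t5\t.\tA\tG\n")
        (tmp_path / "bc.tsv").write_text("BC1\n")
        t = read_cellsnp(
            tmp_path / "AD.mtx", tmp_path / "DP.mtx", tmp_path / "vars.vcf", tmp_path / "bc.tsv"
        )
        assert t.base_counts("A")[0, 0] == 7
        assert t.base_counts("G")[0, 0] == 3
        assert t.base_counts("C")[0, 0] == 0 and t.base_counts("T")[0, 0] == 0

    def test_ad_exceeding_dp_rejected(self, tmp_path):
        from scipy import io as spio
        from scipy import sparse

        spio.mmwrite(str(tmp_path / "AD.mtx"), sparse.coo_matrix([[11]]))
        spio.mmwrite(str(tmp_path / "DP.mtx"), sparse.coo_matrix([[10]]))
        (tmp_path / "vars.vcf").write_text("chrM\t5\tA\tG\n")
        (tmp_path / "bc.tsv").write_text("BC1\n")
        with pytest.raises(ValueError, match="AD exceeds DP"):
            read_cellsnp(
                tmp_path / "AD.mtx", tmp_path / "DP.mtx",
                tmp_path / "vars.vcf", tmp_path / "bc.tsv",
            )

    def test_multiallelic_locus_rejected_by_writer(self):
        counts = np.zeros((4, 2, 1), dtype=int)
        counts[0, :, 0] = 5
        counts[1, :, 0] = 3
        counts[2, :, 0] = 2
        t = AlleleCountTensor(["a", "b"], [("chrM", 1)], counts)
        with pytest.raises(ValueError, match="biallelic"):
            write_fixture(t, "cellsnp", "/tmp/should_not_exist")


class TestStore:
    def test_tensor_round_trip_is_lossless(self, tmp_path, small_tensor):
        store = MitoStore(tmp_path / "s.h5")
        store.write_tensor(small_tensor)
        assert store.read_tensor() == small_tensor

    def test_refit_free_reload_of_fits_and_qvalues(self, tmp_path):
        tensor, _ = simulate_dataset(
            CloneSimSpec(n_cells=40, n_loci=3, seed=4)
        )
        results = MitoMutationModel(tensor).fit()
        store = MitoStore(tmp_path / "s.h5")
        store.write_tensor(tensor)
        store.write_results(results)
        fits = store.read_fits()
        for j, fit in enumerate(fits):
            if fit is not None and results.locus_fits[j].ok:
                assert fit.alpha == results.locus_fits[j].null.alpha
                assert fit.beta == results.locus_fits[j].null.beta
        q = store.read_qvalues()
        assert np.array_equal(q.to_numpy(), results.qvalues, equal_nan=True)

    def test_missing_stage_error_names_step(self, tmp_path, small_tensor):
        store = MitoStore(tmp_path / "s.h5")
        store.write_tensor(small_tensor)
        with pytest.raises(KeyError, match="fit"):
            store.read_qvalues()

    def test_export_af_pure_wt_cell_is_one(self, tmp_path):
        counts = np.zeros((4, 1, 1), dtype=int)
        counts[0, 0, 0] = 12  # m = N = 12
        t = AlleleCountTensor(["BC1"], [("chrM", 7)], counts)
        store = MitoStore(tmp_path / "s.h5")
        store.write_tensor(t)
        export_results(store, "af", tmp_path / "af.tsv")
        body = (tmp_path / "af.tsv").read_text().splitlines()
        assert body[1].split("\t") == ["chrM.7", "1.0"]

    def test_export_qvalues_missing_as_empty(self, tmp_path):
        tensor, _ = simulate_dataset(CloneSimSpec(n_cells=30, n_loci=2, seed=6))
        # zero out one cell entirely -> missing q at both loci
        tensor.counts[:, 0, :] = 0
        results = MitoMutationModel(tensor).fit()
        store = MitoStore(tmp_path / "s.h5")
        store.write_tensor(tensor)
        store.write_results(results)
        export_results(store, "qvalues", tmp_path / "q.tsv")
        first_data_row = (tmp_path / "q.tsv").read_text().splitlines()[1]
        assert first_data_row.split("\t")[1] == ""  # cell 0 at locus 0

    def test_empty_mutation_set_gives_header_only_calls(self, tmp_path):
        tensor, _ = simulate_dataset(CloneSimSpec(n_cells=30, n_loci=2, seed=6))
        results = MitoMutationModel(tensor).fit()
        store = MitoStore(tmp_path / "s.h5")
        store.write_tensor(tensor)
        store.write_results(results)
        store.write_calls(results.call())
        export_results(store, "calls", tmp_path / "c.tsv")
        lines = (tmp_path / "c.tsv").read_text().splitlines()
        assert lines[0].startswith("cell\tlocus")
        assert len(lines) == 1
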