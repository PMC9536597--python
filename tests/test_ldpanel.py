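"""Tests for reference-panel loading and correlation-structure construction."""

import numpy as np
import pytest

from crossgwas.ldpanel import (
    CorrelationStructure,
    GeneWindow,
    PanelError,
    ReferencePanel,
    build_null_covariance,
    correlation_matrix,
    load_panel,
    read_gene_annotation,
)

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
"""


class TestLoadPanel:
    def test_matrix_panel(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text("rs1\trs2\trs3\n0\t1\t2\n1\t1\t0\n2\t0\t1\n0\t2\t2\n")
        panel = load_panel(path, "matrix")
        assert (panel.n_samples, panel.n_snps) == (4, 3)
        assert "rs2" in panel

    def test_vcf_panel_skips_multiallelic(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0|1\n"
            "1\t200\trs2\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\n"
            "1\t300\trs3\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.\t0/1\t1/1\n"
        )
        path = tmp_path / "panel.vcf"
        path.write_text(VCF_HEADER + body)
        panel = load_panel(path, "vcf")
        assert panel.snp_ids == ["rs1", "rs3"]
        # phased collapsed to dosage; missing call is NaN
        assert panel.dosages[3, 0] == 1.0
        assert np.isnan(panel.dosages[1, 1])

    def test_interval_query(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\n"
            "2\t150\trs2\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\n"
        )
        path = tmp_path / "p.vcf"
        path.write_text(VCF_HEADER + body)
        panel = load_panel(path, "vcf")
        assert panel.snps_in_interval("1", 50, 150) == ["rs1"]
        assert panel.snps_in_interval("1", 500, 900) == []

    def test_empty_panel_error(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("rs1\trs2\n")
        with pytest.raises(PanelError):
            load_panel(path, "matrix")


class TestCorrelationMatrix:
    def _panel(self, mat, ids):
        return ReferencePanel(np.asarray(mat, dtype=float), ids)

    def test_identical_columns(self):
        panel = self._panel([[0, 0], [1, 1], [2, 2], [1, 1]], ["a", "b"])
        struct = correlation_matrix(panel, ["a", "b"])
        assert np.allclose(struct.sigma, [[1, 1], [1, 1]])
        assert struct.eigvals == pytest.approx([2.0])
        assert struct.dropped_dims == 1

    def test_single_snp(self):
        panel = self._panel([[0], [1], [2]], ["a"])
        struct = correlation_matrix(panel, ["a"])
        assert np.allclose(struct.sigma, [[1.0]])
        assert struct.eigvals == pytest.approx([1.0])

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(40, 6)).astype(float)
        ids = [f"s{i}" for i in range(6)]
        struct = correlation_matrix(self._panel(geno, ids), ids)
        oracle = np.corrcoef(geno, rowvar=False)
        assert np.allclose(struct.sigma, oracle, atol=1e-12)

    def test_missing_values_mean_imputed(self):
        geno = np.array([[0, 1], [1, np.nan], [2, 0], [1, 2.0]])
        struct = correlation_matrix(self._panel(geno, ["a", "b"]), ["a", "b"])
        filled = geno.copy()
        filled[1, 1] = np.nanmean(geno[:, 1])
        assert np.allclose(struct.sigma, np.corrcoef(filled, rowvar=False))

    def test_monomorphic_dropped(self):
        geno = np.array([[1.0, 0], [1, 1], [1, 2]])
        struct = correlation_matrix(self._panel(geno, ["mono", "ok"]),
                                    ["mono", "ok"])
        assert struct.snp_ids == ["ok"]

    def test_all_absent_error(self):
        panel = self._panel([[0], [1]], ["a"])
        with pytest.raises(PanelError):
            correlation_matrix(panel, ["zzz"])

    def test_trace_equals_retained_snps(self):
        rng = np.random.default_rng(9)
        geno = rng.integers(0, 3, size=(30, 5)).astype(float)
        ids = list("abcde")
        struct = correlation_matrix(self._panel(geno, ids), ids)
        assert np.trace(struct.sigma) == pytest.approx(len(struct.snp_ids))

    def test_eigenvalues_invariant_under_reordering(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(50, 6)).astype(float)
        ids = [f"s{i}" for i in range(6)]
        panel = self._panel(geno, ids)
        s1 = correlation_matrix(panel, ids)
        s2 = correlation_matrix(panel, ids[::-1])
        assert np.allclose(np.sort(s1.eigvals), np.sort(s2.eigvals), atol=1e-10)

    def test_spectral_and_cholesky_reconstruction(self):
        rng = np.random.default_rng(8)
        geno = rng.integers(0, 3, size=(100, 6)).astype(float)
        ids = [f"s{i}" for i in range(6)]
        struct = correlation_matrix(self._panel(geno, ids), ids)
        recon = struct.eigvecs @ np.diag(struct.eigvals) @ struct.eigvecs.T
        assert np.allclose(recon, struct.sigma, atol=1e-8)
        assert np.allclose(struct.chol @ struct.chol.T, struct.sigma, atol=1e-6)


class TestNullCovariance:
    def test_h2_zero_identity(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(30, 4)).astype(float)
        ids = list("abcd")
        panel = ReferencePanel(geno, ids)
        struct = correlation_matrix(panel, ids)
        assert build_null_covariance(struct, panel, 0.0) is struct

    def test_random_effect_null_matches_bruteforce(self):
        rng = np.random.default_rng(12)
        geno = rng.integers(0, 3, size=(50, 8)).astype(float)
        ids = [f"s{i}" for i in range(8)]
        panel = ReferencePanel(geno, ids)
        gene_ids = ids[:3]
        struct = correlation_matrix(panel, gene_ids)
        h2 = 0.4
        out = build_null_covariance(struct, panel, h2)
        # brute force: standardize all columns, x = gene cols, X = all cols
        std = (geno - geno.mean(0)) / geno.std(0, ddof=0)
        x, X = std[:, :3], std
        n, p = X.shape
        expected = h2 * (x.T @ X @ X.T @ x) / (n * p) + (x.T @ x) / n
        assert np.allclose(out.sigma, expected, atol=1e-10)
        # symmetric positive semidefinite
        assert np.allclose(out.sigma, out.sigma.T)
        assert np.linalg.eigvalsh(out.sigma).min() > -1e-10

    def test_invalid_h2(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(30, 4)).astype(float)
        panel = ReferencePanel(geno, list("abcd"))
        struct = correlation_matrix(panel, list("abcd"))
        for h2 in (-0.1, 1.0):
            with pytest.raises(PanelError):
                build_null_covariance(struct, panel, h2)


class TestGeneWindow:
    def test_window_extension_and_clipping(self):
        gw = GeneWindow.from_transcript("g", "1", 30_000, 60_000, 50_000)
        assert (gw.start, gw.end) == (1, 110_000)

    def test_overlap(self):
        a = GeneWindow("a", "1", 100, 200)
        b = GeneWindow("b", "1", 150, 400)
        c = GeneWindow("c", "2", 150, 400)
        assert a.overlaps(b) and not a.overlaps(c)

    def test_annotation_reader(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("gene_id\tchrom\ttx_start\ttx_end\nG1\t1\t60000\t70000\n")
        (gw,) = read_gene_annotation(path, 50_000)
        assert (gw.gene_id, gw.start, gw.end) == ("G1", 10_000, 120_000)


class TestStructureValidation:
    def test_rejects_mismatched_ids(self):
        with pytest.raises(PanelError):
            CorrelationStructure(["a"], np.eye(2))

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(PanelError):
            CorrelationStructure(["a", "b"], np.zeros((2, 2)))
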