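"""Genotype matrix: VCF merging and the filter cascade vs brute-force oracles."""

import numpy as np
import pytest

from conftest import random_matrix
from gbskit.snpmatrix import (
    MISSING,
    FilterAccounting,
    FilterConfig,
    GenotypeMatrix,
    MatrixError,
    SiteKey,
    apply_filter_cascade,
    filter_maf,
    filter_missing,
    het_rate,
    ld_prune,
    mask_repeats,
    merge_vcfs,
    pairwise_r2,
    site_maf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n##contig=<ID=chr2>\n"
)


def write_vcf(path, sample, records):
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos, ref, alt, gt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t30\t.\t.\tGT\t{gt}\n")
    return str(path)


class TestMergeVcfs:
    def test_union_with_missing(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", "A", [("chr1", 100, "A", "G", "0/1")])
        b = write_vcf(tmp_path / "b.vcf", "B", [("chr1", 200, "C", "T", "1/1")])
        m = merge_vcfs([a, b])
        assert m.samples == ["A", "B"]
        assert m.sites == [SiteKey("chr1", 100, "A", "G"), SiteKey("chr1", 200, "C", "T")]
        assert m.dosages.tolist() == [[1, MISSING], [MISSING, 2]]

    def test_dosage_encoding(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", "A", [("chr1", 100, "A", "G", "0/1")])
        b = write_vcf(tmp_path / "b.vcf", "B", [("chr1", 100, "A", "G", "1/1")])
        m = merge_vcfs([a, b])
        assert m.dosages.tolist() == [[1], [2]]

    def test_conflicting_ref_is_error(self, tmp_path):
        a = write_vcf(tmp_path / "a.vcf", "A", [("chr1", 100, "A", "G", "0/1")])
        b = write_vcf(tmp_path / "b.vcf", "B", [("chr1", 100, "C", "G", "0/1")])
        with pytest.raises(MatrixError, match="conflicting REF"):
            merge_vcfs([a, b])

    def test_multiallelic_and_indels_dropped(self, tmp_path):
        a = write_vcf(
            tmp_path / "a.vcf", "A",
            [("chr1", 100, "A", "G,T", "1/2"), ("chr1", 200, "AT", "A", "0/1"),
             ("chr1", 300, "G", "C", "0/0")],
        )
        m = merge_vcfs([a])
        assert m.sites == [SiteKey("chr1", 300, "G", "C")]

    def test_engineered_truth_table(self, tmp_path):
        """5 per-sample VCFs with known overlaps equal the hand-built matrix."""
        rng = np.random.default_rng(3)
        sites = [("chr1", 10 * (j + 1), "A", "C") for j in range(20)]
        truth = np.full((5, 20), MISSING, dtype=int)
        paths = []
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(5):
            present = rng.random(20) < 0.7
            recs = []
            for j, p in enumerate(present):
                if p:
                    d = int(rng.integers(0, 3))
                    truth[i, j] = d
                    recs.append((*sites[j], gt_of[d]))
            paths.append(write_vcf(tmp_path / f"s{i}.vcf", f"s{i}", recs))
        m = merge_vcfs(paths)
        covered = sorted({j for j in range(20) if (truth[:, j] != MISSING).any()})
        assert m.dosages.tolist() == truth[:, covered].tolist()


class TestMaskRepeats:
    def test_boundary_semantics(self):
        m = random_matrix(np.random.default_rng(0), 4, 1, 0)
        site = m.sites[0]  # chr1, pos 10 -> 0-based 9
        out, _ = mask_repeats(m, [("chr1", 9, 10)])
        assert out.n_sites == 0
        out, _ = mask_repeats(m, [("chr1", 10, 200)])
        assert out.n_sites == 1

    def test_negative_coordinate_is_error(self):
        m = random_matrix(np.random.default_rng(0), 4, 2, 0)
        with pytest.raises(MatrixError, match="negative"):
            mask_repeats(m, [("chr1", -5, 10)])

    def test_matches_naive_interval_scan(self, rng):
        m = random_matrix(rng, 20, 100, 0.1)
        mask = []
        for _ in range(30):
            chrom = f"chr{rng.integers(1, 3)}"
            s = int(rng.integers(0, 500))
            mask.append((chrom, s, s + int(rng.integers(1, 60))))
        out, acc = mask_repeats(m, mask)
        naive_keep = [
            k for k in m.sites
            if not any(c == k.seq_id and s <= k.pos - 1 < e for c, s, e in mask)
        ]
        assert out.sites == naive_keep
        assert acc.stages[0]["sites_in"] - acc.stages[0]["sites_removed"] == out.n_sites


class TestMissingness:
    def test_boundary_is_strictly_greater(self):
        d = np.zeros((10, 2), dtype=np.int8)
        d[:2, 0] = MISSING  # exactly 20% missing -> retained
        d[:3, 1] = MISSING  # 30% -> removed
        m = GenotypeMatrix(
            [f"s{i}" for i in range(10)],
            [SiteKey("chr1", 10, "A", "C"), SiteKey("chr1", 20, "A", "C")], d)
        out, _ = filter_missing(m, FilterConfig())
        assert out.sites == [SiteKey("chr1", 10, "A", "C")]

    def test_sites_then_samples_order_rescues_samples(self):
        # sample 0 is bad only because of sites that get removed first
        d = np.zeros((5, 4), dtype=np.int8)
        d[:, 2] = MISSING
        d[:, 3] = MISSING  # two all-missing sites dropped first
        m = GenotypeMatrix(
            [f"s{i}" for i in range(5)],
            [SiteKey("chr1", 10 * (j + 1), "A", "C") for j in range(4)], d)
        out, _ = filter_missing(m, FilterConfig())
        assert out.n_samples == 5 and out.n_sites == 2

    def test_all_sites_removed_is_error(self):
        d = np.full((4, 2), MISSING, dtype=np.int8)
        m = GenotypeMatrix(
            [f"s{i}" for i in range(4)],
            [SiteKey("chr1", 10, "A", "C"), SiteKey("chr1", 20, "A", "C")], d)
        with pytest.raises(MatrixError, match="every site"):
            filter_missing(m, FilterConfig())

    def test_matches_brute_force(self, rng):
        """Fixed-point site/sample removal equals an independent recount."""
        m = random_matrix(rng, 100, 200, 0.15)
        cfg = FilterConfig()
        out, _ = filter_missing(m, cfg)
        keep_sites = list(range(m.n_sites))
        keep_samples = list(range(m.n_samples))
        while True:
            ks = [
                j for j in keep_sites
                if (m.dosages[keep_samples][:, j] == MISSING).mean()
                <= cfg.max_site_missing
            ]
            ksa = [
                i for i in keep_samples
                if (m.dosages[i, ks] == MISSING).mean() <= cfg.max_sample_missing
            ]
            if ks == keep_sites and ksa == keep_samples:
                break
            keep_sites, keep_samples = ks, ksa
        assert out.sites == [m.sites[j] for j in keep_sites]
        assert out.samples == [m.samples[i] for i in keep_samples]
        # output satisfies both constraints simultaneously
        assert ((out.dosages == MISSING).mean(axis=0) <= cfg.max_site_missing).all()
        assert ((out.dosages == MISSING).mean(axis=1) <= cfg.max_sample_missing).all()


class TestMaf:
    def test_hand_arithmetic(self):
        # 8 called samples, dosage sum 3 -> p = 3/16 = 0.1875
        d = np.array([[0, 0, 0, 0, 0, 1, 1, 1, MISSING, MISSING]], dtype=np.int8).T
        m = GenotypeMatrix(
            [f"s{i}" for i in range(10)], [SiteKey("chr1", 10, "A", "C")], d)
        assert site_maf(m)[0] == pytest.approx(0.1875)
        out, _ = filter_maf(m, FilterConfig(min_maf=0.10))
        assert out.n_sites == 1

    def test_monomorphic_removed_boundary_kept(self):
        d = np.zeros((10, 2), dtype=np.int8)
        d[:2, 1] = 2  # p = 4/20 = 0.2 ... make exactly 0.10: 1 hom alt of 10
        d[:1, 1] = 2
        d[1, 1] = 0
        m = GenotypeMatrix(
            [f"s{i}" for i in range(10)],
            [SiteKey("chr1", 10, "A", "C"), SiteKey("chr1", 20, "A", "C")], d)
        maf = site_maf(m)
        assert maf[0] == 0.0 and maf[1] == pytest.approx(0.10)
        out, _ = filter_maf(m, FilterConfig(min_maf=0.10))
        assert out.sites == [SiteKey("chr1", 20, "A", "C")]  # boundary retained

    def test_matches_brute_force(self, rng):
        m = random_matrix(rng, 100, 200, 0.2)
        cfg = FilterConfig()
        out, _ = filter_maf(m, cfg)
        keep = []
        for j in range(m.n_sites):
            col = m.dosages[:, j]
            called = col != MISSING
            if not called.any():
                continue
            p = col[called].sum() / (2 * called.sum())
            if min(p, 1 - p) >= cfg.min_maf:
                keep.append(m.sites[j])
        assert out.sites == keep


class TestLdPrune:
    def test_identical_columns_second_removed(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1]], dtype=np.int8)
        m = GenotypeMatrix(
            [f"s{i}" for i in range(5)],
            [SiteKey("chr1", 10, "A", "C"), SiteKey("chr1", 20, "A", "C")], d)
        out, _ = ld_prune(m, FilterConfig())
        assert out.sites == [SiteKey("chr1", 10, "A", "C")]

    def test_orthogonal_columns_both_kept(self):
        d = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=np.int8)
        m = GenotypeMatrix(
            [f"s{i}" for i in range(4)],
            [SiteKey("chr1", 10, "A", "C"), SiteKey("chr1", 20, "A", "C")], d)
        assert pairwise_r2(d[:, 0], d[:, 1]) == pytest.approx(0.0)
        out, _ = ld_prune(m, FilterConfig())
        assert out.n_sites == 2

    def test_few_shared_or_zero_variance_treated_unlinked(self):
        a = np.array([0, 1, MISSING, MISSING, MISSING], dtype=np.int8)
        b = np.array([0, 1, MISSING, MISSING, MISSING], dtype=np.int8)
        assert pairwise_r2(a, b) == 0.0  # only 2 shared samples
        c = np.array([1, 1, 1, 1, 1], dtype=np.int8)
        d = np.array([0, 1, 2, 0, 1], dtype=np.int8)
        assert pairwise_r2(c, d) == 0.0  # zero variance

    def test_post_hoc_no_high_r2_within_window(self, rng):
        m = random_matrix(rng, 30, 50, 0.1, n_chrom=1)
        # plant strong LD: copy some columns with small perturbations
        d = m.dosages.copy()
        for j in range(1, 50, 5):
            d[:, j] = d[:, j - 1]
        m = GenotypeMatrix(m.samples, m.sites, d)
        cfg = FilterConfig(ld_window_sites=10)
        out, _ = ld_prune(m, cfg)
        for a in range(out.n_sites):
            for b in range(max(0, a - cfg.ld_window_sites), a):
                assert (
                    pairwise_r2(out.dosages[:, a], out.dosages[:, b])
                    <= cfg.ld_r2_cutoff
                )

    def test_matches_brute_force_greedy(self, rng):
        m = random_matrix(rng, 100, 200, 0.1)
        cfg = FilterConfig(ld_window_sites=20)
        out, _ = ld_prune(m, cfg)
        kept: list[int] = []
        by_seq: dict[str, list[int]] = {}
        for j, s in enumerate(m.sites):
            prev = by_seq.setdefault(s.seq_id, [])
            if all(
                pairwise_r2(m.dosages[:, j], m.dosages[:, k]) <= cfg.ld_r2_cutoff
                for k in prev[-cfg.ld_window_sites:]
            ):
                kept.append(j)
                prev.append(j)
        assert out.sites == [m.sites[j] for j in kept]


class TestHetRate:
    def test_all_homozygous_zero(self):
        d = np.array([[0, 2], [2, 0]], dtype=np.int8)
        m = GenotypeMatrix(
            ["a", "b"], [SiteKey("chr1", 10, "A", "C"), SiteKey("chr1", 20, "A", "C")], d)
        overall, per = het_rate(m)
        assert overall == 0.0

    def test_single_het_fraction(self, rng):
        m = random_matrix(rng, 25, 8, 0.1)
        d = np.where(m.dosages == 1, 0, m.dosages).astype(np.int8)
        d[0, 0] = 1 if d[0, 0] != MISSING else d[0, 0]
        d[0, 0] = 1
        m = GenotypeMatrix(m.samples, m.sites, d)
        called = int((d != MISSING).sum())
        overall, per = het_rate(m)
        assert overall == pytest.approx(1 / called)

    def test_per_sample_weighted_average_equals_overall(self, rng):
        m = random_matrix(rng, 20, 50, 0.2)
        overall, per = het_rate(m)
        weights = m.called.sum(axis=1)
        assert np.average(per.to_numpy(), weights=weights) == pytest.approx(overall)

    def test_empty_matrix_is_error(self):
        d = np.full((2, 1), MISSING, dtype=np.int8)
        m = GenotypeMatrix(["a", "b"], [SiteKey("chr1", 10, "A", "C")], d)
        with pytest.raises(MatrixError, match="empty"):
            het_rate(m)


class TestCascade:
    def test_accounting_identity_and_composition(self, rng):
        m = random_matrix(rng, 60, 150, 0.15)
        mask = [("chr1", 0, 200), ("chr2", 100, 400)]
        out, acc = apply_filter_cascade(m, FilterConfig(), mask)
        for st in acc.stages:
            assert st["sites_in"] - st["sites_removed"] == st["sites_out"]
        for a, b in zip(acc.stages, acc.stages[1:]):
            assert a["sites_out"] == b["sites_in"]
        assert acc.stages[0]["sites_in"] == m.n_sites
        assert acc.stages[-1]["sites_out"] == out.n_sites

    @pytest.mark.parametrize("stage", ["mask", "missing", "maf", "ld"])
    def test_filters_idempotent(self, rng, stage):
        m = random_matrix(rng, 50, 120, 0.15)
        cfg = FilterConfig()
        mask = [("chr1", 0, 150)]
        fn = {
            "mask": lambda mm: mask_repeats(mm, mask)[0],
            "missing": lambda mm: filter_missing(mm, cfg)[0],
            "maf": lambda mm: filter_maf(mm, cfg)[0],
            "ld": lambda mm: ld_prune(mm, cfg)[0],
        }[stage]
        once = fn(m)
        twice = fn(once)
        assert twice.sites == once.sites
        assert twice.samples == once.samples

    def test_broken_accounting_raises(self):
        acc = FilterAccounting()
        with pytest.raises(AssertionError):
            acc.add("x", 10, 3, 8, 5, 5)
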