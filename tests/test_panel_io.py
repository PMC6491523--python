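"""Panel container, file formats and QC filters."""

import numpy as np
import pandas as pd
import pytest

from pigdiv import (
    MISSING,
    PanelConfig,
    composite_r2,
    filter_markers,
    filter_samples,
    ld_prune,
    read_csv,
    read_hapmap,
    read_vcf,
    simulate_panel,
    write_csv,
    write_hapmap,
)
from pigdiv.panel import GenotypeMatrix


class TestContainer:
    def test_rejects_bad_dosage_and_duplicate_ids(self, gm_factory):
        with pytest.raises(ValueError, match="dosage values"):
            gm_factory([[0, 3]])
        with pytest.raises(ValueError, match="unique"):
            gm_factory([[0, 1], [2, 0]], accession_ids=["a", "a"])

    def test_requires_sorted_marker_map(self, gm_factory):
        gm = gm_factory([[0, 1], [2, 0]])
        shuffled = gm.marker_map.iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            GenotypeMatrix(gm.accession_ids, gm.marker_ids[::-1],
                           gm.dosage[:, ::-1], shuffled)

    def test_subsetting_keeps_alignment(self, gm_factory):
        gm = gm_factory(np.arange(12).reshape(4, 3) % 3)
        sub = gm.take_markers(["m000", "m002"]).take_accessions(["acc001", "acc003"])
        assert sub.marker_ids == ["m000", "m002"]
        np.testing.assert_array_equal(sub.dosage, gm.dosage[np.ix_([1, 3], [0, 2])])


class TestHapMap:
    def test_dosage_coding_and_missing(self, tmp_path):
        text = "\t".join(
            ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
             "protLSID", "assayLSID", "panelLSID", "QCcode", "s1", "s2"]) + "\n"
        text += "\t".join(["m1", "A/G", "chr01", "100", "+", *["NA"] * 6, "AA", "AG"]) + "\n"
        text += "\t".join(["m2", "C/T", "chr01", "200", "+", *["NA"] * 6, "TT", "NN"]) + "\n"
        p = tmp_path / "x.hmp.txt"
        p.write_text(text)
        gm = read_hapmap(p)
        assert gm.accession_ids == ["s1", "s2"]
        np.testing.assert_array_equal(gm.dosage, [[0, 2], [1, MISSING]])

    def test_round_trip_identity(self, tmp_path, two_group_panel):
        gm, _ = two_group_panel
        write_hapmap(gm, tmp_path / "rt.hmp.txt")
        assert read_hapmap(tmp_path / "rt.hmp.txt") == gm

    def test_triallelic_dropped_with_warning(self, tmp_path):
        head = "\t".join(
            ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
             "protLSID", "assayLSID", "panelLSID", "QCcode", "s1", "s2", "s3"])
        row = "\t".join(["m1", "A/G", "chr01", "100", "+", *["NA"] * 6, "AA", "GG", "CC"])
        row2 = "\t".join(["m2", "A/G", "chr01", "200", "+", *["NA"] * 6, "AA", "AG", "GG"])
        p = tmp_path / "tri.hmp.txt"
        p.write_text(head + "\n" + row + "\n" + row2 + "\n")
        with pytest.warns(UserWarning, match="m1"):
            gm = read_hapmap(p)
        assert gm.marker_ids == ["m2"]

    def test_malformed_row_names_line(self, tmp_path):
        head = "\t".join(
            ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
             "protLSID", "assayLSID", "panelLSID", "QCcode", "s1"])
        p = tmp_path / "bad.hmp.txt"
        p.write_text(head + "\nm1\tA/G\tchr01\t100\n")
        with pytest.raises(ValueError, match="line 2"):
            read_hapmap(p)


class TestCsvAndVcf:
    def test_csv_round_trip(self, tmp_path, two_group_panel):
        gm, _ = two_group_panel
        write_csv(gm, tmp_path / "panel")
        assert read_csv(tmp_path / "panel") == gm

    def test_vcf_gt_parsing(self, tmp_path):
        vcf = (
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr01>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chr01\t100\tm1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "chr01\t200\tm2\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.\n"
        )
        p = tmp_path / "x.vcf"
        p.write_text(vcf)
        gm = read_vcf(p)
        np.testing.assert_array_equal(gm.dosage, [[0, 2], [1, MISSING]])


class TestFilters:
    def test_marker_callrate_and_maf_boundaries(self, gm_factory):
        # marker 0: 6/100 missing (call rate 0.94 < 0.95)  -> removed
        # marker 1: alt count 9 of 200 copies (MAF 0.045)   -> removed
        # marker 2: clean
        d = np.zeros((100, 3), dtype=int)
        d[:6, 0] = MISSING
        d[:9, 1] = 1
        d[:50, 2] = 2
        gm = gm_factory(d)
        out, rep = filter_markers(gm)
        assert rep.markers_removed_by_callrate == ["m000"]
        assert rep.markers_removed_by_maf == ["m001"]
        assert out.marker_ids == ["m002"]

    def test_sample_callrate_boundary(self, gm_factory):
        d = np.zeros((3, 1000), dtype=int)
        d[:, ::2] = 2  # keep polymorphic
        d[0, :51] = MISSING  # 5.1% missing -> removed
        gm = gm_factory(d)
        out, rep = filter_samples(gm)
        assert rep.samples_removed == ["acc000"]
        assert out.n_accessions == 2

    def test_complete_panel_is_identity(self, gm_factory):
        gm = gm_factory([[0, 2], [2, 0], [1, 1]])
        out, rep = filter_samples(gm)
        assert out == gm and rep.samples_removed == []

    def test_all_removed_is_error_not_empty_success(self, gm_factory):
        d = np.full((4, 2), MISSING, dtype=int)
        d[0] = 0
        with pytest.raises(ValueError, match="all markers removed"):
            filter_markers(gm_factory(d))

    def test_filters_idempotent_and_bookkeeping(self):
        cfg = PanelConfig(n_markers=300, n_chromosomes=3,
                          group_spec=(("g", 60, 0.0),), selfing_generations=2,
                          missing_rate=0.04, rng_seed=3)
        gm, _ = simulate_panel(cfg)
        out1, rep1 = filter_markers(gm)
        removed = len(rep1.markers_removed_by_callrate) + len(rep1.markers_removed_by_maf)
        assert gm.n_markers == out1.n_markers + removed
        out2, rep2 = filter_markers(out1)
        assert out2 == out1
        assert not rep2.markers_removed_by_callrate and not rep2.markers_removed_by_maf

    def test_planted_low_call_samples_removed_exactly(self):
        bad = {"g_0003": 8.0, "g_0007": 8.0}  # 40% missing vs 5% baseline
        cfg = PanelConfig(n_markers=400, n_chromosomes=4,
                          group_spec=(("g", 30, 0.0),), missing_rate=0.05,
                          sample_missing_multiplier=bad, rng_seed=9)
        gm, _ = simulate_panel(cfg)
        _, rep = filter_samples(gm, min_call_rate=0.9)
        assert sorted(rep.samples_removed) == sorted(bad)


class TestLdPrune:
    def test_duplicated_column_removes_downstream(self, gm_factory):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 40)
        d = np.column_stack([col, rng.integers(0, 3, 40), col])
        out, rep = ld_prune(gm_factory(d), window=10, increment=1)
        assert rep.markers_removed_by_ld == ["m002"]  # downstream copy goes

    def test_independent_markers_untouched(self, panmictic_panel):
        gm, _ = panmictic_panel
        sub = gm.take_markers(gm.marker_ids[:60])
        out, rep = ld_prune(sub, window=100, increment=1)
        assert rep.markers_removed_by_ld == []

    def test_matches_all_pairs_oracle_and_postcondition(self, gm_factory):
        # brute-force oracle: scan markers in order, keep unless r2 with any
        # previously kept marker exceeds the threshold (no windowing)
        rng = np.random.default_rng(42)
        base = rng.integers(0, 3, (30, 4))
        d = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 2],
                             base[:, 2], base[:, 2], base[:, 3],
                             rng.integers(0, 3, 30), base[:, 1], base[:, 3]])
        gm = gm_factory(d)
        r2 = composite_r2(gm)
        kept_oracle = []
        for j in range(gm.n_markers):
            if all(r2[j, i] <= 0.8 for i in kept_oracle):
                kept_oracle.append(j)
        out, _ = ld_prune(gm, window=gm.n_markers, increment=1)
        assert out.marker_ids == [gm.marker_ids[j] for j in kept_oracle]
        surviving = composite_r2(out)
        iu = np.triu_indices(out.n_markers, 1)
        assert (surviving[iu] <= 0.8).all()

    def test_window_too_small_rejected(self, gm_factory):
        with pytest.raises(ValueError, match="window"):
            ld_prune(gm_factory([[0, 1], [2, 0]]), window=1)
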