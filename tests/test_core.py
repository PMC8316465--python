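import numpy as np
import pytest

from epilink.core import (
    BedParseError,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    SignalTrack,
    merge_intervals,
    read_bed,
    read_bedgraph,
    read_gene_annotation,
    window_sum,
    write_bed,
    write_bedgraph,
)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", 200, 100), ("chr1", 100, 100), ("chr1", -5, 10), ("", 0, 10)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 201)
        assert iv.length == 101
        assert iv.midpoint == 150


class TestBed:
    def test_bed3_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (peak,) = read_bed(p)
        assert (peak.interval.chrom, peak.interval.start, peak.interval.end) == ("chr1", 100, 200)

    def test_narrowpeak_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text(
            "chr1\t100\t200\tpk\t60\t+\t5.0\t4.0\t3.0\t50\n"
            "chr1\t300\t400\tpk2\t60\t-\t5.0\t4.0\t3.0\t-1\n"
        )
        peaks = read_bed(p)
        assert peaks[0].summit_offset == 50
        assert peaks[0].anchor == 150
        assert peaks[1].summit_offset is None

    @pytest.mark.parametrize(
        "line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t100"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_bed6_roundtrip_byte_identical(self, tmp_path):
        src = tmp_path / "src.bed"
        src.write_text(
            "chr1\t0\t50\tpeak_a\t3.5\t+\nchr2\t100\t900\tpeak_b\t0\t-\n"
        )
        out = tmp_path / "out.bed"
        write_bed(read_bed(src), out)
        assert out.read_text() == src.read_text()


class TestGeneAnnotation:
    GTF = (
        'chrT\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "gA"; gene_name "A";\n'
        'chrT\tsrc\tgene\t301\t400\t.\t-\t.\tgene_id "gB"; gene_name "B";\n'
    )

    def test_gtf_coordinate_conversion(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(self.GTF)
        genes = read_gene_annotation(p, dialect="gtf")
        ga, gb = genes
        assert (ga.interval.start, ga.interval.end, ga.tss) == (100, 200, 100)
        assert gb.tss == 399  # minus strand: last covered base

    def test_multi_transcript_first_tss_wins(self, tmp_path, caplog):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chrT\ts\ttranscript\t101\t200\t.\t+\t.\tgene_id "g"; \n'
            'chrT\ts\ttranscript\t151\t260\t.\t+\t.\tgene_id "g"; \n'
        )
        (gene,) = read_gene_annotation(p, dialect="gtf")
        assert gene.tss == 100

    def test_conflicting_strand_is_error(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chrT\ts\ttranscript\t101\t200\t.\t+\t.\tgene_id "g"; \n'
            'chrT\ts\ttranscript\t151\t260\t.\t-\t.\tgene_id "g"; \n'
        )
        with pytest.raises(ValueError, match="strand"):
            read_gene_annotation(p, dialect="gtf")

    def test_tsv_dialect_and_unknown_dialect(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("gene_id\tgene_name\tchrom\tstart\tend\tstrand\ng\tG\tchrT\t10\t20\t-\n")
        (gene,) = read_gene_annotation(p, dialect="tsv")
        assert gene.tss == 19
        with pytest.raises(ValueError, match="dialect"):
            read_gene_annotation(p, dialect="bed")


def brute_force_merge(intervals, max_gap):
    """O(n^2) pairwise merging until fixpoint — the independent oracle."""
    items = [[iv.start, iv.end] for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                gap = max(a[0], b[0]) - min(a[1], b[1])
                if gap <= max_gap:
                    items[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e) for s, e in items)


class TestMergeIntervals:
    def test_gap_within_stitch_distance_merges(self):
        ivs = [GenomicInterval("c", 0, 1000), GenomicInterval("c", 5000, 6000)]
        assert merge_intervals(ivs, 12500) == [GenomicInterval("c", 0, 6000)]

    def test_gap_beyond_stitch_distance_stays_split(self):
        ivs = [GenomicInterval("c", 0, 1000), GenomicInterval("c", 30000, 31000)]
        assert len(merge_intervals(ivs, 12500)) == 2

    def test_single_interval_identity(self):
        ivs = [GenomicInterval("c", 5, 10)]
        assert merge_intervals(ivs, 999) == ivs

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_intervals([], -1)

    def test_matches_brute_force_and_idempotent(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(1, 15)
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                ivs.append(GenomicInterval("c", s, s + int(rng.integers(1, 800))))
            gap = int(rng.integers(0, 600))
            merged = merge_intervals(ivs, gap)
            assert [(m.start, m.end) for m in merged] == brute_force_merge(ivs, gap)
            assert merge_intervals(merged, gap) == merged

    def test_zero_gap_equals_boolean_mask_union(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ivs = []
            for _ in range(rng.integers(1, 12)):
                s = int(rng.integers(0, 2000))
                ivs.append(GenomicInterval("c", s, s + int(rng.integers(1, 300))))
            mask = np.zeros(3000, dtype=bool)
            for iv in ivs:
                mask[iv.start : iv.end] = True
            merged = merge_intervals(ivs, 0)
            covered = np.zeros(3000, dtype=bool)
            for m in merged:
                covered[m.start : m.end] = True
            assert np.array_equal(mask, covered)
            # gap 0 also merges abutting intervals, which the mask cannot
            # distinguish from overlap: check region count from mask runs
            runs = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
            assert len(merged) == int((runs == 1).sum())


class TestWindowSum:
    def track(self, values, bin_size=10):
        return SignalTrack({"c": np.asarray(values, dtype=float)}, bin_size, 1e6)

    def test_uniform_track(self):
        tr = self.track([1.0] * 20)
        assert window_sum(tr, GenomicInterval("c", 0, 100)) == pytest.approx(10.0)

    def test_zero_track(self):
        tr = self.track([0.0] * 20)
        assert window_sum(tr, GenomicInterval("c", 3, 170)) == 0.0

    def test_half_bin_prorated(self):
        tr = self.track([4.0])
        assert window_sum(tr, GenomicInterval("c", 5, 10)) == pytest.approx(2.0)

    def test_unknown_chromosome_raises(self):
        tr = self.track([1.0])
        with pytest.raises(KeyError):
            window_sum(tr, GenomicInterval("chrX", 0, 5))

    def test_rpm_scaling(self):
        tr = SignalTrack({"c": np.array([10.0])}, 10, 2e6)
        assert window_sum(tr, GenomicInterval("c", 0, 10), as_rpm=True) == pytest.approx(5.0)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(3)
        tr = self.track(rng.random(50) * 7, bin_size=7)
        total = window_sum(tr, GenomicInterval("c", 13, 329))
        cuts = sorted(set([13, 329] + list(rng.integers(14, 329, size=5))))
        parts = sum(
            window_sum(tr, GenomicInterval("c", a, b)) for a, b in zip(cuts, cuts[1:])
        )
        assert parts == pytest.approx(total, rel=1e-9)


class TestBedgraph:
    def test_roundtrip_bin_aligned(self, tmp_path):
        rng = np.random.default_rng(0)
        vec = np.round(rng.random(30) * 9)
        tr = SignalTrack({"c": vec}, 25, 12345.0)
        p = tmp_path / "t.bedgraph"
        write_bedgraph(tr, p)
        back = read_bedgraph(p, 25, 12345.0, chrom_sizes={"c": 30 * 25})
        assert np.allclose(back.data["c"], vec)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            SignalTrack({"c": np.array([-1.0])}, 10, 1e6)
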