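"""Interval arithmetic, BED/chain I/O and lift-over against brute-force oracles."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hidden_enhancers.intervals import (
    BedParseError,
    ChainAlignment,
    ChainParseError,
    GenomicInterval,
    PeakCollection,
    PeakMeta,
    intersect_elements,
    map_interval,
    overlap_length,
    read_bed,
    read_chain,
    write_bed,
    write_chain,
)
from hidden_enhancers.synthetic import identity_chain_with_gaps

from _oracles import chain_base_map, count_overlapping_pairs, liftover_span, overlap_bases


def gi(chrom, start, end, asm="mm10"):
    return GenomicInterval(chrom, start, end, asm)


class TestGenomicInterval:
    def test_rejects_empty_and_inverted_spans(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)

    def test_length_is_end_minus_start(self):
        assert gi("chr1", 100, 250).length == 150


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (gi("chr1", 100, 200), gi("chr1", 100, 200), 100),  # identity
            (gi("chr1", 100, 200), gi("chr1", 200, 300), 0),  # half-open adjacency
            (gi("chr1", 100, 200), gi("chr1", 199, 300), 1),  # single shared base
            (gi("chr1", 100, 200), gi("chr2", 100, 200), 0),  # different chromosome
            (gi("chr1", 100, 200), gi("chr1", 100, 200, "hg38"), 0),  # different assembly
        ],
    )
    def test_known_cases(self, a, b, expected):
        assert overlap_length(a, b) == expected

    def test_agrees_with_per_base_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            a0 = int(rng.integers(0, 500))
            b0 = int(rng.integers(0, 500))
            a = gi("chr1", a0, a0 + int(rng.integers(1, 120)))
            b = gi("chr1", b0, b0 + int(rng.integers(1, 120)))
            assert overlap_length(a, b) == overlap_bases(a.start, a.end, b.start, b.end)
            assert overlap_length(a, b) == overlap_length(b, a)  # symmetry
            assert overlap_length(a, b) <= min(a.length, b.length)


class TestIntersectElements:
    def _peaks(self, intervals):
        return PeakCollection(PeakMeta(assembly="mm10"), intervals)

    def test_empty_collection_gives_zero(self):
        counts = intersect_elements([gi("chr1", 0, 100)], self._peaks([]))
        assert counts.tolist() == [0]

    def test_single_base_overlap_qualifies(self):
        peaks = self._peaks([gi("chr1", 199, 300), gi("chr1", 400, 500)])
        assert intersect_elements([gi("chr1", 100, 200)], peaks).tolist() == [1]

    def test_min_overlap_floor_is_respected(self):
        peaks = self._peaks([gi("chr1", 150, 300)])
        el = [gi("chr1", 100, 200)]  # 50 bp shared
        assert intersect_elements(el, peaks, min_overlap=50).tolist() == [1]
        assert intersect_elements(el, peaks, min_overlap=51).tolist() == [0]

    def test_assembly_mismatch_instructs_liftover(self):
        peaks = self._peaks([gi("chr1", 0, 10)])
        with pytest.raises(ValueError, match="lift"):
            intersect_elements([gi("chr1", 0, 10, "hg38")], peaks)

    def test_matches_quadratic_oracle_on_random_sets(self, rng):
        chroms = ["chr1", "chr2"]
        elements = []
        peaks = []
        for _ in range(100):
            s = int(rng.integers(0, 20_000))
            elements.append(gi(chroms[int(rng.integers(0, 2))], s, s + int(rng.integers(50, 2_000))))
        for _ in range(500):
            s = int(rng.integers(0, 20_000))
            peaks.append(gi(chroms[int(rng.integers(0, 2))], s, s + int(rng.integers(50, 1_500))))
        for min_ov in (1, 25, 400):
            got = intersect_elements(elements, self._peaks(peaks), min_overlap=min_ov)
            want = count_overlapping_pairs(
                [(e.chrom, e.start, e.end) for e in elements],
                [(p.chrom, p.start, p.end) for p in peaks],
                min_overlap=min_ov,
            )
            assert got.tolist() == want

    def test_invariant_under_permutation(self, rng):
        elements = [gi("chr1", int(s), int(s) + 100) for s in rng.integers(0, 5_000, size=30)]
        peaks = [gi("chr1", int(s), int(s) + 80) for s in rng.integers(0, 5_000, size=60)]
        base = intersect_elements(elements, self._peaks(peaks))
        perm = rng.permutation(60)
        shuffled = self._peaks([peaks[i] for i in perm])
        assert intersect_elements(elements, shuffled).tolist() == base.tolist()

    def test_agrees_with_bedtools(self, rng, tmp_path):
        # bedtools intersect -c is the field-standard engine the semantics mirror
        if shutil.which("bedtools") is None:
            pytest.fail("bedtools expected on PATH in this environment")
        elements = sorted(
            (gi("chr1", int(s), int(s) + int(rng.integers(100, 900))) for s in rng.integers(0, 50_000, size=40)),
            key=lambda x: x.start,
        )
        peaks = [gi("chr1", int(s), int(s) + int(rng.integers(50, 700))) for s in rng.integers(0, 50_000, size=120)]
        a, b = tmp_path / "a.bed", tmp_path / "b.bed"
        a.write_text("".join(f"{e.chrom}\t{e.start}\t{e.end}\n" for e in elements))
        b.write_text("".join(f"{p.chrom}\t{p.start}\t{p.end}\n" for p in sorted(peaks, key=lambda x: x.start)))
        out = subprocess.run(
            ["bedtools", "intersect", "-c", "-a", str(a), "-b", str(b)],
            capture_output=True, text=True, check=True,
        )
        bedtools_counts = [int(line.split("\t")[3]) for line in out.stdout.strip().split("\n")]
        ours = intersect_elements(elements, self._peaks(peaks))
        assert ours.tolist() == bedtools_counts


class TestBedIO:
    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(p, "bed3", PeakMeta(assembly="mm10"))) == 0

    def test_bed3_line_parses_half_open(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr1\t100\t200\n")
        pc = read_bed(p, "bed3", PeakMeta(assembly="mm10"))
        assert pc.peaks == [gi("chr1", 100, 200)]
        assert pc.peaks[0].length == 100

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("track name=x\n# hello\nbrowser position chr1\nchr1\t5\t10\n")
        assert len(read_bed(p, "bed3", PeakMeta())) == 1

    @pytest.mark.parametrize(
        "content, match",
        [
            ("chr1\t100\n", "columns"),
            ("chr1\tx\t200\n", "integer"),
            ("chr1\t200\t100\n", "invalid interval"),
            ("chr1\t100\t100\n", "invalid interval"),
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, content, match):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + content)
        with pytest.raises(BedParseError, match=match) as err:
            read_bed(p, "bed3", PeakMeta())
        assert ":2:" in str(err.value)

    def test_narrowpeak_roundtrip_50_random_lines(self, rng, tmp_path):
        meta = PeakMeta(assembly="mm10", tissue="limb", mark="H3K27ac", stage="E11.5")
        starts = rng.integers(0, 1_000_000, size=50)
        peaks = [gi("chr%d" % (1 + i % 3), int(s), int(s) + int(rng.integers(100, 2_000))) for i, s in enumerate(starts)]
        signal = rng.gamma(2.0, 5.0, size=50)
        pc = PeakCollection(meta, peaks, signal)
        path = tmp_path / "x.narrowPeak"
        write_bed(pc, path, "narrowPeak")
        back = read_bed(path, "narrowPeak", meta)
        assert back == pc

    def test_bedgraph_returns_interval_value_pairs(self, tmp_path):
        p = tmp_path / "x.bedGraph"
        p.write_text("chr1\t0\t100\t0.25\nchr1\t100\t300\t0.5\n")
        pairs = read_bed(p, "bedgraph", PeakMeta(assembly="mm10"))
        assert [(iv.start, iv.end, v) for iv, v in pairs] == [(0, 100, 0.25), (100, 300, 0.5)]


def identity_chain(chrom="chr1", size=10_000, src="mm10", tgt="hg38", offset=0):
    return identity_chain_with_gaps(chrom, size, [], offset=offset, source_assembly=src, target_assembly=tgt)


class TestChains:
    def test_chain_roundtrip(self, tmp_path):
        chains = [
            identity_chain(),
            ChainAlignment(
                score=90,
                source_chrom="chr2", source_size=5_000, source_start=100, source_end=1_100,
                target_chrom="chr7", target_size=9_000, target_strand="-",
                target_start=200, target_end=1_250,
                blocks=((400, 100, 150), (500, 0, 0)),
                source_assembly="mm10", target_assembly="hg38",
            ),
        ]
        path = tmp_path / "x.chain"
        write_chain(chains, path)
        back = read_chain(path, "mm10", "hg38")
        assert back == chains

    def test_inconsistent_block_extents_rejected(self):
        with pytest.raises(ChainParseError, match="extents"):
            ChainAlignment(
                score=1, source_chrom="chr1", source_size=1_000, source_start=0, source_end=500,
                target_chrom="chr1", target_size=1_000, target_strand="+", target_start=0, target_end=500,
                blocks=((100, 0, 0),),
            )


class TestMapInterval:
    def test_identity_chain_is_identity(self):
        ch = identity_chain()
        q = gi("chr1", 100, 200)
        assert map_interval(q, [ch]) == gi("chr1", 100, 200, "hg38")

    def test_query_inside_gap_is_unmapped(self):
        ch = identity_chain_with_gaps("chr1", 10_000, [(2_000, 4_000)], source_assembly="mm10", target_assembly="hg38")
        assert map_interval(gi("chr1", 2_500, 3_000), [ch]) is None

    def test_min_match_threshold(self):
        # chain covers only [0, 40) of a 1000 bp query -> fraction 0.04 < 0.1
        ch = identity_chain_with_gaps("chr1", 10_000, [(40, 9_000)], source_assembly="mm10", target_assembly="hg38")
        assert map_interval(gi("chr1", 0, 1_000), [ch]) is None
        # covering [0, 150) -> fraction 0.15 passes and spans the mapped bases
        ch2 = identity_chain_with_gaps("chr1", 10_000, [(150, 9_000)], source_assembly="mm10", target_assembly="hg38")
        assert map_interval(gi("chr1", 0, 1_000), [ch2]) == gi("chr1", 0, 150, "hg38")

    def test_reverse_strand_coordinates_flip(self):
        ch = ChainAlignment(
            score=100, source_chrom="chr1", source_size=1_000, source_start=100, source_end=400,
            target_chrom="chr9", target_size=2_000, target_strand="-", target_start=500, target_end=800,
            blocks=((300, 0, 0),), source_assembly="mm10", target_assembly="hg38",
        )
        got = map_interval(gi("chr1", 150, 250), [ch])
        base_map = chain_base_map(ch.blocks, ch.source_start, ch.target_start)
        want = liftover_span(base_map, 150, 250, 0.1, "-", ch.target_size)
        assert (got.start, got.end) == want
        assert got.chrom == "chr9"

    def test_best_chain_by_covered_bases_wins(self):
        small = identity_chain_with_gaps("chr1", 10_000, [(120, 9_000)], offset=0, source_assembly="mm10", target_assembly="hg38")
        big = identity_chain(offset=5_000)
        got = map_interval(gi("chr1", 0, 1_000), [small, big])
        assert got == gi("chr1", 5_000, 6_000, "hg38")

    def test_matches_per_base_block_walk_oracle(self, rng):
        for trial in range(100):
            # random chain over a 3 kb source span
            blocks = []
            n_blocks = int(rng.integers(1, 6))
            for b in range(n_blocks):
                size = int(rng.integers(10, 400))
                ds = int(rng.integers(0, 200)) if b < n_blocks - 1 else 0
                dt = int(rng.integers(0, 200)) if b < n_blocks - 1 else 0
                blocks.append((size, ds, dt))
            src_len = sum(s + ds for s, ds, _ in blocks[:-1]) + blocks[-1][0]
            tgt_len = sum(s + dt for s, _, dt in blocks[:-1]) + blocks[-1][0]
            s0 = int(rng.integers(0, 500))
            t0 = int(rng.integers(0, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            tgt_size = t0 + tgt_len + int(rng.integers(0, 500))
            ch = ChainAlignment(
                score=1, source_chrom="chr1", source_size=s0 + src_len + 100,
                source_start=s0, source_end=s0 + src_len,
                target_chrom="chrT", target_size=tgt_size, target_strand=strand,
                target_start=t0, target_end=t0 + tgt_len,
                blocks=tuple(blocks), source_assembly="mm10", target_assembly="hg38",
            )
            q0 = int(rng.integers(0, s0 + src_len))
            q = gi("chr1", q0, q0 + int(rng.integers(1, 800)))
            got = map_interval(q, [ch], min_match=0.1)
            base_map = chain_base_map(ch.blocks, s0, t0)
            want = liftover_span(base_map, q.start, q.end, 0.1, strand, tgt_size)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.start, got.end) == want
                # mapped span cannot exceed the chain's target span
                assert got.length <= tgt_len


@given(
    start=st.integers(min_value=0, max_value=1_000),
    length_a=st.integers(min_value=1, max_value=500),
    shift=st.integers(min_value=-600, max_value=600),
    length_b=st.integers(min_value=1, max_value=500),
)
def test_overlap_symmetric_and_bounded_property(start, length_a, shift, length_b):
    a = GenomicInterval("chr1", start, start + length_a)
    b_start = max(0, start + shift)
    b = GenomicInterval("chr1", b_start, b_start + length_b)
    ov = overlap_length(a, b)
    assert ov == overlap_length(b, a)
    assert 0 <= ov <= min(a.length, b.length)


@given(data=st.data())
def test_identity_chain_maps_any_inner_query_to_itself(data):
    size = data.draw(st.integers(min_value=1_000, max_value=50_000))
    ch = identity_chain(size=size)
    q0 = data.draw(st.integers(min_value=0, max_value=size - 2))
    q1 = data.draw(st.integers(min_value=q0 + 1, max_value=size))
    q = GenomicInterval("chr1", q0, q1, "mm10")
    got = map_interval(q, [ch])
    assert got is not None and (got.start, got.end) == (q0, q1)
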