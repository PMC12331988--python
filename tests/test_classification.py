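"""Mark matrices, category calls, sequential filtering and validation rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hidden_enhancers.classification import (
    CANONICAL_MARKS,
    TISSUES,
    MarkDataError,
    MarkMatrix,
    TestedElement,
    build_mark_matrix,
    category_proportions,
    classify,
    read_elements_tsv,
    round_half_away,
    sequential_mark_filter,
    validation_rate_by_rank,
    write_elements_tsv,
)
from hidden_enhancers.intervals import GenomicInterval, PeakCollection, PeakMeta
from hidden_enhancers.synthetic import GeneratorConfig, generate


def element(eid, start, tissues_positive, chrom="chr1", asm="mm10", length=1000):
    activity = {t: ("positive" if t in tissues_positive else "negative") for t in TISSUES}
    return TestedElement(eid, GenomicInterval(chrom, start, start + length, asm), "mouse", activity)


def collection(tissue, mark, intervals, stage="E11.5", asm="mm10"):
    return PeakCollection(
        PeakMeta(assembly=asm, tissue=tissue, mark=mark, stage=stage, dataset_id=f"{tissue}-{mark}"),
        intervals,
    )


def full_peaksets(overrides=None, asm="mm10"):
    """One (possibly empty) collection per (tissue, canonical mark)."""
    overrides = overrides or {}
    return [
        collection(t, m, overrides.get((t, m), []), asm=asm)
        for t in TISSUES
        for m in CANONICAL_MARKS
    ]


def matrix_from_counts(rows):
    """rows: (element_id, tissue, k27, k4, atac)."""
    return MarkMatrix(
        pd.DataFrame(
            [
                {"element_id": e, "tissue": t, "H3K27ac": a, "H3K4me1": b, "ATAC": c}
                for e, t, a, b, c in rows
            ]
        )
    )


class TestBuildMarkMatrix:
    def test_single_overlap_single_row(self):
        el = element("e1", 5_000, ["limb"])
        peaks = full_peaksets({("limb", "H3K27ac"): [GenomicInterval("chr1", 5_200, 5_700, "mm10")]})
        mm = build_mark_matrix([el], peaks)
        assert len(mm.table) == 1
        row = mm.table.iloc[0]
        assert (row["H3K27ac"], row["H3K4me1"], row["ATAC"]) == (1, 0, 0)
        assert (row["element_id"], row["tissue"]) == ("e1", "limb")

    def test_element_positive_in_two_tissues_gives_two_rows(self):
        el = element("e1", 5_000, ["limb", "heart"])
        mm = build_mark_matrix([el], full_peaksets())
        assert sorted(mm.table["tissue"]) == ["heart", "limb"]

    def test_missing_tissue_mark_requires_declaration(self):
        el = element("e1", 5_000, ["limb"])
        peaks = [collection("limb", "H3K27ac", [])]  # H3K4me1 and ATAC absent
        with pytest.raises(MarkDataError, match="H3K4me1|ATAC"):
            build_mark_matrix([el], peaks)
        mm = build_mark_matrix(
            [el], peaks, unavailable={("limb", "H3K4me1"), ("limb", "ATAC")}
        )
        assert len(mm.table) == 1

    def test_union_of_datasets_sums_counts(self):
        el = element("e1", 5_000, ["limb"])
        hit = [GenomicInterval("chr1", 5_100, 5_400, "mm10")]
        peaks = full_peaksets({("limb", "ATAC"): hit}) + [collection("limb", "ATAC", hit)]
        mm = build_mark_matrix([el], peaks)
        assert mm.table.iloc[0]["ATAC"] == 2

    def test_matches_generator_ground_truth(self):
        bundle = generate(GeneratorConfig(seed=7, n_elements=150, include_conservation=False,
                                          include_repeats=False, include_ccre=False))
        mm = build_mark_matrix(bundle.elements, bundle.peaksets)
        truth = bundle.ground_truth
        merged = mm.table.merge(truth, on=["element_id", "tissue"], validate="one_to_one")
        assert len(merged) == len(truth)
        for mark in CANONICAL_MARKS:
            # planted peaks only; background stays clear of elements by construction
            assert (merged[mark] == merged[f"n_{mark}"]).all()


class TestClassify:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((2, 1, 1), "THREE_MARKS"),
            ((1, 1, 0), "TWO_MARKS"),
            ((1, 0, 0), "ONE_MARK"),
            ((0, 3, 0), "ONE_MARK"),
            ((0, 0, 0), "HIDDEN"),
        ],
    )
    def test_category_by_present_mark_count(self, counts, expected):
        mm = matrix_from_counts([("e", "limb", *counts)])
        assert classify(mm)["category"].iloc[0] == expected

    def test_extended_marks_do_not_change_categories(self):
        table = pd.DataFrame(
            [{"element_id": "e", "tissue": "limb", "H3K27ac": 0, "H3K4me1": 0, "ATAC": 0, "H3K4me3": 5}]
        )
        mm = MarkMatrix(table, extended=("H3K4me3",))
        assert classify(mm)["category"].iloc[0] == "HIDDEN"

    def test_categories_partition_rows(self, rng):
        rows = [
            ("e%d" % i, TISSUES[int(rng.integers(0, 6))], *rng.integers(0, 3, size=3))
            for i in range(300)
        ]
        rec = classify(matrix_from_counts(rows))
        props = category_proportions(rec)
        assert props["count"].sum() == 300
        per_tissue = category_proportions(rec, by="tissue")
        assert per_tissue.groupby("tissue")["count"].sum().sum() == 300


class TestCategoryProportions:
    def test_all_hidden_degenerate_input(self):
        rec = classify(matrix_from_counts([("e%d" % i, "limb", 0, 0, 0) for i in range(5)]))
        props = category_proportions(rec).set_index("category")
        assert props.loc["HIDDEN", "percent"] == 100
        assert props.loc["THREE_MARKS", "percent"] == 0

    def test_percent_sum_near_100_on_random_inputs(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 200))
            rows = [("e%d" % i, "heart", *rng.integers(0, 2, size=3)) for i in range(n)]
            props = category_proportions(classify(matrix_from_counts(rows)))
            assert abs(props["percent"].sum() - 100) <= 2  # integer rounding slack
            assert np.isclose(props["fraction"].sum(), 1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            category_proportions(pd.DataFrame(columns=["category", "tissue"]))

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(13.5) == 14
        assert round_half_away(12.4) == 12
        assert round_half_away(-2.5) == -3


class TestSequentialMarkFilter:
    def test_waterfall_monotone_and_ends_at_hidden(self, rng):
        rows = [("e%d" % i, "limb", *rng.integers(0, 2, size=3)) for i in range(200)]
        rec = classify(matrix_from_counts(rows))
        hidden = int((rec["category"] == "HIDDEN").sum())
        for order in (
            ("H3K27ac", "H3K4me1", "ATAC"),
            ("ATAC", "H3K27ac", "H3K4me1"),
            ("H3K4me1", "ATAC", "H3K27ac"),
        ):
            wf = sequential_mark_filter(rec, "limb", order)
            assert all(a >= b for a, b in zip(wf, wf[1:]))
            assert wf[-1] == hidden  # set algebra: lacking all three == hidden

    def test_agrees_with_direct_set_oracle(self, rng):
        rows = [("e%d" % i, "heart", *rng.integers(0, 2, size=3)) for i in range(100)]
        rec = classify(matrix_from_counts(rows))
        wf = sequential_mark_filter(rec, "heart", CANONICAL_MARKS)
        lack1 = rec[~rec["has_H3K27ac"]]
        lack2 = lack1[~lack1["has_H3K4me1"]]
        lack3 = lack2[~lack2["has_ATAC"]]
        assert wf == [len(lack1), len(lack2), len(lack3)]

    def test_unknown_tissue_is_an_error(self):
        rec = classify(matrix_from_counts([("e", "limb", 1, 1, 1)]))
        with pytest.raises(ValueError, match="unknown tissue"):
            sequential_mark_filter(rec, "gonad")


class TestValidationRateByRank:
    def _setup(self, signals, validated_flags):
        """One peak per element; peak i validated iff validated_flags[i]."""
        peaks, elements = [], []
        for i, (sig, ok) in enumerate(zip(signals, validated_flags)):
            start = 10_000 * (i + 1)
            peaks.append(GenomicInterval("chr1", start, start + 500, "mm10"))
            elements.append(element(f"e{i}", start + 100, ["limb"] if ok else []))
        # elements with no positive tissue become all-negative tested elements
        for el in elements:
            if not el.positive_tissues:
                el.activity = {t: "negative" for t in TISSUES}
        pc = PeakCollection(PeakMeta(assembly="mm10", tissue="limb", mark="H3K27ac", stage="E11.5"),
                            peaks, signals)
        return pc, elements

    def test_all_validated_gives_rate_one_everywhere(self):
        pc, els = self._setup([5.0, 4.0, 3.0, 2.0], [True] * 4)
        out = validation_rate_by_rank(pc, els, "limb", n_bins=2)
        assert out["bin_rates"].tolist() == [1.0, 1.0]
        assert out["overall_rate"] == 1.0

    def test_planted_ordering_splits_cleanly(self):
        # validated peaks planted with the highest signals -> (1.0, 0.0) in 2 bins
        signals = [9.0, 8.0, 7.0, 6.0, 4.0, 3.0, 2.0, 1.0]
        flags = [True] * 4 + [False] * 4
        pc, els = self._setup(signals, flags)
        out = validation_rate_by_rank(pc, els, "limb", n_bins=2)
        assert out["bin_rates"].tolist() == [1.0, 0.0]
        assert out["overall_rate"] == 0.5

    def test_overall_rate_matches_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            signals = rng.gamma(2.0, 3.0, size=n).tolist()
            flags = (rng.random(n) < 0.4).tolist()
            pc, els = self._setup(signals, flags)
            out = validation_rate_by_rank(pc, els, "limb", n_bins=3)
            assert out["overall_rate"] == pytest.approx(sum(flags) / n)
            assert out["n_tested_peaks"] == n

    def test_no_tested_overlap_is_an_error(self):
        pc = PeakCollection(PeakMeta(assembly="mm10"), [GenomicInterval("chr1", 0, 100, "mm10")], [1.0])
        els = [element("e", 5_000, ["limb"])]
        with pytest.raises(ValueError, match="no peak overlaps"):
            validation_rate_by_rank(pc, els, "limb")


class TestElementsTSV:
    def test_roundtrip(self, tmp_path, rng):
        els = [
            element(f"e{i}", 1_000 * (i + 1), [TISSUES[int(rng.integers(0, 6))]])
            for i in range(20)
        ]
        path = tmp_path / "elements.tsv"
        write_elements_tsv(els, path)
        back = read_elements_tsv(path)
        assert [e.id for e in back] == [e.id for e in els]
        assert [e.interval for e in back] == [e.interval for e in els]
        assert [e.activity for e in back] == [e.activity for e in els]


@given(st.data())
def test_hidden_rows_have_all_zero_counts_property(data):
    n = data.draw(st.integers(min_value=1, max_value=60))
    counts = data.draw(
        st.lists(st.tuples(*[st.integers(0, 3)] * 3), min_size=n, max_size=n)
    )
    rows = [("e%d" % i, "limb", *c) for i, c in enumerate(counts)]
    rec = classify(matrix_from_counts(rows))
    hidden = rec["category"] == "HIDDEN"
    want = [all(x == 0 for x in c) for c in counts]
    assert hidden.tolist() == want
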