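"""Mark-presence classification of validated enhancers.

A transgenically validated element is assessed per *active tissue*: for every
tissue in which it drives reproducible reporter activity, its genomic span is
intersected with that tissue's stage-matched peak calls for the three
canonical enhancer-associated chromatin marks -- H3K27ac ChIP-seq, H3K4me1
ChIP-seq and ATAC-seq open chromatin. The number of canonical marks present
(>= 1 overlapping peak, minimum 1 bp) defines four categories:

==============  =========================================
THREE_MARKS     all three canonical marks present
TWO_MARKS       exactly two present
ONE_MARK        exactly one present
HIDDEN          none present (a "hidden" enhancer)
==============  =========================================

Rows of the mark matrix are (element, tissue) pairs restricted to positive
activity calls; an element active in two tissues contributes two rows and can
be hidden in one tissue while marked in the other. Multiple datasets for the
same (tissue, mark, stage) are unioned: presence in any dataset counts, and
reported counts are summed across datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import (
    ChainAlignment,
    GenomicInterval,
    PeakCollection,
    intersect_elements,
    map_interval,
)

__all__ = [
    "TISSUES",
    "CANONICAL_MARKS",
    "EXTENDED_MARKS",
    "CATEGORIES",
    "TestedElement",
    "MarkMatrix",
    "build_mark_matrix",
    "classify",
    "category_proportions",
    "sequential_mark_filter",
    "validation_rate_by_rank",
    "read_elements_tsv",
    "write_elements_tsv",
    "round_half_away",
]

#: The six scoreable embryonic tissues, fixed study-wide.
TISSUES = ("forebrain", "midbrain", "hindbrain", "craniofacial", "limb", "heart")

#: Canonical enhancer-associated chromatin marks.
CANONICAL_MARKS = ("H3K27ac", "H3K4me1", "ATAC")

#: Additional histone marks / assays sometimes available for annotation.
EXTENDED_MARKS = (
    "H3K27me3",
    "H3K36me3",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me3",
    "DNase",
)

CATEGORIES = ("THREE_MARKS", "TWO_MARKS", "ONE_MARK", "HIDDEN")
_N_TO_CATEGORY = {3: "THREE_MARKS", 2: "TWO_MARKS", 1: "ONE_MARK", 0: "HIDDEN"}


def round_half_away(x: float) -> int:
    """Round half away from zero (report parity with printed integer percents)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class TestedElement:
    """A transgenically assayed sequence with per-tissue activity calls.

    ``activity`` maps tissue name to ``"positive"`` or ``"negative"``; tissues
    absent from the map were not scored (``na``). ``origin_species`` records
    whether the tested sequence is of mouse or human origin (human elements
    were lifted to the mouse assembly before testing).
    """

    id: str
    interval: GenomicInterval
    origin_species: str = "mouse"
    activity: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {v for v in self.activity.values()} - {"positive", "negative"}
        if bad:
            raise ValueError(f"{self.id}: invalid activity calls {sorted(bad)}")
        if not self.activity:
            raise ValueError(f"{self.id}: at least one tissue call required")

    @property
    def positive_tissues(self) -> Tuple[str, ...]:
        return tuple(t for t in TISSUES if self.activity.get(t) == "positive")

    @property
    def is_positive(self) -> bool:
        return any(v == "positive" for v in self.activity.values())


@dataclass
class MarkMatrix:
    """Per-(element, tissue) overlap counts against mark peak sets.

    ``table`` has columns ``element_id``, ``tissue`` and one integer count
    column per mark; rows exist only for tissues where the element is
    positive. ``marks`` lists the canonical columns used for classification;
    ``extended`` lists annotation-only columns that classification ignores.
    ``unmapped`` records element ids that could not be lifted to the peak
    assembly (excluded from the matrix rather than silently dropped).
    """

    table: pd.DataFrame
    marks: Tuple[str, ...] = CANONICAL_MARKS
    extended: Tuple[str, ...] = ()
    stage: str = "E11.5"
    unmapped: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for col in ("element_id", "tissue", *self.marks, *self.extended):
            if col not in self.table.columns:
                raise ValueError(f"mark matrix missing column {col!r}")
        counts = self.table[list(self.marks + self.extended)]
        if (counts.to_numpy() < 0).any():
            raise ValueError("mark counts must be non-negative")


class MarkDataError(ValueError):
    """A required (tissue, mark) combination has no peak data."""


def _pool_collections(
    peaksets: Sequence[PeakCollection], tissue: str, mark: str, stage: str
) -> List[PeakCollection]:
    return [
        pc
        for pc in peaksets
        if pc.meta.tissue == tissue and pc.meta.mark == mark and pc.meta.stage == stage
    ]


def build_mark_matrix(
    elements: Sequence[TestedElement],
    peaksets: Sequence[PeakCollection],
    stage: str = "E11.5",
    marks: Sequence[str] = CANONICAL_MARKS,
    extended_marks: Sequence[str] = (),
    tissues: Sequence[str] = TISSUES,
    chains: Optional[Sequence[ChainAlignment]] = None,
    unavailable: Iterable[Tuple[str, str]] = (),
    min_overlap: int = 1,
    min_match: float = 0.1,
) -> MarkMatrix:
    """Intersect positive (element, tissue) rows with stage-matched peak sets.

    For each tissue with at least one positive element and each requested mark,
    every collection tagged (tissue, mark, stage) is intersected with the
    element spans and the per-dataset counts are summed (union semantics:
    presence in any dataset counts). A (tissue, mark) pair with no data must be
    declared in ``unavailable`` or a :class:`MarkDataError` is raised -- silent
    absence would masquerade as a hidden call.

    Elements on a different assembly than the peaks are lifted through
    ``chains`` first; elements that fail to map are excluded and reported in
    ``MarkMatrix.unmapped``.
    """
    marks = tuple(marks)
    extended_marks = tuple(extended_marks)
    unavailable = {tuple(p) for p in unavailable}

    # only collections this matrix can consult constrain the working assembly
    relevant = [
        pc
        for pc in peaksets
        if pc.meta.stage == stage and pc.meta.mark in marks + extended_marks
    ]
    assemblies = {pc.meta.assembly for pc in relevant if pc.meta.assembly}
    if len(assemblies) > 1:
        raise ValueError(f"peak sets span several assemblies: {sorted(assemblies)}")
    target_assembly = assemblies.pop() if assemblies else ""

    # Lift (or pass through) each element once.
    spans: Dict[str, GenomicInterval] = {}
    unmapped: List[str] = []
    for el in elements:
        iv = el.interval
        if target_assembly and iv.assembly and iv.assembly != target_assembly:
            if chains is None:
                raise ValueError(
                    f"element {el.id} on {iv.assembly} but peaks on {target_assembly}; "
                    "supply chains for lift-over"
                )
            mapped = map_interval(iv, chains, min_match=min_match)
            if mapped is None or mapped.assembly not in ("", target_assembly):
                unmapped.append(el.id)
                continue
            spans[el.id] = mapped
        else:
            spans[el.id] = iv

    rows: List[Tuple[str, str]] = []
    for el in elements:
        if el.id not in spans:
            continue
        for t in el.positive_tissues:
            if t in tissues:
                rows.append((el.id, t))

    all_marks = marks + extended_marks
    data = {m: np.zeros(len(rows), dtype=np.int64) for m in all_marks}
    row_idx_by_tissue: Dict[str, List[int]] = {}
    for i, (_, t) in enumerate(rows):
        row_idx_by_tissue.setdefault(t, []).append(i)

    for tissue, idxs in row_idx_by_tissue.items():
        tissue_spans = [spans[rows[i][0]] for i in idxs]
        for mark in all_marks:
            pools = _pool_collections(peaksets, tissue, mark, stage)
            if not pools:
                if (tissue, mark) in unavailable:
                    continue
                raise MarkDataError(
                    f"no peak data for ({tissue}, {mark}) at {stage}; declare it "
                    "unavailable explicitly if that is intended"
                )
            counts = np.zeros(len(idxs), dtype=np.int64)
            for pc in pools:
                counts += intersect_elements(tissue_spans, pc, min_overlap=min_overlap)
            data[mark][idxs] = counts

    table = pd.DataFrame(
        {
            "element_id": [r[0] for r in rows],
            "tissue": [r[1] for r in rows],
            **{m: data[m] for m in all_marks},
        }
    )
    return MarkMatrix(
        table=table,
        marks=marks,
        extended=extended_marks,
        stage=stage,
        unmapped=tuple(unmapped),
    )


def classify(matrix: MarkMatrix) -> pd.DataFrame:
    """Assign each (element, tissue) row a mark-presence category.

    Only the canonical marks in ``matrix.marks`` are consulted; extended-mark
    columns never influence the category. Returns a frame with per-mark
    presence booleans, ``n_marks`` and ``category``.
    """
    t = matrix.table
    out = pd.DataFrame({"element_id": t["element_id"], "tissue": t["tissue"]})
    n = np.zeros(len(t), dtype=np.int64)
    for m in matrix.marks:
        present = t[m].to_numpy() >= 1
        out[f"has_{m}"] = present
        n += present.astype(np.int64)
    out["n_marks"] = n
    out["category"] = [_N_TO_CATEGORY[int(k)] for k in n]
    return out


def category_proportions(records: pd.DataFrame, by: str = "overall") -> pd.DataFrame:
    """Counts, fractions and printed-parity integer percents per category.

    ``by="overall"`` returns one row per category; ``by="tissue"`` one row per
    (tissue, category). Percents round half away from zero; raw fractions are
    retained so no precision is lost downstream.
    """
    if len(records) == 0:
        raise ValueError("no classification records")
    if by not in ("overall", "tissue"):
        raise ValueError("by must be 'overall' or 'tissue'")

    def _summarise(df: pd.DataFrame) -> pd.DataFrame:
        total = len(df)
        counts = df["category"].value_counts()
        rows = []
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            frac = c / total
            rows.append(
                {"category": cat, "count": c, "fraction": frac, "percent": round_half_away(100 * frac)}
            )
        return pd.DataFrame(rows)

    if by == "overall":
        return _summarise(records)
    parts = []
    for tissue, df in records.groupby("tissue", sort=False):
        part = _summarise(df)
        part.insert(0, "tissue", tissue)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def sequential_mark_filter(
    records: pd.DataFrame,
    tissue: str,
    order: Sequence[str] = CANONICAL_MARKS,
) -> List[int]:
    """Waterfall of tissue rows successively lacking each mark in ``order``.

    Step k counts the rows lacking marks ``order[0..k]`` simultaneously, so the
    sequence is monotone non-increasing and, when ``order`` is the full
    canonical set, the final value equals the tissue's HIDDEN count.
    """
    if tissue not in set(records["tissue"]):
        known = sorted(set(records["tissue"]))
        raise ValueError(f"unknown tissue {tissue!r}; records cover {known}")
    sub = records[records["tissue"] == tissue]
    missing = [m for m in order if f"has_{m}" not in sub.columns]
    if missing:
        raise ValueError(f"records lack presence columns for {missing}")
    mask = np.ones(len(sub), dtype=bool)
    counts: List[int] = []
    for mark in order:
        mask &= ~sub[f"has_{mark}"].to_numpy()
        counts.append(int(mask.sum()))
    return counts


def validation_rate_by_rank(
    peaks: PeakCollection,
    elements: Sequence[TestedElement],
    tissue: str,
    n_bins: int = 4,
    min_overlap: int = 1,
) -> Dict[str, object]:
    """Validation rate of signal-ranked peaks against transgenic outcomes.

    Peaks overlapped by at least one *tested* element are ranked by signal
    value (descending, coordinate tie-break) and split into ``n_bins``
    near-equal bins; each bin's rate is the fraction of its peaks overlapped by
    an element *positive in the tissue*. The overall rate over all tested
    peaks is also returned. High-signal bins validating more often is the
    expected signature of enrichment-ranked candidate lists.
    """
    if peaks.signal is None:
        raise ValueError("peaks must carry signal values (narrowPeak column 7)")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    tested_spans = [el.interval for el in elements]
    positive_spans = [
        el.interval for el in elements if el.activity.get(tissue) == "positive"
    ]
    tested_pc = PeakCollection(peaks.meta, tested_spans)
    pos_pc = PeakCollection(peaks.meta, positive_spans)
    hit_tested = intersect_elements(peaks.peaks, tested_pc, min_overlap=min_overlap) >= 1
    if not hit_tested.any():
        raise ValueError("no peak overlaps any tested element")
    hit_pos = intersect_elements(peaks.peaks, pos_pc, min_overlap=min_overlap) >= 1

    idx = np.flatnonzero(hit_tested)
    sig = peaks.signal[idx]
    coords = [(peaks.peaks[i].chrom, peaks.peaks[i].start, peaks.peaks[i].end) for i in idx]
    order = sorted(range(len(idx)), key=lambda k: (-sig[k], coords[k]))
    ranked_validated = np.asarray([bool(hit_pos[idx[k]]) for k in order])

    bins = np.array_split(ranked_validated, n_bins)
    bin_rates = np.array([float(b.mean()) if len(b) else float("nan") for b in bins])
    return {
        "bin_rates": bin_rates,
        "bin_sizes": np.array([len(b) for b in bins]),
        "overall_rate": float(ranked_validated.mean()),
        "n_tested_peaks": int(len(ranked_validated)),
        "n_validated": int(ranked_validated.sum()),
    }


# ---------------------------------------------------------------------------
# Element table I/O
# ---------------------------------------------------------------------------

_ELEMENT_COLS = ["id", "chrom", "start", "end", "assembly", "species"]


def write_elements_tsv(elements: Sequence[TestedElement], path) -> None:
    """Write the element table: coordinates plus one {pos,neg,na} column per tissue."""
    rows = []
    for el in elements:
        row = {
            "id": el.id,
            "chrom": el.interval.chrom,
            "start": el.interval.start,
            "end": el.interval.end,
            "assembly": el.interval.assembly,
            "species": el.origin_species,
        }
        for t in TISSUES:
            call = el.activity.get(t)
            row[t] = {"positive": "pos", "negative": "neg", None: "na"}[call]
        rows.append(row)
    pd.DataFrame(rows, columns=_ELEMENT_COLS + list(TISSUES)).to_csv(path, sep="\t", index=False)


def read_elements_tsv(path) -> List[TestedElement]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in _ELEMENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    elements: List[TestedElement] = []
    for rec in df.itertuples(index=False):
        activity = {}
        for t in TISSUES:
            call = getattr(rec, t, "na")
            if call == "pos":
                activity[t] = "positive"
            elif call == "neg":
                activity[t] = "negative"
        elements.append(
            TestedElement(
                id=str(rec.id),
                interval=GenomicInterval(str(rec.chrom), int(rec.start), int(rec.end), str(rec.assembly)),
                origin_species=str(rec.species),
                activity=activity,
            )
        )
    return elements
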