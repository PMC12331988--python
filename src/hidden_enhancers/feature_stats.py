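"""Conservation and repeat-content comparisons between enhancer groups.

Hidden enhancers would be easy to dismiss as reporter-assay artifacts if they
looked like random genomic sequence. The comparisons here quantify two
hallmarks of bona fide regulatory elements: elevated evolutionary conservation
(mean phastCons over the element, compared between groups and against a
length-matched random genomic background with a two-sample Kolmogorov-Smirnov
test) and transposable-element composition (per-class tallies of RepeatMasker
annotations overlapping each element).

phastCons is a per-base probability in [0, 1]; bedGraph tracks are stepwise
constant and typically leave unalignable bases uncovered. Two missing-data
policies are offered: ``zero`` treats uncovered bases as score 0 (unaligned ~
unconserved; the default) and ``exclude`` drops them from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .intervals import GenomicInterval, PeakCollection, PeakMeta, intersect_elements, read_bed

__all__ = [
    "REPEAT_CLASSES",
    "ScoreTrack",
    "RepeatAnnotation",
    "mean_score",
    "compare_conservation",
    "sample_background",
    "repeat_composition",
]

REPEAT_CLASSES = ("LINE", "SINE", "DNA", "LTR", "other")


class ScoreTrack:
    """Stepwise-constant per-base scores (bedGraph semantics).

    Intervals must not overlap within a chromosome; uncovered bases carry no
    value. Stored as sorted (starts, ends, values) arrays per chromosome for
    fast interval queries.
    """

    def __init__(
        self,
        data: Mapping[str, Tuple[Sequence[int], Sequence[int], Sequence[float]]],
        assembly: str = "",
    ) -> None:
        self.assembly = assembly
        self.data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            s = np.asarray(starts, dtype=np.int64)
            e = np.asarray(ends, dtype=np.int64)
            v = np.asarray(values, dtype=float)
            if not (len(s) == len(e) == len(v)):
                raise ValueError(f"{chrom}: ragged track arrays")
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e <= s):
                raise ValueError(f"{chrom}: empty or inverted track interval")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping track intervals")
            self.data[chrom] = (s, e, v)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[Tuple[GenomicInterval, float]], assembly: str = ""
    ) -> "ScoreTrack":
        acc: Dict[str, Tuple[List[int], List[int], List[float]]] = {}
        for iv, val in pairs:
            s, e, v = acc.setdefault(iv.chrom, ([], [], []))
            s.append(iv.start)
            e.append(iv.end)
            v.append(val)
        return cls(acc, assembly=assembly)

    @classmethod
    def from_bedgraph(cls, path, assembly: str = "") -> "ScoreTrack":
        pairs = read_bed(path, "bedgraph", PeakMeta(assembly=assembly))
        return cls.from_pairs(pairs, assembly=assembly)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                s, e, v = self.data[chrom]
                for i in range(len(s)):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTrack):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        for chrom in self.data:
            s1, e1, v1 = self.data[chrom]
            s2, e2, v2 = other.data[chrom]
            if not (np.array_equal(s1, s2) and np.array_equal(e1, e2) and np.allclose(v1, v2)):
                return False
        return True


def mean_score(
    element: GenomicInterval,
    track: ScoreTrack,
    missing_policy: str = "zero",
) -> float:
    """Length-weighted mean track value over an element.

    Under ``zero`` uncovered bases contribute score 0 and the denominator is
    the element length; under ``exclude`` they are dropped from the
    denominator, and a fully uncovered element yields ``nan``.
    """
    if missing_policy not in ("zero", "exclude"):
        raise ValueError("missing_policy must be 'zero' or 'exclude'")
    if element.chrom not in track.data:
        total, covered = 0.0, 0
    else:
        s, e, v = track.data[element.chrom]
        lo = int(np.searchsorted(e, element.start, side="right"))
        hi = int(np.searchsorted(s, element.end, side="left"))
        if hi > lo:
            ov = np.minimum(e[lo:hi], element.end) - np.maximum(s[lo:hi], element.start)
            ov = np.clip(ov, 0, None)
            total = float(np.dot(ov, v[lo:hi]))
            covered = int(ov.sum())
        else:
            total, covered = 0.0, 0
    if missing_policy == "zero":
        return total / element.length
    return total / covered if covered else math.nan


def compare_conservation(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "asymp",
) -> Tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test between score samples.

    Returns ``(D, p)`` with ``D = sup |ECDF_A - ECDF_B|``. The asymptotic
    p-value is the default; pass ``method="exact"`` or ``"auto"`` for exact
    small-sample computation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sp_stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def sample_background(
    n: int,
    length_source: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    seed: int,
    assembly: str = "",
) -> List[GenomicInterval]:
    """Length-matched random genomic background intervals.

    Draws ``n`` lengths with replacement from ``length_source`` and places each
    uniformly over all valid positions of the genome (chromosomes weighted by
    the number of admissible start positions). Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not genome:
        raise ValueError("genome must be non-empty")
    if not length_source:
        raise ValueError("length_source must be non-empty")
    rng = np.random.default_rng(seed)
    lengths = [length_source[i].length for i in rng.integers(0, len(length_source), size=n)]
    chroms = sorted(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=np.int64)
    out: List[GenomicInterval] = []
    for L in lengths:
        slots = sizes - L + 1
        valid = slots > 0
        if not valid.any():
            raise ValueError(f"sampled length {L} exceeds every chromosome")
        p = np.where(valid, slots, 0).astype(float)
        ci = int(rng.choice(len(chroms), p=p / p.sum()))
        start = int(rng.integers(0, slots[ci]))
        out.append(GenomicInterval(chroms[ci], start, start + L, assembly))
    return out


@dataclass
class RepeatAnnotation:
    """RepeatMasker-style repeat intervals tagged with class, family and name.

    Classes are normalised onto a fixed vocabulary (``LINE``, ``SINE``,
    ``DNA``, ``LTR``) with everything else mapped to ``other``; subclass
    suffixes such as ``SINE/Alu`` are recognised by their prefix.
    """

    intervals: List[GenomicInterval]
    classes: List[str]
    families: List[str]
    names: List[str]
    assembly: str = ""

    def __post_init__(self) -> None:
        k = len(self.intervals)
        if not (len(self.classes) == len(self.families) == len(self.names) == k):
            raise ValueError("ragged repeat annotation columns")
        self.classes = [self.normalise_class(c) for c in self.classes]

    @staticmethod
    def normalise_class(raw: str) -> str:
        head = raw.split("/")[0].strip()
        return head if head in REPEAT_CLASSES[:-1] else "other"

    @classmethod
    def from_bed(cls, path, assembly: str = "") -> "RepeatAnnotation":
        """Read BED3 plus class/family/name columns (RepeatMasker table export)."""
        intervals: List[GenomicInterval] = []
        classes: List[str] = []
        families: List[str] = []
        names: List[str] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith(("#", "track", "browser")):
                    continue
                fields = s.split("\t")
                if len(fields) < 6:
                    raise ValueError(f"{path}:{lineno}: need 6 columns (bed3 + class/family/name)")
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), assembly)
                )
                classes.append(fields[3])
                families.append(fields[4])
                names.append(fields[5])
        return cls(intervals, classes, families, names, assembly=assembly)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv, c, f, n in zip(self.intervals, self.classes, self.families, self.names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c}\t{f}\t{n}\n")

    def __len__(self) -> int:
        return len(self.intervals)


def repeat_composition(
    elements: Sequence[GenomicInterval],
    repeats: RepeatAnnotation,
    min_overlap: int = 1,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tally repeat entries overlapping each element, grouped by class.

    Returns ``(per_element, summary)``: ``per_element`` has one row per element
    with a count column per repeat class; ``summary`` aggregates counts across
    elements and derives class proportions (summing to 1 whenever any repeat
    overlaps at all).
    """
    per_class: Dict[str, np.ndarray] = {}
    for cls_name in REPEAT_CLASSES:
        members = [iv for iv, c in zip(repeats.intervals, repeats.classes) if c == cls_name]
        pc = PeakCollection(PeakMeta(assembly=repeats.assembly, mark=f"repeat:{cls_name}"), members)
        per_class[cls_name] = (
            intersect_elements(elements, pc, min_overlap=min_overlap)
            if elements
            else np.zeros(0, dtype=np.int64)
        )
    per_element = pd.DataFrame(per_class)
    totals = per_element.sum(axis=0)
    grand = float(totals.sum())
    summary = pd.DataFrame(
        {
            "count": totals.astype(int),
            "proportion": (totals / grand) if grand > 0 else 0.0,
        }
    )
    summary.index.name = "repeat_class"
    return per_element, summary
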