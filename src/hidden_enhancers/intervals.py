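"""Genomic interval primitives, standard-format I/O and overlap arithmetic.

All coordinates in this package are 0-based half-open (BED-native). Inputs in
1-based conventions must be converted at parse time; nothing downstream ever
sees a 1-based coordinate. Strand is ignored for elements and peaks (enhancer
activity is strandless); alignment chains honour strand only for coordinate
arithmetic during lift-over.

The module provides

* :class:`GenomicInterval` -- an immutable coordinate span on a named assembly;
* :class:`PeakCollection` -- a sorted set of peaks tagged with experiment
  metadata (species, assembly, tissue, mark, stage, dataset id) and optional
  per-peak signal values (narrowPeak column 7);
* BED3 / BED6 / narrowPeak / bedGraph readers and writers;
* :func:`overlap_length` and :func:`intersect_elements`, the bedtools-style
  "minimum overlap of 1 bp" intersection used for every chromatin comparison;
* UCSC chain parsing and :func:`map_interval`, a conservative single-chain
  liftOver (``minMatch``-style mapped-fraction threshold, default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakMeta",
    "PeakCollection",
    "ChainAlignment",
    "BedParseError",
    "ChainParseError",
    "overlap_length",
    "intersect_elements",
    "map_interval",
    "read_bed",
    "write_bed",
    "write_intervals_bed",
    "read_chain",
    "write_chain",
]

BED_DIALECTS = ("bed3", "bed6", "narrowPeak", "bedgraph")
_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "bedgraph": 4}


class BedParseError(ValueError):
    """A BED-family line could not be parsed; the message names the line."""


class ChainParseError(ValueError):
    """A UCSC chain record is malformed or internally inconsistent."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a chromosome of an assembly.

    ``assembly`` may be left empty for throwaway intervals; operations that mix
    assemblies treat an empty tag as a wildcard.
    """

    chrom: str
    start: int
    end: int
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start (half-open): {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        tag = f" ({self.assembly})" if self.assembly else ""
        return f"{self.chrom}:{self.start}-{self.end}{tag}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals.

    Returns 0 for different chromosomes or (explicitly) different assemblies;
    half-open adjacency (``a.end == b.start``) is not overlap.
    """
    if a.chrom != b.chrom:
        return 0
    if a.assembly and b.assembly and a.assembly != b.assembly:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class PeakMeta:
    """Provenance tags for a peak set: one (species, assembly, tissue, assay, stage)."""

    species: str = "mouse"
    assembly: str = ""
    tissue: str = ""
    mark: str = ""
    stage: str = ""
    dataset_id: str = ""


class PeakCollection:
    """Sorted, assembly-consistent peak intervals with optional signal values.

    Peaks are stored sorted by (chrom, start, end); the order is re-established
    on construction and therefore survives any load path. ``signal`` parallels
    the peak list (narrowPeak signalValue) and is permuted alongside it.
    """

    def __init__(
        self,
        meta: PeakMeta,
        peaks: Iterable[GenomicInterval] = (),
        signal: Optional[Sequence[float]] = None,
    ) -> None:
        peak_list = list(peaks)
        fixed: List[GenomicInterval] = []
        for p in peak_list:
            if p.assembly and meta.assembly and p.assembly != meta.assembly:
                raise ValueError(
                    f"peak on {p.assembly} in a {meta.assembly} collection: {p}"
                )
            if meta.assembly and not p.assembly:
                p = replace(p, assembly=meta.assembly)
            fixed.append(p)
        if signal is not None and len(signal) != len(fixed):
            raise ValueError("signal length must match number of peaks")
        order = sorted(range(len(fixed)), key=lambda i: (fixed[i].chrom, fixed[i].start, fixed[i].end))
        self.meta = meta
        self.peaks: List[GenomicInterval] = [fixed[i] for i in order]
        self.signal: Optional[np.ndarray] = (
            None if signal is None else np.asarray([signal[i] for i in order], dtype=float)
        )
        self._index: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakCollection):
            return NotImplemented
        sig_eq = (
            (self.signal is None and other.signal is None)
            or (
                self.signal is not None
                and other.signal is not None
                and np.allclose(self.signal, other.signal)
            )
        )
        return self.meta == other.meta and self.peaks == other.peaks and sig_eq

    def _chrom_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        # (starts, ends) per chromosome, ordered by start; built lazily.
        if self._index is None:
            idx: Dict[str, Tuple[List[int], List[int]]] = {}
            for p in self.peaks:
                s, e = idx.setdefault(p.chrom, ([], []))
                s.append(p.start)
                e.append(p.end)
            self._index = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in idx.items()
            }
        return self._index

    @classmethod
    def from_bed(cls, path, dialect: str, meta: PeakMeta) -> "PeakCollection":
        return read_bed(path, dialect, meta)

    def to_bed(self, path, dialect: str = "bed3") -> None:
        write_bed(self, path, dialect)


def intersect_elements(
    elements: Sequence[GenomicInterval],
    peaks: PeakCollection,
    min_overlap: int = 1,
) -> np.ndarray:
    """Per-element count of peaks overlapping by at least ``min_overlap`` bases.

    This is the bedtools ``intersect -c`` semantics with a minimum-overlap
    floor; presence of a mark means ``count >= 1``. Elements and peaks must
    share an assembly -- callers lift over first (see :func:`map_interval`).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    asm = peaks.meta.assembly
    for e in elements:
        if e.assembly and asm and e.assembly != asm:
            raise ValueError(
                f"assembly mismatch ({e.assembly} element vs {asm} peaks): "
                "lift the elements over with map_interval first"
            )
    index = peaks._chrom_index()
    counts = np.zeros(len(elements), dtype=np.int64)
    for i, e in enumerate(elements):
        if e.chrom not in index:
            continue
        starts, ends = index[e.chrom]
        # candidates must start early enough to reach m shared bases
        hi = int(np.searchsorted(starts, e.end - min_overlap, side="right"))
        if hi:
            shared = np.minimum(ends[:hi], e.end) - np.maximum(starts[:hi], e.start)
            counts[i] = int(np.count_nonzero(shared >= min_overlap))
    return counts


# ---------------------------------------------------------------------------
# BED-family I/O
# ---------------------------------------------------------------------------

def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith("#") or s.startswith("track") or s.startswith("browser")


def read_bed(path, dialect: str, meta: Optional[PeakMeta] = None):
    """Read a BED-family file.

    ``bed3``/``bed6``/``narrowPeak`` return a :class:`PeakCollection` (narrowPeak
    column 7 is captured as signal); ``bedgraph`` returns a list of
    ``(GenomicInterval, value)`` pairs. Comment/track/browser lines are skipped.
    Malformed lines and empty intervals raise :class:`BedParseError` naming the
    line number.
    """
    if dialect not in BED_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {BED_DIALECTS}")
    meta = meta or PeakMeta()
    need = _MIN_COLS[dialect]
    intervals: List[GenomicInterval] = []
    signals: List[float] = []
    values: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < need:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {need} columns for {dialect}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end}) (end must exceed start >= 0)"
                )
            intervals.append(GenomicInterval(fields[0], start, end, meta.assembly))
            if dialect == "narrowPeak":
                try:
                    signals.append(float(fields[6]))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad signalValue {fields[6]!r}") from exc
            elif dialect == "bedgraph":
                try:
                    values.append(float(fields[3]))
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad bedGraph value {fields[3]!r}") from exc
    if dialect == "bedgraph":
        return list(zip(intervals, values))
    return PeakCollection(meta, intervals, signals if dialect == "narrowPeak" else None)


def write_bed(collection: PeakCollection, path, dialect: str = "bed3") -> None:
    """Write a peak collection as BED3, BED6 or narrowPeak."""
    if dialect not in ("bed3", "bed6", "narrowPeak"):
        raise ValueError(f"cannot write dialect {dialect!r}")
    sig = collection.signal
    with open(path, "w") as fh:
        for i, p in enumerate(collection.peaks):
            if dialect == "bed3":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            elif dialect == "bed6":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t0\t.\n")
            else:
                s = 0.0 if sig is None else float(sig[i])
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t0\t.\t{s:g}\t-1\t-1\t-1\n"
                )


def write_intervals_bed(intervals: Sequence[GenomicInterval], path, names: Optional[Sequence[str]] = None) -> None:
    """Write bare intervals as BED (BED4 when names are given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")


# ---------------------------------------------------------------------------
# UCSC chains and lift-over
# ---------------------------------------------------------------------------

@dataclass
class ChainAlignment:
    """One UCSC chain: gapless alignment blocks between a source and a target.

    ``blocks`` is an ordered tuple of ``(size, d_source, d_target)`` records;
    the final block carries zero gaps. Source strand is always '+'; a '-'
    target strand stores target coordinates on the reversed strand, as in the
    chain format, and :func:`map_interval` flips them back.
    """

    score: int
    source_chrom: str
    source_size: int
    source_start: int
    source_end: int
    target_chrom: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: Tuple[Tuple[int, int, int], ...]
    source_assembly: str = ""
    target_assembly: str = ""

    def __post_init__(self) -> None:
        if self.target_strand not in "+-":
            raise ChainParseError(f"bad target strand {self.target_strand!r}")
        src_span = 0
        tgt_span = 0
        for k, (size, ds, dt) in enumerate(self.blocks):
            if size < 1:
                raise ChainParseError("chain block size must be >= 1")
            if ds < 0 or dt < 0:
                raise ChainParseError("chain gaps must be non-negative")
            last = k == len(self.blocks) - 1
            src_span += size + (0 if last else ds)
            tgt_span += size + (0 if last else dt)
        if src_span != self.source_end - self.source_start:
            raise ChainParseError(
                f"block extents ({src_span}) disagree with source span "
                f"({self.source_end - self.source_start})"
            )
        if tgt_span != self.target_end - self.target_start:
            raise ChainParseError(
                f"block extents ({tgt_span}) disagree with target span "
                f"({self.target_end - self.target_start})"
            )


def read_chain(path, source_assembly: str = "", target_assembly: str = "") -> List[ChainAlignment]:
    """Parse a UCSC chain file (``chain score tName ... qName ... id``).

    The chain format does not carry assembly names, so they are supplied here;
    the first genome in the header (``t``) is the lift-over source.
    """
    chains: List[ChainAlignment] = []
    header: Optional[List[str]] = None
    blocks: List[Tuple[int, int, int]] = []

    def _flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks:
            raise ChainParseError(f"{path}: chain with no alignment blocks")
        chains.append(
            ChainAlignment(
                score=int(header[1]),
                source_chrom=header[2],
                source_size=int(header[3]),
                source_start=int(header[5]),
                source_end=int(header[6]),
                target_chrom=header[7],
                target_size=int(header[8]),
                target_strand=header[9],
                target_start=int(header[10]),
                target_end=int(header[11]),
                blocks=tuple(blocks),
                source_assembly=source_assembly,
                target_assembly=target_assembly,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                if header is not None and not s:
                    _flush()
                continue
            parts = s.split()
            if parts[0] == "chain":
                _flush()
                if len(parts) < 12:
                    raise ChainParseError(f"{path}:{lineno}: short chain header")
                if parts[4] != "+":
                    raise ChainParseError(f"{path}:{lineno}: source strand must be '+'")
                header = parts
            else:
                if header is None:
                    raise ChainParseError(f"{path}:{lineno}: block outside a chain")
                if len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ChainParseError(f"{path}:{lineno}: bad block line")
    _flush()
    return chains


def write_chain(chains: Sequence[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for cid, ch in enumerate(chains, start=1):
            fh.write(
                f"chain {ch.score} {ch.source_chrom} {ch.source_size} + "
                f"{ch.source_start} {ch.source_end} {ch.target_chrom} {ch.target_size} "
                f"{ch.target_strand} {ch.target_start} {ch.target_end} {cid}\n"
            )
            for k, (size, ds, dt) in enumerate(ch.blocks):
                if k == len(ch.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size}\t{ds}\t{dt}\n")
            fh.write("\n")


def _chain_coverage(
    q: GenomicInterval, ch: ChainAlignment
) -> Tuple[int, Optional[int], Optional[int]]:
    """Covered query bases and the min/max target coordinates for one chain."""
    covered = 0
    lo: Optional[int] = None
    hi: Optional[int] = None
    s = ch.source_start
    t = ch.target_start
    for size, ds, dt in ch.blocks:
        ov_lo = max(s, q.start)
        ov_hi = min(s + size, q.end)
        if ov_lo < ov_hi:
            covered += ov_hi - ov_lo
            t_lo = t + (ov_lo - s)
            t_hi = t + (ov_hi - s)
            lo = t_lo if lo is None else min(lo, t_lo)
            hi = t_hi if hi is None else max(hi, t_hi)
        s += size + ds
        t += size + dt
        if s >= q.end:
            break
    return covered, lo, hi


def map_interval(
    q: GenomicInterval,
    chains: Sequence[ChainAlignment],
    min_match: float = 0.1,
) -> Optional[GenomicInterval]:
    """Lift one interval across assemblies through UCSC chains.

    The single chain whose gapless blocks cover the most query bases is
    selected (ties broken by chain score, then file order); if the covered
    fraction of the query is below ``min_match`` -- the liftOver ``minMatch``
    threshold, 0.1 throughout this package -- or no chain covers any base, the
    query is unmapped and ``None`` is returned. Otherwise the minimal target
    span containing every mapped base of that chain is returned, with
    reverse-strand target coordinates flipped back to the forward strand.

    Split/multi-chain mappings are deliberately not stitched together; this is
    a conservative dialect of liftOver's default single-mapping behaviour.
    """
    best: Optional[Tuple[int, int, int, int, ChainAlignment]] = None
    for order, ch in enumerate(chains):
        if ch.source_chrom != q.chrom:
            continue
        if q.assembly and ch.source_assembly and q.assembly != ch.source_assembly:
            continue
        covered, lo, hi = _chain_coverage(q, ch)
        if covered == 0:
            continue
        key = (covered, ch.score, -order)
        if best is None or key > (best[0], best[1], -best[3]):
            assert lo is not None and hi is not None
            best = (covered, ch.score, lo, order, ch)
            best_span = (lo, hi)
    if best is None:
        return None
    covered, _, _, _, ch = best
    if covered / q.length < min_match:
        return None
    lo, hi = best_span
    if ch.target_strand == "-":
        lo, hi = ch.target_size - hi, ch.target_size - lo
    return GenomicInterval(ch.target_chrom, lo, hi, ch.target_assembly)
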