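"""Design of overlapping ~5 kb tiles across a locus for unbiased testing.

Chromatin-agnostic enhancer screens test *every* base of a locus by cutting it
into elements of roughly constant size that overlap their neighbours, so that
an enhancer falling on a boundary is still fully contained in some element.
The designer here places tiles greedily left to right at a stride of
``target_len - min_overlap`` and, when anchor peaks (e.g. H3K27ac-enriched
regions) are supplied, nudges boundaries so that a peak is captured whole by a
single tile whenever the length bounds allow it.

Guarantees (checked by :meth:`TileSet.validate`): tiles cover the locus
exactly -- first tile starts at the locus start, last tile ends at the locus
end, no gaps; consecutive tiles overlap by at least ``min_overlap``; every
tile length lies within ``(min_len, max_len)``; a locus shorter than
``max_len`` is emitted as a single tile (flagged short when below
``min_len``). Designs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, PeakCollection, overlap_length

__all__ = ["TilingParams", "TileSet", "design_tiles", "audit_tiles"]


@dataclass(frozen=True)
class TilingParams:
    """Tile geometry: ~5000 bp elements with several hundred bp of overlap.

    Defaults: 5000 bp target, 400 bp minimum overlap (mid-range of "several
    hundred"), 4000-6500 bp admissible lengths -- wide enough for the observed
    4985 +/- 456 bp spread of cloned elements while staying PCR-plausible.
    """

    target_len: int = 5000
    min_overlap: int = 400
    min_len: int = 4000
    max_len: int = 6500

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.target_len <= self.max_len):
            raise ValueError(
                f"length bounds must satisfy 0 < min_len <= target_len <= max_len, "
                f"got ({self.min_len}, {self.target_len}, {self.max_len})"
            )
        if not (0 < self.min_overlap < self.min_len):
            raise ValueError(
                f"min_overlap must lie in (0, min_len), got {self.min_overlap}"
            )

    @property
    def stride(self) -> int:
        return self.target_len - self.min_overlap


@dataclass
class TileSet:
    """An ordered tiling of one locus; ``split_peaks`` lists anchors no boundary
    adjustment could keep whole."""

    locus: GenomicInterval
    tiles: List[GenomicInterval]
    params: TilingParams
    split_peaks: List[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        """Raise AssertionError if any tiling invariant is violated."""
        p, tiles = self.params, self.tiles
        assert tiles, "empty tile set"
        assert tiles[0].start == self.locus.start, "first tile must start at locus start"
        assert tiles[-1].end == self.locus.end, "last tile must end at locus end"
        single_short = len(tiles) == 1 and self.locus.length <= p.max_len
        for i, t in enumerate(tiles):
            assert t.chrom == self.locus.chrom
            if not single_short:
                assert p.min_len <= t.length <= p.max_len, (
                    f"tile {i} length {t.length} outside [{p.min_len}, {p.max_len}]"
                )
            if i:
                prev = tiles[i - 1]
                assert t.start > prev.start, "tiles must be strictly ordered"
                assert prev.end - t.start >= p.min_overlap, (
                    f"tiles {i - 1}/{i} overlap {prev.end - t.start} < {p.min_overlap}"
                )
        covered = tiles[0].length
        for i in range(1, len(tiles)):
            covered += tiles[i].end - max(tiles[i].start, tiles[i - 1].end)
        assert covered == self.locus.length, "tiles must cover the locus exactly"

    @property
    def lengths(self) -> np.ndarray:
        return np.array([t.length for t in self.tiles])


def _anchor_containing(boundary: int, anchors: Sequence[GenomicInterval]) -> Optional[GenomicInterval]:
    # strictly inside: a boundary at a peak edge does not split it
    for a in anchors:
        if a.start < boundary < a.end:
            return a
    return None


def design_tiles(
    locus: GenomicInterval,
    params: Optional[TilingParams] = None,
    anchors: Optional[PeakCollection] = None,
) -> TileSet:
    """Tile a locus with overlapping elements, keeping anchor peaks whole.

    Boundaries are proposed at stride ``target_len - min_overlap``. A proposed
    boundary falling strictly inside an anchor peak is moved: the tile is
    extended rightward to the peak end if that keeps it within ``max_len``
    (preferred -- maximises intact capture), else shrunk leftward to the peak
    start if that keeps it above ``min_len``, else left in place and the peak
    recorded as split. The final tile is right-aligned to the locus end; its
    fixed ``target_len`` length and the stride arithmetic guarantee the
    overlap bound.
    """
    params = params or TilingParams()
    if anchors is not None and anchors.meta.assembly and locus.assembly:
        if anchors.meta.assembly != locus.assembly:
            raise ValueError(
                f"anchors on {anchors.meta.assembly} but locus on {locus.assembly}"
            )
    anchor_list = (
        [a for a in anchors if a.chrom == locus.chrom] if anchors is not None else []
    )

    if locus.length <= params.max_len:
        return TileSet(locus, [locus], params)

    chrom, asm = locus.chrom, locus.assembly
    tiles: List[GenomicInterval] = []
    splits: List[GenomicInterval] = []
    pos = locus.start
    while True:
        remaining = locus.end - pos
        if remaining <= params.target_len:
            # right-align the last tile; loop invariant keeps start >= locus.start
            start = locus.end - params.target_len
            tiles.append(GenomicInterval(chrom, start, locus.end, asm))
            break
        end = pos + params.target_len
        # iterate: an adjusted boundary may land inside another peak
        for _ in range(len(anchor_list) + 1):
            peak = _anchor_containing(end, anchor_list)
            if peak is None:
                break
            if peak.end - pos <= params.max_len:
                end = peak.end
            elif peak.start - pos >= params.min_len:
                end = peak.start
            else:
                if peak not in splits:
                    splits.append(peak)  # split, unavoidable
                break
        if end >= locus.end:
            tiles.append(GenomicInterval(chrom, pos, locus.end, asm))
            break
        tiles.append(GenomicInterval(chrom, pos, end, asm))
        pos = end - params.min_overlap

    ts = TileSet(locus, tiles, params, split_peaks=splits)
    ts.validate()
    return ts


def audit_tiles(tiles: TileSet, peaks: Optional[PeakCollection] = None) -> Dict[str, object]:
    """Coverage and peak-capture report for a tile set.

    ``coverage`` is the fraction of locus bases covered by the tile union and
    must be 1.0 for any valid design. Peak capture counts consider only peaks
    overlapping the locus: ``n_peaks_contained`` are wholly inside at least one
    tile; ``n_peaks_split`` are not (i.e. every tile cuts them).
    """
    locus = tiles.locus
    covered = 0
    prev_end = locus.start
    for t in sorted(tiles.tiles, key=lambda x: x.start):
        covered += max(0, min(t.end, locus.end) - max(t.start, prev_end, locus.start))
        prev_end = max(prev_end, t.end)
    lengths = tiles.lengths
    report: Dict[str, object] = {
        "n_tiles": len(tiles.tiles),
        "coverage": covered / locus.length,
        "length_mean": float(lengths.mean()),
        "length_sd": float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        "n_split_at_design": len(tiles.split_peaks),
    }
    if peaks is not None:
        contained = 0
        split = 0
        for p in peaks:
            if overlap_length(p, locus) == 0:
                continue
            if any(t.start <= p.start and p.end <= t.end for t in tiles.tiles):
                contained += 1
            else:
                split += 1
        report["n_peaks_contained"] = contained
        report["n_peaks_split"] = split
    return report
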