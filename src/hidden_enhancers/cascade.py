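"""Ordered recovery of hidden enhancers through complementary chromatin data.

A hidden enhancer -- an (element, tissue) activity with no tissue-matched
canonical mark at the assayed stage -- is re-examined against three
complementary resources, in a fixed order:

1. ``EARLIER_BULK``: bulk H3K27ac and/or H3K4me1 peaks from the same tissue at
   an earlier developmental stage (E10.5). Residual reporter signal from
   earlier activity is the leading explanation for hidden calls.
2. ``SINGLE_CELL``: single-cell/-nucleus chromatin accessibility peaks, which
   can resolve marks confined to rare cell populations that bulk data average
   away. Such data exist only for some tissues (forebrain, hindbrain here).
3. ``CROSS_SPECIES``: tissue-matched, similar-staged chromatin data from the
   other species; applies only to elements of human origin and to tissues with
   available human data (craniofacial, heart, limb).

Each record is evaluated at each stage only while still unrecovered, only
where the stage applies, and only where data are available; the first
recovering stage wins, so terminal states partition the input. Per-stage
availability is tracked explicitly so that "could not be recovered despite
data being available" is a computable statement, not an anecdote.

Availability vs. applicability: a stage's *data type* can be available for a
record (a dataset of that kind covers the element) even when the stage cannot
assess it (e.g. single-cell data exist but not for the record's tissue, or
human data exist for the tissue but the element is mouse-derived). Assessment
requires applicability AND availability; the ">= 2 of 3 data types available"
summary counts data-type availability alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classification import TestedElement, round_half_away
from .intervals import (
    ChainAlignment,
    GenomicInterval,
    PeakCollection,
    intersect_elements,
    map_interval,
)

__all__ = [
    "EARLIER_BULK",
    "SINGLE_CELL",
    "CROSS_SPECIES",
    "STAGE_ORDER",
    "TERMINAL_STATES",
    "CascadeStage",
    "CascadeResult",
    "run_cascade",
    "stages_from_bundle",
    "ccre_overlap_analysis",
]

EARLIER_BULK = "EARLIER_BULK"
SINGLE_CELL = "SINGLE_CELL"
CROSS_SPECIES = "CROSS_SPECIES"
STAGE_ORDER = (EARLIER_BULK, SINGLE_CELL, CROSS_SPECIES)
TERMINAL_STATES = (
    "RECOVERED_EARLIER_BULK",
    "RECOVERED_SINGLE_CELL",
    "RECOVERED_CROSS_SPECIES",
    "UNRECOVERED",
)


@dataclass
class CascadeStage:
    """One recovery stage: peak resources keyed by tissue, plus gating rules.

    ``resources`` maps tissue -> peak collections searched for overlap (>= 1 bp
    by default). ``availability``, when given, is a per-(element_id, tissue)
    boolean overriding the tissue-level default "data exist for this tissue";
    records absent from the mapping count as unavailable. ``human_only``
    restricts applicability to human-derived elements (the cross-species
    stage). ``chains`` lift elements onto the resources' assembly when it
    differs from the elements' own.
    """

    stage_id: str
    resources: Mapping[str, Sequence[PeakCollection]]
    availability: Optional[Mapping[Tuple[str, str], bool]] = None
    human_only: bool = False
    chains: Optional[Sequence[ChainAlignment]] = None
    min_match: float = 0.1

    def __post_init__(self) -> None:
        if self.stage_id not in STAGE_ORDER:
            raise ValueError(f"unknown stage id {self.stage_id!r}")

    def tissue_has_data(self, tissue: str) -> bool:
        return bool(self.resources.get(tissue))

    def data_available(self, element_id: str, tissue: str) -> bool:
        """Is this stage's *data type* available for the record?

        Ignores the origin-species gate deliberately: human tissue data for the
        limb are "available data" for a mouse-derived limb enhancer even though
        this stage does not assess it.
        """
        if self.availability is not None:
            return bool(self.availability.get((element_id, tissue), False))
        return self.tissue_has_data(tissue)

    def applies_to(self, element: TestedElement, tissue: str) -> bool:
        if self.human_only and element.origin_species != "human":
            return False
        return self.tissue_has_data(tissue)

    def _target_assembly(self) -> str:
        for pcs in self.resources.values():
            for pc in pcs:
                if pc.meta.assembly:
                    return pc.meta.assembly
        return ""

    def overlaps(self, element: TestedElement, tissue: str, min_overlap: int = 1) -> bool:
        """Does the element overlap any resource peak set for the tissue?"""
        span: Optional[GenomicInterval] = element.interval
        target = self._target_assembly()
        if target and span.assembly and span.assembly != target:
            if self.chains is None:
                raise ValueError(
                    f"stage {self.stage_id}: element {element.id} on {span.assembly} "
                    f"but resources on {target}; supply chains"
                )
            span = map_interval(span, self.chains, min_match=self.min_match)
            if span is None:
                return False
        for pc in self.resources.get(tissue, ()):
            if intersect_elements([span], pc, min_overlap=min_overlap)[0] >= 1:
                return True
        return False


@dataclass
class CascadeResult:
    """Per-record terminal states with per-stage flags, plus derived summaries.

    ``table`` has one row per input record: ``element_id``, ``tissue``,
    ``origin``, ``terminal``, and per stage ``<stage>_applicable``,
    ``<stage>_available``, ``<stage>_assessed``, ``<stage>_recovered``.
    ``summary`` reports counts and starting-set-relative percentages.
    """

    table: pd.DataFrame
    stage_ids: Tuple[str, ...]
    summary: Dict[str, object] = field(default_factory=dict)


def _validate_stages(stages: Sequence[CascadeStage]) -> Tuple[str, ...]:
    ids = tuple(s.stage_id for s in stages)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate cascade stages: {ids}")
    positions = [STAGE_ORDER.index(i) for i in ids]
    if positions != sorted(positions):
        raise ValueError(f"stages out of order {ids}; required order {STAGE_ORDER}")
    return ids


def run_cascade(
    hidden: Sequence[Tuple[TestedElement, str]],
    stages: Sequence[CascadeStage],
    min_overlap: int = 1,
) -> CascadeResult:
    """Evaluate hidden (element, tissue) records through the ordered stages.

    Recovery at a stage means >= ``min_overlap`` bp overlap with any of the
    stage's tissue-matched peak sets; recovered states are mutually exclusive
    (first recovering stage wins) and together with ``UNRECOVERED`` partition
    the input exactly. All percentages are reported relative to the starting
    hidden set, not to per-stage survivors.
    """
    stage_ids = _validate_stages(stages)
    rows: List[Dict[str, object]] = []
    for element, tissue in hidden:
        rec: Dict[str, object] = {
            "element_id": element.id,
            "tissue": tissue,
            "origin": element.origin_species,
            "terminal": "UNRECOVERED",
        }
        recovered = False
        for stage in stages:
            applicable = stage.applies_to(element, tissue)
            available = stage.data_available(element.id, tissue)
            assessed = (not recovered) and applicable and available
            hit = False
            if assessed:
                hit = stage.overlaps(element, tissue, min_overlap=min_overlap)
                if hit:
                    recovered = True
                    rec["terminal"] = f"RECOVERED_{stage.stage_id}"
            rec[f"{stage.stage_id}_applicable"] = applicable
            rec[f"{stage.stage_id}_available"] = available
            rec[f"{stage.stage_id}_assessed"] = assessed
            rec[f"{stage.stage_id}_recovered"] = hit
        rows.append(rec)

    cols = ["element_id", "tissue", "origin", "terminal"] + [
        f"{sid}_{suffix}"
        for sid in stage_ids
        for suffix in ("applicable", "available", "assessed", "recovered")
    ]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)

    n = len(table)
    summary: Dict[str, object] = {"n_input": n}
    for state in TERMINAL_STATES:
        c = int((table["terminal"] == state).sum()) if n else 0
        summary[state] = c
        summary[f"{state}_pct"] = round_half_away(100 * c / n) if n else 0
    for sid in stage_ids:
        summary[f"{sid}_assessed"] = int(table[f"{sid}_assessed"].sum()) if n else 0
        summary[f"{sid}_recovered"] = int(table[f"{sid}_recovered"].sum()) if n else 0
    if n:
        unrec = table["terminal"] == "UNRECOVERED"
        avail_cols = [f"{sid}_available" for sid in stage_ids]
        n_types = table[avail_cols].sum(axis=1) if avail_cols else pd.Series(0, index=table.index)
        summary["unrecovered_ge2_types_available"] = int((unrec & (n_types >= 2)).sum())
        if f"{SINGLE_CELL}_available" in table.columns:
            sc = table[f"{SINGLE_CELL}_available"]
            summary["unrecovered_no_single_cell"] = int((unrec & ~sc).sum())
    else:
        summary["unrecovered_ge2_types_available"] = 0
        summary["unrecovered_no_single_cell"] = 0

    assert sum(summary[s] for s in TERMINAL_STATES) == n
    return CascadeResult(table=table, stage_ids=stage_ids, summary=summary)


def stages_from_bundle(bundle) -> List[CascadeStage]:
    """Wire the three cascade stages from a bundle's peak resources.

    Accepts any object with ``peaksets`` (peak collections tagged by
    tissue/mark/stage), ``availability`` (per-(element, tissue) single-cell
    coverage flags) and ``chains`` (lift-over for cross-species resources):
    both synthetic bundles and fixtures qualify. Stage membership is derived
    from the tags -- E10.5 H3K27ac/H3K4me1 feed the earlier-bulk stage,
    single-cell accessibility peaks the single-cell stage, human-species
    collections the cross-species stage.
    """
    bulk: Dict[str, List[PeakCollection]] = {}
    sc: Dict[str, List[PeakCollection]] = {}
    xs: Dict[str, List[PeakCollection]] = {}
    for pc in bundle.peaksets:
        m = pc.meta
        if m.species == "human":
            xs.setdefault(m.tissue, []).append(pc)
        elif m.mark in ("scATAC", "snATAC"):
            sc.setdefault(m.tissue, []).append(pc)
        elif m.stage == "E10.5" and m.mark in ("H3K27ac", "H3K4me1"):
            bulk.setdefault(m.tissue, []).append(pc)
    return [
        CascadeStage(EARLIER_BULK, bulk),
        CascadeStage(SINGLE_CELL, sc, availability=bundle.availability or None),
        CascadeStage(CROSS_SPECIES, xs, human_only=True, chains=bundle.chains or None),
    ]


def ccre_overlap_analysis(
    hidden: Sequence[TestedElement],
    negatives: Sequence[TestedElement],
    catalog: PeakCollection,
    chains: Optional[Sequence[ChainAlignment]] = None,
    min_overlap: int = 1,
    min_match: float = 0.1,
) -> Dict[str, object]:
    """Overlap of hidden enhancers and transgenic negatives with a cCRE catalog.

    Both element sets are lifted to the catalog assembly where needed;
    unmappable elements are excluded from the denominators and reported. The
    catalog is typically a broad multi-tissue collection of enhancer-like
    signatures, so the negative-set fraction doubles as a specificity control:
    a catalog covering most *negative* elements has little predictive power.
    """
    if not hidden or not negatives:
        raise ValueError("hidden and negative element sets must be non-empty")

    target = catalog.meta.assembly

    def _mapped(elements: Sequence[TestedElement]) -> Tuple[List[GenomicInterval], int]:
        spans: List[GenomicInterval] = []
        n_unmapped = 0
        for el in elements:
            iv = el.interval
            if target and iv.assembly and iv.assembly != target:
                if chains is None:
                    raise ValueError(
                        f"element {el.id} on {iv.assembly} but catalog on {target}; "
                        "supply chains for lift-over"
                    )
                mapped = map_interval(iv, chains, min_match=min_match)
                if mapped is None:
                    n_unmapped += 1
                    continue
                spans.append(mapped)
            else:
                spans.append(iv)
        return spans, n_unmapped

    out: Dict[str, object] = {}
    for label, elements in (("hidden", hidden), ("negative", negatives)):
        spans, n_unmapped = _mapped(elements)
        if spans:
            hits = intersect_elements(spans, catalog, min_overlap=min_overlap) >= 1
            n_overlap = int(hits.sum())
        else:
            n_overlap = 0
        n_mappable = len(spans)
        frac = n_overlap / n_mappable if n_mappable else 0.0
        out[f"{label}_n_input"] = len(elements)
        out[f"{label}_n_unmappable"] = n_unmapped
        out[f"{label}_n_mappable"] = n_mappable
        out[f"{label}_n_overlap"] = n_overlap
        out[f"{label}_fraction"] = frac
        out[f"{label}_percent"] = round_half_away(100 * frac)
    return out
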