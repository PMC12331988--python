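"""Synthetic input bundles with known ground truth.

The generator emulates every input the analysis consumes -- tested-element
tables with per-tissue activity calls, tissue/mark/stage peak tracks with a
controlled fraction of mark-free ("hidden") activities, earlier-stage and
single-cell recovery resources, a cross-assembly chain, a stepwise
conservation track with an uplift inside active enhancers, repeat annotations
and a broad cCRE-style catalog -- and records the planted truth for every
(element, tissue) row so that pipeline output can be checked exactly.

Planting is constructive, not rejection-sampled: elements sit on a spacing
grid with guard zones, mark peaks are placed *inside* marked elements only,
and background peaks are confined to inter-element gaps with clearance, so a
row drawn "hidden" is guaranteed peak-free across all canonical marks under
the >= 1 bp overlap rule. Two runs with the same seed produce byte-identical
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classification import (
    CANONICAL_MARKS,
    TISSUES,
    TestedElement,
    write_elements_tsv,
)
from .feature_stats import REPEAT_CLASSES, RepeatAnnotation, ScoreTrack
from .intervals import (
    ChainAlignment,
    GenomicInterval,
    PeakCollection,
    PeakMeta,
    write_bed,
    write_chain,
)

__all__ = ["GeneratorConfig", "SyntheticBundle", "generate", "identity_chain_with_gaps"]


@dataclass
class GeneratorConfig:
    """Knobs of the stated synthetic world.

    Defaults mirror the study's observed conditions where stated: six tissues
    scored per element, a hidden fraction of 0.14 among positive activities,
    E10.5 bulk recovery probability 0.56, single-cell data for forebrain and
    hindbrain with recovery probability 0.18, human-origin fraction 0.76 with
    human data for craniofacial/heart/limb and recovery probability 0.20, and
    cCRE coverage of 0.90 for active and 0.82 for inactive elements.
    Geometry values (element length 1500 bp, 2 kb peaks bound, 10 kb spacing)
    are desk-scale choices documented in the methods note.
    """

    seed: int = 0
    genome: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 8_000_000, "chr2": 8_000_000}
    )
    assembly: str = "mm10"
    n_elements: int = 400
    element_length: int = 1500
    spacing: int = 10_000
    margin: int = 50_000
    clearance: int = 200
    tissues: Tuple[str, ...] = TISSUES
    activity_prob: float = 0.2
    hidden_fraction: float = 0.14
    mark_prob: float = 0.75
    extra_peaks_rate: float = 0.3
    peak_length_mean: int = 700
    peak_length_sd: int = 120
    background_peaks_per_mb: float = 5.0
    earlier_recovery_prob: float = 0.56
    single_cell_tissues: Tuple[str, ...] = ("forebrain", "hindbrain")
    single_cell_recovery_prob: float = 0.18
    human_fraction: float = 0.76
    human_data_tissues: Tuple[str, ...] = ("craniofacial", "heart", "limb")
    cross_species_recovery_prob: float = 0.20
    chain_offset: int = 1_000_000
    unmappable_fraction: float = 0.0
    conservation_step: int = 500
    conservation_baseline_a: float = 0.25
    conservation_baseline_b: float = 3.0
    conservation_uplift: float = 0.40
    repeats_per_mb: Mapping[str, float] = field(
        default_factory=lambda: {"SINE": 120.0, "LINE": 60.0, "DNA": 30.0, "LTR": 40.0, "other": 20.0}
    )
    ccre_active_rate: float = 0.90
    ccre_inactive_rate: float = 0.82
    include_conservation: bool = True
    include_repeats: bool = True
    include_ccre: bool = True

    def validate(self) -> None:
        for name in (
            "activity_prob",
            "hidden_fraction",
            "mark_prob",
            "earlier_recovery_prob",
            "single_cell_recovery_prob",
            "human_fraction",
            "cross_species_recovery_prob",
            "unmappable_fraction",
            "ccre_active_rate",
            "ccre_inactive_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.element_length + 2 * self.clearance >= self.spacing:
            raise ValueError(
                "unsatisfiable geometry: spacing must exceed element length plus "
                "clearance on both sides (hidden rows could not be kept peak-free)"
            )


@dataclass
class SyntheticBundle:
    """Everything one analysis run consumes, plus the planted ground truth.

    ``ground_truth`` has one row per positive (element, tissue) activity with
    the planted category bits and cascade flags; ``availability`` carries the
    per-(element, tissue) single-cell coverage flags consumed by the cascade.
    """

    genome: Dict[str, int]
    assembly: str
    elements: List[TestedElement]
    peaksets: List[PeakCollection]
    chains: List[ChainAlignment]
    ground_truth: pd.DataFrame
    availability: Dict[Tuple[str, str], bool] = field(default_factory=dict)
    conservation: Optional[ScoreTrack] = None
    repeats: Optional[RepeatAnnotation] = None
    ccre: Optional[PeakCollection] = None

    def peaks(self, tissue: str, mark: str, stage: str) -> List[PeakCollection]:
        return [
            pc
            for pc in self.peaksets
            if pc.meta.tissue == tissue and pc.meta.mark == mark and pc.meta.stage == stage
        ]

    def write(self, outdir) -> Dict[str, str]:
        """Write the bundle as plain-text standard formats; returns a manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: Dict[str, str] = {}

        with open(out / "genome.tsv", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f"{chrom}\t{self.genome[chrom]}\n")
        manifest["genome"] = str(out / "genome.tsv")

        write_elements_tsv(self.elements, out / "elements.tsv")
        manifest["elements"] = str(out / "elements.tsv")

        peak_dir = out / "peaks"
        peak_dir.mkdir(exist_ok=True)
        for pc in self.peaksets:
            m = pc.meta
            name = f"{m.species}_{m.assembly}_{m.tissue}_{m.mark}_{m.stage}.narrowPeak"
            write_bed(pc, peak_dir / name, "narrowPeak")
            manifest[f"peaks/{name}"] = str(peak_dir / name)

        if self.chains:
            by_pair: Dict[Tuple[str, str], List[ChainAlignment]] = {}
            for ch in self.chains:
                by_pair.setdefault((ch.source_assembly, ch.target_assembly), []).append(ch)
            for (src, tgt), chs in by_pair.items():
                name = f"{src or 'src'}_to_{tgt or 'tgt'}.chain"
                write_chain(chs, out / name)
                manifest[f"chain/{name}"] = str(out / name)

        if self.conservation is not None:
            self.conservation.to_bedgraph(out / "conservation.bedGraph")
            manifest["conservation"] = str(out / "conservation.bedGraph")
        if self.repeats is not None:
            self.repeats.to_bed(out / "repeats.bed")
            manifest["repeats"] = str(out / "repeats.bed")
        if self.ccre is not None:
            write_bed(self.ccre, out / "ccre.bed", "bed3")
            manifest["ccre"] = str(out / "ccre.bed")

        self.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        manifest["ground_truth"] = str(out / "ground_truth.tsv")
        if self.availability:
            av = pd.DataFrame(
                [(e, t, int(v)) for (e, t), v in sorted(self.availability.items())],
                columns=["element_id", "tissue", "single_cell_available"],
            )
            av.to_csv(out / "availability.tsv", sep="\t", index=False)
            manifest["availability"] = str(out / "availability.tsv")
        return manifest


def identity_chain_with_gaps(
    chrom: str,
    size: int,
    gaps: Sequence[Tuple[int, int]],
    offset: int = 0,
    source_assembly: str = "",
    target_assembly: str = "",
    target_chrom: Optional[str] = None,
    score: int = 1000,
) -> ChainAlignment:
    """Chain mapping ``x -> x + offset`` everywhere except inside ``gaps``.

    Gap spans (half-open, sorted, non-overlapping, strictly inside the
    chromosome) are skipped on both genomes, so queries inside a gap are
    unmappable while everything else lifts by a constant offset.
    """
    gaps = sorted(gaps)
    blocks: List[Tuple[int, int, int]] = []
    cur = 0
    for g0, g1 in gaps:
        if not (0 < g0 < g1 < size):
            raise ValueError(f"gap ({g0}, {g1}) not strictly inside [0, {size})")
        if g0 < cur:
            raise ValueError("gaps must be sorted and non-overlapping")
        if g0 > cur:
            blocks.append((g0 - cur, g1 - g0, g1 - g0))
        else:
            # adjacent gap: extend the previous gap instead of a zero block
            sz, ds, dt = blocks[-1]
            blocks[-1] = (sz, ds + (g1 - g0), dt + (g1 - g0))
        cur = g1
    blocks.append((size - cur, 0, 0))
    return ChainAlignment(
        score=score,
        source_chrom=chrom,
        source_size=size,
        source_start=0,
        source_end=size,
        target_chrom=target_chrom or chrom,
        target_size=size + offset,
        target_strand="+",
        target_start=offset,
        target_end=size + offset,
        blocks=tuple(blocks),
        source_assembly=source_assembly,
        target_assembly=target_assembly,
    )


def _element_slots(config: GeneratorConfig) -> List[Tuple[str, int]]:
    slots: List[Tuple[str, int]] = []
    for chrom in sorted(config.genome):
        size = config.genome[chrom]
        pos = config.margin
        while pos + config.spacing <= size - config.margin:
            slots.append((chrom, pos))
            pos += config.spacing
    return slots


def generate(config: Optional[GeneratorConfig] = None) -> SyntheticBundle:
    """Draw one complete synthetic bundle from the configured world.

    For each positive (element, tissue) row a Bernoulli(1 - hidden_fraction)
    draw decides "marked"; marked rows receive at least one peak in at least
    one canonical mark (per-mark presence ~ Bernoulli(mark_prob), conditioned
    on >= 1), hidden rows receive none and are shielded from background peaks
    by the grid geometry. Cascade resources, conservation, repeats, the cCRE
    catalog and the lift-over chain are planted analogously; everything is a
    deterministic function of ``config.seed``.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    slots = _element_slots(config)
    if config.n_elements > len(slots):
        raise ValueError(
            f"unsatisfiable geometry: {config.n_elements} elements need more room "
            f"than the genome offers ({len(slots)} slots)"
        )
    tissues = list(config.tissues)
    n_t = len(tissues)

    # --- elements and activity calls -------------------------------------
    elements: List[TestedElement] = []
    spans: List[GenomicInterval] = []
    for i in range(config.n_elements):
        chrom, pos = slots[i]
        start = pos + int(rng.integers(0, config.spacing - config.element_length - 2 * config.clearance))
        start += config.clearance
        iv = GenomicInterval(chrom, start, start + config.element_length, config.assembly)
        spans.append(iv)

    activity = rng.random((config.n_elements, n_t)) < config.activity_prob
    for i in range(config.n_elements):
        if not activity[i].any():
            activity[i, int(rng.integers(0, n_t))] = True
    origin = np.where(rng.random(config.n_elements) < config.human_fraction, "human", "mouse")
    unmappable = rng.random(config.n_elements) < config.unmappable_fraction

    for i in range(config.n_elements):
        calls = {t: ("positive" if activity[i, j] else "negative") for j, t in enumerate(tissues)}
        elements.append(
            TestedElement(
                id=f"syn{i:05d}",
                interval=spans[i],
                origin_species=str(origin[i]),
                activity=calls,
            )
        )

    # --- per-row planting --------------------------------------------------
    peak_acc: Dict[Tuple[str, str, str, str, str], Tuple[List[GenomicInterval], List[float]]] = {}

    def _plant(species: str, assembly: str, tissue: str, mark: str, stage: str,
               lo: int, hi: int, chrom: str) -> None:
        L = int(np.clip(rng.normal(config.peak_length_mean, config.peak_length_sd), 150, None))
        start = int(rng.integers(lo, max(lo + 1, hi - L)))
        key = (species, assembly, tissue, mark, stage)
        ivs, sigs = peak_acc.setdefault(key, ([], []))
        ivs.append(GenomicInterval(chrom, start, start + L, assembly))
        sigs.append(float(rng.gamma(2.0, 4.0)))

    truth_rows: List[Dict[str, object]] = []
    availability: Dict[Tuple[str, str], bool] = {}
    sc_tissues = set(config.single_cell_tissues)
    human_tissues = set(config.human_data_tissues)

    for i, el in enumerate(elements):
        iv = el.interval
        for j, tissue in enumerate(tissues):
            if not activity[i, j]:
                continue
            hidden = bool(rng.random() < config.hidden_fraction)
            bits = {m: 0 for m in CANONICAL_MARKS}
            if not hidden:
                present = rng.random(len(CANONICAL_MARKS)) < config.mark_prob
                if not present.any():
                    present[int(rng.integers(0, len(CANONICAL_MARKS)))] = True
                for k, mark in enumerate(CANONICAL_MARKS):
                    if not present[k]:
                        continue
                    n_peaks = 1 + int(rng.poisson(config.extra_peaks_rate))
                    bits[mark] = n_peaks
                    for _ in range(n_peaks):
                        _plant("mouse", config.assembly, tissue, mark, "E11.5",
                               iv.start, iv.end, iv.chrom)
            # cascade flags (meaningful for hidden rows; planted for all)
            earlier = bool(hidden and rng.random() < config.earlier_recovery_prob)
            if earlier:
                mark = "H3K27ac" if rng.random() < 0.5 else "H3K4me1"
                _plant("mouse", config.assembly, tissue, mark, "E10.5",
                       iv.start, iv.end, iv.chrom)
            sc_avail = tissue in sc_tissues
            availability[(el.id, tissue)] = sc_avail
            sc_rec = bool(
                hidden and not earlier and sc_avail
                and rng.random() < config.single_cell_recovery_prob
            )
            if sc_rec:
                _plant("mouse", config.assembly, tissue, "scATAC", "E11.5",
                       iv.start, iv.end, iv.chrom)
            xs_applicable = (
                el.origin_species == "human" and tissue in human_tissues and not unmappable[i]
            )
            xs_rec = bool(
                hidden and not earlier and not sc_rec and xs_applicable
                and rng.random() < config.cross_species_recovery_prob
            )
            if xs_rec:
                _plant("human", "hg38", tissue, "H3K27ac", "similar-stage",
                       iv.start + config.chain_offset, iv.end + config.chain_offset, iv.chrom)
            truth_rows.append(
                {
                    "element_id": el.id,
                    "tissue": tissue,
                    "origin": el.origin_species,
                    "hidden": hidden,
                    **{f"n_{m}": bits[m] for m in CANONICAL_MARKS},
                    "earlier_recovered": earlier,
                    "single_cell_available": sc_avail,
                    "single_cell_recovered": sc_rec,
                    "cross_species_recovered": xs_rec,
                }
            )

    # --- background peaks in inter-element gaps ---------------------------
    gap_zones: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.genome}
    by_chrom: Dict[str, List[GenomicInterval]] = {c: [] for c in config.genome}
    for iv in spans:
        by_chrom[iv.chrom].append(iv)
    for chrom, size in config.genome.items():
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur = 0
        for iv in ivs:
            lo, hi = cur, iv.start - config.clearance
            if hi - lo > 2000:
                gap_zones[chrom].append((lo, hi))
            cur = iv.end + config.clearance
        if size - cur > 2000:
            gap_zones[chrom].append((cur, size))

    def _background(species: str, assembly: str, tissue: str, mark: str, stage: str) -> None:
        for chrom, zones in gap_zones.items():
            if not zones:
                continue
            zone_lens = np.array([hi - lo for lo, hi in zones], dtype=float)
            n_bg = int(rng.poisson(config.background_peaks_per_mb * zone_lens.sum() / 1e6))
            for _ in range(n_bg):
                zi = int(rng.choice(len(zones), p=zone_lens / zone_lens.sum()))
                lo, hi = zones[zi]
                _plant(species, assembly, tissue, mark, stage, lo, hi - 1500, chrom)

    for tissue in tissues:
        for mark in CANONICAL_MARKS:
            _background("mouse", config.assembly, tissue, mark, "E11.5")
        for mark in ("H3K27ac", "H3K4me1"):
            _background("mouse", config.assembly, tissue, mark, "E10.5")

    # Every (tissue, mark, stage) the classifier needs must exist, even if empty.
    for tissue in tissues:
        for mark in CANONICAL_MARKS:
            peak_acc.setdefault(("mouse", config.assembly, tissue, mark, "E11.5"), ([], []))
        for mark in ("H3K27ac", "H3K4me1"):
            peak_acc.setdefault(("mouse", config.assembly, tissue, mark, "E10.5"), ([], []))
    for tissue in sc_tissues:
        peak_acc.setdefault(("mouse", config.assembly, tissue, "scATAC", "E11.5"), ([], []))
    for tissue in human_tissues:
        peak_acc.setdefault(("human", "hg38", tissue, "H3K27ac", "similar-stage"), ([], []))

    peaksets = [
        PeakCollection(
            PeakMeta(
                species=sp,
                assembly=asm,
                tissue=t,
                mark=m,
                stage=st,
                dataset_id=f"synth_{sp}_{t}_{m}_{st}",
            ),
            ivs,
            sigs,
        )
        for (sp, asm, t, m, st), (ivs, sigs) in sorted(peak_acc.items())
    ]

    # --- chain (source assembly -> hg38 analogue) -------------------------
    chains: List[ChainAlignment] = []
    gaps_by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in config.genome}
    for i, iv in enumerate(spans):
        if unmappable[i]:
            gaps_by_chrom[iv.chrom].append((iv.start - 10, iv.end + 10))
    for chrom, size in sorted(config.genome.items()):
        chains.append(
            identity_chain_with_gaps(
                chrom,
                size,
                sorted(gaps_by_chrom[chrom]),
                offset=config.chain_offset,
                source_assembly=config.assembly,
                target_assembly="hg38",
            )
        )

    # --- conservation track -----------------------------------------------
    conservation = None
    if config.include_conservation:
        positive_any = activity.any(axis=1)
        track_data: Dict[str, Tuple[List[int], List[int], List[float]]] = {}
        for chrom, size in sorted(config.genome.items()):
            n_bins = size // config.conservation_step
            vals = rng.beta(config.conservation_baseline_a, config.conservation_baseline_b, size=n_bins)
            starts = np.arange(n_bins, dtype=np.int64) * config.conservation_step
            ends = starts + config.conservation_step
            for i, iv in enumerate(spans):
                if iv.chrom != chrom or not positive_any[i]:
                    continue
                b0 = iv.start // config.conservation_step
                b1 = -(-iv.end // config.conservation_step)
                vals[b0:b1] = np.minimum(1.0, vals[b0:b1] + config.conservation_uplift)
            track_data[chrom] = (list(starts), list(ends), list(vals))
        conservation = ScoreTrack(track_data, assembly=config.assembly)

    # --- repeats ------------------------------------------------------------
    repeats = None
    if config.include_repeats:
        rep_iv: List[GenomicInterval] = []
        rep_cls: List[str] = []
        rep_fam: List[str] = []
        rep_name: List[str] = []
        typical_len = {"SINE": 180, "LINE": 900, "DNA": 350, "LTR": 450, "other": 250}
        for chrom, size in sorted(config.genome.items()):
            for cls_name in REPEAT_CLASSES:
                dens = config.repeats_per_mb.get(cls_name, 0.0)
                k = int(rng.poisson(dens * size / 1e6))
                for _ in range(k):
                    L = max(50, int(rng.exponential(typical_len[cls_name])))
                    start = int(rng.integers(0, max(1, size - L)))
                    rep_iv.append(GenomicInterval(chrom, start, start + L, config.assembly))
                    rep_cls.append(cls_name)
                    rep_fam.append(f"{cls_name}_fam")
                    rep_name.append(f"{cls_name}_{len(rep_iv)}")
        repeats = RepeatAnnotation(rep_iv, rep_cls, rep_fam, rep_name, assembly=config.assembly)

    # --- cCRE catalog -------------------------------------------------------
    ccre = None
    ccre_flags: Dict[str, bool] = {}
    if config.include_ccre:
        cat: List[GenomicInterval] = []
        for i, el in enumerate(elements):
            rate = config.ccre_active_rate if el.is_positive else config.ccre_inactive_rate
            covered = bool(rng.random() < rate)
            ccre_flags[el.id] = covered
            if covered:
                iv = el.interval
                mid = (iv.start + iv.end) // 2
                cat.append(GenomicInterval(iv.chrom, mid - 150, mid + 150, config.assembly))
        ccre = PeakCollection(
            PeakMeta(species="pooled", assembly=config.assembly, mark="cCRE-ELS", dataset_id="synth_ccre"),
            cat,
        )

    ground_truth = pd.DataFrame(truth_rows)
    if ccre_flags:
        ground_truth["ccre_covered"] = [
            ccre_flags.get(e, False) for e in ground_truth["element_id"]
        ]
    return SyntheticBundle(
        genome=dict(config.genome),
        assembly=config.assembly,
        elements=elements,
        peaksets=peaksets,
        chains=chains,
        ground_truth=ground_truth,
        availability=availability,
        conservation=conservation,
        repeats=repeats,
        ccre=ccre,
    )
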