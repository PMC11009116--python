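"""Perturbation footprints, fixed genomic binning, merging and interval-set statistics.

CRISPR perturbations act beyond the guide's 3-bp PAM anchor: Cas9 cutting
disrupts ~±10 bp while dCas9-KRAB spreads repressive chromatin over ~±150 bp.
Element-level analyses therefore expand each guide to its modality-specific
footprint before intersecting with fixed 100-bp bins tiled across the
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .screen_io import GenomicInterval, GuideRecord, ScreenFormatError

#: hg38 effective genome size (bp) used for genome-fraction reporting
EFFECTIVE_GENOME_SIZE = 3_088_269_832

#: modality -> half-width (bp) of the perturbation footprint around the PAM
FOOTPRINT_HALF_WIDTH = {
    "cas9": 10,
    "dcas9": 10,
    "dcas9_krab": 150,
    # no published value; same epigenetic-window rationale as dCas9-KRAB
    "dcas9_activator": 150,
}


class IntervalError(ValueError):
    pass


@dataclass
class BinGrid:
    """Fixed-width bins on each chromosome.

    With ``anchor="chromosome_zero"`` bin k on a chromosome is
    [k*bin_size, (k+1)*bin_size).  ``anchor="library_upstream"`` instead
    starts the first bin at the most upstream coordinate among the supplied
    anchor positions (one per chromosome), mirroring tools that tile from the
    first guide of the library.
    """

    bin_size: int = 100
    anchor: str = "chromosome_zero"
    anchor_positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise IntervalError("bin_size must be positive")
        if self.anchor not in ("chromosome_zero", "library_upstream"):
            raise IntervalError(f"unknown anchor {self.anchor!r}")

    def origin(self, chrom: str) -> int:
        if self.anchor == "chromosome_zero":
            return 0
        if chrom not in self.anchor_positions:
            raise KeyError(f"no anchor position for chromosome {chrom}")
        return self.anchor_positions[chrom]

    def bins_overlapping(self, interval: GenomicInterval) -> list[GenomicInterval]:
        """All grid bins overlapping the interval by >=1 bp."""
        origin = self.origin(interval.chrom)
        first = (interval.start - origin) // self.bin_size
        last = (interval.end - 1 - origin) // self.bin_size
        out = []
        for k in range(first, last + 1):
            start = origin + k * self.bin_size
            if start < 0:
                continue
            out.append(GenomicInterval(interval.chrom, start, start + self.bin_size))
        return out


def expand_footprint(guide: GuideRecord, modality: str) -> GenomicInterval:
    """Expand a guide's 3-bp PAM window to its modality perturbation footprint.

    Returns [pam_start − w, pam_end + w) with the start clamped at 0.
    """
    if not guide.has_coordinates:
        raise IntervalError(f"guide {guide.guide_id} has no coordinates")
    if modality not in FOOTPRINT_HALF_WIDTH:
        raise IntervalError(f"unknown modality {modality!r}")
    w = FOOTPRINT_HALF_WIDTH[modality]
    return GenomicInterval(
        guide.chrom,
        max(0, guide.pam_start - w),
        guide.pam_end + w,
        name=guide.guide_id,
        strand=guide.strand,
    )


def tile_and_assign(
    intervals: Sequence[GenomicInterval], grid: BinGrid
) -> dict[tuple[str, int, int], list[str]]:
    """Assign each interval to every grid bin it overlaps by >=1 bp.

    Returns {(chrom, bin_start, bin_end): [interval names]}.  Intervals
    spanning multiple bins contribute to each of them.
    """
    assignment: dict[tuple[str, int, int], list[str]] = {}
    for i, iv in enumerate(intervals):
        name = iv.name if iv.name is not None else str(i)
        for b in grid.bins_overlapping(iv):
            assignment.setdefault((b.chrom, b.start, b.end), []).append(name)
    return assignment


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 1
) -> tuple[list[GenomicInterval], int]:
    """Merge intervals separated by <= max_gap bp (bedtools merge -d semantics).

    Input may be unsorted.  Returns (sorted disjoint merged intervals,
    total merged bp).
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    total_bp = sum(len(iv) for iv in merged)
    return merged, total_bp


def genome_fraction(total_bp: int, genome_size: int = EFFECTIVE_GENOME_SIZE) -> float:
    return total_bp / genome_size


def _coverage_and_intersection(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> tuple[int, int, int]:
    """Nucleotide coverage of A, of B, and of their intersection (merged)."""
    a, bp_a = merge_intervals(set_a, max_gap=0)
    b, bp_b = merge_intervals(set_b, max_gap=0)
    inter = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in a:
        for jv in by_chrom.get(iv.chrom, []):
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if hi > lo:
                inter += hi - lo
    return bp_a, bp_b, inter


def jaccard_similarity(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> float:
    """Nucleotide-level Jaccard |A∩B| / |A∪B| over merged coverages.

    Defined as 0 when both sets are empty.
    """
    bp_a, bp_b, inter = _coverage_and_intersection(set_a, set_b)
    union = bp_a + bp_b - inter
    if union == 0:
        return 0.0
    return inter / union


def overlap_enrichment(
    features: Sequence[GenomicInterval],
    hits: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
) -> tuple[float, float, list[list[int]]]:
    """Fisher-exact enrichment of feature overlap among hit vs non-hit regions.

    The universe is the set of perturbed regions (typically merged 100-bp
    bins).  Each universe region is cross-classified as hit (overlapping a
    significant element) or not, and feature-marked (overlapping an
    annotation feature) or not; the two-sided Fisher exact test is run on
    that 2x2 table.  Features wholly outside the universe never contribute.
    Returns (odds ratio, two-sided p, table); an empty margin (e.g. hits ==
    universe) yields an infinite/undefined OR from the exact test.
    """
    universe_merged, bp_u = merge_intervals(universe, max_gap=0)
    if bp_u == 0:
        raise IntervalError("empty perturbed universe")
    hits_merged, _ = merge_intervals(hits, max_gap=0)
    feats_merged, _ = merge_intervals(features, max_gap=0)

    def overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
        return any(iv.overlaps(o) for o in others)

    if not any(overlaps_any(f, universe_merged) for f in feats_merged):
        raise IntervalError("no features overlap the perturbed universe")

    table = [[0, 0], [0, 0]]
    for region in universe:
        is_hit = overlaps_any(region, hits_merged)
        has_feat = overlaps_any(region, feats_merged)
        table[0 if is_hit else 1][0 if has_feat else 1] += 1
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if b * c == 0 and a > 0:
        odds = float("inf")
    return float(odds), float(p), table


def same_tad(
    cre: GenomicInterval,
    gene,
    tads: Sequence[GenomicInterval],
    promoter_halfwidth: int = 500,
) -> str:
    """Whether a CRE and its target gene's promoter share a TAD.

    The promoter window is TSS±promoter_halfwidth.  Returns "same",
    "different" or "cre_not_in_tad" (CREs outside every TAD are excluded
    from same/different classification).
    """
    for i, t in enumerate(tads):
        for u in tads[i + 1:]:
            if t.overlaps(u):
                raise IntervalError(
                    f"overlapping TADs {t.chrom}:{t.start}-{t.end} and "
                    f"{u.chrom}:{u.start}-{u.end}"
                )
    promoter = GenomicInterval(
        gene.chrom, gene.tss - promoter_halfwidth, gene.tss + promoter_halfwidth
    )
    cre_tads = [t for t in tads if t.overlaps(cre)]
    if not cre_tads:
        return "cre_not_in_tad"
    for t in cre_tads:
        if t.overlaps(promoter):
            return "same"
    return "different"
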