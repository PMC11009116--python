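"""Binned Fisher-aggregation CRE caller.

Per-guide two-sided p-values (a control-calibrated z-test by default, or
p-values ingested from an external differential-abundance tool) are combined
per 100-bp genomic bin with Fisher's method: X = −2·Σ ln p over the k guides
whose modality-expanded footprints overlap the bin, compared against a
chi-square distribution with 2k degrees of freedom.  Aggregated bin p-values
are Benjamini–Hochberg adjusted across all tested bins; significant bins
(FDR < 0.01 by default) are merged (gap ≤ 1 bp) into element calls.

The caller is deliberately sensitive to single strong guides; the
``outlier_sensitivity`` mode quantifies this by dropping the most significant
guide per bin and recalling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome_intervals import BinGrid, expand_footprint
from .guide_effects import EffectTable
from .screen_io import GenomicInterval, GuideRecord

MIN_CONTROL_GUIDES = 30
#: p=0 inputs (underflowed external tools) are clamped here, with a warning
P_FLOOR = 5e-324


class CallerError(ValueError):
    pass


@dataclass
class BinStat:
    """Fisher-aggregated statistics for one genomic bin."""

    bin: GenomicInterval
    guide_ids: list[str]
    fisher_stat: float
    aggregated_p: float
    mean_effect: float
    fdr: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.guide_ids)

    @property
    def df(self) -> int:
        return 2 * self.k


@dataclass
class CRECall:
    """A merged run of significant bins."""

    interval: GenomicInterval
    fdr: float
    aggregated_p: float
    mean_effect: float
    n_guides: int


def per_guide_pvalues(
    table: EffectTable,
    controls: Sequence[str],
    mode: str = "control_z",
    external: Mapping[str, float] | None = None,
) -> pd.Series:
    """Two-sided per-guide p-values.

    ``control_z``: z-test of each guide's replicate-mean effect against the
    mean/SD of the negative-control guides' replicate-mean effects
    (p = 2·Φ(−|e − μ0|/σ0)); requires ≥30 controls.  ``external``: validated
    passthrough of p-values computed elsewhere (e.g. DESeq2 Wald tests).
    """
    if mode == "external":
        if external is None:
            raise CallerError("external mode requires a p-value mapping")
        p = pd.Series(dict(external), name="p", dtype=float)
        bad = p[(p <= 0) | (p > 1)]
        if len(bad):
            raise CallerError(
                f"external p-values outside (0,1] for guides {list(bad.index)[:5]}"
            )
        return p
    if mode != "control_z":
        raise CallerError(f"unknown p-value mode {mode!r}")
    controls = [c for c in controls if c in table.data.index]
    if len(controls) < MIN_CONTROL_GUIDES:
        raise CallerError(
            f"control_z needs >={MIN_CONTROL_GUIDES} negative-control guides, "
            f"got {len(controls)}"
        )
    ctrl = table.data.loc[controls, "mean"]
    mu0 = float(ctrl.mean())
    sd0 = float(ctrl.std(ddof=1))
    if sd0 == 0:
        raise CallerError("control effects are constant; cannot calibrate z-test")
    z = (table.data["mean"] - mu0).abs() / sd0
    p = 2.0 * stats.norm.sf(z)
    return pd.Series(np.minimum(p, 1.0), index=table.data.index, name="p")


def fisher_aggregate(pvalues: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: returns (X = −2Σln p, chi-square upper-tail p at 2k df)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0):
        warnings.warn("p=0 input clamped to smallest positive float", RuntimeWarning)
        p = np.maximum(p, P_FLOOR)
    x = float(-2.0 * np.sum(np.log(p)))
    agg = float(stats.chi2.sf(x, df=2 * len(p)))
    return x, agg


def _assign_guides_to_bins(
    guides: Sequence[GuideRecord], grid: BinGrid, modality: str
) -> dict[tuple[str, int, int], list[str]]:
    assignment: dict[tuple[str, int, int], list[str]] = {}
    for g in guides:
        if not g.has_coordinates:
            continue
        fp = expand_footprint(g, modality)
        for b in grid.bins_overlapping(fp):
            assignment.setdefault((b.chrom, b.start, b.end), []).append(g.guide_id)
    return assignment


def aggregate_and_call(
    pvalues: Mapping[str, float],
    guides: Sequence[GuideRecord],
    grid: BinGrid,
    modality: str,
    fdr_threshold: float = 0.01,
    effects: Mapping[str, float] | None = None,
    direction: str | None = None,
) -> tuple[list[BinStat], list[CRECall]]:
    """Fisher-aggregate guide p-values per bin, BH-adjust, and merge calls.

    ``effects`` (per-guide replicate-mean effects) drive the reported
    mean_effect and, when ``direction`` is "positive"/"negative", the
    optional one-directional calling that only aggregates guides whose
    effect has the expected sign.
    """
    pvalues = dict(pvalues)
    assignment = _assign_guides_to_bins(
        [g for g in guides if g.guide_id in pvalues], grid, modality
    )
    bins: list[BinStat] = []
    for (chrom, start, end), members in sorted(assignment.items()):
        if direction is not None and effects is not None:
            sign = 1.0 if direction == "positive" else -1.0
            members = [m for m in members if sign * effects.get(m, 0.0) > 0]
            if not members:
                continue
        members = sorted(members)
        x, agg = fisher_aggregate([pvalues[m] for m in members])
        mean_eff = (
            float(np.mean([effects[m] for m in members]))
            if effects is not None
            else float("nan")
        )
        bins.append(
            BinStat(
                bin=GenomicInterval(chrom, start, end),
                guide_ids=members,
                fisher_stat=x,
                aggregated_p=agg,
                mean_effect=mean_eff,
            )
        )
    if not bins:
        return [], []
    agg_p = np.array([b.aggregated_p for b in bins])
    fdr = stats.false_discovery_control(agg_p, method="bh")
    for b, q in zip(bins, fdr):
        b.fdr = float(q)
    significant = [b for b in bins if b.fdr < fdr_threshold]
    calls = _merge_significant_bins(significant)
    return bins, calls


def _merge_significant_bins(significant: Sequence[BinStat]) -> list[CRECall]:
    calls: list[CRECall] = []
    current: list[BinStat] = []

    def flush() -> None:
        if not current:
            return
        chrom = current[0].bin.chrom
        start = current[0].bin.start
        end = current[-1].bin.end
        guide_ids = sorted({g for b in current for g in b.guide_ids})
        calls.append(
            CRECall(
                interval=GenomicInterval(
                    chrom, start, end, name=f"cre_{len(calls) + 1}"
                ),
                fdr=min(b.fdr for b in current),
                aggregated_p=min(b.aggregated_p for b in current),
                mean_effect=float(np.mean([b.mean_effect for b in current])),
                n_guides=len(guide_ids),
            )
        )

    for b in sorted(significant, key=lambda b: (b.bin.chrom, b.bin.start)):
        if (
            current
            and b.bin.chrom == current[-1].bin.chrom
            and b.bin.start - current[-1].bin.end <= 1
        ):
            current.append(b)
        else:
            flush()
            current = [b]
    flush()
    return calls


def outlier_sensitivity(
    pvalues: Mapping[str, float],
    guides: Sequence[GuideRecord],
    grid: BinGrid,
    modality: str,
    fdr_threshold: float = 0.01,
    effects: Mapping[str, float] | None = None,
) -> dict:
    """Recall after dropping the single most significant guide per bin.

    Removal happens independently in every bin (ties broken by guide_id);
    bins left with no guide become untested.  Returns the full and dropped
    bin/call sets plus the bins that lose significance.
    """
    bins_full, calls_full = aggregate_and_call(
        pvalues, guides, grid, modality, fdr_threshold, effects
    )
    pvalues = dict(pvalues)
    assignment = _assign_guides_to_bins(
        [g for g in guides if g.guide_id in pvalues], grid, modality
    )
    dropped_bins: list[BinStat] = []
    for (chrom, start, end), members in sorted(assignment.items()):
        members = sorted(members)
        best = min(members, key=lambda m: (pvalues[m], m))
        kept = [m for m in members if m != best]
        if not kept:
            continue
        x, agg = fisher_aggregate([pvalues[m] for m in kept])
        mean_eff = (
            float(np.mean([effects[m] for m in kept]))
            if effects is not None
            else float("nan")
        )
        dropped_bins.append(
            BinStat(
                bin=GenomicInterval(chrom, start, end),
                guide_ids=kept,
                fisher_stat=x,
                aggregated_p=agg,
                mean_effect=mean_eff,
            )
        )
    if dropped_bins:
        q = stats.false_discovery_control(
            np.array([b.aggregated_p for b in dropped_bins]), method="bh"
        )
        for b, qq in zip(dropped_bins, q):
            b.fdr = float(qq)
    sig_dropped = [b for b in dropped_bins if b.fdr < fdr_threshold]
    calls_dropped = _merge_significant_bins(sig_dropped)
    sig_full_keys = {
        (b.bin.chrom, b.bin.start) for b in bins_full if b.fdr < fdr_threshold
    }
    sig_drop_keys = {(b.bin.chrom, b.bin.start) for b in sig_dropped}
    lost = sorted(sig_full_keys - sig_drop_keys)
    return {
        "bins_full": bins_full,
        "calls_full": calls_full,
        "bins_dropped": dropped_bins,
        "calls_dropped": calls_dropped,
        "bins_losing_significance": lost,
    }
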