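"""Per-guide effect sizes from sorted-bin (or time-point) read counts.

Two estimators are provided, both with a fixed pseudocount of 1:

* ``mean_norm``:   e_i = log2((1 + A_i/mean(A)) / (1 + B_i/mean(B)))
* ``linear``:      e_i = log2(((1 + A_i)/sum(A)) / ((1 + B_i)/sum(B)))

where A and B are the per-guide read-count vectors of the low- and
high-expression sorting bins (or earlier/later time points).  Mean
normalization deliberately shrinks guides with few reads toward zero, which
makes it more reproducible between replicates at realistic depths.  Under the
default ``A_enriched_positive`` sign convention, expression-lowering
(or growth-depleting) guides get positive effects; ``B_enriched_positive``
flips the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_io import GenomicInterval, GuideRecord, ScreenDesign

PSEUDOCOUNT = 1.0


class EffectError(ValueError):
    pass


@dataclass
class EffectTable:
    """Per-guide, per-replicate effect sizes (log2 units) plus replicate means.

    ``data`` is indexed by guide_id with one ``rep<k>`` column per replicate
    comparison and a ``mean`` column (arithmetic mean over replicates).
    """

    data: pd.DataFrame
    method: str
    sign_convention: str
    pseudocount: float = PSEUDOCOUNT

    @property
    def guide_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def rep_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("rep")]

    def mean_effects(self) -> pd.Series:
        return self.data["mean"]


def effect_mean_norm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean-normalized log2 fold change per guide."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.log2((PSEUDOCOUNT + a / a.mean()) / (PSEUDOCOUNT + b / b.mean()))


def effect_linear(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear-transformed log2 fold change per guide."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.log2(((PSEUDOCOUNT + a) / a.sum()) / ((PSEUDOCOUNT + b) / b.sum()))


_METHODS = {"mean_norm": effect_mean_norm, "linear": effect_linear}


def compute_effects(
    guides: Sequence[GuideRecord],
    design: ScreenDesign,
    method: str = "mean_norm",
) -> EffectTable:
    """Compute per-replicate and replicate-mean effect sizes for every guide."""
    if method not in _METHODS:
        raise EffectError(f"unknown effect method {method!r}")
    fn = _METHODS[method]
    ids = [g.guide_id for g in guides]
    cols: dict[str, np.ndarray] = {}
    for k, (sample_a, sample_b) in enumerate(design.comparisons, start=1):
        a = np.array([g.counts[sample_a] for g in guides], dtype=float)
        b = np.array([g.counts[sample_b] for g in guides], dtype=float)
        if a.sum() == 0 or b.sum() == 0:
            raise EffectError(
                f"all-zero counts in sample {sample_a if a.sum() == 0 else sample_b}"
            )
        e = fn(a, b)
        if design.sign_convention == "B_enriched_positive":
            e = -e
        cols[f"rep{k}"] = e
    df = pd.DataFrame(cols, index=pd.Index(ids, name="guide_id"))
    df["mean"] = df.mean(axis=1)
    return EffectTable(data=df, method=method, sign_convention=design.sign_convention)


def flag_dropouts(
    guides: Sequence[GuideRecord],
    design: ScreenDesign,
    min_reads: int = 10,
) -> tuple[pd.Series, float]:
    """Flag guides with < min_reads in the A or B sample of any replicate.

    Returns (per-guide boolean Series, dropout rate).
    """
    flags = {}
    for g in guides:
        dropout = any(
            g.counts[a] < min_reads or g.counts[b] < min_reads
            for a, b in design.comparisons
        )
        flags[g.guide_id] = dropout
    series = pd.Series(flags, name="dropout")
    rate = float(series.mean()) if len(series) else 0.0
    return series, rate


def average_replicates(table: EffectTable) -> pd.DataFrame:
    """Per-guide mean and min–max range across replicates."""
    reps = table.data[table.rep_columns]
    return pd.DataFrame(
        {
            "mean": reps.mean(axis=1),
            "min": reps.min(axis=1),
            "max": reps.max(axis=1),
        }
    )


def normalize_to_element_mean(
    table: EffectTable,
    element: GenomicInterval,
    guides: Sequence[GuideRecord],
) -> pd.Series:
    """Divide each in-element guide's mean effect by the element's mean effect.

    A guide belongs to the element when its 3-bp PAM window intersects the
    element interval.
    """
    members = [
        g.guide_id
        for g in guides
        if g.has_coordinates and g.pam_interval().overlaps(element)
    ]
    if not members:
        raise EffectError(
            f"no guide PAM window intersects element "
            f"{element.chrom}:{element.start}-{element.end}"
        )
    effects = table.data.loc[members, "mean"]
    m = effects.mean()
    if m == 0:
        raise EffectError("element mean effect is zero; cannot normalize")
    return effects / m


def summit_distance_profile(
    table: EffectTable,
    guides: Sequence[GuideRecord],
    summits: Sequence[tuple[str, int]],
    half_window: int = 150,
    span: int = 2000,
    normalized: Mapping[str, float] | None = None,
) -> dict[tuple[str, int], float]:
    """Per-base mean effect track around DHS summits.

    Each guide within ``span`` bp of a summit is expanded by ±half_window
    around its PAM window and its (normalized) effect is painted over every
    base; overlapping windows are averaged per base.  Returns a sparse
    {(chrom, pos): value} mapping (bases covered by no guide are absent);
    convert with :func:`profile_to_bedgraph`.
    """
    values = normalized if normalized is not None else table.data["mean"]
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    for g in guides:
        if not g.has_coordinates:
            continue
        near = any(
            g.chrom == chrom and abs(g.pam_start - pos) <= span
            for chrom, pos in summits
        )
        if not near or g.guide_id not in values:
            continue
        e = float(values[g.guide_id])
        lo = max(0, g.pam_start - half_window)
        hi = g.pam_end + half_window
        for pos in range(lo, hi):
            key = (g.chrom, pos)
            sums[key] = sums.get(key, 0.0) + e
            counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def profile_to_bedgraph(profile: Mapping[tuple[str, int], float], path) -> None:
    """Write a per-base profile as a 4-column bedGraph, merging equal runs."""
    items = sorted(profile.items())
    with open(path, "w") as fh:
        run_start = None
        prev = None
        for (chrom, pos), value in items:
            if (
                prev is not None
                and prev[0] == chrom
                and pos == prev[1] + 1
                and value == prev[2]
            ):
                prev = (chrom, pos, value)
                continue
            if prev is not None:
                fh.write(
                    f"{prev[0]}\t{run_start}\t{prev[1] + 1}\t{prev[2]:g}\n"
                )
            run_start = pos
            prev = (chrom, pos, value)
        if prev is not None:
            fh.write(f"{prev[0]}\t{run_start}\t{prev[1] + 1}\t{prev[2]:g}\n")
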