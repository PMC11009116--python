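"""Guide filtering, off-target diagnostics, control-variance analysis and
library-design selection strategies.

Covers the practical screen-design questions: which guides to discard
(low off-target specificity, U6 terminator in the spacer), whether
low-specificity guides are enriched for spurious effects far from any
regulatory element, how many negative controls are enough (variance of
subsamples vs the full control set), and how to pick a small guide subset
per element (closest-to-summit, distal, evenly spaced, random) or per TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import GenomicInterval, GuideRecord

SPECIFICITY_THRESHOLD = 0.2
U6_TERMINATOR = "TTTT"


class DesignQCError(ValueError):
    pass


@dataclass
class SelectionStrategy:
    name: str  # closest | distal | every_nth | random
    k: int
    distal_offset: int = 179  # half the median DHS peak length (bp)
    random_draws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("closest", "distal", "every_nth", "random"):
            raise DesignQCError(f"unknown selection strategy {self.name!r}")
        if self.k < 1:
            raise DesignQCError("k must be >= 1")
        if self.distal_offset < 0:
            raise DesignQCError("distal_offset must be >= 0")


def filter_guides(
    guides: Sequence[GuideRecord],
    min_specificity: float = SPECIFICITY_THRESHOLD,
    forbid_u6_terminator: bool = True,
) -> tuple[list[GuideRecord], pd.DataFrame]:
    """Partition guides into kept and removed (with reasons).

    Removal reasons: specificity strictly below the threshold, or the U6 Pol
    III terminator 'TTTT' in the protospacer (as stored, transcribed-strand
    context).  Guides with no specificity score pass that filter but are
    flagged.
    """
    kept: list[GuideRecord] = []
    removed_rows = []
    flags = []
    for g in guides:
        reasons = []
        if g.specificity is not None and g.specificity < min_specificity:
            reasons.append("low_specificity")
        if forbid_u6_terminator and U6_TERMINATOR in g.protospacer.upper():
            reasons.append("u6_terminator")
        if reasons:
            removed_rows.append(
                {"guide_id": g.guide_id, "reasons": ";".join(reasons)}
            )
        else:
            kept.append(g)
            if g.specificity is None:
                flags.append(g.guide_id)
    removed = pd.DataFrame(removed_rows, columns=["guide_id", "reasons"])
    removed.attrs["missing_specificity"] = flags
    return kept, removed


def offtarget_enrichment(
    effects: pd.Series,
    guides: Sequence[GuideRecord],
    control_effects: np.ndarray,
    dhs: Sequence[GenomicInterval],
    elements: Sequence[GenomicInterval],
    exclusion_bp: int = 1000,
    specificity_threshold: float = SPECIFICITY_THRESHOLD,
) -> tuple[float, float, pd.DataFrame]:
    """Are low-specificity guides enriched for outlier effects far from DHSs?

    Universe: guides whose PAM lies at least ``exclusion_bp`` from any DHS
    peak or significant element.  A guide is an outlier when its mean effect
    is more than 2 control SDs from the control mean.  Returns (odds ratio,
    two-sided Fisher p, 2x2 table as DataFrame with rows low/high specificity
    and columns outlier/not).
    """
    control_effects = np.asarray(control_effects, dtype=float)
    mu = control_effects.mean()
    sd = control_effects.std(ddof=1)
    avoid = list(dhs) + list(elements)

    def far_from_all(g: GuideRecord) -> bool:
        for iv in avoid:
            if g.chrom != iv.chrom:
                continue
            if g.pam_start < iv.end + exclusion_bp and iv.start - exclusion_bp < g.pam_end:
                return False
        return True

    table = np.zeros((2, 2), dtype=int)
    for g in guides:
        if not g.has_coordinates or g.specificity is None:
            continue
        if g.guide_id not in effects.index or not far_from_all(g):
            continue
        low = g.specificity < specificity_threshold
        outlier = abs(effects[g.guide_id] - mu) > 2 * sd
        table[0 if low else 1, 0 if outlier else 1] += 1
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise DesignQCError(
            "need guides in both specificity categories after the distance filter"
        )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    df = pd.DataFrame(
        table,
        index=["low_specificity", "high_specificity"],
        columns=["outlier", "not_outlier"],
    )
    return float(odds), float(p), df


def control_variance_curve(
    control_effects: np.ndarray,
    increment: int = 10,
    n_sub: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    center: str = "median",
) -> pd.DataFrame:
    """Empirical significance rate of Levene tests of subsamples vs the full set.

    For each subsample size s in {increment, 2·increment, …, full size}, the
    control set is subsampled n_sub times without replacement and a Levene
    (Brown–Forsythe by default) test against the full set is run; the
    empirical p at s is the fraction of subsamples with test p < alpha.
    """
    full = np.asarray(control_effects, dtype=float)
    if len(full) < 2 * increment:
        raise DesignQCError("full control set must have at least 2·increment guides")
    rng = np.random.default_rng(seed)
    rows = []
    sizes = list(range(increment, len(full) + 1, increment))
    for s in sizes:
        if s > len(full):
            raise DesignQCError(f"subsample size {s} exceeds full set {len(full)}")
        hits = 0
        for _ in range(n_sub):
            sub = rng.choice(full, size=s, replace=False)
            if s == len(full):
                p = 1.0  # subsample is the full set
            else:
                p = stats.levene(sub, full, center=center).pvalue
            if p < alpha:
                hits += 1
        rows.append({"size": s, "empirical_p": hits / n_sub})
    return pd.DataFrame(rows)


def compare_control_variance(
    safe_effects: np.ndarray,
    nontargeting_effects: np.ndarray,
    center: str = "median",
) -> dict:
    """Compare safe-targeting vs nontargeting controls: variances, Levene
    (Brown–Forsythe) p for variance difference, Welch p for mean difference."""
    safe = np.asarray(safe_effects, dtype=float)
    nt = np.asarray(nontargeting_effects, dtype=float)
    if len(safe) < 2 or len(nt) < 2:
        raise DesignQCError("need >=2 guides per control set")
    out = {
        "safe_variance": float(safe.var(ddof=1)),
        "nontargeting_variance": float(nt.var(ddof=1)),
    }
    if out["safe_variance"] == 0 or out["nontargeting_variance"] == 0:
        import warnings

        warnings.warn("degenerate (constant) control set; tests skipped",
                      RuntimeWarning)
        out["levene_p"] = float("nan")
        out["welch_p"] = float("nan")
        return out
    out["levene_p"] = float(stats.levene(safe, nt, center=center).pvalue)
    out["welch_p"] = float(stats.ttest_ind(safe, nt, equal_var=False).pvalue)
    return out


def _sorted_by_distance(
    guides: Sequence[GuideRecord], key
) -> list[GuideRecord]:
    return sorted(guides, key=lambda g: (key(g), g.guide_id))


def select_guides(
    guides: Sequence[GuideRecord],
    summit: int,
    strategy: SelectionStrategy,
) -> list[str] | list[list[str]]:
    """Select k guides around a DHS summit by the given strategy.

    closest: k smallest |pam_start − summit|.  distal: k closest to
    ``distal_offset`` bp from the summit.  every_nth: order by pam_start and
    take ranks round(linspace(1, n, k)).  random: returns ``random_draws``
    independent k-subsets (a list of lists) for downstream averaging.
    Ties break by guide_id.
    """
    candidates = [g for g in guides if g.has_coordinates]
    if len(candidates) < strategy.k:
        raise DesignQCError(
            f"only {len(candidates)} candidate guides for k={strategy.k}"
        )
    k = strategy.k
    if strategy.name == "closest":
        ordered = _sorted_by_distance(candidates, lambda g: abs(g.pam_start - summit))
        return [g.guide_id for g in ordered[:k]]
    if strategy.name == "distal":
        ordered = _sorted_by_distance(
            candidates,
            lambda g: abs(abs(g.pam_start - summit) - strategy.distal_offset),
        )
        return [g.guide_id for g in ordered[:k]]
    if strategy.name == "every_nth":
        ordered = sorted(candidates, key=lambda g: (g.pam_start, g.guide_id))
        ranks = np.rint(np.linspace(1, len(ordered), k)).astype(int)
        return [ordered[r - 1].guide_id for r in ranks]
    # random
    rng = np.random.default_rng(strategy.seed)
    ids = sorted(g.guide_id for g in candidates)
    return [
        sorted(rng.choice(ids, size=k, replace=False).tolist())
        for _ in range(strategy.random_draws)
    ]


def select_tss_controls(
    guides: Sequence[GuideRecord],
    tss_list: Sequence[tuple[str, int]],
    k: int = 10,
) -> dict[tuple[str, int], list[str]]:
    """Per TSS, the k guides minimizing |pam_start − TSS| on that chromosome.

    Fewer than k available returns all of them with a warning.
    """
    out: dict[tuple[str, int], list[str]] = {}
    for chrom, tss in tss_list:
        candidates = [g for g in guides if g.has_coordinates and g.chrom == chrom]
        ordered = _sorted_by_distance(candidates, lambda g: abs(g.pam_start - tss))
        if len(ordered) < k:
            import warnings

            warnings.warn(
                f"TSS {chrom}:{tss}: only {len(ordered)} guides available (k={k})",
                RuntimeWarning,
            )
        out[(chrom, tss)] = [g.guide_id for g in ordered[:k]]
    return out
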