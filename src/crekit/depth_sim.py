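"""Bootstrap sequencing-depth simulation and precision–recall evaluation.

To emulate a screen sequenced to an average of d reads per guide, N·d reads
(N = number of distinct guides) are resampled with replacement from the
observed count distribution of each sample, independently per bootstrap and
per bioreplicate.  Dropout (guides with < 10 resampled reads in the low or
high sample) and between-replicate reproducibility (Pearson correlation of
log2[(1+A)/(1+B)] across rep1×rep2 bootstrap pairs) are summarized per depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .screen_io import GuideRecord, ScreenDesign


class DepthSimError(ValueError):
    pass


@dataclass
class DepthSimConfig:
    depths: list[int] = field(
        default_factory=lambda: [5, 25, 50, 100, 250, 500, 1000]
    )
    n_boot: int = 100
    min_reads: int = 10
    normalize_depth: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.depths):
            raise DepthSimError("depths must be positive")
        if self.n_boot < 1:
            raise DepthSimError("n_boot must be >= 1")


def bootstrap_counts(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample N·depth reads with replacement from a per-guide count vector.

    Each read picks guide i with probability counts_i / Σcounts; the output
    always sums to exactly N·depth.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DepthSimError("cannot bootstrap an all-zero count vector")
    n_reads = int(len(counts) * depth)
    return rng.multinomial(n_reads, counts / total)


def exclude_zero_guides(
    count_matrix: pd.DataFrame, samples: Sequence[str]
) -> pd.DataFrame:
    """Drop guides with zero mapped reads in any of the listed samples."""
    keep = (count_matrix[list(samples)] > 0).all(axis=1)
    return count_matrix.loc[keep]


def _log_fc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.log2((1.0 + a) / (1.0 + b))


def depth_curves(
    guides: Sequence[GuideRecord],
    design: ScreenDesign,
    config: DepthSimConfig,
) -> pd.DataFrame:
    """Dropout rate and replicate correlation as a function of depth.

    Requires two replicate comparisons for the correlation (with one
    replicate, correlation columns are NaN and only dropout is computed).
    Correlations are averaged over all rep1×rep2 bootstrap pairs; the
    normalized column divides by the correlation at ``normalize_depth``.
    """
    samples = design.samples
    matrix = pd.DataFrame(
        {s: [g.counts[s] for g in guides] for s in samples},
        index=[g.guide_id for g in guides],
    )
    matrix = exclude_zero_guides(matrix, samples)
    if matrix.empty:
        raise DepthSimError("no guides left after zero-read exclusion")
    two_reps = len(design.comparisons) >= 2
    if not two_reps:
        import warnings

        warnings.warn(
            "single replicate: correlation skipped, dropout still computed",
            RuntimeWarning,
        )

    depths = list(config.depths)
    if two_reps and config.normalize_depth not in depths:
        depths = depths + [config.normalize_depth]

    rows = []
    for depth in depths:
        rng = np.random.default_rng((config.seed, depth))
        dropout_rates = []
        # per replicate: list of (A_boot, B_boot) tuples over bootstraps
        boot_effects: list[list[np.ndarray]] = [[] for _ in design.comparisons]
        for _ in range(config.n_boot):
            for r, (sa, sb) in enumerate(design.comparisons):
                a = bootstrap_counts(matrix[sa].to_numpy(), depth, rng)
                b = bootstrap_counts(matrix[sb].to_numpy(), depth, rng)
                dropout = (a < config.min_reads) | (b < config.min_reads)
                dropout_rates.append(dropout.mean())
                boot_effects[r].append(_log_fc(a, b))
        if two_reps:
            corrs = [
                np.corrcoef(e1, e2)[0, 1]
                for e1 in boot_effects[0]
                for e2 in boot_effects[1]
            ]
            mean_r = float(np.mean(corrs))
        else:
            mean_r = float("nan")
        rows.append(
            {"depth": depth, "dropout_rate": float(np.mean(dropout_rates)),
             "replicate_r": mean_r}
        )
    df = pd.DataFrame(rows)
    if two_reps:
        ref = float(
            df.loc[df["depth"] == config.normalize_depth, "replicate_r"].iloc[0]
        )
        df["replicate_r_normalized"] = df["replicate_r"] / ref
    else:
        df["replicate_r_normalized"] = float("nan")
    return df[df["depth"].isin(config.depths)].reset_index(drop=True)


def pr_curve(
    scores: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Precision–recall points at each distinct score threshold (descending).

    Ties share a threshold.  Guides are ranked by descending score, so
    expression-lowering guides (positive under A_enriched_positive) rank
    first.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DepthSimError("PR curve needs both positive and negative labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(int)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tie group (threshold = distinct score)
    last_of_group = np.r_[s[1:] != s[:-1], True]
    idx = np.flatnonzero(last_of_group)
    return pd.DataFrame(
        {
            "threshold": s[idx],
            "tp": tp[idx],
            "fp": fp[idx],
            "precision": tp[idx] / (tp[idx] + fp[idx]),
            "recall": tp[idx] / n_pos,
        }
    )


def pr_auprc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """PR curve plus AUPRC as average precision (step integral, tie-grouped).

    AP = Σ_thresholds (ΔTP at threshold) · precision(threshold) / n_pos.
    """
    curve = pr_curve(scores, labels)
    tp = curve["tp"].to_numpy()
    prev_tp = np.r_[0, tp[:-1]]
    n_pos = int(np.asarray(labels, dtype=bool).sum())
    ap = float(np.sum((tp - prev_tp) * curve["precision"].to_numpy()) / n_pos)
    return curve, ap


def guide_labels_from_elements(
    guides: Sequence[GuideRecord], elements
) -> pd.Series:
    """Positive iff the guide's 3-bp PAM window overlaps any element interval."""
    labels = {}
    for g in guides:
        if not g.has_coordinates:
            continue
        pam = g.pam_interval()
        labels[g.guide_id] = any(pam.overlaps(e) for e in elements)
    return pd.Series(labels, name="in_cre")
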