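"""Effect-size-dependent power simulation for sgRNA number per element.

Given the measured per-guide effects within one element (on the fractional
expression scale), the element's guide set is rescaled to a grid of target
mean effects.  For each (target effect, n guides) pair, the simulation
repeatedly samples n guides without replacement, runs a Welch two-sample
t-test against the negative-control guides, applies a conservative
Benjamini–Hochberg adjustment for the number of co-tested elements, and
counts the fraction of draws rejected at FDR < alpha as power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PowerSimError(ValueError):
    pass


@dataclass
class PowerGrid:
    """Simulation grid: target mean effects × guide numbers.

    ``m_elements`` is the BH family size (number of elements co-tested in
    the screen); the element's adjusted p is taken conservatively at worst
    rank, i.e. p·m_elements.  ``dof_override`` replaces the
    Welch–Satterthwaite degrees of freedom when set (literal reproduction of
    a dof=1 Welch call).
    """

    effect_targets: list[float] = field(
        default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5]
    )
    n_guides: list[int] = field(default_factory=lambda: list(range(2, 31)))
    n_reps: int = 500
    alpha: float = 0.05
    m_elements: int = 100
    dof_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise PowerSimError("n_reps must be >= 1")
        for t in self.effect_targets:
            if not (0.0 <= abs(t) <= 1.0):
                raise PowerSimError(f"effect target {t} outside [0,1] in magnitude")


def rescale_element_effects(
    effects: np.ndarray, target_mean: float | None
) -> np.ndarray:
    """Scale guide effects so their mean equals target_mean exactly.

    ``target_mean=None`` means "unscaled" passthrough.  Fails when the
    current mean is zero and a nonzero target is requested.
    """
    effects = np.asarray(effects, dtype=float)
    if target_mean is None:
        return effects.copy()
    m = effects.mean()
    if target_mean == 0:
        return np.zeros_like(effects)
    if m == 0:
        raise PowerSimError("element mean effect is zero; cannot rescale")
    return effects * (target_mean / m)


def welch_pvalue(
    sample: np.ndarray, controls: np.ndarray, dof_override: float | None = None
) -> float:
    """Two-sided Welch t-test p-value, with optional df override."""
    sample = np.asarray(sample, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if dof_override is None:
        return float(stats.ttest_ind(sample, controls, equal_var=False).pvalue)
    n1, n2 = len(sample), len(controls)
    v1 = sample.var(ddof=1) / n1
    v2 = controls.var(ddof=1) / n2
    denom = np.sqrt(v1 + v2)
    if denom == 0:
        return 1.0
    t = (sample.mean() - controls.mean()) / denom
    return float(2.0 * stats.t.sf(abs(t), df=dof_override))


def simulate_power(
    element_effects: np.ndarray,
    control_effects: np.ndarray,
    grid: PowerGrid,
) -> pd.DataFrame:
    """Power table over (effect_target, n) pairs.

    Effects are on the fractional expression scale (e.g. 0.4 = 40%
    knockdown; signs are preserved through rescaling).  The RNG is fully
    determined by ``grid.seed``.
    """
    element_effects = np.asarray(element_effects, dtype=float)
    control_effects = np.asarray(control_effects, dtype=float)
    if len(control_effects) == 0:
        raise PowerSimError("control set is empty")
    rng = np.random.default_rng(grid.seed)
    scaled_sets = [
        rescale_element_effects(element_effects, t) for t in grid.effect_targets
    ]
    # common random numbers: the same guide draws are reused across effect
    # targets so that power is monotone in the target per draw, not just in
    # expectation
    power = {}
    for n in grid.n_guides:
        if n < 2:
            raise PowerSimError("need >=2 guides per draw for a t-test")
        if n > len(element_effects):
            raise PowerSimError(
                f"cannot sample {n} guides from {len(element_effects)} available"
            )
        rejections = [0] * len(grid.effect_targets)
        for _ in range(grid.n_reps):
            idx = rng.choice(len(element_effects), size=n, replace=False)
            for j, scaled in enumerate(scaled_sets):
                p = welch_pvalue(scaled[idx], control_effects, grid.dof_override)
                p_adj = min(1.0, p * grid.m_elements)
                if p_adj < grid.alpha:
                    rejections[j] += 1
        for target, r in zip(grid.effect_targets, rejections):
            power[(target, n)] = r / grid.n_reps
    rows = [
        {"effect_target": target, "n": n, "power": power[(target, n)]}
        for target in grid.effect_targets
        for n in grid.n_guides
    ]
    return pd.DataFrame(rows)


def log2fc_to_fraction(effect: np.ndarray) -> np.ndarray:
    """Convert log2 fold changes (A-enriched-positive) to expression-lowering
    fractions: f = 1 − 2^(−e), so e=1 (twofold low-bin enrichment) → 50%."""
    return 1.0 - np.power(2.0, -np.asarray(effect, dtype=float))
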