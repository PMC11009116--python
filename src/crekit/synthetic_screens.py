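"""Synthetic CRISPRi tiling screens with known ground truth.

The generator emulates a sorting-based (FlowFISH-style) or growth-based
tiling screen over a single synthetic locus:

* guides tile both strands alternately at a fixed spacing; planted elements
  give nearby guides a true knockdown fraction that decays linearly with
  distance from the element's summit;
* inside annotated gene bodies, template-strand guides are attenuated by a
  configurable factor (the CRISPRi strand bias);
* the sorting readout draws per-guide cell counts (Poisson at the configured
  coverage), splits cells into low/high expression bins using exact
  log-normal tail probabilities, and converts bin cell counts into reads by
  multinomial sampling at the configured sequencing depth;
* nontargeting controls have exactly zero effect; safe-targeting controls
  get small half-normal effects, reproducing their higher variance.

Using exact tail probabilities (rather than per-cell expression draws) keeps
the bin-assignment model closed-form and testable while preserving the
multinomial count noise of a real screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .screen_io import GenomicInterval, GuideRecord, ScreenDesign
from .strand_bias import GeneModel, classify_guide

SIM_CHROM = "chrSim"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedElement:
    """A planted CRE: interval, summit and the mean knockdown of its guides."""

    start: int
    end: int
    summit: int
    mean_effect: float
    name: str = ""
    in_gene_body: bool = False

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            SIM_CHROM, self.start, self.end, name=self.name or None
        )


@dataclass
class SimConfig:
    locus_length: int = 30_000
    genes: list[GeneModel] = field(default_factory=list)
    elements: list[PlantedElement] = field(default_factory=list)
    guide_spacing: int = 20
    coverage: float = 200.0  # cells per guide
    depth: float = 500.0  # reads per guide per sample
    bin_fraction: float = 0.10  # top/bottom sorting gates
    sigma_expression: float = 0.5  # log-normal expression noise
    sigma_guide: float = 0.03  # per-guide effect noise
    decay_window: int = 300  # bp of linear effect decay from the summit
    template_factor: float = 0.4  # gene-body template-strand attenuation
    n_nontargeting: int = 100
    n_safe: int = 100
    sigma_safe: float = 0.05
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0 or self.depth <= 0:
            raise SimulationError("coverage and depth must be positive")
        if not (0 < self.bin_fraction < 0.5):
            raise SimulationError("bin_fraction must be in (0, 0.5)")
        if not (0 < self.template_factor <= 1):
            raise SimulationError("template_factor must be in (0, 1]")
        for el in self.elements:
            if not (0 <= el.start < el.end <= self.locus_length):
                raise SimulationError(
                    f"element [{el.start},{el.end}) outside locus of length "
                    f"{self.locus_length}"
                )
            if not (0.0 <= el.mean_effect <= 1.0):
                raise SimulationError("element mean_effect must be in [0,1]")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard study conditions: 3 elements with mean knockdowns
    {0.2, 0.4, 0.8}, 20 guides each, 200x coverage, 500x depth, 2 replicates."""
    cfg = SimConfig(
        elements=[
            PlantedElement(5000, 5400, 5200, 0.2, name="el_weak"),
            PlantedElement(12000, 12400, 12200, 0.4, name="el_mid"),
            PlantedElement(20000, 20400, 20200, 0.8, name="el_strong"),
        ],
        seed=seed,
    )
    return replace(cfg, **overrides)


def strand_bias_config(seed: int = 0, **overrides) -> SimConfig:
    """Study conditions for the strand-bias analysis.

    A 30-kb locus with one + strand gene whose transcribed body carries
    CRISPRi activity throughout (the strand asymmetry is a property of
    transcribed regions, not of isolated elements): the gene body is tiled
    with contiguous 600-bp activity elements of mean knockdown 0.3, each
    attenuated to 0.3·template_factor on the template strand.
    """
    tss, tes = 6000, 26_000
    width = 600
    elements = [
        PlantedElement(start, start + width, start + width // 2, 0.3,
                       name=f"body_{start}", in_gene_body=True)
        for start in range(tss + 2000, tes - width + 1, width)
    ]
    cfg = SimConfig(
        genes=[GeneModel("geneA", SIM_CHROM, "+", tss=tss, tes=tes)],
        elements=elements,
        seed=seed,
    )
    return replace(cfg, **overrides)


def sorting_bin_probabilities(
    effect: np.ndarray, sigma: float, bin_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact low/high sorting-bin probabilities for knockdown fraction e.

    Per-cell expression is X = LogNormal(0, sigma)·(1−e); gates q_low/q_high
    are the bin_fraction tails of the unperturbed distribution, so

        p_low(e)  = Φ(z + ln(1/(1−e))/sigma),   z = Φ⁻¹(bin_fraction)
        p_high(e) = Φ(z + ln(1−e)/sigma)

    and p_low(0) = p_high(0) = bin_fraction.
    """
    # e < 0 (expression increase) is supported for model inversion
    e = np.clip(np.asarray(effect, dtype=float), -0.95, 1.0)
    z = stats.norm.ppf(bin_fraction)
    with np.errstate(divide="ignore"):
        log_surv = np.log1p(-e)  # ln(1−e), −inf at e=1
    p_low = stats.norm.cdf(z - log_surv / sigma)
    p_high = stats.norm.cdf(z + log_surv / sigma)
    return p_low, p_high


_BASES = np.array(list("ACGT"))


def _tile_guides(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Targeting guides tiled on alternating strands, plus controls."""
    rows = []
    positions = range(cfg.guide_spacing, cfg.locus_length - 3, cfg.guide_spacing)
    for i, pos in enumerate(positions):
        rows.append(
            {
                "guide_id": f"g{i:05d}",
                "category": "targeting",
                "pam_start": pos,
                "strand": "+" if i % 2 == 0 else "-",
            }
        )
    # safe-targeting guides avoid all element neighborhoods
    forbidden = [
        (el.summit - cfg.decay_window, el.summit + cfg.decay_window)
        for el in cfg.elements
    ]
    n_placed = 0
    while n_placed < cfg.n_safe:
        pos = int(rng.integers(0, cfg.locus_length - 3))
        if any(lo <= pos <= hi for lo, hi in forbidden):
            continue
        rows.append(
            {
                "guide_id": f"safe{n_placed:04d}",
                "category": "safe_targeting",
                "pam_start": pos,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        n_placed += 1
    for i in range(cfg.n_nontargeting):
        rows.append(
            {
                "guide_id": f"nt{i:04d}",
                "category": "nontargeting",
                "pam_start": None,
                "strand": None,
            }
        )
    for r in rows:
        r["protospacer"] = "".join(rng.choice(_BASES, size=20))
        r["specificity"] = float(np.round(rng.beta(8, 1), 4))
    return rows


def _true_effects(cfg: SimConfig, rows: list[dict], rng: np.random.Generator) -> None:
    """Assign per-guide true knockdown fractions in place.

    Element guides get a linear summit-distance decay rescaled so the mean
    over guides inside the element interval equals the configured
    mean_effect; template-strand guides inside a gene body are attenuated by
    template_factor; all targeting guides get Normal(0, sigma_guide) noise
    and are clipped to [0, 1].
    """
    for r in rows:
        r["true_effect"] = 0.0
        r["element"] = ""
    targeting = [r for r in rows if r["category"] == "targeting"]
    for el in cfg.elements:
        raws = {}
        for r in targeting:
            dist = abs(r["pam_start"] - el.summit)
            raw = max(0.0, 1.0 - dist / cfg.decay_window)
            if raw > 0:
                raws[r["guide_id"]] = raw
        inside = [
            r for r in targeting if el.start <= r["pam_start"] < el.end
        ]
        if not inside:
            continue
        mean_raw = float(np.mean([raws.get(r["guide_id"], 0.0) for r in inside]))
        if mean_raw == 0:
            continue
        scale = el.mean_effect / mean_raw
        for r in targeting:
            raw = raws.get(r["guide_id"], 0.0)
            if raw > 0 and raw * scale > r["true_effect"]:
                r["true_effect"] = raw * scale
                if el.start <= r["pam_start"] < el.end:
                    r["element"] = el.name or f"el_{el.start}"
    # strand attenuation + guide noise
    for r in rows:
        r["strand_class"] = ""
        r["region"] = ""
        if r["category"] not in ("targeting", "safe_targeting"):
            continue
        guide = GuideRecord(
            guide_id=r["guide_id"],
            chrom=SIM_CHROM,
            pam_start=r["pam_start"],
            pam_end=r["pam_start"] + 3,
            strand=r["strand"],
            protospacer=r["protospacer"],
            category=r["category"],
            specificity=r["specificity"],
        )
        for gene in cfg.genes:
            label = classify_guide(guide, gene)
            if label.region != "outside":
                r["strand_class"] = label.strand_class
                r["region"] = label.region
                if (
                    label.region == "gene_body"
                    and label.strand_class == "template"
                ):
                    r["true_effect"] *= cfg.template_factor
                break
    for r in rows:
        if r["category"] == "targeting":
            e = r["true_effect"] + rng.normal(0.0, cfg.sigma_guide)
        elif r["category"] == "safe_targeting":
            e = abs(rng.normal(0.0, cfg.sigma_safe))
        else:
            e = 0.0
        r["true_effect"] = float(np.clip(e, 0.0, 1.0))


def _reads_from_cells(
    cells: np.ndarray, total_reads: int, rng: np.random.Generator
) -> np.ndarray:
    total_cells = cells.sum()
    if total_cells == 0:
        raise SimulationError("no cells in sorting bin; coverage too low")
    return rng.multinomial(total_reads, cells / total_cells)


def _rows_to_guides(rows: list[dict], counts: dict[str, np.ndarray]) -> list[GuideRecord]:
    guides = []
    for i, r in enumerate(rows):
        has_coords = r["pam_start"] is not None
        guides.append(
            GuideRecord(
                guide_id=r["guide_id"],
                chrom=SIM_CHROM if has_coords else None,
                pam_start=r["pam_start"],
                pam_end=r["pam_start"] + 3 if has_coords else None,
                strand=r["strand"],
                protospacer=r["protospacer"],
                category=r["category"],
                specificity=r["specificity"],
                counts={s: int(c[i]) for s, c in counts.items()},
            )
        )
    return guides


def _truth_frame(rows: list[dict], cfg: SimConfig) -> pd.DataFrame:
    truth = pd.DataFrame(rows).set_index("guide_id")
    truth.attrs["elements"] = [el.interval() for el in cfg.elements]
    truth.attrs["element_means"] = {
        (el.name or f"el_{el.start}"): el.mean_effect for el in cfg.elements
    }
    return truth


def simulate_sorting_screen(
    cfg: SimConfig,
) -> tuple[list[GuideRecord], ScreenDesign, pd.DataFrame]:
    """Simulate a sorting (FlowFISH-style) screen.

    Returns (guides with low/high bin counts per replicate, design, truth
    table).  Replicates share true effects but draw cells and reads
    independently from per-replicate RNG substreams.
    """
    rng_truth = np.random.default_rng((cfg.seed, 10_007))
    rows = _tile_guides(cfg, rng_truth)
    _true_effects(cfg, rows, rng_truth)
    effects = np.array([r["true_effect"] for r in rows])
    p_low, p_high = sorting_bin_probabilities(
        effects, cfg.sigma_expression, cfg.bin_fraction
    )
    n = len(rows)
    total_reads = int(round(cfg.depth * n))
    counts: dict[str, np.ndarray] = {}
    comparisons = []
    for rep in range(1, cfg.replicates + 1):
        rng = np.random.default_rng((cfg.seed, rep))
        cells = rng.poisson(cfg.coverage, size=n)
        low_cells = np.zeros(n, dtype=int)
        high_cells = np.zeros(n, dtype=int)
        for i in range(n):
            rest = max(0.0, 1.0 - p_low[i] - p_high[i])
            low, high, _ = rng.multinomial(
                cells[i], [p_low[i], p_high[i], rest]
            )
            low_cells[i] = low
            high_cells[i] = high
        sa, sb = f"low_rep{rep}", f"high_rep{rep}"
        counts[sa] = _reads_from_cells(low_cells, total_reads, rng)
        counts[sb] = _reads_from_cells(high_cells, total_reads, rng)
        comparisons.append((sa, sb))
    design = ScreenDesign(
        modality="dcas9_krab", readout="sorting", comparisons=comparisons
    )
    return _rows_to_guides(rows, counts), design, _truth_frame(rows, cfg)


def simulate_growth_screen(
    cfg: SimConfig,
    generations: tuple[float, float] = (7.0, 21.0),
    fitness_map: Callable[[np.ndarray], np.ndarray] | None = None,
    fitness_scale: float = 0.2,
) -> tuple[list[GuideRecord], ScreenDesign, pd.DataFrame]:
    """Simulate a growth screen with plasmid, early (T7) and late (T21) samples.

    Guide abundance at time t is a0·2^(f·g_t); the default fitness map is
    f = −fitness_scale·e (knockdown proportionally slows growth).  The
    returned design compares T7 (A) to T21 (B) per replicate; the plasmid
    sample is included for alternative comparisons.
    """
    rng_truth = np.random.default_rng((cfg.seed, 10_007))
    rows = _tile_guides(cfg, rng_truth)
    _true_effects(cfg, rows, rng_truth)
    effects = np.array([r["true_effect"] for r in rows])
    if fitness_map is None:
        fitness = -fitness_scale * effects
    else:
        fitness = np.asarray(fitness_map(effects), dtype=float)
    if np.any(fitness[effects > 0] > 0):
        raise SimulationError("deleterious guides must have fitness <= 0")
    n = len(rows)
    total_reads = int(round(cfg.depth * n))
    a0 = rng_truth.lognormal(0.0, 0.25, size=n)
    counts: dict[str, np.ndarray] = {
        "plasmid": np.random.default_rng((cfg.seed, 0)).multinomial(
            total_reads, a0 / a0.sum()
        )
    }
    comparisons = []
    g7, g21 = generations
    for rep in range(1, cfg.replicates + 1):
        rng = np.random.default_rng((cfg.seed, rep))
        for label, g in (("t7", g7), ("t21", g21)):
            abundance = a0 * np.power(2.0, fitness * g)
            counts[f"{label}_rep{rep}"] = rng.multinomial(
                total_reads, abundance / abundance.sum()
            )
        comparisons.append((f"t7_rep{rep}", f"t21_rep{rep}"))
    design = ScreenDesign(
        modality="dcas9_krab", readout="growth", comparisons=comparisons
    )
    return _rows_to_guides(rows, counts), design, _truth_frame(rows, cfg)


def estimate_knockdown_from_bins(
    guides: Sequence[GuideRecord],
    design: ScreenDesign,
    cfg: SimConfig,
    control_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Invert the sorting model: per-guide knockdown fraction from bin skew.

    The low/high read ratio of each guide, calibrated against the
    nontargeting-control median ratio, equals p_low(e)/p_high(e) in
    expectation; solving that monotone relation per guide recovers e.
    Negative skews give negative estimates (expression increase), so count
    noise on null guides averages to zero instead of piling up at a floor;
    estimates are bounded to (−0.9, 0.999).
    """
    if design.readout != "sorting":
        raise SimulationError("knockdown inversion requires a sorting readout")
    ids = [g.guide_id for g in guides]
    if control_ids is None:
        control_ids = [g.guide_id for g in guides if g.category == "nontargeting"]
    control_set = set(control_ids)

    # invert the monotone e -> p_low/p_high relation on a fine grid
    e_grid = np.linspace(-0.9, 0.999, 4000)
    p_low, p_high = sorting_bin_probabilities(
        e_grid, cfg.sigma_expression, cfg.bin_fraction
    )
    log_ratio_grid = np.log(p_low) - np.log(p_high)

    per_rep = []
    for sa, sb in design.comparisons:
        a = np.array([g.counts[sa] for g in guides], dtype=float)
        b = np.array([g.counts[sb] for g in guides], dtype=float)
        ratio = ((a + 0.5) / a.sum()) / ((b + 0.5) / b.sum())
        ctrl = [r for g, r in zip(guides, ratio) if g.guide_id in control_set]
        calib = float(np.median(ctrl)) if ctrl else 1.0
        est = np.interp(np.log(ratio / calib), log_ratio_grid, e_grid)
        per_rep.append(est)
    return pd.Series(np.mean(per_rep, axis=0), index=ids, name="knockdown_est")
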