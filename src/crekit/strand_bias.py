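"""Strand- and region-aware classification of guides and the CRISPRi
coding/template asymmetry in gene bodies.

A guide's protospacer lies on either the coding (sense) or template strand
of its target gene; inside transcribed gene bodies, CRISPRi with
dCas9-KRAB represses more strongly from the coding strand, plausibly
because elongating Pol II competes dCas9 off the template strand.  Regions
are defined in transcription orientation from the PAM start position:
promoter = [TSS−2000, TSS), gene body = [TSS+2000, TES] (the 2-kb spacer
excludes TSS-proximal guides whose effects reflect promoter activity), and
everything else is outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import GuideRecord

PROMOTER_WIDTH = 2000
GENE_BODY_OFFSET = 2000
MIN_GUIDES_PER_CELL = 5


class StrandBiasError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Genomic TSS/TES for one gene; for − strand genes tss > tes."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise StrandBiasError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise StrandBiasError(f"+ gene {self.gene_id} needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise StrandBiasError(f"- gene {self.gene_id} needs tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)


@dataclass(frozen=True)
class StrandRegionLabel:
    strand_class: str  # coding | template
    region: str  # promoter | gene_body | outside


def classify_guide(guide: GuideRecord, gene: GeneModel) -> StrandRegionLabel:
    """Label one guide relative to one gene.

    Strand class: coding iff the guide's strand equals the gene's strand.
    Region from the PAM start in transcription coordinates u (u=0 at the
    TSS, increasing downstream): promoter −2000 ≤ u < 0; gene body
    2000 ≤ u ≤ gene length; outside otherwise.
    """
    if not guide.has_coordinates:
        raise StrandBiasError(f"guide {guide.guide_id} has no coordinates")
    if guide.chrom != gene.chrom:
        raise StrandBiasError(
            f"guide {guide.guide_id} on {guide.chrom}, gene on {gene.chrom}"
        )
    strand_class = "coding" if guide.strand == gene.strand else "template"
    if gene.strand == "+":
        u = guide.pam_start - gene.tss
    else:
        u = gene.tss - guide.pam_start
    if gene.length <= GENE_BODY_OFFSET:
        warnings.warn(
            f"gene {gene.gene_id}: TES within {GENE_BODY_OFFSET} bp of TSS; "
            "gene body region is empty",
            RuntimeWarning,
        )
    if -PROMOTER_WIDTH <= u < 0:
        region = "promoter"
    elif GENE_BODY_OFFSET <= u <= gene.length:
        region = "gene_body"
    else:
        region = "outside"
    return StrandRegionLabel(strand_class=strand_class, region=region)


def classify_guides(
    guides: Sequence[GuideRecord], gene: GeneModel
) -> pd.DataFrame:
    """Per-guide strand/region labels as a DataFrame indexed by guide_id."""
    rows = {}
    for g in guides:
        if not g.has_coordinates:
            continue
        label = classify_guide(g, gene)
        rows[g.guide_id] = {
            "strand_class": label.strand_class,
            "region": label.region,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def strand_bias_summary(
    effects: Mapping[str, float], labels: pd.DataFrame
) -> pd.DataFrame:
    """Per-region coding/template mean effects, their ratio, and Welch p.

    Screens with fewer than 5 guides in any of the four promoter/gene-body
    strand cells are flagged ineligible (ratios reported, p-values withheld).
    """
    effects = pd.Series(dict(effects), dtype=float)
    labels = labels.loc[labels.index.intersection(effects.index)]
    cells = {
        (region, sc): effects[
            labels[(labels["region"] == region) & (labels["strand_class"] == sc)].index
        ].to_numpy()
        for region in ("promoter", "gene_body")
        for sc in ("coding", "template")
    }
    eligible = all(len(v) >= MIN_GUIDES_PER_CELL for v in cells.values())
    rows = []
    for region in ("promoter", "gene_body", "outside"):
        coding = effects[
            labels[
                (labels["region"] == region) & (labels["strand_class"] == "coding")
            ].index
        ].to_numpy()
        template = effects[
            labels[
                (labels["region"] == region) & (labels["strand_class"] == "template")
            ].index
        ].to_numpy()
        if len(coding) == 0 and len(template) == 0:
            continue
        mean_c = float(coding.mean()) if len(coding) else float("nan")
        mean_t = float(template.mean()) if len(template) else float("nan")
        ratio = mean_c / mean_t if mean_t not in (0.0,) else float("inf")
        if eligible and len(coding) >= 2 and len(template) >= 2:
            p = float(stats.ttest_ind(coding, template, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            {
                "region": region,
                "n_coding": len(coding),
                "n_template": len(template),
                "mean_coding": mean_c,
                "mean_template": mean_t,
                "ratio": ratio,
                "welch_p": p,
                "eligible": eligible,
            }
        )
    return pd.DataFrame(rows)


def read_gene_models(path) -> list[GeneModel]:
    """Read genes.tsv with columns gene_id, chrom, strand, tss, tes."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "strand", "tss", "tes"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StrandBiasError(f"gene model file missing columns {missing}")
    return [
        GeneModel(
            gene_id=r.gene_id, chrom=r.chrom, strand=r.strand,
            tss=int(r.tss), tes=int(r.tes),
        )
        for r in df.itertuples()
    ]
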