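"""Coding/template strand bias in the gene-body screen.

Effects are model-inverted knockdown fractions (the sorting log2FC is
nonlinear in knockdown, which would distort the ratio).

Reads results/screens/strand.*, writes results/strand_bias/.
"""

from pathlib import Path

from crekit import screen_io, strand_bias as sb, synthetic_screens as ss

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "strand_bias"
    out.mkdir(parents=True, exist_ok=True)
    guides = screen_io.read_guide_quant(ROOT / "screens" / "strand.guideQuant.tsv")
    design = screen_io.read_design(ROOT / "screens" / "strand.design.yaml")
    gene = sb.read_gene_models(ROOT / "screens" / "strand.genes.tsv")[0]

    cfg = ss.strand_bias_config(seed=SEED)
    est = ss.estimate_knockdown_from_bins(guides, design, cfg)
    labels = sb.classify_guides(
        [g for g in guides if g.has_coordinates and g.chrom == gene.chrom], gene
    )
    labels.to_csv(out / "labels.tsv", sep="\t")
    summary = sb.strand_bias_summary(est.to_dict(), labels)
    summary.insert(0, "gene_id", gene.gene_id)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
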