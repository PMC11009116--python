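"""Generate the study-condition synthetic screens used by all downstream steps.

Writes, under results/screens/:
  sorting.{guideQuant.tsv,design.yaml,truth.tsv,elements.bed}
  growth.{guideQuant.tsv,design.yaml,truth.tsv}
  strand.{guideQuant.tsv,design.yaml,truth.tsv}
"""

from pathlib import Path

from crekit import screen_io, synthetic_screens as ss

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "screens"


def write_screen(prefix: Path, guides, design, truth) -> None:
    screen_io.write_guide_quant(guides, f"{prefix}.guideQuant.tsv")
    screen_io.write_design(design, f"{prefix}.design.yaml")
    truth.to_csv(f"{prefix}.truth.tsv", sep="\t")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = ss.default_config(seed=SEED)
    guides, design, truth = ss.simulate_sorting_screen(cfg)
    write_screen(OUT / "sorting", guides, design, truth)
    screen_io.write_intervals(truth.attrs["elements"], OUT / "sorting.elements.bed")
    print(f"sorting screen: {len(guides)} guides, "
          f"{len(cfg.elements)} planted elements")

    guides, design, truth = ss.simulate_growth_screen(ss.default_config(seed=SEED))
    write_screen(OUT / "growth", guides, design, truth)
    print(f"growth screen: {len(guides)} guides")

    scfg = ss.strand_bias_config(seed=SEED)
    guides, design, truth = ss.simulate_sorting_screen(scfg)
    write_screen(OUT / "strand", guides, design, truth)
    gene = scfg.genes[0]
    (OUT / "strand.genes.tsv").write_text(
        "gene_id\tchrom\tstrand\ttss\ttes\n"
        f"{gene.gene_id}\t{gene.chrom}\t{gene.strand}\t{gene.tss}\t{gene.tes}\n"
    )
    print(f"strand-bias screen: {len(guides)} guides over gene "
          f"{gene.gene_id} [{gene.tss},{gene.tes}]")


if __name__ == "__main__":
    main()
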