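"""Element calling on the sorting screen, plus outlier sensitivity and
recovery against the planted truth.

Reads results/screens/sorting.*, writes results/calls/.
"""

from pathlib import Path

import pandas as pd

from crekit import element_caller as ec, guide_effects as ge, screen_io
from crekit.genome_intervals import BinGrid, jaccard_similarity

ROOT = Path(__file__).resolve().parent.parent / "results"
FDR = 0.01


def main() -> None:
    out = ROOT / "calls"
    out.mkdir(parents=True, exist_ok=True)
    guides = screen_io.read_guide_quant(ROOT / "screens" / "sorting.guideQuant.tsv")
    design = screen_io.read_design(ROOT / "screens" / "sorting.design.yaml")
    truth_elements = screen_io.read_intervals(
        ROOT / "screens" / "sorting.elements.bed", "bed6"
    )

    table = ge.compute_effects(guides, design)
    # safe-targeting controls pass through the targeting noise path and are
    # the more stringent calibration set
    controls = [g.guide_id for g in guides if g.category == "safe_targeting"]
    pvals = ec.per_guide_pvalues(table, controls)
    effects = table.data["mean"].to_dict()
    grid = BinGrid()

    bins, calls = ec.aggregate_and_call(
        pvals, guides, grid, design.modality, fdr_threshold=FDR, effects=effects
    )
    screen_io.write_element_quant(calls, out / "elements.tsv")

    sensitivity = ec.outlier_sensitivity(
        pvals, guides, grid, design.modality, fdr_threshold=FDR, effects=effects
    )
    pd.DataFrame(
        [
            {"metric": "n_bins_tested", "value": len(bins)},
            {"metric": "n_calls", "value": len(calls)},
            {"metric": "n_calls_after_outlier_drop",
             "value": len(sensitivity["calls_dropped"])},
            {"metric": "n_bins_losing_significance",
             "value": len(sensitivity["bins_losing_significance"])},
            {"metric": "jaccard_vs_truth",
             "value": jaccard_similarity(
                 [c.interval for c in calls], truth_elements)},
        ]
    ).to_csv(out / "summary.tsv", sep="\t", index=False)

    for call in calls:
        print(f"{call.interval.name}: {call.interval.chrom}:"
              f"{call.interval.start}-{call.interval.end} "
              f"fdr={call.fdr:.3g} mean_effect={call.mean_effect:.3f} "
              f"n_guides={call.n_guides}")


if __name__ == "__main__":
    main()
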