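"""Per-guide effect sizes, dropout rates and replicate agreement.

Reads results/screens/sorting.*, writes results/effects/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crekit import guide_effects as ge, screen_io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "effects"
    out.mkdir(parents=True, exist_ok=True)
    guides = screen_io.read_guide_quant(ROOT / "screens" / "sorting.guideQuant.tsv")
    design = screen_io.read_design(ROOT / "screens" / "sorting.design.yaml")

    for method in ("mean_norm", "linear"):
        table = ge.compute_effects(guides, design, method=method)
        table.data.to_csv(out / f"effects_{method}.tsv", sep="\t")

    table = ge.compute_effects(guides, design)
    flags, rate = ge.flag_dropouts(guides, design)
    flags.to_frame().to_csv(out / "dropouts.tsv", sep="\t")

    reps = table.data[table.rep_columns]
    r = float(np.corrcoef(reps["rep1"], reps["rep2"])[0, 1])
    truth = pd.read_csv(ROOT / "screens" / "sorting.truth.tsv", sep="\t",
                        index_col="guide_id")
    summary = pd.DataFrame(
        [
            {"metric": "dropout_rate", "value": rate},
            {"metric": "replicate_pearson_r", "value": r},
            {
                "metric": "effect_vs_truth_r",
                "value": float(np.corrcoef(
                    table.data["mean"], truth.loc[table.data.index, "true_effect"]
                )[0, 1]),
            },
        ]
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
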