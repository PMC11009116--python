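"""Sequencing-depth bootstrap and coverage-titration AUPRC.

Reads results/screens/sorting.*, writes results/depth/.
"""

from pathlib import Path

import pandas as pd

from crekit import depth_sim as ds, guide_effects as ge, screen_io
from crekit import synthetic_screens as ss

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "depth"
    out.mkdir(parents=True, exist_ok=True)
    guides = screen_io.read_guide_quant(ROOT / "screens" / "sorting.guideQuant.tsv")
    design = screen_io.read_design(ROOT / "screens" / "sorting.design.yaml")

    curves = ds.depth_curves(guides, design, ds.DepthSimConfig(seed=SEED))
    curves.to_csv(out / "depth_curves.tsv", sep="\t", index=False)
    print(curves.to_string(index=False))

    rows = []
    for coverage in (20, 50, 100, 200):
        cfg = ss.default_config(seed=SEED, coverage=float(coverage))
        cov_guides, cov_design, truth = ss.simulate_sorting_screen(cfg)
        table = ge.compute_effects(cov_guides, cov_design)
        labels = ds.guide_labels_from_elements(cov_guides, truth.attrs["elements"])
        scores = table.data.loc[labels.index, "mean"].to_numpy()
        curve, ap = ds.pr_auprc(scores, labels.to_numpy())
        curve.to_csv(out / f"pr_curve_cov{coverage}.tsv", sep="\t", index=False)
        rows.append({"coverage": coverage, "auprc": ap,
                     "prevalence": float(labels.mean())})
    auprc = pd.DataFrame(rows)
    auprc.to_csv(out / "auprc_by_coverage.tsv", sep="\t", index=False)
    print(auprc.to_string(index=False))


if __name__ == "__main__":
    main()
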