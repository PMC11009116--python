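"""Library design QC on the sorting screen: guide filtering, off-target
outlier enrichment, control-variance curves and selection strategies.

Reads results/screens/sorting.*, writes results/design_qc/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crekit import design_qc as dq, guide_effects as ge, screen_io

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "design_qc"
    out.mkdir(parents=True, exist_ok=True)
    guides = screen_io.read_guide_quant(ROOT / "screens" / "sorting.guideQuant.tsv")
    design = screen_io.read_design(ROOT / "screens" / "sorting.design.yaml")
    elements = screen_io.read_intervals(
        ROOT / "screens" / "sorting.elements.bed", "bed6"
    )
    table = ge.compute_effects(guides, design)

    kept, removed = dq.filter_guides(guides)
    removed.to_csv(out / "removed_guides.tsv", sep="\t", index=False)

    safe = table.data.loc[
        [g.guide_id for g in guides if g.category == "safe_targeting"], "mean"
    ].to_numpy()
    nt = table.data.loc[
        [g.guide_id for g in guides if g.category == "nontargeting"], "mean"
    ].to_numpy()
    comparison = dq.compare_control_variance(safe, nt)
    pd.DataFrame([comparison]).to_csv(out / "control_comparison.tsv",
                                      sep="\t", index=False)
    print({k: round(v, 6) for k, v in comparison.items()})

    curve = dq.control_variance_curve(nt, increment=10, n_sub=200, seed=SEED)
    curve.to_csv(out / "control_variance_curve.tsv", sep="\t", index=False)

    try:
        odds, p, ctab = dq.offtarget_enrichment(
            table.data["mean"], guides, nt, dhs=elements, elements=elements,
        )
        ctab.to_csv(out / "offtarget_table.tsv", sep="\t")
        print(f"off-target outlier enrichment: OR={odds:.2f}, p={p:.3g}")
    except dq.DesignQCError as exc:
        # this library carries essentially no sub-threshold-specificity
        # guides, so the 2x2 cannot be formed; record that outcome
        (out / "offtarget_table.tsv").write_text(f"not_applicable\t{exc}\n")
        print(f"off-target outlier enrichment not applicable: {exc}")

    # selection strategies around the strongest planted element's summit
    strong = [e for e in elements if e.name == "el_strong"][0]
    summit = (strong.start + strong.end) // 2
    near = [g for g in guides
            if g.has_coordinates and strong.start <= g.pam_start < strong.end]
    rows = []
    for name in ("closest", "distal", "every_nth", "random"):
        strat = dq.SelectionStrategy(name, k=5, seed=SEED)
        sel = dq.select_guides(near, summit, strat)
        if name == "random":
            means = [table.data.loc[s, "mean"].mean() for s in sel]
            mean_effect = float(np.mean(means))
        else:
            mean_effect = float(table.data.loc[sel, "mean"].mean())
        rows.append({"strategy": name, "k": 5, "mean_effect": mean_effect})
    selection = pd.DataFrame(rows)
    selection.to_csv(out / "selection_strategies.tsv", sep="\t", index=False)
    print(selection.to_string(index=False))


if __name__ == "__main__":
    main()
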