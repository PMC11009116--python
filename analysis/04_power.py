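"""Guide-number power simulation driven by measured effects from the screen.

Element effects are the model-inverted knockdown fractions of the mid-strength
planted element's guides; controls are the safe-targeting guides.  Both are
centered on the control mean (the same calibration the caller's z-test uses)
before rescaling.

Reads results/screens/sorting.*, writes results/power/.
"""

from pathlib import Path

import pandas as pd

from crekit import power_sim as ps, screen_io, synthetic_screens as ss

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "power"
    out.mkdir(parents=True, exist_ok=True)
    guides = screen_io.read_guide_quant(ROOT / "screens" / "sorting.guideQuant.tsv")
    design = screen_io.read_design(ROOT / "screens" / "sorting.design.yaml")
    truth = pd.read_csv(ROOT / "screens" / "sorting.truth.tsv", sep="\t",
                        index_col="guide_id")

    cfg = ss.default_config(seed=SEED)
    est = ss.estimate_knockdown_from_bins(guides, design, cfg)
    safe = [g.guide_id for g in guides if g.category == "safe_targeting"]
    controls = est[safe].to_numpy()
    mu0 = controls.mean()

    frames = []
    for element_name in ("el_weak", "el_mid", "el_strong"):
        members = truth.index[truth["element"] == element_name]
        element = est[members].to_numpy() - mu0
        grid = ps.PowerGrid(
            effect_targets=[0.1, 0.2, 0.3, 0.4, 0.5],
            n_guides=list(range(2, 21)),
            n_reps=500, seed=SEED,
        )
        table = ps.simulate_power(element, controls - mu0, grid)
        table.insert(0, "element", element_name)
        frames.append(table)
    result = pd.concat(frames, ignore_index=True)
    result.to_csv(out / "power.tsv", sep="\t", index=False)

    mid = result[(result["element"] == "el_mid") & (result["effect_target"] == 0.4)]
    enough = mid[mid["power"] >= 0.8]
    n80 = int(enough["n"].min()) if len(enough) else None
    print(f"guides needed for 80% power at a 40% effect (el_mid): {n80}")


if __name__ == "__main__":
    main()
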