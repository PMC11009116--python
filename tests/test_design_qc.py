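import numpy as np
import pandas as pd
import pytest

from crekit import design_qc as dq
from crekit.design_qc import DesignQCError, SelectionStrategy
from crekit.screen_io import GenomicInterval

from conftest import make_guide


class TestFilterGuides:
    def test_reasons_and_flags(self):
        guides = [
            make_guide("ok", specificity=0.9),
            make_guide("lowspec", pam_start=200, specificity=0.19),
            make_guide("term", pam_start=300, specificity=0.9,
                       protospacer="ACGTTTTACGTACGTACGTA"),
            make_guide("both", pam_start=400, specificity=0.1,
                       protospacer="TTTTACGTACGTACGTACGT"),
            make_guide("nospec", pam_start=500, specificity=None),
        ]
        kept, removed = dq.filter_guides(guides)
        assert {g.guide_id for g in kept} == {"ok", "nospec"}
        reasons = dict(zip(removed["guide_id"], removed["reasons"]))
        assert reasons["lowspec"] == "low_specificity"
        assert reasons["term"] == "u6_terminator"
        assert reasons["both"] == "low_specificity;u6_terminator"
        assert removed.attrs["missing_specificity"] == ["nospec"]

    def test_threshold_is_strict(self):
        kept, removed = dq.filter_guides([make_guide("edge", specificity=0.2)])
        assert len(kept) == 1 and removed.empty

    def test_terminator_filter_optional(self):
        g = make_guide("t", protospacer="TTTT" + "A" * 16)
        kept, _ = dq.filter_guides([g], forbid_u6_terminator=False)
        assert len(kept) == 1


class TestOfftargetEnrichment:
    def _build(self):
        # worked 2x2: low-spec 8/20 outliers, high-spec 2/80 -> OR = 26.0
        controls = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        guides, effects = [], {}
        pos = 100_000  # far from the DHS below
        idx = 0
        for n, low_spec, n_outlier in [(20, True, 8), (80, False, 2)]:
            for i in range(n):
                gid = f"{'lo' if low_spec else 'hi'}{i}"
                guides.append(make_guide(
                    gid, pam_start=pos, specificity=0.1 if low_spec else 0.9,
                ))
                effects[gid] = 5.0 if i < n_outlier else 0.0
                pos += 100
                idx += 1
        return controls, guides, effects

    def test_worked_odds_ratio(self):
        controls, guides, effects = self._build()
        odds, p, table = dq.offtarget_enrichment(
            pd.Series(effects), guides, controls,
            dhs=[GenomicInterval("chr1", 0, 200)], elements=[],
        )
        assert table.loc["low_specificity", "outlier"] == 8
        assert table.loc["high_specificity", "outlier"] == 2
        assert odds == pytest.approx((8 * 78) / (12 * 2))  # 26.0
        assert p < 0.01

    def test_guides_near_dhs_excluded(self):
        controls, guides, effects = self._build()
        # a low-spec outlier 500 bp from the DHS must not enter the table
        near = make_guide("near", pam_start=700, specificity=0.1)
        effects["near"] = 5.0
        odds, _, table = dq.offtarget_enrichment(
            pd.Series(effects), guides + [near], controls,
            dhs=[GenomicInterval("chr1", 0, 200)], elements=[],
        )
        assert table.to_numpy().sum() == 100

    def test_single_category_rejected(self):
        controls, guides, effects = self._build()
        only_low = [g for g in guides if g.specificity == 0.1]
        with pytest.raises(DesignQCError, match="categories"):
            dq.offtarget_enrichment(
                pd.Series(effects), only_low, controls, dhs=[], elements=[],
            )


class TestControlVariance:
    def test_curve_sizes_and_endpoint(self):
        rng = np.random.default_rng(0)
        full = rng.normal(0, 0.1, 60)
        df = dq.control_variance_curve(full, increment=10, n_sub=50, seed=1)
        assert list(df["size"]) == [10, 20, 30, 40, 50, 60]
        # at full size the subsample IS the full set: never significant
        assert df["empirical_p"].iloc[-1] == 0.0
        assert ((0 <= df["empirical_p"]) & (df["empirical_p"] <= 1)).all()

    def test_too_small_full_set(self):
        with pytest.raises(DesignQCError):
            dq.control_variance_curve(np.zeros(15), increment=10)

    def test_compare_distinguishes_variances(self):
        rng = np.random.default_rng(2)
        out = dq.compare_control_variance(
            rng.normal(0, 0.3, 400), rng.normal(0, 0.1, 400)
        )
        assert out["safe_variance"] > out["nontargeting_variance"]
        assert out["levene_p"] < 1e-6

    def test_compare_identical_sets(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.1, 200)
        out = dq.compare_control_variance(x, x.copy())
        assert out["levene_p"] == pytest.approx(1.0)

    def test_degenerate_sets_warn(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = dq.compare_control_variance(np.zeros(5), np.ones(5))
        assert np.isnan(out["levene_p"])


class TestSelectGuides:
    guides = [make_guide(f"g{p}", pam_start=p) for p in (900, 950, 990, 1010, 1100)]

    def test_closest(self):
        got = dq.select_guides(self.guides, 1000,
                               SelectionStrategy("closest", k=2))
        assert set(got) == {"g990", "g1010"}

    def test_distal_offset_179(self):
        # distances {100, 50, 10, 10, 100}; |d-179| = {79, 129, 169, 169, 79}
        got = dq.select_guides(self.guides, 1000,
                               SelectionStrategy("distal", k=2))
        assert set(got) == {"g900", "g1100"}

    def test_every_nth_linspace_ranks(self):
        got = dq.select_guides(self.guides, 1000,
                               SelectionStrategy("every_nth", k=3))
        assert got == ["g900", "g990", "g1100"]  # ranks {1, 3, 5}

    def test_random_returns_deterministic_draws(self):
        strat = SelectionStrategy("random", k=2, random_draws=10, seed=4)
        draws = dq.select_guides(self.guides, 1000, strat)
        assert len(draws) == 10 and all(len(d) == 2 for d in draws)
        assert draws == dq.select_guides(self.guides, 1000, strat)

    def test_tie_break_by_guide_id(self):
        tied = [make_guide("b", pam_start=990), make_guide("a", pam_start=1010)]
        got = dq.select_guides(tied, 1000, SelectionStrategy("closest", k=1))
        assert got == ["a"]

    def test_too_few_candidates(self):
        with pytest.raises(DesignQCError, match="candidate"):
            dq.select_guides(self.guides, 1000, SelectionStrategy("closest", k=9))

    def test_strategy_validation(self):
        with pytest.raises(DesignQCError):
            SelectionStrategy("nearest", k=2)
        with pytest.raises(DesignQCError):
            SelectionStrategy("closest", k=0)


class TestSelectTssControls:
    def test_ten_closest(self):
        guides = [make_guide(f"g{d}", pam_start=1000 + d)
                  for d in range(5, 105, 5)]
        out = dq.select_tss_controls(guides, [("chr1", 1000)], k=10)
        chosen = out[("chr1", 1000)]
        assert chosen == [f"g{d}" for d in range(5, 55, 5)]

    def test_warns_when_fewer_than_k(self):
        guides = [make_guide("only", pam_start=1100)]
        with pytest.warns(RuntimeWarning, match="only 1"):
            out = dq.select_tss_controls(guides, [("chr1", 1000)], k=10)
        assert out[("chr1", 1000)] == ["only"]
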