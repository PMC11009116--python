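import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crekit import element_caller as ec
from crekit.element_caller import CallerError
from crekit.genome_intervals import BinGrid
from crekit.guide_effects import EffectTable

from conftest import make_guide


def _table(effects: dict[str, float]) -> EffectTable:
    df = pd.DataFrame({"rep1": effects, "mean": effects})
    df.index.name = "guide_id"
    return EffectTable(data=df, method="mean_norm",
                       sign_convention="A_enriched_positive")


class TestPerGuidePvalues:
    def test_control_z_matches_formula(self):
        rng = np.random.default_rng(0)
        ctrl = {f"c{i}": float(x) for i, x in enumerate(rng.normal(0, 0.1, 40))}
        effects = {**ctrl, "hit": 0.8}
        table = _table(effects)
        p = ec.per_guide_pvalues(table, list(ctrl))
        mu = np.mean(list(ctrl.values()))
        sd = np.std(list(ctrl.values()), ddof=1)
        expected = 2 * stats.norm.sf(abs(0.8 - mu) / sd)
        assert p["hit"] == pytest.approx(expected, rel=1e-12)
        assert (p > 0).all() and (p <= 1).all()

    def test_requires_30_controls(self):
        effects = {f"c{i}": 0.1 * i for i in range(29)}
        with pytest.raises(CallerError, match=">=30"):
            ec.per_guide_pvalues(_table(effects), list(effects))

    def test_constant_controls_rejected(self):
        effects = {f"c{i}": 0.0 for i in range(40)}
        with pytest.raises(CallerError, match="constant"):
            ec.per_guide_pvalues(_table(effects), list(effects))

    def test_external_passthrough_and_validation(self):
        table = _table({"a": 1.0, "b": 2.0})
        p = ec.per_guide_pvalues(table, [], mode="external",
                                 external={"a": 0.01, "b": 1.0})
        assert p["a"] == 0.01 and p["b"] == 1.0
        with pytest.raises(CallerError, match="outside"):
            ec.per_guide_pvalues(table, [], mode="external",
                                 external={"a": 0.0})
        with pytest.raises(CallerError):
            ec.per_guide_pvalues(table, [], mode="external", external=None)


class TestFisherAggregate:
    def test_df4_closed_form(self):
        # chi-square(4) survival has the closed form e^(-x/2)(1 + x/2)
        for pa, pb in [(0.5, 0.5), (0.01, 0.9), (1e-6, 0.3), (0.2, 0.04)]:
            x, agg = ec.fisher_aggregate([pa, pb])
            assert x == pytest.approx(-2 * (math.log(pa) + math.log(pb)), abs=1e-12)
            closed = math.exp(-x / 2) * (1 + x / 2)
            assert agg == pytest.approx(closed, abs=1e-12)

    def test_worked_example(self):
        x, agg = ec.fisher_aggregate([0.5, 0.5])
        assert x == pytest.approx(2.7726, abs=1e-4)
        assert agg == pytest.approx(0.5966, abs=1e-4)

    def test_k1_identity(self):
        for p in (0.01, 0.5, 0.999):
            _, agg = ec.fisher_aggregate([p])
            assert agg == pytest.approx(p, rel=1e-12)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            x, agg = ec.fisher_aggregate([0.0, 0.5])
        assert math.isfinite(x) and agg >= 0.0


def _isolated_guides(n, spacing=1000):
    """Guides whose dcas9_krab footprints each occupy exactly one 100-bp bin."""
    return [
        make_guide(f"g{i:03d}", pam_start=i * spacing + 550) for i in range(n)
    ]


class TestAggregateAndCall:
    def test_bh_worked_example(self):
        # 100 one-guide bins: 5 with p=1e-5, 95 with p=0.5 -> BH-adjusted
        # 1e-5*100/5 = 2e-4 < 0.01 -> exactly 5 significant bins/calls
        guides = _isolated_guides(100)
        pvals = {g.guide_id: (1e-5 if i < 5 else 0.5)
                 for i, g in enumerate(guides)}
        bins, calls = ec.aggregate_and_call(
            pvals, guides, BinGrid(), "cas9", fdr_threshold=0.01
        )
        assert len(bins) == 100
        sig = [b for b in bins if b.fdr < 0.01]
        assert len(sig) == 5
        assert len(calls) == 5
        for b in sig:
            assert b.fdr == pytest.approx(2e-4, rel=1e-9)

    def test_adjacent_significant_bins_merge(self):
        # krab footprint (±150) spreads one strong guide over 4 bins;
        # the run of significant bins merges into a single call
        guides = [make_guide("strong", pam_start=1000)] + _isolated_guides(
            60, spacing=2000
        )
        pvals = {"strong": 1e-12, **{g.guide_id: 0.5 for g in guides[1:]}}
        _, calls = ec.aggregate_and_call(
            pvals, guides, BinGrid(), "dcas9_krab", fdr_threshold=0.01
        )
        assert len(calls) == 1
        call = calls[0]
        assert call.interval.start == 800 and call.interval.end == 1200
        assert call.interval.name == "cre_1"

    def test_direction_restriction(self):
        guides = _isolated_guides(40)
        pvals = {g.guide_id: (1e-8 if i < 2 else 0.5)
                 for i, g in enumerate(guides)}
        effects = {g.guide_id: (0.5 if i == 0 else -0.5 if i == 1 else 0.0)
                   for i, g in enumerate(guides)}
        _, pos_calls = ec.aggregate_and_call(
            pvals, guides, BinGrid(), "cas9", effects=effects,
            direction="positive",
        )
        assert len(pos_calls) == 1
        assert pos_calls[0].mean_effect > 0

    def test_empty_input(self):
        assert ec.aggregate_and_call({}, [], BinGrid(), "cas9") == ([], [])


class TestOutlierSensitivity:
    def test_single_outlier_bin_loses_significance(self):
        # one bin carried by p=[1e-10, 0.6, 0.7]: dropping the outlier leaves
        # X = -2(ln 0.6 + ln 0.7) = 1.735, df 4 -> p = 0.784
        base = 550
        guides = [
            make_guide("a", pam_start=base),
            make_guide("b", pam_start=base + 1),
            make_guide("c", pam_start=base + 2),
        ] + _isolated_guides(50, spacing=2000)[1:]
        pvals = {"a": 1e-10, "b": 0.6, "c": 0.7,
                 **{g.guide_id: 0.5 for g in guides[3:]}}
        result = ec.outlier_sensitivity(pvals, guides, BinGrid(), "cas9")
        assert len(result["calls_full"]) == 1
        assert result["calls_dropped"] == []
        assert result["bins_losing_significance"] == [("chr1", 500)]
        dropped = [b for b in result["bins_dropped"] if b.bin.start == 500][0]
        assert dropped.fisher_stat == pytest.approx(
            -2 * (math.log(0.6) + math.log(0.7)), abs=1e-4
        )
        assert dropped.aggregated_p == pytest.approx(0.784, abs=1e-3)

    def test_robust_bin_stays_significant(self):
        # p = [1e-6, 1e-6, 1e-6]: after removal X = 55.26, and the df=4
        # closed form e^(-x/2)(1+x/2) gives p = 2.86e-11
        base = 550
        guides = [
            make_guide("a", pam_start=base),
            make_guide("b", pam_start=base + 1),
            make_guide("c", pam_start=base + 2),
        ] + _isolated_guides(50, spacing=2000)[1:]
        pvals = {"a": 1e-6, "b": 1e-6, "c": 1e-6,
                 **{g.guide_id: 0.5 for g in guides[3:]}}
        result = ec.outlier_sensitivity(pvals, guides, BinGrid(), "cas9")
        assert len(result["calls_dropped"]) == 1
        dropped = [b for b in result["bins_dropped"] if b.bin.start == 500][0]
        assert dropped.fisher_stat == pytest.approx(55.26, abs=0.01)
        x = dropped.fisher_stat
        assert dropped.aggregated_p == pytest.approx(
            math.exp(-x / 2) * (1 + x / 2), rel=1e-9
        )
        assert dropped.aggregated_p == pytest.approx(2.863e-11, rel=0.01)
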