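"""Cis/trans decomposition: estimates, contrasts, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aseq.amplicon import AlleleCount
from aseq.cistrans import (
    RatioObservation,
    decompose,
    log_allele_ratio,
    maternal_allele_check,
)
from aseq.cistrans import test_cis as cis_contrast
from aseq.cistrans import test_trans as trans_contrast

PAIRS = ("C2xS1", "C4xS2", "C6xS3")


def binomial_observations(prop_a, cross_types, depth=20_000, reps=4, seed=0, gene="fiz"):
    """Binomial allele counts -> log-ratio observations across the design."""
    rng = np.random.default_rng(seed)
    obs = []
    for pair in PAIRS:
        for ct in cross_types:
            for rep in range(reps):
                n_a = int(rng.binomial(depth, prop_a))
                count = AlleleCount(
                    f"{pair}_{ct}_{rep}", gene, n_a, depth - n_a, 0, depth
                )
                obs.append(log_allele_ratio(count, cross_type=ct, pair_id=pair))
    return obs


class TestLogAlleleRatio:
    def test_balanced_counts_give_zero(self):
        obs = log_allele_ratio(AlleleCount("s", "g", 5000, 5000, 0, 10_000))
        assert obs.log_ratio == 0.0
        assert obs.prop_b == 0.5

    def test_direct_arithmetic(self):
        obs = log_allele_ratio(AlleleCount("s", "g", 500, 100, 0, 600))
        assert obs.log_ratio == pytest.approx(math.log(5.0))

    def test_pseudocount_only_on_zero(self):
        obs = log_allele_ratio(AlleleCount("s", "g", 100, 0, 0, 100))
        assert obs.log_ratio == pytest.approx(math.log(100.5 / 0.5))
        # nonzero counts untouched
        exact = log_allele_ratio(AlleleCount("s", "g", 100, 1, 0, 101))
        assert exact.log_ratio == pytest.approx(math.log(100.0))

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            log_allele_ratio(AlleleCount("s", "g", 0, 0, 0, 0))


class TestCisContrast:
    def test_all_zero_ratios_report_no_deviation(self):
        obs = [
            RatioObservation(f"s{i}", "g", ct, pair, 0.0, 0.5)
            for i, (pair, ct) in enumerate(
                (p, c) for p in PAIRS for c in ("F1_SC", "F1_CS")
            )
        ]
        res = cis_contrast(obs)
        assert res.estimate == 0.0
        assert res.p == 1.0

    def test_pure_cis_simulation_detected(self):
        # 5-fold allele bias: F1 allele-b proportion 1/6
        obs = binomial_observations(prop_a=5 / 6, cross_types=("F1_SC", "F1_CS"), seed=1)
        res = cis_contrast(obs)
        assert res.p < 0.01
        assert res.estimate == pytest.approx(math.log(5.0), abs=0.05)
        assert res.df == 5  # 3 pairs x 2 directions - 1

    def test_single_cell_rejected(self):
        obs = [RatioObservation("s", "g", "F1_SC", "C2xS1", 1.0, 0.3)]
        with pytest.raises(ValueError):
            cis_contrast(obs)


class TestTransContrast:
    def test_identical_groups_give_null(self):
        f1 = binomial_observations(prop_a=0.5, cross_types=("F1_SC", "F1_CS"), seed=2)
        mix = [
            RatioObservation(o.sample_id + "m", o.gene_id, "MIX_5050", o.pair_id,
                             o.log_ratio, o.prop_b)
            for o in f1
        ]
        res = trans_contrast(f1, mix)
        assert res.estimate == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pure_trans_simulation_detected(self):
        # F1 balanced, parental (mix) 4-fold: everything is trans
        f1 = binomial_observations(prop_a=0.5, cross_types=("F1_SC", "F1_CS"), seed=3)
        mix = binomial_observations(prop_a=0.8, cross_types=("MIX_5050",), seed=4)
        res = trans_contrast(f1, mix)
        assert res.p < 0.05
        assert res.estimate == pytest.approx(math.log(4.0), abs=0.05)

    def test_pure_cis_simulation_is_null_for_trans(self):
        f1 = binomial_observations(prop_a=5 / 6, cross_types=("F1_SC", "F1_CS"), seed=5)
        mix = binomial_observations(prop_a=5 / 6, cross_types=("MIX_5050",), seed=6)
        res = trans_contrast(f1, mix)
        assert abs(res.estimate) < 0.05
        assert res.p > 0.05


class TestDecompose:
    def test_cis_only_gives_percent_cis_near_100(self):
        f1 = binomial_observations(prop_a=5 / 6, cross_types=("F1_SC", "F1_CS"), seed=7)
        mix = binomial_observations(prop_a=5 / 6, cross_types=("MIX_5050",), seed=8)
        res = decompose(f1, mix)
        assert res.percent_cis == pytest.approx(100.0, abs=5.0)
        assert res.cis_estimate + res.trans_estimate == res.total_estimate  # exact

    def test_trans_only_gives_percent_cis_near_0(self):
        f1 = binomial_observations(prop_a=0.5, cross_types=("F1_SC", "F1_CS"), seed=9)
        mix = binomial_observations(prop_a=0.8, cross_types=("MIX_5050",), seed=10)
        res = decompose(f1, mix)
        assert res.percent_cis == pytest.approx(0.0, abs=5.0)

    def test_degenerate_zero_total_flagged(self):
        f1 = [
            RatioObservation(f"f{i}", "g", ct, pair, 0.0, 0.5)
            for i, (pair, ct) in enumerate((p, c) for p in PAIRS for c in ("F1_SC", "F1_CS"))
        ]
        mix = [
            RatioObservation(f"m{i}", "g", "MIX_5050", pair, 0.0, 0.5)
            for i, pair in enumerate(PAIRS)
        ]
        res = decompose(f1, mix)
        assert res.trans_estimate == 0.0
        assert not res.percent_cis_defined
        assert math.isnan(res.percent_cis)

    def test_label_swap_negates_estimates_keeps_p(self):
        rng_seeds = (11, 12)
        f1 = binomial_observations(prop_a=5 / 6, cross_types=("F1_SC", "F1_CS"), seed=rng_seeds[0])
        mix = binomial_observations(prop_a=5 / 6, cross_types=("MIX_5050",), seed=rng_seeds[1])
        flip = lambda obs: [
            RatioObservation(o.sample_id, o.gene_id, o.cross_type, o.pair_id,
                             -o.log_ratio, 1 - o.prop_b)
            for o in obs
        ]
        res = decompose(f1, mix)
        res_flipped = decompose(flip(f1), flip(mix))
        assert res_flipped.cis_estimate == pytest.approx(-res.cis_estimate)
        assert res_flipped.total_estimate == pytest.approx(-res.total_estimate)
        assert res_flipped.cis_test.p == pytest.approx(res.cis_test.p)
        assert res_flipped.trans_test.p == pytest.approx(res.trans_test.p)

    @given(
        cis_fold=st.floats(1.5, 8.0),
        trans_fold=st.floats(1.0, 4.0),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=15, deadline=None)
    def test_parameter_recovery_property(self, cis_fold, trans_fold, seed):
        # F1 proportion encodes the cis fold; the mix encodes cis x trans
        f1_prop = cis_fold / (1 + cis_fold)
        total_fold = cis_fold * trans_fold
        mix_prop = total_fold / (1 + total_fold)
        f1 = binomial_observations(prop_a=f1_prop, cross_types=("F1_SC", "F1_CS"),
                                   depth=50_000, seed=seed)
        mix = binomial_observations(prop_a=mix_prop, cross_types=("MIX_5050",),
                                    depth=50_000, seed=seed + 1)
        res = decompose(f1, mix)
        # binomial SE of a cell-mean log ratio at this depth is ~0.01; 3 SE margin
        margin = 3 * math.sqrt(1 / (50_000 * f1_prop * (1 - f1_prop)) / 4)
        assert res.cis_estimate == pytest.approx(math.log(cis_fold), abs=max(margin, 0.02))
        assert res.trans_estimate == pytest.approx(math.log(trans_fold), abs=max(2 * margin, 0.04))


class TestMaternalCheck:
    def _expr(self, f1_sc, f1_cs, sel=-2.0, ctl=0.0, reps=3):
        rows = []
        for group, mean in (
            ("PARENT_SEL", sel), ("PARENT_CTL", ctl), ("F1_SC", f1_sc), ("F1_CS", f1_cs)
        ):
            for i in range(reps):
                rows.append((f"{group}_{i}", group, mean))
        return pd.DataFrame(rows, columns=["sample_id", "group", "log2_expr"])

    def test_f1_at_maternal_mean_is_maternal_like(self):
        out = maternal_allele_check(self._expr(f1_sc=-2.0, f1_cs=0.0))
        assert out["F1_SC"].s == pytest.approx(1.0)
        assert out["F1_SC"].label == "maternal_like"
        assert out["F1_CS"].label == "maternal_like"

    def test_midway_is_intermediate(self):
        out = maternal_allele_check(self._expr(f1_sc=-1.0, f1_cs=-1.0))
        assert out["F1_SC"].s == pytest.approx(0.5)
        assert out["F1_SC"].label == "intermediate"

    def test_x_linked_cis_simulation_both_maternal(self):
        rng = np.random.default_rng(0)
        rows = []
        for group, mean in (
            ("PARENT_SEL", -2.0), ("PARENT_CTL", 0.0), ("F1_SC", -2.0), ("F1_CS", 0.0)
        ):
            for i in range(4):
                rows.append((f"{group}_{i}", group, mean + rng.normal(0, 0.1)))
        out = maternal_allele_check(pd.DataFrame(rows, columns=["sample_id", "group", "log2_expr"]))
        assert out["F1_SC"].label == "maternal_like"
        assert out["F1_CS"].label == "maternal_like"

    def test_equal_parents_rejected(self):
        with pytest.raises(ValueError, match="axis undefined"):
            maternal_allele_check(self._expr(f1_sc=0.0, f1_cs=0.0, sel=0.0, ctl=0.0))
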