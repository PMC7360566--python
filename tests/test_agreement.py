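"""Correlations, call-set algebra, t tests, CV and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synscreen as ss
from synscreen.agreement import CallSet, significance_stars
from synscreen.errors import DesignError


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(5.0)
        assert ss.pearson_r(x, x)[0] == pytest.approx(1.0)
        assert ss.pearson_r(x, -2 * x + 5)[0] == pytest.approx(-1.0)

    def test_hand_computed_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        # direct product-moment formula
        oracle = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        r, n = ss.pearson_r(x, y)
        assert r == pytest.approx(oracle, rel=1e-12)
        assert n == 4

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.1]
        r, n = ss.pearson_r(x, y)
        assert n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(DesignError):
            ss.pearson_r([1, 1, 1], [1, 2, 3])


class TestUniqueCalls:
    def _cs(self, readout, calls):
        return CallSet(readout=readout, culture_format="2D",
                       calls=frozenset(calls))

    def test_identical_callsets_have_no_unique(self):
        calls = {("c1", ("A", "B"))}
        out = ss.unique_calls([self._cs("viability", calls),
                               self._cs("confluency", calls)])
        assert out["viability"]["unique"] == set()
        assert out["confluency"]["unique"] == set()

    def test_single_caller_owns_its_call(self):
        a = ("c1", ("A", "B"))
        out = ss.unique_calls([self._cs("viability", {a}),
                               self._cs("confluency", set())])
        assert out["viability"]["unique"] == {a}

    def test_constructed_overlaps_match_set_algebra(self):
        rng = np.random.default_rng(4)
        grid = [(f"c{i}", (f"d{j}", f"d{k}")) for i in range(3)
                for j in range(4) for k in range(j + 1, 4)]
        callsets = []
        member = {}
        for name in ("viability", "confluency", "celltox", "nucview"):
            calls = {g for g in grid if rng.random() < 0.3}
            member[name] = calls
            callsets.append(self._cs(name, calls))
        out = ss.unique_calls(callsets)
        for name, calls in member.items():
            others = set().union(*(v for k, v in member.items() if k != name))
            assert out[name]["unique"] == calls - others
            assert out[name]["total"] == len(calls)
        # partition: union of uniques plus shared calls rebuilds the union
        union_all = set().union(*member.values())
        uniques = set().union(*(out[n]["unique"] for n in member))
        shared = {c for c in union_all
                  if sum(c in m for m in member.values()) >= 2}
        assert uniques | shared == union_all

    def test_mismatched_grids_rejected(self):
        g1 = frozenset({("c1", ("A", "B"))})
        g2 = frozenset({("c2", ("A", "B"))})
        with pytest.raises(DesignError):
            ss.unique_calls([CallSet("viability", "2D", frozenset(), g1),
                             CallSet("confluency", "2D", frozenset(), g2)])


class TestCompareGroups:
    def test_identical_groups_no_star(self):
        res = ss.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0)
        assert res.stars == ""

    def test_strong_separation_three_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        res = ss.compare_groups(a, b)
        assert res.stars == "***"
        # direction agreement between paired and unpaired variants
        paired = ss.compare_groups(a, b, paired=True)
        assert np.sign(paired.statistic) == np.sign(res.statistic)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(DesignError):
            ss.compare_groups([1, 2, 3], [1, 2], paired=True)

    def test_insufficient_n_rejected(self):
        with pytest.raises(DesignError):
            ss.compare_groups([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.05, "*"), (0.02, "*"), (0.01, "**"),
        (0.002, "**"), (0.001, "***"), (1e-6, "***")])
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars


class TestCV:
    def test_constant_vector_zero(self):
        assert ss.cv([3.0, 3.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        # sample sd of (8, 12) is 2*sqrt(2); mean 10
        assert ss.cv([8.0, 12.0]) == pytest.approx(2 * np.sqrt(2) / 10, rel=1e-12)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        v = np.array([4.0, 5.0, 6.5, 5.5])
        assert ss.cv(c * v) == pytest.approx(ss.cv(v), rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(DesignError):
            ss.cv([-1.0, 1.0])

    def test_multiplicative_noise_recovered_from_screen(self):
        """Per-condition CV of normalized wells ~ the generator's noise sd."""
        cfg = ss.default_config(cell_lines=("HCT-116",), formats=("2D",),
                                drugs={"A": ss.HillParams(), "B": ss.HillParams()},
                                ec50_scale={}, interactions={},
                                noise_sd={"2D": 0.10}, n_tech=4, n_bio=2,
                                include_single_screen=True,
                                readouts=("viability",), seed=21)
        tbl = ss.cv_table(ss.normalize_dataset(ss.simulate_screen(cfg)))
        # mean CV concentrates near 0.10 (small-sample sd bias of n=4
        # shrinks it by c4 ~ 0.921); 0.015 is ~3 sampling SEs of the mean
        assert tbl["cv"].mean() == pytest.approx(0.10 * 0.921, abs=0.015)

    def test_overall_cv_is_group_mean(self):
        tbl = pd.DataFrame({"bio_rep": [1, 1, 2], "readout": ["viability"] * 3,
                            "cv": [0.1, 0.3, 0.2]})
        out = ss.overall_cv(tbl)
        r1 = out[out["bio_rep"] == 1]["cv_overall"].iloc[0]
        assert r1 == pytest.approx(0.2)
        assert out[out["bio_rep"] == 2]["cv_overall"].iloc[0] == pytest.approx(0.2)


class TestReplicateCorrelation:
    def test_duplicated_replicate_gives_r_one(self):
        cfg = ss.default_config(cell_lines=("HCT-116",), formats=("2D",),
                                drugs={"A": ss.HillParams(1, 0.2, 0.5, 1),
                                       "B": ss.HillParams(1, 0.3, 1.0, 1)},
                                ec50_scale={}, interactions={("A", "B"): -0.1},
                                noise_sd={"2D": 0.0}, include_single_screen=False,
                                readouts=("viability",), seed=0)
        norm = ss.normalize_dataset(ss.simulate_screen(cfg))
        rep = ss.replicate_correlation(norm, "intra_screen")
        assert rep.pearson_r[("2D", "viability")] == pytest.approx(1.0, abs=1e-9)

    def test_inter_screen_requires_shared_doses(self):
        cfg = ss.default_config(cell_lines=("HCT-116",), formats=("2D",),
                                drugs={"A": ss.HillParams(), "B": ss.HillParams()},
                                ec50_scale={}, interactions={},
                                noise_sd={"2D": 0.0}, include_single_screen=False,
                                readouts=("viability",), seed=0)
        norm = ss.normalize_dataset(ss.simulate_screen(cfg))
        # single-drug screen absent -> no shared single-agent conditions
        with pytest.raises(DesignError):
            ss.replicate_correlation(norm, "inter_screen")

    def test_unknown_level_rejected(self, noise_free_normalized):
        with pytest.raises(DesignError):
            ss.replicate_correlation(noise_free_normalized, "between_labs")
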