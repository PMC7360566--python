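"""Bliss scoring, replicate averaging, summaries, synergy counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import synscreen as ss
from synscreen.errors import DesignError
from synscreen.screen_model import DoseMatrix

DOSES = np.array([0.0, 0.1, 0.3, 1.0, 3.0])


def make_matrix(response, bio_rep=1, **kw):
    response = np.asarray(response, dtype=float)
    n = np.full(response.shape, 4)
    fields = dict(cell_line="HCT-116", culture_format="2D", drug_a="A",
                  drug_b="B", doses_a=DOSES.copy(), doses_b=DOSES.copy(),
                  readout="viability", bio_rep=bio_rep, response=response,
                  n_tech=n)
    fields.update(kw)
    return DoseMatrix(**fields)


def outer_product_matrix(edge_a, edge_b):
    """Bliss-null matrix: interior equals the outer product of its edges."""
    resp = np.empty((5, 5))
    resp[0, 0] = 1.0
    resp[1:, 0] = edge_a
    resp[0, 1:] = edge_b
    resp[1:, 1:] = np.outer(edge_a, edge_b)
    return make_matrix(resp)


class TestBlissFormulas:
    @pytest.mark.parametrize("ea,eb,expected", [
        (0.0, 0.0, 0.0), (1.0, 0.3, 1.0), (0.5, 0.5, 0.75)])
    def test_expected_effect(self, ea, eb, expected):
        assert ss.bliss_expected_effect(ea, eb) == pytest.approx(expected)
        assert ss.bliss_expected_effect(eb, ea) == pytest.approx(expected)

    def test_excess_zero_under_independence(self):
        assert ss.bliss_excess(0.6 * 0.5, 0.6, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_excess_sign_convention(self):
        assert ss.bliss_excess(0.2, 0.6, 0.5) == pytest.approx(-0.10)

    def test_out_of_range_clamped(self):
        # supra-vehicle single agents are clamped to 1 before the product
        assert ss.bliss_excess(1.0, 1.2, 1.0) == pytest.approx(0.0)

    @given(v_obs=st.floats(0.0, 1.5), v_a=st.floats(0.0, 1.0),
           v_b=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_effect_and_viability_scales_agree(self, v_obs, v_a, v_b):
        """(E_A + E_B - E_A*E_B) - E_obs == V_obs - V_A*V_B with E = 1 - V."""
        via_scale = ss.bliss_excess(v_obs, v_a, v_b)
        eff_scale = ss.bliss_expected_effect(1 - v_a, 1 - v_b) - (1 - v_obs)
        assert via_scale == pytest.approx(eff_scale, abs=1e-12)


class TestScoreMatrix:
    def test_outer_product_scores_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            m = outer_product_matrix(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
            g = ss.score_matrix(m)
            assert np.nanmax(np.abs(g.excess)) < 1e-12

    def test_missing_cell_propagates(self):
        m = outer_product_matrix(np.full(4, 0.8), np.full(4, 0.7))
        m.response[2, 3] = np.nan
        m.n_tech[2, 3] = 0
        g = ss.score_matrix(m)
        assert np.isnan(g.excess[1, 2])
        assert np.isfinite(g.excess).sum() == 15

    def test_missing_edge_blanks_dependents(self):
        m = outer_product_matrix(np.full(4, 0.8), np.full(4, 0.7))
        m.response[3, 0] = np.nan  # drug A edge at its 3rd nonzero dose
        g = ss.score_matrix(m)
        assert np.isnan(g.excess[2, :]).all()
        assert np.isfinite(g.excess).sum() == 12

    def test_uniform_delta_recovered(self):
        edge_a, edge_b = np.array([0.9, 0.8, 0.7, 0.6]), np.array([0.95, 0.8, 0.6, 0.5])
        resp = outer_product_matrix(edge_a, edge_b).response
        resp[1:, 1:] -= 0.1
        g = ss.score_matrix(make_matrix(resp))
        assert np.allclose(g.excess, -0.1)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        resp = rng.uniform(0.1, 1.0, (5, 5))
        m = make_matrix(resp)
        g, gt = ss.score_matrix(m), ss.score_matrix(m.transpose())
        assert np.allclose(gt.excess, g.excess.T)
        s, st_ = ss.summarize(g), ss.summarize(gt)
        assert st_.mean_excess == pytest.approx(s.mean_excess)
        assert st_.mean_viability == pytest.approx(s.mean_viability)
        assert st_.n_effective == s.n_effective


class TestAverageReplicates:
    def test_identical_grids_mean_and_zero_sd(self):
        g = ss.score_matrix(outer_product_matrix(np.full(4, 0.8), np.full(4, 0.6)))
        avg = ss.average_replicates([g, g])
        assert np.allclose(avg.excess, g.excess)
        assert np.allclose(avg.sd, 0.0)
        assert (avg.n_rep == 2).all()

    def test_cellwise_mean(self):
        base = outer_product_matrix(np.full(4, 0.9), np.full(4, 0.9))
        r1, r2 = base.response.copy(), base.response.copy()
        r1[1, 1] -= 0.2  # excess -0.2 in replicate 1, 0.0 in replicate 2
        g1 = ss.score_matrix(make_matrix(r1, bio_rep=1))
        g2 = ss.score_matrix(make_matrix(r2, bio_rep=2))
        avg = ss.average_replicates([g1, g2])
        assert avg.excess[0, 0] == pytest.approx(-0.1)
        assert avg.sd[0, 0] == pytest.approx(np.std([-0.2, 0.0], ddof=1))

    def test_incompatible_axes_rejected(self):
        g1 = ss.score_matrix(outer_product_matrix(np.full(4, .8), np.full(4, .8)))
        other = make_matrix(outer_product_matrix(np.full(4, .8), np.full(4, .8)).response,
                            doses_a=DOSES * 2)
        with pytest.raises(DesignError):
            ss.average_replicates([g1, ss.score_matrix(other)])

    def test_stochastic_cell_means_within_sampling_bound(self):
        """Cell means over tech x bio replicates stay within 3 sampling SEs of
        the injected deviation when noise is applied directly to the
        combination cells (sigma=0.05, 4 tech x 2 bio)."""
        rng = np.random.default_rng(99)
        sigma, t, b, delta = 0.05, 4, 2, -0.1
        edge_a, edge_b = np.full(4, 0.9), np.full(4, 0.8)
        misses = trials = 0
        for _ in range(50):
            grids = []
            for bio in range(b):
                resp = outer_product_matrix(edge_a, edge_b).response
                resp[1:, 1:] += delta + rng.normal(0, sigma / np.sqrt(t), (4, 4))
                grids.append(ss.score_matrix(make_matrix(resp, bio_rep=bio + 1)))
            avg = ss.average_replicates(grids)
            trials += avg.excess.size
            misses += int((np.abs(avg.excess - delta) > 3 * sigma / np.sqrt(t * b)).sum())
        assert misses / trials < 0.05  # 3-sigma coverage ~99.7%


class TestSummaries:
    def test_zero_grid_not_synergistic(self):
        g = ss.score_matrix(outer_product_matrix(np.full(4, 0.8), np.full(4, 0.8)))
        s = ss.summarize(g)
        assert s.synergistic is False  # strict inequality at exactly 0
        assert s.n_effective == 0

    def test_low_viability_synergy_all_effective(self):
        resp = outer_product_matrix(np.full(4, 0.8), np.full(4, 0.5)).response
        resp[1:, 1:] = 0.4  # excess 0.4 - 0.4 = 0 ... adjust to negative
        resp[1:, 1:] -= 0.05
        s = ss.summarize(ss.score_matrix(make_matrix(resp)))
        assert s.synergistic and s.n_effective == 16

    def test_viability_gate_blocks_weak_killing(self):
        resp = outer_product_matrix(np.full(4, 0.9), np.full(4, 0.8)).response
        resp[1:, 1:] -= 0.05  # synergy, but viability ~0.67 > 0.5
        s = ss.summarize(ss.score_matrix(make_matrix(resp)))
        assert s.synergistic and s.n_effective == 0

    def test_boundary_viability_exactly_half_counts(self):
        """The effectiveness gate is <= 0.5; excess must be strictly < 0."""
        resp = outer_product_matrix(np.full(4, 0.9), np.full(4, 0.7)).response
        resp[1:, 1:] = 0.5  # viability exactly at the threshold
        s = ss.summarize(ss.score_matrix(make_matrix(resp)))
        # every cell has excess 0.5 - 0.63 < 0 and viability == 0.5
        assert s.n_effective == 16
        resp[1:, 1:] = np.outer(np.full(4, 0.9), np.full(4, 0.7))  # excess exactly 0
        s0 = ss.summarize(ss.score_matrix(make_matrix(resp)))
        assert s0.n_effective == 0 and s0.synergistic is False

    def test_all_missing_rejected(self):
        m = make_matrix(np.full((5, 5), np.nan))
        with pytest.raises(DesignError):
            ss.summarize(ss.score_matrix(m))


class TestCountSynergies:
    def _summary(self, fmt, cell, pair, mean_excess):
        resp = outer_product_matrix(np.full(4, 0.9), np.full(4, 0.9)).response
        resp[1:, 1:] += mean_excess
        m = make_matrix(resp, cell_line=cell, culture_format=fmt,
                        drug_a=pair[0], drug_b=pair[1])
        return ss.summarize(ss.score_matrix(m))

    def test_all_null_counts_zero(self):
        sums = [self._summary("2D", c, ("A", "B"), 0.0) for c in ("c1", "c2", "c3")]
        out = ss.count_synergies(sums)
        assert out["2D"]["n_synergistic_combinations"] == 0

    def test_at_least_one_cell_line_semantics(self):
        sums = [self._summary("2D", "c1", ("A", "B"), -0.1),
                self._summary("2D", "c2", ("A", "B"), -0.1),
                self._summary("2D", "c3", ("A", "B"), 0.1),
                self._summary("2D", "c1", ("A", "C"), 0.1)]
        out = ss.count_synergies(sums)
        assert out["2D"]["n_synergistic_combinations"] == 1
        assert out["2D"]["synergistic_pairs"] == [("A", "B")]

    def test_incomplete_design_reports_missing(self):
        sums = [self._summary("2D", "c1", ("A", "B"), 0.0)]
        with pytest.raises(DesignError, match="missing"):
            ss.count_synergies(sums, drug_panel=["A", "B", "C"], cell_lines=["c1"])

    def test_bin_counts_partition_all_summaries(self):
        rng = np.random.default_rng(2)
        sums = [self._summary("3D", f"c{i}", ("A", "B"), float(d))
                for i, d in enumerate(rng.uniform(-0.3, 0.3, 9))]
        out = ss.count_synergies(sums)
        assert sum(out["3D"]["bin_counts"]) == 9

    def test_noise_free_screen_counts_match_truth(self, noise_free_config,
                                                  noise_free_summaries):
        truth = ss.truth_table(noise_free_config)
        expected = {}
        for fmt in ("2D", "3D"):
            sub = truth[truth["culture_format"] == fmt]
            syn = sub[sub["synergistic"]]
            expected[fmt] = syn.groupby(["drug_a", "drug_b"]).ngroups
        out = ss.count_synergies(list(noise_free_summaries.values()),
                                 drug_panel=sorted(noise_free_config.drugs),
                                 cell_lines=noise_free_config.cell_lines)
        for fmt in ("2D", "3D"):
            assert out[fmt]["n_synergistic_combinations"] == expected[fmt]
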