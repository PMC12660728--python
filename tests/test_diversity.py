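"""Diversity partitioning, turnover, river summaries, QC and regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverscape.diversity import (
    absolute_turnover,
    alpha_density,
    diversity_profile,
    incidence_by_stream_order,
    minmax_normalize,
    occurrence_qc,
    ols_r2,
    richness_by_order,
    summarize_river_network,
    turnover_matrix,
    whittaker_beta,
)
from riverscape.errors import ValidationError


def _records(rows):
    return pd.DataFrame(rows, columns=["species", "lat", "lon", "basin",
                                       "stream_order"])


class TestMinMaxNormalize:
    def test_example(self):
        np.testing.assert_allclose(minmax_normalize([0, 5, 10]), [0, 0.5, 1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            minmax_normalize([7, 7, 7])

    @given(
        xs=st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=20).filter(
            lambda v: max(v) > min(v)
        ),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    @settings(deadline=None, derandomize=True)
    def test_affine_invariance(self, xs, a, b):
        base = minmax_normalize(xs)
        trans = minmax_normalize([a * x + b for x in xs])
        np.testing.assert_allclose(trans, base, atol=1e-9)


class TestWhittakerBeta:
    @pytest.mark.parametrize("gamma,alphas,expected",
                             [(12, (4, 4, 4), 3.0),
                              (5, (5, 5, 5), 1.0),
                              (10, (2, 3, 5), 3.0)])
    def test_values(self, gamma, alphas, expected):
        assert whittaker_beta(gamma, alphas) == pytest.approx(expected)

    def test_zero_mean_alpha_rejected(self):
        with pytest.raises(ValidationError):
            whittaker_beta(5, (0, 0))

    def test_gamma_below_max_alpha_rejected(self):
        with pytest.raises(ValidationError):
            whittaker_beta(3, (4, 2))

    def test_removing_a_species_from_one_order_raises_beta(self):
        """Losing one incidence (not the whole species) lowers mean alpha
        while gamma is unchanged, so beta_W must increase."""
        inc = pd.DataFrame(
            [[1, 1, 1], [1, 1, 0], [0, 1, 1]],
            index=["s1", "s2", "s3"], columns=[1, 2, 3],
        )
        S = richness_by_order(inc)
        before = whittaker_beta(len(inc), S.to_numpy())
        inc2 = inc.copy()
        inc2.loc["s1", 2] = 0
        after = whittaker_beta(len(inc2), richness_by_order(inc2).to_numpy())
        assert after > before


class TestAbsoluteTurnover:
    @pytest.mark.parametrize("s1,s2,c,expected",
                             [(5, 7, 3, 6), (4, 4, 4, 0), (4, 5, 0, 9)])
    def test_values(self, s1, s2, c, expected):
        assert absolute_turnover(s1, s2, c) == expected

    def test_shared_count_cannot_exceed_smaller_richness(self):
        with pytest.raises(ValidationError):
            absolute_turnover(3, 7, 4)

    @given(s1=st.integers(0, 50), s2=st.integers(0, 50), c=st.integers(0, 50))
    @settings(deadline=None, derandomize=True)
    def test_symmetry(self, s1, s2, c):
        if c <= min(s1, s2):
            assert absolute_turnover(s1, s2, c) == absolute_turnover(s2, s1, c)


class TestTurnoverMatrix:
    def test_disjoint_and_identical_orders(self):
        inc = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], columns=[1, 2],
            index=[f"s{i}" for i in range(5)],
        )
        beta, sim = turnover_matrix(inc)
        assert beta.loc[1, 2] == 5  # S1 + S2, fully disjoint
        assert sim.loc[1, 2] == 0.0
        inc_same = pd.DataFrame([[1, 1], [1, 1]], columns=[1, 2],
                                index=["a", "b"])
        beta2, sim2 = turnover_matrix(inc_same)
        assert beta2.loc[1, 2] == 0 and sim2.loc[1, 2] == 1.0

    def test_matrix_composes_pairwise_scalar_calls(self):
        rng = np.random.default_rng(7)
        inc = pd.DataFrame(rng.integers(0, 2, size=(20, 3)), columns=[2, 4, 6])
        inc = inc[inc.sum(axis=1) > 0]
        beta, sim = turnover_matrix(inc)
        X = inc.to_numpy().astype(bool)
        for i, oi in enumerate(inc.columns):
            for j, oj in enumerate(inc.columns):
                if i == j:
                    assert beta.loc[oi, oj] == 0 and sim.loc[oi, oj] == 1.0
                    continue
                s1, s2 = X[:, i].sum(), X[:, j].sum()
                c = (X[:, i] & X[:, j]).sum()
                assert beta.loc[oi, oj] == absolute_turnover(s1, s2, c)
        assert np.array_equal(beta.to_numpy(), beta.to_numpy().T)

    def test_single_order_rejected(self):
        inc = pd.DataFrame([[1], [1]], columns=[3], index=["a", "b"])
        with pytest.raises(ValidationError):
            turnover_matrix(inc)


class TestIncidence:
    def test_species_present_at_observed_orders_only(self):
        recs = _records([("sp1", -1, -60, "b", 2), ("sp1", -1.5, -61, "b", 3),
                         ("sp2", -2, -62, "b", 1), ("sp3", -3, -63, "b", 10)])
        inc = incidence_by_stream_order(recs)
        assert inc.loc["sp1", 2] == 1 and inc.loc["sp1", 3] == 1
        assert inc.loc["sp1", 1] == 0
        S = richness_by_order(inc)
        assert S[1] == 1 and S[10] == 1 and S[2] == 1

    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(3)
        rows = []
        placed = {}
        for i in range(20):
            orders = sorted(rng.choice(range(1, 9), size=rng.integers(1, 4),
                                       replace=False))
            placed[f"sp{i}"] = set(int(o) for o in orders)
            for o in orders:
                rows.append((f"sp{i}", -1.0 - i * 0.01, -60.0, "b", int(o)))
        inc = incidence_by_stream_order(_records(rows))
        S = richness_by_order(inc)
        for k in S.index:
            assert S[k] == sum(1 for v in placed.values() if k in v)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            inc = incidence_by_stream_order(_records([]))
        assert inc.empty


class TestOccurrenceQC:
    def test_duplicates_collapsed(self):
        recs = _records([("sp1", -1.00001, -60.00001, "b", 2),
                         ("sp1", -1.00001, -60.00001, "b", 2)])
        clean, report = occurrence_qc(recs)
        assert len(clean) == 1 and report.n_duplicate == 1

    def test_out_of_domain_latitude_malformed(self):
        recs = _records([("sp1", 95.0, -60.0, "b", 2),
                         ("sp1", -1.0, -60.0, "b", 2)])
        clean, report = occurrence_qc(recs)
        assert report.n_malformed == 1 and len(clean) == 1

    def test_planted_fixture_retains_expected_rows(self):
        """10 rows with 3 planted duplicates and 2 out-of-bounds -> 5 kept."""
        base = [(f"sp{i}", -1.0 - i, -60.0 - i, "b", 1 + i % 5) for i in range(5)]
        dups = [base[0], base[1], base[2]]
        oob = [("sp0", 45.0, 10.0, "b", 2), ("sp1", 50.0, 15.0, "b", 3)]
        recs = _records(base + dups + oob)
        bounds = {f"sp{i}": (-20.0, 0.0, -80.0, -50.0) for i in range(5)}
        clean, report = occurrence_qc(recs, bounds=bounds)
        assert len(clean) == 5
        assert report.n_duplicate == 3 and report.n_out_of_bounds == 2

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        recs = _records(
            [(f"sp{i % 4}", float(rng.uniform(-10, 0)),
              float(rng.uniform(-70, -60)), "b", int(rng.integers(1, 9)))
             for i in range(30)]
        )
        once, _ = occurrence_qc(recs)
        twice, rep2 = occurrence_qc(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_duplicate == 0 and rep2.n_malformed == 0


class TestRiverNetworkSummary:
    def _segments(self, rows):
        return pd.DataFrame(
            rows, columns=["segment_id", "basin", "stream_order", "length_km",
                           "area_km2", "volume_km3"]
        )

    def test_single_segment_all_proportions_one(self):
        s = self._segments([("s1", "b", 3, 10.0, 1.0, 0.1)])
        net = summarize_river_network(s)
        for m in ("length", "area", "volume"):
            assert net.by_order[f"{m}_prop"].sum() == pytest.approx(1.0)
            assert net.by_order.loc[3, f"{m}_prop"] == 1.0

    def test_two_equal_orders_split_evenly(self):
        s = self._segments([("s1", "b", 1, 5.0, 0.5, 0.05),
                            ("s2", "b", 2, 5.0, 0.5, 0.05)])
        net = summarize_river_network(s)
        assert net.by_order.loc[1, "length_prop"] == pytest.approx(0.5)

    def test_horton_geometric_series_small_order_dominance(self):
        """Total length per order ~ (Rl/Rb)^k; with Rb=4, Rl=2 orders 1-5
        hold (1-r^5)/(1-r^8) = 97.3% of length for r=1/2 (closed form)."""
        from riverscape.simulate import simulate_riverscape

        seg = simulate_riverscape(8, bifurcation_ratio=4.0, length_ratio=2.0,
                                  noise_sigma=0.0, seed=0)
        net = summarize_river_network(seg)
        share = net.share("length", range(1, 6))
        r = 0.5
        closed_form = (1 - r**5) / (1 - r**8)
        assert share == pytest.approx(closed_form, abs=1e-9)
        assert share > 0.9

    def test_proportions_sum_to_one(self):
        from riverscape.simulate import simulate_riverscape

        net = summarize_river_network(simulate_riverscape(6, seed=5))
        for m in ("length", "area", "volume"):
            assert net.by_order[f"{m}_prop"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_magnitude_rejected(self):
        s = self._segments([("s1", "b", 1, -5.0, 0.5, 0.05)])
        with pytest.raises(ValidationError):
            summarize_river_network(s)


class TestAlphaDensity:
    def test_ratio_and_scaling(self):
        rich = pd.Series({1: 10, 2: 4})
        length = pd.Series({1: 5.0, 2: 2.0})
        dens = alpha_density(rich, length)
        assert dens[1] == 2.0 and dens[2] == 2.0
        halved = alpha_density(rich, 2 * length)
        np.testing.assert_allclose(halved.to_numpy(), dens.to_numpy() / 2)

    def test_zero_length_with_richness_rejected(self):
        with pytest.raises(ValidationError):
            alpha_density(pd.Series({1: 3}), pd.Series({1: 0.0}))


class TestRegression:
    def test_perfect_line_and_constant_y(self):
        x = np.arange(1, 9)
        assert ols_r2(x, 3 * x + 1).r2 == pytest.approx(1.0)
        assert ols_r2(x, np.full(8, 2.0)).r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_on_fixture(self):
        """Textbook normal-equation R^2 computed inline as the oracle."""
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        y = np.array([2.1, 2.5, 3.9, 3.2, 5.0, 5.1, 6.3, 6.1, 7.8, 8.2])
        res = ols_r2(x, y)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        sxx = ((x - x.mean()) ** 2).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert res.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert res.r2 == pytest.approx(sxy**2 / (sxx * syy), abs=1e-12)
        assert 0 < res.p_value < 1

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError):
            ols_r2([2, 2, 2], [1, 2, 3])


class TestProfile:
    def test_profile_composes_parts(self):
        from riverscape.simulate import (
            make_species_pool,
            simulate_occurrences,
            simulate_riverscape,
        )

        seg = simulate_riverscape(6, seed=21)
        pool = make_species_pool(15, 6, 22)
        occ, _ = simulate_occurrences(pool, seg, 300, 23)
        clean, _ = occurrence_qc(occ)
        prof = diversity_profile(clean, segments=seg)
        assert prof.gamma == clean["species"].nunique()
        S = prof.per_order["pooled_richness"]
        assert prof.beta_w == pytest.approx(prof.gamma / S.mean())
        assert (prof.per_order["beta_w_order"] >= 1.0 - 1e-12).all()
        assert prof.beta_a.shape[0] == prof.per_order.shape[0]
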