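"""The synthetic-data generator: determinism and distributional checks."""

import math

import numpy as np
import pytest

from riverscape.dec import DECParams
from riverscape.diversity import (
    incidence_by_stream_order,
    occurrence_qc,
    richness_by_order,
    whittaker_beta,
)
from riverscape.errors import ValidationError
from riverscape.geography import RangeState, build_lem, stepping_stone_chain
from riverscape.phylo import read_newick
from riverscape.simulate import (
    SimulationConfig,
    SpeciesNiche,
    make_species_pool,
    simulate_bundle,
    simulate_dec_history,
    simulate_occurrences,
    simulate_riverscape,
    simulate_tree,
)


class TestSimulateTree:
    def test_two_tip_tree_is_ultrametric(self):
        tree = simulate_tree(1.0, 0.0, 2, seed=42)
        assert tree.n_tips == 2
        tree.node_ages()  # raises if not ultrametric

    def test_same_seed_reproduces_newick(self):
        a = simulate_tree(0.5, 0.1, 12, seed=99).to_newick()
        b = simulate_tree(0.5, 0.1, 12, seed=99).to_newick()
        assert a == b

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            simulate_tree(0.1, 0.2, 10, seed=1)
        with pytest.raises(ValidationError):
            simulate_tree(1.0, 0.0, 1, seed=1)

    def test_yule_mean_crown_age_matches_closed_form(self):
        """Pure-birth expectation for the crown (root) age: waiting times
        from 2 lineages until the nth tip is born,
        E[age] = sum_{k=2}^{n-1} 1/(k*lambda).  The simulator's stem edge
        is discarded, so root_age is the crown age."""
        lam, n, reps = 1.0, 6, 400
        heights = [
            simulate_tree(lam, 0.0, n, seed=10_000 + i).root_age
            for i in range(reps)
        ]
        h = np.asarray(heights)
        expected = sum(1 / (k * lam) for k in range(2, n))
        se = h.std(ddof=1) / math.sqrt(reps)
        assert abs(h.mean() - expected) < 4 * se


class TestSimulateDECHistory:
    def test_zero_rates_no_anagenetic_events(self, chain4):
        """With delta = e = 0 no anagenetic events occur; a singleton root
        is inherited unchanged by every node and tip (multi-area roots
        still split at cladogenesis)."""
        tree = simulate_tree(0.3, 0.0, 12, seed=5)
        seen_singleton = False
        for seed in range(40):
            hist = simulate_dec_history(tree, chain4, DECParams(0, 0), seed=seed)
            assert len(hist.events) == 0
            if hist.root_state.size == 1:
                seen_singleton = True
                for st in hist.tip_ranges.values():
                    assert st == hist.root_state
                for st in hist.node_ranges.values():
                    assert st == hist.root_state
        assert seen_singleton

    def test_same_seed_is_bit_reproducible(self, chain4):
        tree = simulate_tree(0.3, 0.0, 15, seed=8)
        h1 = simulate_dec_history(tree, chain4, DECParams(0.05, 0.01), seed=9)
        h2 = simulate_dec_history(tree, chain4, DECParams(0.05, 0.01), seed=9)
        assert h1.tip_ranges == h2.tip_ranges
        assert h1.events.equals(h2.events)

    def test_cladogenetic_outcomes_uniform_over_six_events(self, lem2):
        """From a 2-area ancestor the six ordered daughter pairs must each
        appear with frequency 1/6 (within 3 binomial SEs).  With
        delta = e = 0 on a 2-tip tree the tips reveal the drawn daughters;
        histories whose root is not {A,B} are skipped."""
        tree = read_newick("(T1:1,T2:1);")
        counts = {}
        n_draws = 0
        for i in range(6000):
            hist = simulate_dec_history(tree, lem2, DECParams(0, 0), seed=i)
            if hist.root_state.size != 2:
                continue
            key = (hist.tip_ranges["T1"].bits, hist.tip_ranges["T2"].bits)
            counts[key] = counts.get(key, 0) + 1
            n_draws += 1
        assert len(counts) == 6
        se = math.sqrt((1 / 6) * (5 / 6) / n_draws)
        for key, c in counts.items():
            assert abs(c / n_draws - 1 / 6) < 3 * se, (key, c / n_draws)

    def test_dispersal_rate_matches_delta_m(self):
        """1-area -> 2-area system: P(gain within t) = 1 - exp(-delta*m*t)."""
        m = 0.6
        lem = build_lem({"name": "pair", "regions": ["A", "B"],
                         "slices": [{"start_age": "inf", "end_age": 0,
                                     "matrix": [[0, m], [m, 0]]}]})
        delta, t = 0.3, 2.0
        tree = read_newick(f"(T1:{t},T2:{t});")
        gains = trials = 0
        for i in range(4000):
            hist = simulate_dec_history(tree, lem, DECParams(delta, 0.0),
                                        seed=50_000 + i)
            if hist.root_state.size != 1:
                continue
            for tip in ("T1", "T2"):
                trials += 1
                gains += hist.tip_ranges[tip].size == 2
        p_expected = 1 - math.exp(-delta * m * t)
        se = math.sqrt(p_expected * (1 - p_expected) / trials)
        assert abs(gains / trials - p_expected) < 3 * se

    def test_reject_replicate_mode_yields_no_null(self, lem2):
        tree = simulate_tree(0.5, 0.0, 8, seed=31)
        hist = simulate_dec_history(tree, lem2, DECParams(0.1, 0.05), seed=32,
                                    null_handling="reject-replicate",
                                    max_attempts=2000)
        assert not hist.any_null
        assert all(not s.is_null for s in hist.tip_ranges.values())


class TestSimulateRiverscape:
    def test_zero_noise_exact_geometric_series(self):
        seg = simulate_riverscape(5, bifurcation_ratio=3.0, length_ratio=2.0,
                                  noise_sigma=0.0, seed=1)
        counts = seg.groupby("stream_order").size()
        lengths = seg.groupby("stream_order")["length_km"].mean()
        for k in range(1, 6):
            assert counts[k] == round(3.0 ** (5 - k))
            assert lengths[k] == pytest.approx(2.0 ** (k - 1))

    def test_small_orders_dominate_length(self):
        seg = simulate_riverscape(8, length_ratio=2.0, seed=2)
        total = seg["length_km"].sum()
        low = seg.loc[seg["stream_order"] <= 5, "length_km"].sum()
        assert low / total > 0.9

    def test_same_seed_identical_table(self):
        a = simulate_riverscape(6, seed=3)
        b = simulate_riverscape(6, seed=3)
        assert a.equals(b)

    @pytest.mark.parametrize("kwargs", [{"n_orders": 1}, {"n_orders": 11},
                                        {"bifurcation_ratio": 1.0},
                                        {"length_ratio": 0.5}])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValidationError):
            simulate_riverscape(**{"n_orders": 5, "seed": 1, **kwargs})


class TestSimulateOccurrences:
    def test_zero_breadth_pins_records_to_modal_order(self):
        seg = simulate_riverscape(8, seed=4)
        pool = [SpeciesNiche("sp1", modal_order=3, breadth=0.0)]
        occ, _ = simulate_occurrences(pool, seg, 50, seed=5)
        assert (occ["stream_order"] == 3).all()

    def test_planted_duplicates_removed_exactly_by_qc(self):
        seg = simulate_riverscape(8, seed=6)
        pool = make_species_pool(10, 8, seed=7)
        occ, truth = simulate_occurrences(pool, seg, 100, seed=8,
                                          planted_duplicates=5)
        assert truth["n_duplicates"] == 5
        _, report = occurrence_qc(occ)
        assert report.n_duplicate == 5

    def test_stenotopic_pool_has_higher_whittaker_beta(self):
        """Narrow stream-order niches concentrate species into few orders,
        raising beta_W relative to a eurytopic pool (directional check
        over replicate pools)."""
        seg = simulate_riverscape(8, seed=9)

        def mean_beta(breadth, seeds):
            betas = []
            for s in seeds:
                rng = np.random.default_rng(s)
                pool = [SpeciesNiche(f"sp{i}", int(rng.integers(1, 9)), breadth)
                        for i in range(12)]
                occ, _ = simulate_occurrences(pool, seg, 400, seed=s)
                inc = incidence_by_stream_order(occ)
                S = richness_by_order(inc)
                betas.append(whittaker_beta(inc.shape[0], S.to_numpy()))
            return np.mean(betas)

        steno = mean_beta(0.3, range(100, 140))
        eury = mean_beta(4.0, range(200, 240))
        assert steno > eury


class TestBundle:
    def test_bundle_writes_all_inputs_and_is_seed_reproducible(self, tmp_path):
        config = SimulationConfig(seed=77, n_tips=12, n_records=60)
        m1 = simulate_bundle(config, tmp_path / "a")
        m2 = simulate_bundle(config, tmp_path / "b")
        for name in ("tree.nwk", "ranges.csv", "lem.yaml", "occurrences.csv",
                     "segments.csv", "truth.json"):
            fa = (tmp_path / "a" / name).read_bytes()
            fb = (tmp_path / "b" / name).read_bytes()
            assert fa == fb, f"{name} differs between identical seeds"
        assert len(m1["files"]) >= 6
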