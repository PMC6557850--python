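"""Tie-aware Kendall tau and the truncation-radius analysis."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from gravityrank import (
    SIRConfig,
    consecutive_radius_similarity,
    diameter,
    evaluate_method,
    gravity_model,
    kendall_tau,
    local_gravity_model,
    predict_radius,
    standard_ranking,
    sweep_radius,
)
from gravityrank.centrality import degree_centrality
from gravityrank.generators import GeneratorSpec, generate
from gravityrank.oracles import brute_force_kendall_tau, exhaustive_sir_expectation
from gravityrank.sir import InfluenceVector

from conftest import random_graphs


def random_pairs(count, seed):
    rng = random.Random(seed)
    for _ in range(count):
        n = rng.randint(2, 50)
        if rng.random() < 0.5:  # force heavy ties half the time
            x = [rng.randint(0, 4) for _ in range(n)]
            y = [rng.randint(0, 4) for _ in range(n)]
        else:
            x = [rng.random() for _ in range(n)]
            y = [rng.random() for _ in range(n)]
        yield x, y


class TestKendallTau:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3, 4), (1, 2, 3, 4), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (1, 3, 2), 1 / 3),
            ((1, 1, 2), (1, 2, 3), 2 / 3),  # tied pair counts in neither n+ nor n-
        ],
    )
    def test_hand_counted_examples(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1])
        with pytest.raises(ValueError):
            kendall_tau([1], [1])

    def test_matches_pair_enumeration_oracle(self):
        """Merge-count tau equals O(N^2) enumeration on 1000 random pairs."""
        for x, y in random_pairs(1000, seed=101):
            assert kendall_tau(x, y) == pytest.approx(
                brute_force_kendall_tau(x, y), abs=1e-12
            )

    @given(
        st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=25)
        .flatmap(lambda x: st.tuples(
            st.just(x),
            st.lists(st.integers(min_value=0, max_value=6),
                     min_size=len(x), max_size=len(x)),
        ))
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_symmetry_and_bounds(self, xy):
        x, y = xy
        t = kendall_tau(x, y)
        assert t == pytest.approx(kendall_tau(y, x))
        n = len(x)
        ties = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if x[i] == x[j] or y[i] == y[j]
        )
        assert abs(t) <= 1 - 2 * ties / (n * (n - 1)) + 1e-12

    def test_invariant_under_monotone_transform(self):
        for x, y in random_pairs(50, seed=7):
            t = kendall_tau(x, y)
            assert kendall_tau([3 * v + 1 for v in x], y) == pytest.approx(t)
            assert kendall_tau(x, [v**3 for v in y]) == pytest.approx(t)

    def test_negated_by_reversal_without_ties(self):
        rng = random.Random(5)
        x = [rng.random() for _ in range(30)]
        y = [rng.random() for _ in range(30)]
        assert kendall_tau(x, [-v for v in y]) == pytest.approx(-kendall_tau(x, y))

    def test_agrees_with_scipy_when_tie_free(self):
        # without ties the tie rule is vacuous, so tau-b is the same number
        from scipy.stats import kendalltau

        rng = random.Random(13)
        x = [rng.random() for _ in range(40)]
        y = [rng.random() for _ in range(40)]
        assert kendall_tau(x, y) == pytest.approx(kendalltau(x, y).statistic)


class TestEvaluateMethod:
    def _standard_from(self, net, scores, beta=0.5):
        cfg = SIRConfig(beta=beta, runs=1)
        return InfluenceVector(scores, {k: 0.0 for k in scores}, cfg)

    def test_identical_untied_scores_give_tau_one(self, path4):
        sv = gravity_model(path4)
        sv.scores = {lab: float(i) for i, lab in enumerate(path4.labels)}
        std = self._standard_from(path4, dict(sv.scores))
        assert evaluate_method(path4, sv, std).tau == pytest.approx(1.0)

    def test_identical_tied_scores_give_tie_limited_tau(self, path4):
        # a symmetric graph yields tied gravity scores; self-tau is then
        # 1 - 2t/(N(N-1)), not 1 (ties count in neither n+ nor n-)
        sv = gravity_model(path4)
        std = self._standard_from(path4, dict(sv.scores))
        assert evaluate_method(path4, sv, std).tau == pytest.approx(2 / 3)

    def test_negated_untied_scores_give_tau_minus_one(self, path4):
        # use an untied artificial standard: negation must flip perfectly
        std = self._standard_from(path4, {lab: float(i) for i, lab in enumerate(path4.labels)})
        sv = gravity_model(path4)
        sv.scores = {lab: -float(i) for i, lab in enumerate(path4.labels)}
        assert evaluate_method(path4, sv, std).tau == pytest.approx(-1.0)

    def test_node_set_mismatch(self, path4, path3):
        sv = gravity_model(path3)
        std = self._standard_from(path4, {lab: 0.0 for lab in path4.labels})
        with pytest.raises(ValueError):
            evaluate_method(path4, sv, std)

    def test_star_dc_vs_exact_sir_expectations(self, star4):
        """DC against exact percolation expectations: ties on the leaves in
        both sequences, checked against the pair-enumeration oracle."""
        exact = {
            lab: exhaustive_sir_expectation(star4, lab, 0.5)
            for lab in star4.labels
        }
        std = self._standard_from(star4, exact)
        rep = evaluate_method(star4, degree_centrality(star4), std)
        order = star4.labels
        want = brute_force_kendall_tau(
            [degree_centrality(star4).scores[o] for o in order],
            [exact[o] for o in order],
        )
        assert rep.tau == pytest.approx(want)
        assert rep.n_nodes == 5 and rep.beta == 0.5


class TestRadiusAnalysis:
    def test_predict_radius_rounding(self):
        # path of 13 nodes: <d> = 14/3 = 4.667 -> half = 2.33 -> R = 2
        assert predict_radius(generate(GeneratorSpec("path", 13))) == 2
        # complete graph: <d> = 1 -> half rounds up to the floor of 1
        assert predict_radius(generate(GeneratorSpec("complete", 5))) == 1
        # path of 5: <d> = 2 -> half = 1.0 -> R = 1
        assert predict_radius(generate(GeneratorSpec("path", 5))) == 1

    def test_predict_radius_half_integers_round_down(self):
        # star: <d> = 1.6 -> 0.8 -> 1; cycle of 12: <d> = 36/11 -> 1.64 -> 2
        assert predict_radius(generate(GeneratorSpec("star", 4))) == 1
        net = generate(GeneratorSpec("cycle", 12))
        assert predict_radius(net) == 2

    def test_sweep_small_diameter(self, star4):
        std = standard_ranking(star4, SIRConfig(beta=0.5, runs=400, rng_seed=3))
        prof = sweep_radius(star4, std)
        assert prof.radii == [1, 2]  # diameter 2
        assert prof.optimal_R in (1, 2)
        assert prof.predicted_R == 1

    def test_sweep_tau_saturates_at_diameter(self):
        net = generate(GeneratorSpec("erdos_renyi", 25, p=0.15, rng_seed=9))
        std = standard_ranking(net, SIRConfig(beta=0.3, runs=200, rng_seed=4))
        dia = diameter(net)
        prof = sweep_radius(net, std, R_max=dia + 1)
        assert prof.taus[-1] == pytest.approx(prof.taus[dia - 1])
        order = net.labels
        gm_tau = kendall_tau(
            gravity_model(net).aligned(order), std.aligned(order)
        )
        assert prof.taus[-1] == pytest.approx(gm_tau)

    def test_argmax_prefers_smallest_radius_on_ties(self, k4):
        std = standard_ranking(k4, SIRConfig(beta=0.2, runs=100, rng_seed=5))
        prof = sweep_radius(k4, std, R_max=3)  # all radii identical on K4
        assert prof.optimal_R == 1

    def test_consecutive_similarity_complete_graph(self, k5):
        # K5 gives identical all-tied score vectors at R=1 and R=2; under the
        # strict tie rule every pair is tied in both, so tau is 0 (not 1)
        assert consecutive_radius_similarity(k5, 2) == [(1, 0.0)]

    def test_consecutive_similarity_path6_vs_oracle(self):
        net = generate(GeneratorSpec("path", 6))
        order = net.labels
        seqs = {R: local_gravity_model(net, R).aligned(order) for R in (1, 2, 3)}
        got = consecutive_radius_similarity(net, 3)
        for (R, tau) in got:
            assert tau == pytest.approx(
                brute_force_kendall_tau(seqs[R], seqs[R + 1])
            )

    def test_consecutive_similarity_saturates_at_diameter(self):
        """Beyond the diameter the LGM vectors stop changing, so tau(R)
        reaches its tie-limited maximum (exactly 1 when scores are untied)."""
        for net in random_graphs(10, 12, seed=77, min_n=4):
            if net.E < 2:
                continue
            dia = diameter(net)
            if dia < 2:
                continue
            order = net.labels
            at_dia = local_gravity_model(net, dia).aligned(order)
            beyond = local_gravity_model(net, dia + 1).aligned(order)
            assert at_dia == beyond
            sims = dict(consecutive_radius_similarity(net, dia + 1))
            assert sims[dia] == pytest.approx(kendall_tau(at_dia, at_dia))
            if len(set(at_dia)) == len(at_dia):  # no ties: full agreement
                assert sims[dia] == pytest.approx(1.0)
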