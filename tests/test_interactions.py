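import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from phylocomp.interactions import (GuildHistory, InteractionTimeline, MkModel,
                                    RegionHistory, build_timeline, fit_mk_ard,
                                    mk_loglik, node_state_posteriors,
                                    pairwise_congruence, read_history,
                                    sample_stochastic_maps, write_history)
from phylocomp.synth import sim_guild_history, sim_tree
from phylocomp.tree import read_tree


def brute_force_mk_loglik(tree, Q, tip_states, states):
    """Sum over all internal-node state assignments (flat root prior)."""
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    internal = list(range(tree.n_tips, 2 * tree.n_tips - 1))
    P = {v: expm(Q * tree.length[v]) for v in range(2 * tree.n_tips - 1)
         if tree.parent[v] >= 0}
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for lab in tree.labels:
            assign[tree.tip_index(lab)] = idx[tip_states[lab]]
        lik = 1.0 / k  # flat root prior
        for v in range(2 * tree.n_tips - 1):
            p = tree.parent[v]
            if p >= 0:
                lik *= P[v][assign[p], assign[v]]
        total += lik
    return np.log(total)


class TestMk:
    def test_single_state_errors(self, tree3):
        with pytest.raises(ValueError, match="at least 2"):
            fit_mk_ard(tree3, {"A": "x", "B": "x", "C": "x"})

    def test_pruning_matches_enumeration(self):
        tree = read_tree("(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")
        states = ("0", "1")
        tips = {"A": "0", "B": "1", "C": "0", "D": "1", "E": "0"}
        Q = np.array([[-0.3, 0.3], [0.5, -0.5]])
        got = mk_loglik(tree, Q, tips, states)
        want = brute_force_mk_loglik(tree, Q, tips, states)
        assert got == pytest.approx(want, abs=1e-10)

    def test_symmetric_rate_recovery(self):
        """ARD fit on data generated with q01 = q10 recovers similar rates."""
        Q_true = np.array([[-0.5, 0.5], [0.5, -0.5]]) * (2.0 / 25.0)
        # rate 0.04/My on a 25-My tree: a handful of expected transitions
        tree = sim_tree(0.3, 0.0, 200, seed=11)
        ratios, recovered = [], []
        for rep in range(10):
            _, tips = sim_guild_history(tree, ("0", "1"), Q_true, seed=rep)
            if len(set(tips.values())) < 2:
                continue
            m = fit_mk_ard(tree, tips, n_restarts=2)
            q01, q10 = m.Q[0, 1], m.Q[1, 0]
            recovered.append((q01 + q10) / 2.0)
            ratios.append(q01 / q10)
        assert 0.5 < np.median(recovered) / 0.04 < 2.0
        assert 0.2 < np.median(ratios) < 5.0

    def test_q_validation(self):
        with pytest.raises(ValueError, match="sum to zero"):
            MkModel(("a", "b"), np.array([[0.1, 0.2], [0.3, -0.3]]))


class TestStochasticMaps:
    def test_zero_rates_constant_maps(self, tree3):
        model = MkModel(("s", "t"), np.zeros((2, 2)))
        tips = {"A": "s", "B": "s", "C": "s"}
        maps = sample_stochastic_maps(tree3, model, tips, 5, seed=0)
        for h in maps:
            for segs in h.segments.values():
                assert all(p == "s" for _, _, p in segs)

    def test_maps_match_tip_states(self, tree6):
        tips = {lab: ("0" if lab < "D" else "1") for lab in tree6.labels}
        model = fit_mk_ard(tree6, tips, n_restarts=1)
        maps = sample_stochastic_maps(tree6, model, tips, 20, seed=1)
        for h in maps:
            for lab in tree6.labels:
                assert h.state_at(tree6.tip_index(lab), 0.0) == tips[lab]

    def test_node_state_frequencies_match_posterior(self):
        """Sampled node states agree with exact conditionals (3 MC SE)."""
        tree = read_tree("(((A:1,B:1):1,C:2):1,(D:2.5,E:2.5):0.5);")
        tips = {"A": "0", "B": "1", "C": "0", "D": "1", "E": "0"}
        Q = np.array([[-0.4, 0.4], [0.6, -0.6]])
        model = MkModel(("0", "1"), Q)
        post = node_state_posteriors(tree, model, tips)
        # the belief-propagation posterior itself checks against enumeration
        for v in range(tree.n_tips, 2 * tree.n_tips - 1):
            num = 0.0
            den = 0.0
            for s in range(2):
                den += np.exp(_cond_loglik_with_node(tree, Q, tips, v, s))
            num = np.exp(_cond_loglik_with_node(tree, Q, tips, v, 1))
            assert post[v, 1] == pytest.approx(num / den, abs=1e-9)
        n_maps = 2000
        maps = sample_stochastic_maps(tree, model, tips, n_maps, seed=5)
        for v in [tree.root, tree.n_tips]:
            freq = np.mean([
                h.state_at(tree.children[v][0],
                           tree.age[v]) == "1"
                for h in maps
            ])
            p = post[v, 1]
            se = np.sqrt(p * (1 - p) / n_maps)
            assert abs(freq - p) < 3 * se + 1e-9

    def test_uniformization_fallback(self, tree3):
        # forcing max_reject=0 exercises the uniformization path
        Q = np.array([[-0.4, 0.4], [0.6, -0.6]])
        model = MkModel(("0", "1"), Q)
        tips = {"A": "0", "B": "1", "C": "0"}
        maps = sample_stochastic_maps(tree3, model, tips, 10, seed=2,
                                      max_reject=1)
        for h in maps:
            for lab in tree3.labels:
                assert h.state_at(tree3.tip_index(lab), 0.0) == tips[lab]


def _cond_loglik_with_node(tree, Q, tips, node, state):
    """Enumeration likelihood with one internal node clamped."""
    k = 2
    states = ("0", "1")
    idx = {s: i for i, s in enumerate(states)}
    internal = [v for v in range(tree.n_tips, 2 * tree.n_tips - 1) if v != node]
    P = {v: expm(Q * tree.length[v]) for v in range(2 * tree.n_tips - 1)
         if tree.parent[v] >= 0}
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        assign[node] = state
        for lab in tree.labels:
            assign[tree.tip_index(lab)] = idx[tips[lab]]
        lik = 1.0 / k
        for v in range(2 * tree.n_tips - 1):
            p = tree.parent[v]
            if p >= 0:
                lik *= P[v][assign[p], assign[v]]
        total += lik
    return np.log(total)


def _uniform_regions(tree, region_set):
    segs = {v: [(tree.age[tree.parent[v]], tree.age[v], region_set)]
            for v in range(2 * tree.n_tips - 1) if v != tree.root}
    return RegionHistory(tree, segs)


def _uniform_guild(tree, state):
    segs = {v: [(tree.age[tree.parent[v]], tree.age[v], state)]
            for v in range(2 * tree.n_tips - 1) if v != tree.root}
    return GuildHistory(tree, segs)


class TestBuildTimeline:
    def test_all_shared(self, tree3):
        tl = build_timeline(tree3, _uniform_regions(tree3, {"a"}),
                            _uniform_guild(tree3, "g"), "g")
        for i in range(tl.n_intervals):
            d = len(tl.alive[i])
            assert np.array_equal(tl.A[i], np.ones((d, d), int) - np.eye(d, dtype=int))
            assert np.array_equal(tl.n[i], np.full(d, d))

    def test_disjoint_regions(self, tree3):
        segs = {v: [(tree3.age[tree3.parent[v]], tree3.age[v],
                     frozenset({f"r{v}"})) ]
                for v in range(5) if v != tree3.root}
        rh = RegionHistory(tree3, segs)
        tl = build_timeline(tree3, rh, _uniform_guild(tree3, "g"), "g")
        for i in range(tl.n_intervals):
            assert tl.A[i].sum() == 0
            assert np.array_equal(tl.n[i], np.ones(len(tl.alive[i]), int))

    def test_dispersal_event_splits_interval(self):
        """One mid-branch dispersal at age 0.5 adds one breakpoint and
        flips exactly one pair."""
        tree = read_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        gh = _uniform_guild(tree, "g")
        segs = {}
        for v in range(2 * tree.n_tips - 1):
            if v == tree.root:
                continue
            top, bot = tree.age[tree.parent[v]], tree.age[v]
            if v == tree.tip_index("A"):
                # A starts in region b, disperses into a at age 0.5
                segs[v] = [(top, 0.5, frozenset("b")),
                           (0.5, bot, frozenset({"a", "b"}))]
            else:
                segs[v] = [(top, bot, frozenset("a"))]
        rh = RegionHistory(tree, segs)
        tl = build_timeline(tree, rh, gh, "g")
        assert any(abs(bp - 0.5) < 1e-12 for bp in tl.breakpoints)
        i_before = tl.interval_at(0.75)
        i_after = tl.interval_at(0.25)
        a = tree.tip_index("A")
        ja = list(tl.alive[i_before]).index(a)
        assert tl.A[i_before][ja].sum() == 0          # A isolated before
        jb = list(tl.alive[i_after]).index(a)
        assert tl.A[i_after][jb].sum() == 3           # A joins everyone after
        diff = tl.A[i_after].sum() - tl.A[i_before].sum()
        assert diff == 6  # one lineage gains 3 partners (symmetric count)

    def test_nonfocal_rows_zero(self, tree6):
        Q = np.array([[-0.1, 0.1], [0.1, -0.1]])
        gh, _ = sim_guild_history(tree6, ("g", "h"), Q, seed=3)
        tl = build_timeline(tree6, _uniform_regions(tree6, {"a"}), gh, "g")
        for i in range(tl.n_intervals):
            nf = ~tl.focal[i]
            assert tl.A[i][nf].sum() == 0
            assert np.all(tl.n[i][nf] == 1)

    def test_history_not_tiling_errors(self, tree3):
        segs = {v: [(tree3.age[tree3.parent[v]], tree3.age[v], frozenset("a"))]
                for v in range(5) if v != tree3.root}
        # truncate one edge's segment
        bad = tree3.tip_index("C")
        segs[bad] = [(1.0, 0.0, frozenset("a"))]
        with pytest.raises(ValueError, match="tile"):
            RegionHistory(tree3, segs)

    def test_interval_count_bound(self, tree50):
        rh = _uniform_regions(tree50, frozenset("a"))
        Q = np.array([[-0.05, 0.05], [0.05, -0.05]])
        gh, _ = sim_guild_history(tree50, ("g", "h"), Q, seed=9)
        tl = build_timeline(tree50, rh, gh, "g")
        n_guild_changes = len(gh.change_ages())
        # branchings (n-1 internal nodes incl. root) + changes + 1
        assert tl.n_intervals <= (tree50.n_tips - 1) + n_guild_changes + 1


class TestCongruence:
    def test_identical_timelines(self, tree6):
        tl = InteractionTimeline.full_sympatry(tree6)
        prof = pairwise_congruence([tl, tl], grid=[0.0, 1.0, 2.0])
        assert np.allclose(prof["congruence"], 1.0)

    def test_complementary_two_lineage(self):
        tree = read_tree("(A:1,B:1);")
        tl1 = InteractionTimeline.full_sympatry(tree)
        tl2 = InteractionTimeline.full_allopatry(tree)
        prof = pairwise_congruence([tl1, tl2], grid=[0.0, 0.5])
        assert np.allclose(prof["congruence"], 0.0)

    def test_brute_force_recount_at_present(self):
        tree = sim_tree(0.3, 0.0, 10, seed=3)
        tls = []
        for m in range(3):
            from phylocomp.synth import sim_region_history

            rh = sim_region_history(tree, n_regions=3, seed=m)
            tls.append(build_timeline(tree, rh, _uniform_guild(tree, "g"), "g"))
        prof = pairwise_congruence(tls, grid=[0.0])
        mats = [tl.A[-1][np.ix_(np.argsort(tl.alive[-1]),
                                np.argsort(tl.alive[-1]))] for tl in tls]
        agree = []
        iu = np.triu_indices(10, 1)
        for x in range(3):
            for y in range(x + 1, 3):
                agree.append(np.mean(mats[x][iu] == mats[y][iu]))
        assert prof["congruence"][0] == pytest.approx(np.mean(agree))


class TestEventTables:
    def test_round_trip(self, tree6, tmp_path):
        from phylocomp.synth import sim_region_history

        bank = [sim_region_history(tree6, n_regions=3, seed=s, map_id=s)
                for s in range(2)]
        p = tmp_path / "regions.tsv"
        write_history(bank, p)
        back = read_history(p, tree6, kind="region")
        assert len(back) == 2
        for h0, h1 in zip(bank, back):
            assert set(h0.segments) == set(h1.segments)
            for v in h0.segments:
                for s0, s1 in zip(h0.segments[v], h1.segments[v]):
                    assert s0[2] == s1[2]
                    assert s0[0] == pytest.approx(s1[0], abs=1e-9)

    def test_missing_columns(self, tree6, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("lineage_id\tpayload\n0\ta\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_history(p, tree6)
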