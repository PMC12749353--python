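"""Tree statistics, MAD rooting and ancestral reconstruction.

The likelihood oracle enumerates every joint internal-state assignment with
scipy matrix exponentials; the parsimony oracle minimises the change count
exhaustively; the MAD oracle scans a fine offset grid per branch.  All are
independent of the pruning / Fitch / analytic-minimiser code paths.
"""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from qsvar import phylo
from qsvar.phylo import (
    AsrResult,
    FlatTree,
    acctran_asr,
    assigned_states,
    cophenetic_distances,
    er_log_likelihood,
    filter_outliers,
    fit_er_asr,
    mad_root,
    mad_scan,
    qs_change_rate,
    read_newick,
    root_type,
    subunit_count,
)
from qsvar.synthetic_data import evolve_er, sim_tree


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def enum_er(flat, tip_states, states, rate):
    """Exhaustive-likelihood oracle: sum over all internal assignments."""
    k = len(states)
    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, -(k - 1) * rate)
    P = {v: expm(Q * flat.blen[v]) for v in range(flat.n_nodes) if flat.parent[v] >= 0}
    pos = {s: i for i, s in enumerate(states)}
    internals = [v for v in range(flat.n_nodes) if flat.children[v]]
    total = 0.0
    marg = {v: np.zeros(k) for v in internals}
    for joint in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, joint))
        for t in flat.tips:
            amap[t] = pos[tip_states[flat.labels[t]]]
        lik = 1.0 / k  # uniform root prior
        for v in range(flat.n_nodes):
            if flat.parent[v] >= 0:
                lik *= P[v][amap[flat.parent[v]], amap[v]]
        total += lik
        for v in internals:
            marg[v][amap[v]] += lik
    return math.log(total), {v: m / total for v, m in marg.items()}


def enum_parsimony(flat, tip_states, states):
    """Minimum change count over all joint internal assignments."""
    pos = {s: i for i, s in enumerate(states)}
    internals = [v for v in range(flat.n_nodes) if flat.children[v]]
    best = math.inf
    for joint in itertools.product(range(len(states)), repeat=len(internals)):
        amap = dict(zip(internals, joint))
        for t in flat.tips:
            amap[t] = pos[tip_states[flat.labels[t]]]
        changes = sum(
            1
            for v in range(flat.n_nodes)
            if flat.parent[v] >= 0 and amap[v] != amap[flat.parent[v]]
        )
        best = min(best, changes)
    return best


def mad_grid_oracle(flat, n_grid=4000):
    """Grid-scan MAD oracle over every branch."""
    from qsvar.phylo import _mad_edges

    labels, dmat = cophenetic_distances(flat)
    tips = flat.tips
    tip_pos = {t: i for i, t in enumerate(tips)}
    adj = [[] for _ in range(flat.n_nodes)]
    for v in range(flat.n_nodes):
        p = flat.parent[v]
        if p >= 0:
            adj[v].append((p, flat.blen[v]))
            adj[p].append((v, flat.blen[v]))
    ntd = np.zeros((flat.n_nodes, len(tips)))
    for j, t in enumerate(tips):
        dist = {t: 0.0}
        stack = [t]
        while stack:
            v = stack.pop()
            for w, L in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + L
                    stack.append(w)
        for v in range(flat.n_nodes):
            ntd[v, j] = dist[v]
    below = [set() for _ in range(flat.n_nodes)]
    for v in flat.postorder():
        below[v] = (
            {tip_pos[v]}
            if not flat.children[v]
            else set().union(*(below[c] for c in flat.children[v]))
        )
    all_tips = set(range(len(tips)))
    best = (None, None, math.inf)
    for eidx, (u, v, L) in enumerate(_mad_edges(flat)):
        sv = sorted(below[v])
        su = sorted(all_tips - below[v])
        xs = np.linspace(0.0, L, n_grid)
        sq = np.zeros(n_grid)
        n_pairs = 0
        for side, anchor in ((su, u), (sv, v)):
            for ii in range(len(side)):
                for jj in range(ii + 1, len(side)):
                    b, c = side[ii], side[jj]
                    D = dmat[b, c]
                    if D <= 0:
                        continue
                    dmb = (ntd[anchor, b] + D - ntd[anchor, c]) / 2.0
                    sq += (2.0 * dmb / D - 1.0) ** 2
                    n_pairs += 1
        for b in su:
            for c in sv:
                D = ntd[u, b] + L + ntd[v, c]
                if D <= 0:
                    continue
                sq = sq + (2.0 * (xs + ntd[u, b]) / D - 1.0) ** 2
                n_pairs += 1
        rms = np.sqrt(sq / n_pairs)
        i = int(rms.argmin())
        if rms[i] < best[2]:
            best = (eidx, float(xs[i]), float(rms[i]))
    return best


def random_flat(rng, n_tips, jitter=True):
    tree = sim_tree(n_tips, 1.0, rng)
    flat = FlatTree.from_dendropy(tree)
    if jitter:  # break ultrametricity so rooting is non-trivial
        for i in range(flat.n_nodes):
            flat.blen[i] *= float(rng.uniform(0.4, 2.5))
    return flat


# ---------------------------------------------------------------------------
# Cophenetic distances and outliers
# ---------------------------------------------------------------------------

class TestCopheneticDistances:
    def test_two_tip_path_sum(self):
        tree = read_newick("(a:0.1,b:0.2);")
        labels, d = cophenetic_distances(tree)
        assert d[labels.index("a"), labels.index("b")] == pytest.approx(0.3)

    def test_star_tree_symmetry(self):
        tree = read_newick("(a:0.5,b:0.5,c:0.5,d:0.5);")
        _, d = cophenetic_distances(tree)
        off = d[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)

    def test_caterpillar_hand_sums(self):
        tree = read_newick("(((a:1,b:2):3,c:4):5,d:6);")
        labels, d = cophenetic_distances(tree)
        i = {l: j for j, l in enumerate(labels)}
        assert d[i["a"], i["b"]] == pytest.approx(3.0)
        assert d[i["a"], i["c"]] == pytest.approx(8.0)
        assert d[i["a"], i["d"]] == pytest.approx(15.0)
        assert d[i["c"], i["d"]] == pytest.approx(15.0)

    def test_matches_dendropy(self, rng):
        tree = sim_tree(10, 1.0, rng)
        labels, d = cophenetic_distances(tree)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert d[i, j] == pytest.approx(
                        pdm.patristic_distance(taxa[a], taxa[b])
                    )

    def test_missing_branch_length_is_error(self):
        tree = read_newick("((a:1,b),c:1);")
        with pytest.raises(ValueError):
            cophenetic_distances(tree)


class TestFilterOutliers:
    def test_balanced_ultrametric_keeps_all(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        retained, excluded = filter_outliers(tree)
        assert excluded == [] and len(retained) == 4

    def test_long_branch_tip_excluded(self, rng):
        # n must be large enough that one outlier can exceed mean + 3 SD at
        # all: a single outlier among n tip means is bounded at (n-1)/sqrt(n)
        # standard deviations, which stays below 3 for n <= 10
        tree = sim_tree(20, 1.0, rng)
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == "t001":
                leaf.edge.length = (leaf.edge.length or 0.1) * 100
        retained, excluded = filter_outliers(tree)
        assert excluded == ["t001"]
        assert "t001" not in retained and len(retained) == 19

    def test_infinite_k_excludes_nothing(self, rng):
        tree = sim_tree(8, 1.0, rng)
        retained, excluded = filter_outliers(tree, k=math.inf)
        assert excluded == []


# ---------------------------------------------------------------------------
# MAD rooting
# ---------------------------------------------------------------------------

class TestMadRoot:
    def test_two_tip_midpoint(self):
        flat = FlatTree.from_dendropy(read_newick("(a:0.6,b:0.2);"))
        # the root must land at path distance 0.4 from both tips (midpoint)
        result = mad_root(flat)
        _, d = cophenetic_distances(FlatTree.from_dendropy(result.tree))
        assert d[0, 1] == pytest.approx(0.8)
        depths = sorted(
            leaf.distance_from_root() for leaf in result.tree.leaf_node_iter()
        )
        assert depths[0] == pytest.approx(0.4) and depths[1] == pytest.approx(0.4)

    def test_ultrametric_root_recovered(self):
        tree = read_newick("((a:1,b:1):2,(c:2,d:2):1);")
        result = mad_root(tree)
        assert result.score == pytest.approx(0.0, abs=1e-9)
        # the recovered root must separate {a,b} from {c,d}
        assert result.edge_split in (frozenset({"a", "b"}), frozenset({"c", "d"}))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        flat = random_flat(rng, 8)
        scan = mad_scan(flat)
        eidx, x, score = min(scan, key=lambda t: (round(t[2], 12), t[0], t[1]))
        g_eidx, g_x, g_score = mad_grid_oracle(flat)
        assert eidx == g_eidx
        L = phylo._mad_edges(flat)[eidx][2]
        assert x == pytest.approx(g_x, abs=max(1e-9, 2 * L / 4000))
        assert score == pytest.approx(g_score, abs=1e-6)

    def test_zero_length_tree_is_error(self):
        flat = FlatTree.from_dendropy(read_newick("(a:0,b:0,c:0);"))
        with pytest.raises(ValueError):
            mad_scan(flat)


# ---------------------------------------------------------------------------
# ER maximum likelihood
# ---------------------------------------------------------------------------

class TestErAsr:
    def test_single_state_all_certain(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        fit, asr = fit_er_asr(tree, {t: 2 for t in "abcd"})
        assert np.allclose(asr.node_probs, 1.0)
        assert asr.resolved.all()

    def test_symmetric_two_tip_root_is_even(self):
        tree = read_newick("(a:0.5,b:0.5);")
        fit, asr = fit_er_asr(tree, {"a": 1, "b": 2})
        assert asr.root_probs == pytest.approx([0.5, 0.5], abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_matches_enumeration(self, seed):
        """Likelihood and marginals vs the exhaustive-summation oracle."""
        rng = np.random.default_rng(seed)
        flat = random_flat(rng, int(rng.integers(3, 7)), jitter=False)
        k = int(rng.integers(2, 4))
        states = list(range(1, k + 1))
        ev = evolve_er(flat, states, 0.5, rng)
        rate = float(rng.uniform(0.05, 2.0))
        ll = er_log_likelihood(flat, ev.tip_states, rate, states=states)
        ll_oracle, marg_oracle = enum_er(flat, ev.tip_states, states, rate)
        assert ll == pytest.approx(ll_oracle, abs=1e-8)
        # marginals at the fixed rate, via the inside-outside machinery
        tip_idx = phylo._tip_state_indices(flat, ev.tip_states, states)
        partial, message, _ = phylo._er_up_pass(flat, tip_idx, k, rate)
        outside = [None] * flat.n_nodes
        outside[flat.root] = np.full(k, 1.0 / k)
        for v in flat.preorder():
            vec = outside[v] * partial[v]
            for node, expected in marg_oracle.items():
                if node == v:
                    assert vec / vec.sum() == pytest.approx(expected, abs=1e-8)
            for c in flat.children[v]:
                m = outside[v].copy()
                for sib in flat.children[v]:
                    if sib is not c:
                        m = m * message[sib]
                e = math.exp(-k * rate * flat.blen[c])
                out = e * m + (1.0 - e) / k * m.sum()
                outside[c] = out / out.max()

    def test_zero_length_branch_identity(self):
        tree = read_newick("((a:0,b:1):1,c:1);")
        fit, asr = fit_er_asr(tree, {"a": 1, "b": 2, "c": 2})
        # zero-length branch: the parent of a must share a's posterior support
        flat = asr.flat
        a_idx = next(t for t in flat.tips if flat.labels[t] == "a")
        assert asr.node_probs[a_idx, 0] == 1.0

    def test_rate_recovery_on_simulated_data(self, rng):
        rates = []
        for _ in range(40):
            flat = FlatTree.from_dendropy(sim_tree(64, 1.0, rng))
            ev = evolve_er(flat, [1, 2, 4], 0.5, rng)
            if len(set(ev.tip_states.values())) < 2:
                continue
            fit, _ = fit_er_asr(flat, ev.tip_states)
            rates.append(fit.rate)
        assert np.median(rates) == pytest.approx(0.5, rel=0.25)


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

class TestAcctran:
    def test_constant_tips_score_zero(self):
        tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        score, asr = acctran_asr(tree, {t: 1 for t in "abcd"})
        assert score == 0
        assert all(s == 1 for s in asr.best_states())

    def test_two_tip_single_change(self):
        score, _ = acctran_asr(read_newick("(a:1,b:1);"), {"a": 1, "b": 2})
        assert score == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_score_equals_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        flat = random_flat(rng, int(rng.integers(4, 8)), jitter=False)
        states = [1, 2, 4]
        ev = evolve_er(flat, states, 1.0, rng)
        score, asr = acctran_asr(flat, ev.tip_states, states=states)
        assert score == enum_parsimony(flat, ev.tip_states, states)
        # the realised assignment implies exactly that many changes
        assign = asr.node_probs.argmax(axis=1)
        implied = sum(
            1
            for v in range(flat.n_nodes)
            if flat.parent[v] >= 0 and assign[v] != assign[flat.parent[v]]
        )
        assert implied == score


# ---------------------------------------------------------------------------
# Change rate and root type
# ---------------------------------------------------------------------------

def one_hot_asr(flat, states, assign, resolved=None):
    k = len(states)
    probs = np.zeros((flat.n_nodes, k))
    probs[np.arange(flat.n_nodes), assign] = 1.0
    res = np.ones(flat.n_nodes, dtype=bool) if resolved is None else resolved
    return AsrResult(flat, states, probs, res, "test")


class TestChangeRate:
    def test_constant_states_rate_zero(self):
        flat = FlatTree.from_dendropy(read_newick("((a:1,b:1):1,c:1);"))
        asr = one_hot_asr(flat, [2], np.zeros(flat.n_nodes, dtype=int))
        s = qs_change_rate(asr)
        assert s.rate_total == 0.0 and s.n_pairs_used == s.n_pairs_total

    def test_alternating_states_rate_one(self):
        flat = FlatTree.from_dendropy(read_newick("(a:1,b:1);"))
        # root state 0, both children state 1 -> both edges change
        asr = one_hot_asr(flat, [1, 2], np.array([0, 1, 1]))
        s = qs_change_rate(asr)
        assert s.rate_total == 1.0 and s.n_gains == 2

    def test_unresolved_node_drops_incident_pairs(self):
        flat = FlatTree.from_dendropy(read_newick("((a:1,b:1):1,(c:1,d:1):1);"))
        # internal node with children a,b unresolved -> its 3 incident pairs drop
        assign = np.zeros(flat.n_nodes, dtype=int)
        resolved = np.ones(flat.n_nodes, dtype=bool)
        inner = next(
            v for v in range(flat.n_nodes)
            if flat.children[v] and v != flat.root
            and {flat.labels[c] for c in flat.children[v]} == {"a", "b"}
        )
        resolved[inner] = False
        asr = one_hot_asr(flat, [1, 2], assign, resolved)
        s = qs_change_rate(asr)
        assert s.n_pairs_total == 6 and s.n_pairs_used == 3

    def test_gain_loss_lateral_partition(self):
        flat = FlatTree.from_dendropy(read_newick("((a:1,b:1):1,c:1);"))
        states = ["1:m", "2:x", "2:y"]
        # root dimer-x; inner monomer (loss); a dimer-x (gain); b dimer-y ...
        label_of = {flat.labels[t]: t for t in flat.tips}
        assign = np.zeros(flat.n_nodes, dtype=int)
        inner = next(v for v in range(flat.n_nodes)
                     if flat.children[v] and v != flat.root)
        assign[flat.root] = 1
        assign[inner] = 0
        assign[label_of["a"]] = 1
        assign[label_of["b"]] = 2
        assign[label_of["c"]] = 2
        asr = one_hot_asr(flat, states, assign)
        s = qs_change_rate(asr)
        assert (s.n_gains, s.n_losses, s.n_lateral) == (2, 1, 1)
        assert s.n_changes == s.n_gains + s.n_losses + s.n_lateral

    def test_tie_breaks_toward_parent(self):
        flat = FlatTree.from_dendropy(read_newick("(a:1,b:1);"))
        probs = np.array([[0.0, 1.0], [0.5, 0.5], [0.5, 0.5]])
        asr = AsrResult(flat, [1, 2], probs, np.ones(3, dtype=bool), "test")
        assign = assigned_states(asr)
        assert assign[1] == assign[flat.root] and assign[2] == assign[flat.root]


class TestRootType:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ({"1:m": 0.1, "2:d": 0.9}, "homomer"),
            ({"1:m": 0.6, "2:d": 0.4}, "monomer"),
            ({"1:m": 0.51, "2:d": 0.49}, "unresolved"),  # strictly-above rule
        ],
    )
    def test_rules(self, probs, expected):
        flat = FlatTree.from_dendropy(read_newick("(a:1,b:1);"))
        states = list(probs)
        p = np.tile(np.array([probs[s] for s in states]), (flat.n_nodes, 1))
        asr = AsrResult(flat, states, p, np.ones(flat.n_nodes, dtype=bool), "test")
        assert root_type(asr) == expected


def test_subunit_count_parsers():
    assert subunit_count(4) == 4
    assert subunit_count((2, "x")) == 2
    assert subunit_count("8:OG1_p3") == 8
    with pytest.raises(ValueError):
        subunit_count("dimer")


def test_polytomy_resolution_is_binary_and_deterministic():
    flat = FlatTree.from_dendropy(read_newick("(a:1,b:1,c:1,d:1);"))
    assert all(len(ch) in (0, 2) for ch in flat.children)
    flat2 = FlatTree.from_dendropy(read_newick("(a:1,b:1,c:1,d:1);"))
    assert flat.to_newick() == flat2.to_newick()
    # zero-length internal branches keep path lengths intact
    _, d = cophenetic_distances(flat)
    assert np.allclose(d[~np.eye(4, dtype=bool)], 2.0)
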