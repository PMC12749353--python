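"""Tree hygiene, rooting, and ancestral quaternary-structure reconstruction.

The evolving character is a protein's quaternary structure (QS): subunit
count plus interface topology.  Per orthogroup tree the pipeline

1. drops long-branch outlier tips (mean cophenetic distance above the grand
   mean + 3 SD);
2. roots the tree by Minimal Ancestor Deviation (MAD) — the root position
   minimizing the RMS relative deviation, over tip pairs, of the inferred
   ancestor's distance from the pair midpoint;
3. reconstructs ancestral QS states by equal-rates (ER) Mk maximum
   likelihood (marginal probabilities, Felsenstein pruning) and, separately,
   by Fitch parsimony with accelerated-transformation resolution;
4. summarises QS evolution as the fraction of resolved parent–child node
   pairs whose states differ, split into subunit gains, losses and lateral
   (same count, different interface) changes.

Internal nodes whose best state has marginal probability not above 0.51
count as unresolved; pairs touching them enter neither numerator nor
denominator, and trees whose root is unresolved are excluded from
root-type strata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

RESOLVE_THRESHOLD = 0.51  # strict: "higher than 51%"
OUTLIER_SD_FACTOR = 3.0
MIN_TIPS_FOR_ASR = 10  # orthogroups entering the phylogenetic analysis


# ---------------------------------------------------------------------------
# Tree containers and IO
# ---------------------------------------------------------------------------

def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=source, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


@dataclass
class FlatTree:
    """Array view of a rooted tree for the reconstruction algorithms.

    Nodes are indexed 0..n-1 in the order encountered by a preorder walk of
    the source tree (children kept in input order); multifurcations are
    resolved to binary deterministically, left to right, with zero-length
    branches.  ``blen[i]`` is the branch above node ``i`` (0 for the root).
    """

    parent: list[int]
    children: list[list[int]]
    blen: list[float]
    labels: list[str | None]
    root: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[int]:
        return [i for i, ch in enumerate(self.children) if not ch]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, resolve_polytomies: bool = True
                      ) -> "FlatTree":
        parent: list[int] = []
        children: list[list[int]] = []
        blen: list[float] = []
        labels: list[str | None] = []

        def add(node, parent_idx: int) -> int:
            idx = len(parent)
            parent.append(parent_idx)
            children.append([])
            blen.append(node.edge.length if node.edge.length is not None else 0.0)
            labels.append(node.taxon.label if node.taxon is not None else None)
            if parent_idx >= 0:
                children[parent_idx].append(idx)
            return idx

        def walk(node, parent_idx: int) -> None:
            idx = add(node, parent_idx)
            for ch in node.child_nodes():
                walk(ch, idx)

        walk(tree.seed_node, -1)
        flat = cls(parent, children, blen, labels)
        if resolve_polytomies:
            flat._resolve_polytomies()
        seen = [l for l in flat.tip_labels if l is not None]
        if len(seen) != len(set(seen)):
            raise ValueError("duplicate tip labels in tree")
        return flat

    def _resolve_polytomies(self) -> None:
        # left-to-right: ((c1,c2),c3,...) with zero-length inserted branches
        for v in list(range(self.n_nodes)):
            while len(self.children[v]) > 2:
                c1, c2 = self.children[v][0], self.children[v][1]
                new = len(self.parent)
                self.parent.append(v)
                self.children.append([c1, c2])
                self.blen.append(0.0)
                self.labels.append(None)
                self.parent[c1] = new
                self.parent[c2] = new
                self.children[v] = [new] + self.children[v][2:]

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                core = self.labels[v] or ""
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core + ";"
            return f"{core}:{self.blen[v]:.10g}"

        return rec(self.root)


def _as_flat(tree) -> FlatTree:
    if isinstance(tree, FlatTree):
        return tree
    return FlatTree.from_dendropy(tree)


# ---------------------------------------------------------------------------
# Cophenetic distances and outlier tips
# ---------------------------------------------------------------------------

def cophenetic_distances(tree) -> tuple[list[str], np.ndarray]:
    """Tip×tip patristic distance matrix (path sums of branch lengths)."""
    if not isinstance(tree, FlatTree):
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise ValueError("tree has branches without lengths")
    flat = _as_flat(tree)
    tips = flat.tips
    labels = [flat.labels[t] for t in tips]
    # adjacency walk from each tip (trees are small; O(n^2) is fine)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(flat.n_nodes)]
    for v in range(flat.n_nodes):
        p = flat.parent[v]
        if p >= 0:
            adj[v].append((p, flat.blen[v]))
            adj[p].append((v, flat.blen[v]))
    dmat = np.zeros((len(tips), len(tips)))
    index_of = {t: i for i, t in enumerate(tips)}
    for i, start in enumerate(tips):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            v = stack.pop()
            for w, L in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + L
                    stack.append(w)
        for t, j in index_of.items():
            dmat[i, j] = dist[t]
    return labels, dmat


def filter_outliers(tree, k: float = OUTLIER_SD_FACTOR) -> tuple[list[str], list[str]]:
    """Single-pass long-branch filter on mean cophenetic distances.

    A tip is excluded when its mean distance to all other tips exceeds the
    grand mean of those tip means plus ``k`` standard deviations.  Returns
    (retained, excluded) label lists.
    """
    labels, dmat = cophenetic_distances(tree)
    n = len(labels)
    if n < 4:
        return list(labels), []
    means = dmat.sum(axis=1) / (n - 1)
    grand = means.mean()
    sd = means.std(ddof=1)
    cut = grand + k * sd
    retained = [l for l, m in zip(labels, means) if m <= cut]
    excluded = [l for l, m in zip(labels, means) if m > cut]
    return retained, excluded


def prune_to(tree: dendropy.Tree, labels: list[str]) -> dendropy.Tree:
    """Copy of the tree retaining only the given tip labels."""
    pruned = tree.clone(depth=1)
    keep = [t for t in pruned.taxon_namespace if t.label in set(labels)]
    pruned.retain_taxa(keep)
    return pruned


# ---------------------------------------------------------------------------
# Minimal Ancestor Deviation rooting
# ---------------------------------------------------------------------------

@dataclass
class MADRootResult:
    tree: dendropy.Tree          # rooted binary tree with the new root
    edge_index: int              # index into the deterministic edge list
    offset: float                # distance of the root from the edge's parent-side node
    score: float                 # RMS relative deviation at the minimum
    edge_split: frozenset[str]   # tip labels on the child side of the root edge


def _mad_edges(flat: FlatTree) -> list[tuple[int, int, float]]:
    """Deterministic edge list (u=parent-side, v=child-side, length)."""
    return [(flat.parent[v], v, flat.blen[v])
            for v in flat.preorder() if flat.parent[v] >= 0]


def mad_scan(flat: FlatTree) -> list[tuple[int, float, float]]:
    """Per-edge analytic MAD minimisation.

    Returns, for each edge in :func:`_mad_edges` order, the tuple
    (edge_index, best offset from the parent-side node, RMS deviation).
    Pairs of tips at zero distance are skipped (their deviation is undefined).
    """
    tips = flat.tips
    if len(tips) < 2:
        raise ValueError("MAD rooting needs at least 2 tips")
    if all(L <= 0 for _, _, L in _mad_edges(flat)):
        raise ValueError("cannot MAD-root a tree whose branch lengths are all zero")
    labels, dmat = cophenetic_distances(flat)
    tip_pos = {t: i for i, t in enumerate(tips)}

    # node -> distance to every tip (reuse adjacency walk)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(flat.n_nodes)]
    for v in range(flat.n_nodes):
        p = flat.parent[v]
        if p >= 0:
            adj[v].append((p, flat.blen[v]))
            adj[p].append((v, flat.blen[v]))
    node_tip_dist = np.zeros((flat.n_nodes, len(tips)))
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
            node_tip_dist[v, j] = dist[v]

    # tips below each node in the flat (arbitrary) rooting
    below: list[set[int]] = [set() for _ in range(flat.n_nodes)]
    for v in flat.postorder():
        if not flat.children[v]:
            below[v] = {tip_pos[v]}
        else:
            below[v] = set().union(*(below[c] for c in flat.children[v]))

    all_tips = set(range(len(tips)))
    results: list[tuple[int, float, float]] = []
    for eidx, (u, v, L) in enumerate(_mad_edges(flat)):
        side_v = sorted(below[v])
        side_u = sorted(all_tips - below[v])
        sq_const = 0.0
        n_pairs = 0
        # same-side pairs: ancestor is the meeting point toward this edge
        for side, anchor in ((side_u, u), (side_v, v)):
            for ii in range(len(side)):
                for jj in range(ii + 1, len(side)):
                    b, c = side[ii], side[jj]
                    D = dmat[b, c]
                    if D <= 0:
                        continue
                    dmb = (node_tip_dist[anchor, b] + D - node_tip_dist[anchor, c]) / 2.0
                    sq_const += (2.0 * dmb / D - 1.0) ** 2
                    n_pairs += 1
        # straddling pairs: ancestor is the candidate root itself
        a_coef: list[float] = []
        c_coef: list[float] = []
        for b in side_u:
            for c in side_v:
                D = node_tip_dist[u, b] + L + node_tip_dist[v, c]
                if D <= 0:
                    continue
                a_coef.append(2.0 / D)
                c_coef.append(2.0 * node_tip_dist[u, b] / D - 1.0)
                n_pairs += 1
        if n_pairs == 0:
            results.append((eidx, 0.0, math.inf))
            continue
        a = np.asarray(a_coef)
        c = np.asarray(c_coef)
        if a.size and a @ a > 0:
            x = float(np.clip(-(a @ c) / (a @ a), 0.0, L))
        else:
            x = 0.0
        sq = sq_const + float(((a * x + c) ** 2).sum()) if a.size else sq_const
        results.append((eidx, x, math.sqrt(sq / n_pairs)))
    return results


def mad_root(tree) -> MADRootResult:
    """Root the tree at the global MAD minimum.

    Ties are broken by the smallest edge index, then the smallest offset.
    The input's own rooting is ignored (treated as unrooted).
    """
    flat = _as_flat(tree)
    scan = mad_scan(flat)
    eidx, x, score = min(scan, key=lambda t: (round(t[2], 12), t[0], t[1]))
    edges = _mad_edges(flat)
    u, v, L = edges[eidx]

    below: list[set[str]] = [set() for _ in range(flat.n_nodes)]
    for w in flat.postorder():
        if not flat.children[w]:
            below[w] = {flat.labels[w]}
        else:
            below[w] = set().union(*(below[c] for c in flat.children[w]))

    # rebuild rooted: new root splits edge (u, v) at offset x from u
    adj: dict[int, list[tuple[int, float]]] = {w: [] for w in range(flat.n_nodes)}
    for w in range(flat.n_nodes):
        p = flat.parent[w]
        if p >= 0 and not (w == v and p == u):
            adj[w].append((p, flat.blen[w]))
            adj[p].append((w, flat.blen[w]))

    def subtree_newick(node: int, came_from: int | None) -> str:
        kids = [(w, Lw) for w, Lw in adj[node] if w != came_from]
        if not kids and not flat.children[node]:
            return flat.labels[node] or ""
        parts = []
        for w, Lw in kids:
            parts.append(f"{subtree_newick(w, node)}:{Lw:.10g}")
        # a degree-2 pass-through node (old root of the flat view) is kept
        return "(" + ",".join(parts) + ")" if parts else (flat.labels[node] or "")

    nwk = f"({subtree_newick(u, None)}:{x:.10g},{subtree_newick(v, None)}:{L - x:.10g});"
    rooted = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    rooted.is_rooted = True
    rooted.suppress_unifurcations()
    return MADRootResult(rooted, eidx, x, score, frozenset(below[v]))


# ---------------------------------------------------------------------------
# Equal-rates Mk maximum-likelihood ancestral reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ERModelFit:
    """Fitted one-parameter (equal rates) Mk model."""

    rate: float
    log_likelihood: float
    states: list


@dataclass
class AsrResult:
    """Per-node state estimates on a flattened rooted tree.

    ``node_probs[i]`` are marginal probabilities (ML) or a one-hot assignment
    (parsimony) for node ``i`` of ``flat``; tips carry their observed state
    with probability 1.  ``resolved[i]`` is True when the best state's
    probability exceeds the 0.51 threshold (strictly).
    """

    flat: FlatTree
    states: list
    node_probs: np.ndarray
    resolved: np.ndarray
    method: str
    parsimony_score: int | None = None

    def best_states(self) -> list:
        return [self.states[int(i)] for i in self.node_probs.argmax(axis=1)]

    @property
    def root_probs(self) -> np.ndarray:
        return self.node_probs[self.flat.root]


def _sorted_states(values) -> list:
    try:
        return sorted(set(values))
    except TypeError:
        return sorted(set(values), key=str)


def _tip_state_indices(flat: FlatTree, tip_states: dict, states: list) -> dict[int, int]:
    pos = {s: i for i, s in enumerate(states)}
    out = {}
    for t in flat.tips:
        label = flat.labels[t]
        if label not in tip_states:
            raise ValueError(f"no observed state for tip {label!r}")
        s = tip_states[label]
        if s not in pos:
            raise ValueError(f"tip {label!r} has state {s!r} outside the state space")
        out[t] = pos[s]
    return out


def _er_up_pass(flat: FlatTree, tip_idx: dict[int, int], k: int, rate: float):
    """Felsenstein pruning with the closed-form ER transition.

    For the equal-rates model P(t) = e^{-k r t} I + (1 - e^{-k r t})/k J, so a
    child's message to its parent is e*L(s) + (1-e)/k * sum(L).  Partials are
    rescaled per node; returns (partials, messages, total log scale).
    """
    n = flat.n_nodes
    partial = [None] * n
    message = [None] * n  # child's contribution, indexed by parent state
    log_scale = 0.0
    for v in flat.postorder():
        if not flat.children[v]:
            vec = np.zeros(k)
            vec[tip_idx[v]] = 1.0
        else:
            vec = np.ones(k)
            for c in flat.children[v]:
                vec = vec * message[c]
        mx = vec.max()
        if mx <= 0 or not np.isfinite(mx):
            raise FloatingPointError("non-finite or zero partial likelihood")
        vec = vec / mx
        log_scale += math.log(mx)
        partial[v] = vec
        if v != flat.root:
            e = math.exp(-k * rate * flat.blen[v])
            message[v] = e * vec + (1.0 - e) / k * vec.sum()
    return partial, message, log_scale


def er_log_likelihood(flat: FlatTree, tip_states: dict, rate: float,
                      states: list | None = None,
                      root_prior: str | np.ndarray = "uniform") -> float:
    """Log-likelihood of tip states under the ER Mk model at a fixed rate."""
    flat = _as_flat(flat)
    if states is None:
        states = _sorted_states(tip_states.values())
    k = len(states)
    tip_idx = _tip_state_indices(flat, tip_states, states)
    if k == 1:
        return 0.0
    prior = _root_prior_vector(root_prior, k)
    partial, _, log_scale = _er_up_pass(flat, tip_idx, k, rate)
    lik = float(prior @ partial[flat.root])
    if lik <= 0 or not np.isfinite(lik):
        raise FloatingPointError("non-finite likelihood")
    return math.log(lik) + log_scale


def _root_prior_vector(root_prior, k: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior != "uniform":
            raise ValueError(f"unknown root prior {root_prior!r}")
        return np.full(k, 1.0 / k)
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (k,) or prior.min() < 0 or not math.isclose(prior.sum(), 1.0):
        raise ValueError("root prior must be a length-k probability vector")
    return prior


def _er_marginals_at_rate(flat: FlatTree, tip_idx: dict[int, int], k: int,
                          rate: float, prior: np.ndarray) -> np.ndarray:
    """Marginal node probabilities at a fixed ER rate (inside–outside)."""
    partial, message, _ = _er_up_pass(flat, tip_idx, k, rate)
    outside = [None] * flat.n_nodes
    outside[flat.root] = prior.copy()
    probs = np.zeros((flat.n_nodes, k))
    for v in flat.preorder():
        vec = outside[v] * partial[v]
        probs[v] = vec / vec.sum()
        for c in flat.children[v]:
            m = outside[v].copy()
            for sib in flat.children[v]:
                if sib is not c:
                    m = m * message[sib]
            e = math.exp(-k * rate * flat.blen[c])
            out = e * m + (1.0 - e) / k * m.sum()
            mx = out.max()
            outside[c] = out / mx if mx > 0 else out
    return probs


def er_marginals(tree, tip_states: dict, rate: float, states: list | None = None,
                 root_prior: str | np.ndarray = "uniform") -> tuple[list, np.ndarray]:
    """Marginal ancestral state probabilities at a fixed ER rate.

    Returns (states, probabilities) with one row per node of the flattened
    tree; rows sum to 1.
    """
    flat = _as_flat(tree)
    if states is None:
        states = _sorted_states(tip_states[l] for l in flat.tip_labels)
    k = len(states)
    tip_idx = _tip_state_indices(flat, tip_states, states)
    if k == 1:
        return list(states), np.ones((flat.n_nodes, 1))
    prior = _root_prior_vector(root_prior, k)
    return list(states), _er_marginals_at_rate(flat, tip_idx, k, rate, prior)


def fit_er_asr(tree, tip_states: dict, states: list | None = None,
               root_prior: str | np.ndarray = "uniform",
               resolve_threshold: float = RESOLVE_THRESHOLD,
               ) -> tuple[ERModelFit, AsrResult]:
    """Fit the ER rate by ML and compute marginal ancestral state probabilities.

    The state space defaults to the states observed at the tips of this tree
    (unobserved QS classes are not imputed).  The single transition rate is
    estimated by bracketed scalar optimisation of the pruning log-likelihood
    on a log scale; marginal node probabilities come from the standard
    inside–outside (re-rooting) computation with a uniform root prior by
    default.  Nodes are flagged resolved when their best state's probability
    strictly exceeds ``resolve_threshold``.
    """
    flat = _as_flat(tree)
    if len(flat.tips) < 2:
        raise ValueError("ASR needs at least 2 tips")
    if states is None:
        states = _sorted_states(tip_states[l] for l in flat.tip_labels)
    k = len(states)
    tip_idx = _tip_state_indices(flat, tip_states, states)
    n = flat.n_nodes

    if k == 1:
        probs = np.ones((n, 1))
        fit = ERModelFit(0.0, 0.0, list(states))
        return fit, AsrResult(flat, list(states), probs,
                              np.ones(n, dtype=bool), "ml")

    prior = _root_prior_vector(root_prior, k)

    def neg_loglik(log_r: float) -> float:
        partial, _, log_scale = _er_up_pass(flat, tip_idx, k, math.exp(log_r))
        lik = float(prior @ partial[flat.root])
        return -(math.log(lik) + log_scale)

    res = minimize_scalar(neg_loglik, bounds=(math.log(1e-9), math.log(1e5)),
                          method="bounded", options={"xatol": 1e-8})
    rate = math.exp(res.x)
    loglik = -res.fun
    if not np.isfinite(loglik):
        raise FloatingPointError("ER fit produced a non-finite likelihood")

    probs = _er_marginals_at_rate(flat, tip_idx, k, rate, prior)
    resolved = probs.max(axis=1) > resolve_threshold
    for t in flat.tips:
        resolved[t] = True
    fit = ERModelFit(rate, loglik, list(states))
    return fit, AsrResult(flat, list(states), probs, resolved, "ml")


# ---------------------------------------------------------------------------
# Fitch parsimony with ACCTRAN-style resolution
# ---------------------------------------------------------------------------

def acctran_asr(tree, tip_states: dict, states: list | None = None
                ) -> tuple[int, AsrResult]:
    """Most-parsimonious ancestral assignment (Fitch) resolved rootward.

    Downpass computes Fitch state sets and the parsimony score (number of
    union events).  The uppass assigns the root the smallest state of its
    set, and each child keeps the parent's state when the parent's state is
    in the child's set — otherwise the change is placed on that edge, as
    close to the root as forced placements allow, taking the smallest state
    of the child's set.  The implied change count equals the Fitch score.
    """
    flat = _as_flat(tree)
    if states is None:
        states = _sorted_states(tip_states[l] for l in flat.tip_labels)
    k = len(states)
    tip_idx = _tip_state_indices(flat, tip_states, states)

    down: list[set[int]] = [set() for _ in range(flat.n_nodes)]
    score = 0
    for v in flat.postorder():
        if not flat.children[v]:
            down[v] = {tip_idx[v]}
        else:
            sets = [down[c] for c in flat.children[v]]
            inter = set.intersection(*sets)
            if inter:
                down[v] = inter
            else:
                down[v] = set.union(*sets)
                score += len(sets) - 1

    assign = np.full(flat.n_nodes, -1, dtype=int)
    for v in flat.preorder():
        if v == flat.root:
            assign[v] = min(down[v])
        else:
            p = assign[flat.parent[v]]
            assign[v] = p if p in down[v] else min(down[v])

    probs = np.zeros((flat.n_nodes, k))
    probs[np.arange(flat.n_nodes), assign] = 1.0
    result = AsrResult(flat, list(states), probs,
                       np.ones(flat.n_nodes, dtype=bool), "acctran",
                       parsimony_score=score)
    return score, result


# ---------------------------------------------------------------------------
# QS change-rate statistics
# ---------------------------------------------------------------------------

@dataclass
class ChangeRateSummary:
    """Parent–child QS transition counts and rates over one tree."""

    n_pairs_total: int
    n_pairs_used: int
    n_changes: int
    n_gains: int
    n_losses: int
    n_lateral: int
    rate_total: float
    rate_gain: float
    rate_loss: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def subunit_count(state) -> int:
    """Subunit count of a QS state label.

    Accepts plain integers, (n_subunits, topology) tuples, or strings of the
    form ``"<n>:<class>"``.
    """
    if isinstance(state, (int, np.integer)):
        return int(state)
    if isinstance(state, tuple):
        return int(state[0])
    if isinstance(state, str) and ":" in state:
        return int(state.split(":", 1)[0])
    raise ValueError(f"cannot infer subunit count from state {state!r}")


def assigned_states(asr: AsrResult, tie_tol: float = 1e-9) -> np.ndarray:
    """Point state per node: argmax probability, ties broken toward the parent.

    Resolved in preorder so the parent's assignment is available; the root's
    tie breaks to the smallest state index.
    """
    flat = asr.flat
    out = np.full(flat.n_nodes, -1, dtype=int)
    for v in flat.preorder():
        p = asr.node_probs[v]
        best = p.max()
        cands = np.flatnonzero(p >= best - tie_tol)
        if v == flat.root or out[flat.parent[v]] not in cands:
            out[v] = int(cands[0])
        else:
            out[v] = out[flat.parent[v]]
    return out


def qs_change_rate(asr: AsrResult, subunits_of=subunit_count) -> ChangeRateSummary:
    """Fraction of resolved parent–child pairs whose QS states differ.

    Iterates every edge of the tree, tip edges included.  Pairs with an
    unresolved endpoint are skipped entirely (they enter neither count nor
    denominator).  A change is a gain when the child has more subunits than
    the parent, a loss when fewer, and lateral when the counts are equal but
    the topology class differs.
    """
    flat = asr.flat
    states = asr.states
    assign = assigned_states(asr)
    subs = [subunits_of(s) for s in states]

    n_total = n_used = n_changes = n_gain = n_loss = n_lateral = 0
    for v in range(flat.n_nodes):
        p = flat.parent[v]
        if p < 0:
            continue
        n_total += 1
        if not (asr.resolved[v] and asr.resolved[p]):
            continue
        n_used += 1
        if assign[v] != assign[p]:
            n_changes += 1
            dv, dp = subs[assign[v]], subs[assign[p]]
            if dv > dp:
                n_gain += 1
            elif dv < dp:
                n_loss += 1
            else:
                n_lateral += 1

    def rate(c: int) -> float:
        return c / n_used if n_used else math.nan

    return ChangeRateSummary(n_total, n_used, n_changes, n_gain, n_loss,
                             n_lateral, rate(n_changes), rate(n_gain), rate(n_loss))


def root_type(asr: AsrResult, subunits_of=subunit_count,
              threshold: float = RESOLVE_THRESHOLD) -> str:
    """Classify the root as homomer / monomer / unresolved (strict 0.51 rule)."""
    p = asr.root_probs
    if p.max() <= threshold:
        return "unresolved"
    state = asr.states[int(p.argmax())]
    return "monomer" if subunits_of(state) == 1 else "homomer"


def tree_report(fit: ERModelFit | None, asr: AsrResult,
                summary: ChangeRateSummary, subunits_of=subunit_count) -> dict:
    """JSON-ready per-tree summary of the reconstruction."""
    return {
        "method": asr.method,
        "n_tips": len(asr.flat.tips),
        "states": [str(s) for s in asr.states],
        "rate": fit.rate if fit else None,
        "log_likelihood": fit.log_likelihood if fit else None,
        "root_type": root_type(asr, subunits_of),
        "root_probs": {str(s): float(p) for s, p in zip(asr.states, asr.root_probs)},
        "change_rate": summary.to_dict(),
    }
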