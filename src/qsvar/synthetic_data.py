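"""Synthetic study generator with known ground truth.

Emulates every input the pipeline consumes: Yule orthogroup trees, a
quaternary-structure character evolved along them under a continuous-time
gain/loss ladder (1 ↔ 2 ↔ 4 ↔ 8 subunits), toy complexes expressed as
per-residue SASA tables with planted interfaces, identity structural
alignment maps, a small GO-style ontology with redundant ancestor
annotations, and moonlighting (MO) vs non-MO orthogroup tables with a
controllable effect size on annotation richness and on QS transition rates.

Everything is deterministic under the configured seed; a JSON manifest
records the ground-truth parameters so recovery tests can state their
expectations without re-running the simulator.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .annotations import AnnotationTable, OntologyDAG, write_annotations
from .interfaces import load_max_areas
from .phylo import FlatTree
from .topology import AlignmentMap, write_alignment_maps

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default QS ladder: subunit counts reachable by one-step gains/losses
DEFAULT_STATES = (1, 2, 4, 8)


@dataclass
class SimConfig:
    """Study-generation parameters (defaults define the test conditions)."""

    seed: int = 0
    n_orthogroups: int = 50          # per arm (MO and non-MO)
    n_tips_min: int = 3
    n_tips_max: int = 48
    tip_geometric_p: float = 0.15    # extra tips ~ geometric: most orthogroups small
    birth_rate: float = 1.0
    states: tuple[int, ...] = DEFAULT_STATES
    gain_rate: float = 0.25          # events per unit branch length
    loss_rate: float = 0.25
    qs_effect: float = 1.0           # transition-rate multiplier for MO trees
    annotation_effect: float = 1.5   # MO mean terms/protein multiplier
    annotation_mean: float = 4.0     # non-MO mean terms per protein
    annotation_dispersion: float = 5.0
    ancestor_injection_p: float = 0.5
    n_residues: int = 120
    interface_fraction: float = 0.15
    sasa_noise: float = 0.02         # relative jitter on complex SASA

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("birth_rate", "gain_rate", "loss_rate", "qs_effect",
                     "annotation_effect", "annotation_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tips_min < 3:
            raise ValueError("trees need at least 3 tips")
        if not 0 <= self.sasa_noise < 0.05:
            raise ValueError("sasa_noise must stay below half the burial threshold")
        if len(self.states) < 2 or list(self.states) != sorted(set(self.states)):
            raise ValueError("states must be >= 2 strictly increasing subunit counts")


# ---------------------------------------------------------------------------
# Trees and character evolution
# ---------------------------------------------------------------------------

def sim_tree(n_tips: int, birth_rate: float, seed_or_rng) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times.

    Branch lengths are in the same arbitrary units as the transition rates
    ("substitutions/site" scale).  Deterministic under the seed.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    parent = [-1, 0, 0]
    children = [[1, 2], [], []]
    blen = [0.0, 0.0, 0.0]
    active = [1, 2]
    now = 0.0
    birth_time = {1: 0.0, 2: 0.0}
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        v = active[i]
        blen[v] = now - birth_time[v]
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([v, v])
        children[v] = [c1, c2]
        children.extend([[], []])
        blen.extend([0.0, 0.0])
        active[i] = c1
        active.append(c2)
        birth_time.pop(v)
        birth_time[c1] = birth_time[c2] = now
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    labels: list[str | None] = [None] * len(parent)
    for j, v in enumerate(sorted(active)):
        blen[v] = now - birth_time[v]
        labels[v] = f"t{j + 1:03d}"
    flat = FlatTree(parent, children, blen, labels)
    tree = dendropy.Tree.get(data=flat.to_newick(), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@dataclass
class EvolvedStates:
    """Ground truth of a character simulation on one tree."""

    flat: FlatTree
    node_states: list
    tip_states: dict


def _simulate_markov(tree, states, rate_fn, rng) -> EvolvedStates:
    flat = tree if isinstance(tree, FlatTree) else FlatTree.from_dendropy(tree)
    k = len(states)
    node_state = [-1] * flat.n_nodes
    node_state[flat.root] = int(rng.integers(k))
    for v in flat.preorder():
        if v == flat.root:
            continue
        s = node_state[flat.parent[v]]
        t_left = flat.blen[v]
        while True:
            rates = rate_fn(s)
            total = sum(r for _, r in rates)
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if wait > t_left:
                break
            t_left -= wait
            u = rng.random() * total
            acc = 0.0
            for target, r in rates:
                acc += r
                if u <= acc:
                    s = target
                    break
        node_state[v] = s
    tip_states = {flat.labels[t]: states[node_state[t]] for t in flat.tips}
    return EvolvedStates(flat, [states[s] for s in node_state], tip_states)


def evolve_qs(tree, states, gain_rate: float, loss_rate: float, seed_or_rng
              ) -> EvolvedStates:
    """Evolve the QS ladder along the tree (one-step gains and losses).

    Gains move one state up the subunit ladder at ``gain_rate`` per unit
    branch length, losses one state down at ``loss_rate``; events are drawn
    exactly (Gillespie sampling along each branch).  The root state is drawn
    uniformly.  Both tip states and the full node-state truth are returned.
    """
    states = list(states)
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    k = len(states)

    def rate_fn(s: int):
        out = []
        if s + 1 < k:
            out.append((s + 1, gain_rate))
        if s - 1 >= 0:
            out.append((s - 1, loss_rate))
        return out

    return _simulate_markov(tree, states, rate_fn, rng)


def evolve_er(tree, states, rate: float, seed_or_rng) -> EvolvedStates:
    """Evolve a character under the equal-rates model (any state to any other)."""
    states = list(states)
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    k = len(states)

    def rate_fn(s: int):
        return [(t, rate) for t in range(k) if t != s]

    return _simulate_markov(tree, states, rate_fn, rng)


# ---------------------------------------------------------------------------
# Toy complexes and alignment maps
# ---------------------------------------------------------------------------

def gen_toy_complex(protein_id: str, n_subunits: int, n_residues: int,
                    planted_interface: set[int], seed_or_rng,
                    sasa_noise: float = 0.0) -> pd.DataFrame:
    """Per-residue SASA table of a toy complex with a planted interface.

    Planted residues get monomer RSA in [0.3, 0.9] and a 20–80% SASA drop in
    the complex (strictly beyond both classification thresholds); the rest
    split between surface residues (exposed, <5% drop) and buried ones
    (RSA below 0.15, no drop).  ``sasa_noise`` jitters the complex SASA
    multiplicatively but is kept well below the 10% burial threshold.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    if not set(planted_interface) <= set(range(1, n_residues + 1)):
        raise ValueError("planted interface must be a subset of residue indices")
    if n_subunits == 1 and planted_interface:
        raise ValueError("a monomer cannot have a planted interface")
    max_areas = load_max_areas()
    rows = []
    for i in range(1, n_residues + 1):
        aa = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        if i in planted_interface:
            rsa = rng.uniform(0.3, 0.9)
            burial = rng.uniform(0.2, 0.8)
        elif rng.random() < 0.6:
            rsa = rng.uniform(0.25, 0.9)     # surface: exposed, negligible drop
            burial = rng.uniform(0.0, 0.05)
        else:
            rsa = rng.uniform(0.02, 0.15)    # buried in the monomer already
            burial = 0.0
        mono = rsa * max_areas[aa]
        cplx = mono * (1.0 - burial)
        if sasa_noise:
            cplx *= 1.0 + rng.uniform(-sasa_noise, sasa_noise)
        rows.append({"protein_id": protein_id, "chain_id": "A", "residue_index": i,
                     "residue_type": aa, "sasa_complex": round(cplx, 4),
                     "sasa_monomer": round(mono, 4)})
    return pd.DataFrame(rows)


def identity_alignment(protein_a: str, protein_b: str, n_residues: int,
                       chain: str = "A") -> AlignmentMap:
    """Residue-identity alignment map between two equal-length toy structures."""
    pairs = [((chain, i), (chain, i)) for i in range(1, n_residues + 1)]
    return AlignmentMap(protein_a, protein_b, pairs)


# ---------------------------------------------------------------------------
# Ontology and annotations
# ---------------------------------------------------------------------------

def gen_ontology(depth: int, branching: int, seed_or_rng=0, n_namespaces: int = 2
                 ) -> OntologyDAG:
    """Rooted DAG per namespace: a balanced is_a tree of the given depth."""
    import networkx as nx

    if depth < 2:
        raise ValueError("depth must be >= 2")
    graph = nx.MultiDiGraph()
    for ns in range(n_namespaces):
        ns_name = f"namespace_{ns}"
        counter = [0]

        def new_term():
            counter[0] += 1
            tid = f"NS{ns}:{counter[0]:05d}"
            graph.add_node(tid, namespace=ns_name, name=tid)
            return tid

        level = [new_term()]
        for _ in range(depth - 1):
            nxt = []
            for parent in level:
                for _ in range(branching):
                    child = new_term()
                    graph.add_edge(child, parent, key="is_a")
                    nxt.append(child)
            level = nxt
    return OntologyDAG(graph)


def _ontology_leaves(dag: OntologyDAG) -> dict[str, list[str]]:
    leaves: dict[str, list[str]] = {}
    for term in sorted(dag.graph.nodes):
        if dag.graph.in_degree(term) == 0:  # no child edges -> leaf
            leaves.setdefault(dag.namespace(term), []).append(term)
    return leaves


def sample_annotations(dag: OntologyDAG, protein_ids: list[str], mean_terms: float,
                       dispersion: float, ancestor_injection_p: float, rng,
                       source: str = "GO") -> AnnotationTable:
    """Draw per-protein leaf terms (negative-binomial counts) plus redundant ancestors.

    With probability ``ancestor_injection_p`` each sampled leaf also
    contributes one of its proper ancestors, so hierarchy filtering has work
    to do; evidence codes are drawn from a mix of IEA / IDA / IMP / TAS.
    """
    leaves_by_ns = _ontology_leaves(dag)
    all_leaves = [t for terms in leaves_by_ns.values() for t in terms]
    evidence_codes = ["IEA", "IDA", "IMP", "TAS"]
    table = AnnotationTable()
    p = dispersion / (dispersion + mean_terms)
    for pid in protein_ids:
        count = int(rng.negative_binomial(dispersion, p)) if mean_terms > 0 else 0
        for _ in range(count):
            leaf = all_leaves[rng.integers(len(all_leaves))]
            ev = evidence_codes[rng.integers(len(evidence_codes))]
            table.add(pid, source, leaf, ev)
            if rng.random() < ancestor_injection_p:
                anc = sorted(dag.ancestors(leaf))
                if anc:
                    table.add(pid, source, anc[rng.integers(len(anc))], ev)
    return table


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialise a DAG in minimal OBO format (is_a and part_of edges)."""
    lines = ["format-version: 1.2", "ontology: qsvar/synthetic", ""]
    for term in sorted(dag.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.graph.nodes[term].get('name', term)}")
        lines.append(f"namespace: {dag.namespace(term)}")
        for _, parent, rel in sorted(dag.graph.out_edges(term, keys=True)):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Reduced simulation studies (calibration of the comparison machinery)
# ---------------------------------------------------------------------------

def sim_change_rate_study(n_trees_per_arm: int, n_tips: int, qs_effect: float,
                          seed_or_rng, gain_rate: float = 0.25,
                          loss_rate: float = 0.25,
                          states: tuple[int, ...] = DEFAULT_STATES) -> dict:
    """One replicate of the MO vs non-MO change-rate comparison.

    Simulates ``n_trees_per_arm`` Yule trees per arm, evolves the QS ladder
    (MO trees at ``qs_effect`` times the base rates), reconstructs ancestral
    states by ER ML, and compares the per-tree change-rate statistics with
    Wilcoxon tests (total, gain and loss rates) corrected jointly by BH.
    Returns the per-arm rate samples and the three test results.
    """
    from . import phylo as phylo_mod
    from . import stats_compare as stats_mod

    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    arms: dict[str, dict[str, list[float]]] = {}
    for arm, mult in (("MO", qs_effect), ("nonMO", 1.0)):
        rates = {"rate_total": [], "rate_gain": [], "rate_loss": []}
        for _ in range(n_trees_per_arm):
            tree = sim_tree(n_tips, 1.0, rng)
            flat = FlatTree.from_dendropy(tree)
            ev = evolve_qs(flat, list(states), gain_rate * mult, loss_rate * mult, rng)
            if len(set(ev.tip_states.values())) < 2:
                for key in rates:
                    rates[key].append(0.0)
                continue
            _, asr = phylo_mod.fit_er_asr(flat, ev.tip_states)
            summ = phylo_mod.qs_change_rate(asr)
            for key in rates:
                val = getattr(summ, key)
                if not math.isnan(val):
                    rates[key].append(val)
        arms[arm] = rates

    study = stats_mod.StudyResults()
    for key in ("rate_total", "rate_gain", "rate_loss"):
        study.add(stats_mod.wilcoxon_rank_sum(arms["MO"][key], arms["nonMO"][key],
                                              f"change_{key}"))
    study.finalize()
    return {"arms": arms, "tests": {r.test_id: r for r in study.results}}


def sim_null_battery(seed_or_rng) -> list[float]:
    """Raw p-values of one fully null study battery (no group effect anywhere).

    Exercises each test family the pipeline uses — rank-sum on continuous
    and on skewed data, the two-proportion test, ANCOVA's group effect and
    the Spearman partial correlation — on data simulated with no group
    difference, for type-I-error calibration of the whole battery.
    """
    from . import stats_compare as stats_mod

    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) \
        else seed_or_rng
    ps = []
    ps.append(stats_mod.wilcoxon_rank_sum(rng.normal(size=25), rng.normal(size=25)).p_raw)
    ps.append(stats_mod.wilcoxon_rank_sum(rng.lognormal(size=18), rng.lognormal(size=18)).p_raw)
    k1, k2 = rng.binomial(60, 0.4), rng.binomial(60, 0.4)
    ps.append(stats_mod.prop_test_ci(int(k1), 60, int(k2), 60).p_raw)
    z = rng.normal(size=30)
    g = np.repeat([0, 1], 15)
    y = 0.5 * z + rng.normal(size=30)
    ps.append(stats_mod.ancova_group_effect(y, g, z).p_raw)
    x2, y2, z2 = rng.normal(size=30), rng.normal(size=30), rng.normal(size=30)
    ps.append(stats_mod.spearman_partial(x2, y2, z2).p_raw)
    return ps


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

def gen_study(config: SimConfig, out_dir) -> dict:
    """Generate a complete two-arm study bundle on disk.

    Produces, under ``out_dir``: per-orthogroup Newick trees, the
    per-protein QS state table, combined SASA and alignment tables, an OBO
    ontology with annotations, the orthogroup membership table with MO
    flags, and a JSON manifest of the ground-truth parameters.  MO trees
    evolve their QS character at ``qs_effect`` times the base rates, and MO
    proteins draw ``annotation_effect`` times more terms on average.
    """
    config.validate()
    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    states = list(config.states)
    records, state_rows, sasa_frames, amaps = [], [], [], []
    truth = {"trees": {}}
    # one shared planted interface per subunit count: same-count homomers in
    # an orthogroup overlap fully, so lateral (interface-only) changes are off
    n_iface = max(3, int(round(config.interface_fraction * config.n_residues)))

    for arm, is_mo in (("MO", True), ("nonMO", False)):
        mult = config.qs_effect if is_mo else 1.0
        for g in range(config.n_orthogroups):
            og_id = f"{arm}_{g:04d}"
            n_tips = min(config.n_tips_max,
                         config.n_tips_min + int(rng.geometric(config.tip_geometric_p)) - 1)
            tree = sim_tree(n_tips, config.birth_rate, rng)
            for taxon in tree.taxon_namespace:  # tips are the protein ids
                taxon.label = f"{og_id}_{taxon.label}"
            evolved = evolve_qs(tree, states, config.gain_rate * mult,
                                config.loss_rate * mult, rng)
            tree.write(path=str(out / "trees" / f"{og_id}.nwk"), schema="newick",
                       unquoted_underscores=True)
            flat = evolved.flat
            root_state = evolved.node_states[flat.root]
            truth["trees"][og_id] = {
                "n_tips": n_tips,
                "root_state": root_state,
                "gain_rate": config.gain_rate * mult,
                "loss_rate": config.loss_rate * mult,
            }
            iface_start = 1 + rng.integers(config.n_residues - n_iface)
            for pid, state in sorted(evolved.tip_states.items()):
                n_sub = int(state)
                planted = (set(range(iface_start, iface_start + n_iface))
                           if n_sub > 1 else set())
                sasa_frames.append(gen_toy_complex(pid, n_sub, config.n_residues,
                                                   planted, rng, config.sasa_noise))
                state_rows.append({"protein_id": pid, "orthogroup_id": og_id,
                                   "n_subunits": n_sub})
                records.append({
                    "protein_id": pid, "orthogroup_id": og_id,
                    "resolution": round(float(rng.uniform(1.2, 2.8)), 3),
                    "coverage": round(float(rng.uniform(0.82, 1.0)), 4),
                    "length": config.n_residues,
                    "n_subunits": n_sub,
                    "is_moonlighting": bool(is_mo and rng.random() < 0.1),
                    "is_predicted_moonlighting": False,
                    "is_MO_arm": is_mo,
                })
            # identity alignments between same-orthogroup proteins of equal count
            members = [(r["protein_id"], r["n_subunits"]) for r in state_rows
                       if r["orthogroup_id"] == og_id]
            for i, (pa, na) in enumerate(members):
                for pb, nb in members[i + 1:]:
                    if na == nb and na > 1:
                        amaps.append(identity_alignment(pa, pb, config.n_residues))

    # make sure each MO arm orthogroup has >= 1 flagged moonlighting protein
    df = pd.DataFrame(records)
    for og_id, grp in df[df["is_MO_arm"]].groupby("orthogroup_id"):
        if not grp["is_moonlighting"].any():
            df.loc[grp.index[0], "is_moonlighting"] = True

    dag = gen_ontology(depth=4, branching=3, seed_or_rng=rng)
    ann = AnnotationTable()
    for _, row in df.iterrows():
        mean = config.annotation_mean * (config.annotation_effect if row["is_MO_arm"] else 1.0)
        single = sample_annotations(dag, [row["protein_id"]], mean,
                                    config.annotation_dispersion,
                                    config.ancestor_injection_p, rng)
        for src, per_protein in single.sources.items():
            for pid, pairs in per_protein.items():
                for term, ev in pairs:
                    ann.add(pid, src, term, ev)

    df.drop(columns=["is_MO_arm"]).to_csv(out / "orthogroups.tsv", sep="\t", index=False)
    pd.DataFrame(state_rows).to_csv(out / "states.tsv", sep="\t", index=False)
    pd.concat(sasa_frames, ignore_index=True).to_csv(out / "sasa.tsv", sep="\t",
                                                     index=False)
    write_alignment_maps(amaps, out / "alignments.tsv")
    write_obo(dag, out / "ontology.obo")
    write_annotations(ann, out / "annotations.tsv")

    manifest = {"config": asdict(config), "truth": truth,
                "n_proteins": int(len(df)),
                "n_orthogroups": 2 * config.n_orthogroups}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
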