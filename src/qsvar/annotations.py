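"""Ontology handling and annotation-richness counts.

Functional annotation sets (GO, Reactome, Pfam domains, PPI partners,
subcellular locations) are compared between protein groups as mean terms per
protein.  GO and Reactome term sets are first de-redundified against the
term hierarchy: when two annotated terms lie on the same ancestor–descendant
path (via is_a / part_of, within one namespace), only the more specific
(lowest-level) term is kept — e.g. of "mitochondrion" and "mitochondrial
inner membrane", only the latter survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

#: GO evidence codes counted as experimental
EXPERIMENTAL_EVIDENCE = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
)

ANCESTRY_RELATIONS = ("is_a", "part_of")


class OntologyDAG:
    """Directed acyclic term hierarchy with within-namespace ancestry queries.

    Edges run child → parent and carry a relation label; only is_a / part_of
    edges that stay inside one namespace define ancestry.
    """

    def __init__(self, graph: nx.MultiDiGraph):
        self.graph = graph
        anc = nx.DiGraph()
        anc.add_nodes_from(graph.nodes)
        for child, parent, rel in graph.edges(keys=True):
            if rel not in ANCESTRY_RELATIONS:
                continue
            ns_c = graph.nodes[child].get("namespace")
            ns_p = graph.nodes[parent].get("namespace")
            if ns_c is not None and ns_p is not None and ns_c != ns_p:
                continue
            anc.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(anc):
            raise ValueError("ontology is cyclic over is_a/part_of")
        self._ancestry = anc

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestors(self, term: str) -> set[str]:
        """Proper ancestors of a term via is_a/part_of within its namespace."""
        return nx.descendants(self._ancestry, term)

    def is_ancestor(self, a: str, b: str) -> bool:
        """True when ``a`` is a proper ancestor of ``b``."""
        return a in self.ancestors(b)


def read_obo(path) -> OntologyDAG:
    """Read an OBO ontology (obsolete terms are dropped, with a warning)."""
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    obsolete = [n for n, d in graph.nodes(data=True) if d.get("is_obsolete") == "true"]
    if obsolete:
        warnings.warn(f"dropping {len(obsolete)} obsolete ontology terms")
        graph.remove_nodes_from(obsolete)
    return OntologyDAG(graph)


def load_mini_obo() -> OntologyDAG:
    """Packaged synthetic miniature GO-style ontology used in tests/examples."""
    import importlib.resources

    ref = importlib.resources.files("qsvar.data") / "mini_go_synthetic.obo"
    with importlib.resources.as_file(ref) as path:
        return read_obo(path)


def read_reactome_relations(path) -> OntologyDAG:
    """Build a DAG from a parent<TAB>child relation file (Reactome style)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"],
                     dtype=str, comment="#")
    graph = nx.MultiDiGraph()
    for row in df.itertuples():
        graph.add_edge(row.child, row.parent, key="is_a")
    return OntologyDAG(graph)


def filter_redundant_terms(terms: set[str], dag: OntologyDAG) -> set[str]:
    """Keep only the lowest-level term of every ancestor–descendant pair.

    A term is removed iff it is a proper ancestor (is_a / part_of closure,
    within its namespace) of another term in the set; the result is an
    antichain and the operation is idempotent.  Terms in unrelated
    namespaces never eliminate each other.
    """
    unknown = sorted(t for t in terms if t not in dag)
    if unknown:
        raise KeyError(f"terms not in the ontology: {unknown}")
    terms = set(terms)
    ancestors_in_set: set[str] = set()
    for t in terms:
        ancestors_in_set |= dag.ancestors(t) & terms
    return terms - ancestors_in_set


@dataclass
class AnnotationTable:
    """protein → {(term, evidence)} per annotation source."""

    sources: dict[str, dict[str, set[tuple[str, str | None]]]] = field(
        default_factory=dict
    )

    def add(self, protein_id: str, source: str, term: str,
            evidence: str | None = None) -> None:
        self.sources.setdefault(source, {}).setdefault(protein_id, set()).add(
            (term, evidence)
        )

    def terms(self, protein_id: str, source: str) -> set[str]:
        return {t for t, _ in self.sources.get(source, {}).get(protein_id, set())}

    def proteins(self, source: str) -> set[str]:
        return set(self.sources.get(source, {}))


def read_annotations(path) -> AnnotationTable:
    """Read a TSV with columns protein_id, source, term_id, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    table = AnnotationTable()
    for row in df.itertuples():
        ev = None if pd.isna(row.evidence) else str(row.evidence)
        table.add(str(row.protein_id), str(row.source), str(row.term_id), ev)
    return table


def write_annotations(table: AnnotationTable, path) -> None:
    rows = [
        {"protein_id": pid, "source": src, "term_id": term, "evidence": ev}
        for src, per_protein in sorted(table.sources.items())
        for pid, pairs in sorted(per_protein.items())
        for term, ev in sorted(pairs, key=lambda p: (p[0], p[1] or ""))
    ]
    pd.DataFrame(rows, columns=["protein_id", "source", "term_id", "evidence"]
                 ).to_csv(path, sep="\t", index=False)


def evidence_subset(table: AnnotationTable, mode: str,
                    experimental_codes: frozenset[str] = EXPERIMENTAL_EVIDENCE,
                    ) -> AnnotationTable:
    """Filter GO-style annotations by evidence code.

    ``all`` keeps everything; ``drop_IEA`` removes electronically inferred
    terms; ``experimental_only`` keeps the standard experimental codes.
    Annotations without an evidence code are kept only under ``all``.
    """
    if mode == "all":
        keep = lambda ev: True
    elif mode == "drop_IEA":
        keep = lambda ev: ev != "IEA"
    elif mode == "experimental_only":
        keep = lambda ev: ev in experimental_codes
    else:
        raise ValueError(f"unknown evidence mode {mode!r}")
    out = AnnotationTable()
    for src, per_protein in table.sources.items():
        for pid, pairs in per_protein.items():
            for term, ev in pairs:
                if keep(ev):
                    out.add(pid, src, term, ev)
    return out


def richness(table: AnnotationTable, group: set[str], source: str,
             dag: OntologyDAG | None = None) -> float:
    """Mean number of (optionally de-redundified) terms per protein in a group.

    Proteins with no annotations for the source count as zero.
    """
    if not group:
        raise ValueError("empty protein group")
    total = 0
    for pid in group:
        terms = table.terms(pid, source)
        if dag is not None and terms:
            terms = filter_redundant_terms(terms, dag)
        total += len(terms)
    return total / len(group)
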