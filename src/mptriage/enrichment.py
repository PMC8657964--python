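"""Nested inclusive GO-DAG enrichment of a gene class versus the rest of genome.

Each gene class (SEMP/CPMP/ICMP) is compared against the rest of the tested
genome (ROG) term by term with a two-sided Fisher's exact test on the 2x2
table [[k_class, n_class - k_class], [k_rog, n_rog - k_rog]].  Terms are
tested level by level (level = shortest-path depth from the namespace root,
root = level 1), by default from level 3 to level 9, with Benjamini-Hochberg
adjustment within each level.  A significant term is reported as "deepest"
when no significant descendant of it was found within the tested levels, so
the headline output is an antichain in the DAG — one deepest significant
term per ancestry branch.

Annotations are propagated to all ancestors first (true-path rule), so a
gene annotated to a leaf also counts at every tested ancestor level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NAMESPACES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}
#: edge relations that define the ancestry used for propagation and levels
ANCESTRY_RELATIONS = ("is_a", "part_of")
DEFAULT_LEVELS = tuple(range(3, 10))


@dataclass
class GoDag:
    """Ontology structure: terms, child->parent edges, and root-depth levels."""

    names: dict[str, str]
    namespaces: dict[str, str]  # term -> BP | CC | MF
    parents: dict[str, set[str]]
    levels: dict[str, int]
    roots: dict[str, str]  # namespace code -> root term

    @property
    def graph(self) -> nx.DiGraph:
        """Child -> parent DiGraph (cached)."""
        g = getattr(self, "_graph", None)
        if g is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.names)
            for child, ps in self.parents.items():
                for p in ps:
                    g.add_edge(child, p)
            object.__setattr__(self, "_graph", g)
        return g

    def ancestors(self, term: str) -> set[str]:
        """All (proper) ancestors of ``term`` along is_a/part_of edges."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self.graph, term)

    def terms_at_level(self, level: int, namespace: str | None = None) -> list[str]:
        return [
            t
            for t, lv in self.levels.items()
            if lv == level and (namespace is None or self.namespaces[t] == namespace)
        ]


def build_dag(
    names: Mapping[str, str],
    namespaces: Mapping[str, str],
    parents: Mapping[str, Iterable[str]],
) -> GoDag:
    """Construct a :class:`GoDag` from explicit term data, validating shape.

    Roots are the terms without parents (one per namespace required); levels
    are shortest-path depths from the namespace root with root = 1.
    """
    parent_sets = {t: set(parents.get(t, ())) for t in names}
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for child, ps in parent_sets.items():
        for p in ps:
            if p not in names:
                raise ValueError(f"term {child} has unknown parent {p}")
            g.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    roots: dict[str, str] = {}
    for t in names:
        if not parent_sets[t]:
            ns = namespaces[t]
            if ns in roots:
                raise ValueError(f"namespace {ns} has multiple roots: {roots[ns]}, {t}")
            roots[ns] = t
    for t in names:
        if namespaces[t] not in roots:
            raise ValueError(f"namespace {namespaces[t]} has no root term")
    levels: dict[str, int] = {}
    rev = g.reverse()  # parent -> child for BFS from roots
    for ns, root in roots.items():
        depth = nx.single_source_shortest_path_length(rev, root)
        for t, d in depth.items():
            levels[t] = d + 1
    unreachable = set(names) - set(levels)
    if unreachable:
        raise ValueError(
            f"{len(unreachable)} term(s) unreachable from any root, "
            f"e.g. {sorted(unreachable)[:3]}"
        )
    return GoDag(
        names=dict(names),
        namespaces=dict(namespaces),
        parents=parent_sets,
        levels=levels,
        roots=roots,
    )


def load_ontology(obo_path: str) -> GoDag:
    """Read an OBO 1.2 file into a :class:`GoDag` (obsolete terms skipped)."""
    import obonet

    graph = obonet.read_obo(obo_path, ignore_obsolete=True)
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    default_ns = None
    for term, data in graph.nodes(data=True):
        names[term] = data.get("name", term)
        ns = data.get("namespace", default_ns)
        if ns is None:
            raise ValueError(f"term {term} lacks a namespace")
        namespaces[term] = NAMESPACES.get(ns, ns)
        ps = set(data.get("is_a", ()))
        for rel in data.get("relationship", ()):
            kind, _, target = rel.partition(" ")
            if kind == "part_of":
                ps.add(target.strip())
        parents[term] = ps
    # drop dangling parents (e.g. part_of targets pruned as obsolete)
    for t, ps in parents.items():
        parents[t] = {p for p in ps if p in names}
    return build_dag(names, namespaces, parents)


def propagate_annotations(
    raw: Mapping[str, Iterable[str]], dag: GoDag
) -> tuple[dict[str, frozenset[str]], int]:
    """Close each gene's annotation set under ancestry (true-path rule).

    Unknown term IDs are skipped; the count of skipped (gene, term) records
    is returned alongside the map.
    """
    anc_cache: dict[str, frozenset[str]] = {}

    def closed(term: str) -> frozenset[str]:
        if term not in anc_cache:
            anc_cache[term] = frozenset({term} | dag.ancestors(term))
        return anc_cache[term]

    out: dict[str, frozenset[str]] = {}
    skipped = 0
    for gene, terms in raw.items():
        acc: set[str] = set()
        for t in terms:
            if t not in dag.names:
                skipped += 1
                continue
            acc |= closed(t)
        out[gene] = frozenset(acc)
    return out, skipped


@dataclass
class EnrichmentRecord:
    """One term's 2x2 test result against the rest of genome."""

    term_id: str
    term_name: str
    namespace: str
    level: int
    k_class: int
    n_class: int
    k_rog: int
    n_rog: int
    odds_ratio: float
    p: float
    fdr_p: float = float("nan")
    deepest: bool = False


def fisher_term_test(
    class_genes: Iterable[str],
    rog_genes: Iterable[str],
    term: str,
    annot: Mapping[str, frozenset[str]],
    dag: GoDag,
) -> EnrichmentRecord:
    """Two-sided Fisher's exact test of one term, class vs rest of genome."""
    class_genes, rog_genes = set(class_genes), set(rog_genes)
    if not class_genes:
        raise ValueError("class gene list is empty")
    if class_genes & rog_genes:
        raise ValueError("class and ROG gene lists overlap")
    k_class = sum(1 for g in class_genes if term in annot.get(g, ()))
    k_rog = sum(1 for g in rog_genes if term in annot.get(g, ()))
    n_class, n_rog = len(class_genes), len(rog_genes)
    table = [[k_class, n_class - k_class], [k_rog, n_rog - k_rog]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentRecord(
        term_id=term,
        term_name=dag.names.get(term, term),
        namespace=dag.namespaces.get(term, "?"),
        level=dag.levels.get(term, -1),
        k_class=k_class,
        n_class=n_class,
        k_rog=k_rog,
        n_rog=n_rog,
        odds_ratio=float(odds),
        p=float(p),
    )


def nested_inclusive_analysis(
    class_genes: Iterable[str],
    rog_genes: Iterable[str],
    dag: GoDag,
    annot: Mapping[str, frozenset[str]],
    levels: Iterable[int] = DEFAULT_LEVELS,
    alpha: float = 0.05,
    namespaces: Iterable[str] = ("BP", "CC"),
) -> list[EnrichmentRecord]:
    """Level-wise enrichment with deepest-significant-term reporting.

    For each namespace and each level in ``levels``, every term at that level
    carried by at least one class gene is tested; p-values are BH-adjusted
    within the level.  After all levels, a significant term (adjusted
    p <= alpha) is flagged ``deepest`` when none of its descendants is also
    significant, so the flagged terms form an antichain: the deepest
    significant term of each branch.
    """
    levels = sorted(set(levels))
    if not levels:
        raise ValueError("level range is empty")
    class_genes, rog_genes = set(class_genes), set(rog_genes)
    records: list[EnrichmentRecord] = []
    for ns in namespaces:
        ns_records: list[EnrichmentRecord] = []
        for level in levels:
            terms = [
                t
                for t in dag.terms_at_level(level, namespace=ns)
                if any(t in annot.get(g, ()) for g in class_genes)
            ]
            if not terms:
                continue
            recs = [
                fisher_term_test(class_genes, rog_genes, t, annot, dag) for t in terms
            ]
            adj = multipletests([r.p for r in recs], method="fdr_bh")[1]
            for r, q in zip(recs, adj):
                r.fdr_p = float(q)
            ns_records.extend(recs)
        significant = {r.term_id for r in ns_records if r.fdr_p <= alpha}
        for r in ns_records:
            if r.term_id in significant:
                r.deepest = not (dag.descendants(r.term_id) & significant)
        records.extend(ns_records)
    return records


def records_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "namespace": r.namespace,
            "level": r.level,
            "k_class": r.k_class,
            "n_class": r.n_class,
            "k_rog": r.k_rog,
            "n_rog": r.n_rog,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
            "fdr_p": r.fdr_p,
            "deepest": r.deepest,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def deepest_terms(records: Iterable[EnrichmentRecord]) -> list[EnrichmentRecord]:
    return [r for r in records if r.deepest]


# -- synthetic ontology helper (testing / validation) -----------------------


def make_random_dag(
    n_terms: int,
    rng,
    namespace: str = "BP",
    max_parents: int = 2,
) -> GoDag:
    """A random single-namespace DAG for validation studies.

    Term ``T0`` is the root; each later term attaches to 1..max_parents
    earlier terms, which yields realistic diamond structures and a spread of
    shortest-path levels.
    """
    names = {f"T{i}": f"term {i}" for i in range(n_terms)}
    namespaces = {t: namespace for t in names}
    parents: dict[str, set[str]] = {"T0": set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        k = min(k, i)
        choice = rng.choice(i, size=k, replace=False)
        parents[f"T{i}"] = {f"T{j}" for j in choice}
    return build_dag(names, namespaces, parents)
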